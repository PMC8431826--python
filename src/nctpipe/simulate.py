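"""Synthetic connectomes and behavioral trial tables.

The connectome generator plants a weighted stochastic-block structure:
within-module edges appear with probability ``p_in``, between-module edges
with ``p_out``, and nonzero weights are drawn log-normally, emulating the
positive, right-skewed distribution of streamline densities. The behavioral
generator produces trial-level response times whose natural log follows a
linear fixed-effect structure (stimulation group, session, task, item
selection/retrieval demands, a per-subject boundary-controllability covariate
and their interactions) plus a subject random intercept, a subject random
slope on trial order, and Gaussian residual noise; a configurable share of
trials is contaminated with implausibly fast/slow responses and error flags,
mimicking the exclusions real data require.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .networks import Connectome

__all__ = [
    "ConnectomeGenConfig",
    "BehaviorGenConfig",
    "generate_connectome",
    "generate_trials",
]


@dataclasses.dataclass
class ConnectomeGenConfig:
    """Weighted stochastic-block connectome parameters.

    Defaults give a 111-region, 5-module network (roughly the size of an
    anatomical whole-brain parcellation with cerebellum) with an 8:1
    within/between edge-probability contrast and log-normal weights.
    """

    n_nodes: int = 111
    n_modules: int = 5
    p_in: float = 0.4
    p_out: float = 0.05
    weight_mu: float = 0.0       # log-scale mean of nonzero weights
    weight_sigma: float = 0.5    # log-scale SD of nonzero weights
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if self.n_modules < 2:
            raise ValueError("need at least 2 modules")
        if self.n_nodes < 2 * self.n_modules:
            raise ValueError("need n_nodes >= 2 * n_modules")
        if self.weight_sigma < 0:
            raise ValueError("weight_sigma must be >= 0")


def generate_connectome(cfg: ConnectomeGenConfig):
    """Draw a weighted SBM connectome; returns (Connectome, planted labels).

    Node 0 is labeled ``LIFG`` and designated the target node; modules are
    near-equal blocks of contiguous nodes.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_nodes
    planted = np.array_split(np.arange(n), cfg.n_modules)
    labels = np.empty(n, dtype=int)
    for m, idx in enumerate(planted):
        labels[idx] = m
    same = labels[:, None] == labels[None, :]
    p = np.where(same, cfg.p_in, cfg.p_out)
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < p[iu]
    w = np.zeros((n, n))
    weights = np.exp(rng.normal(cfg.weight_mu, cfg.weight_sigma, size=present.sum()))
    w[iu[0][present], iu[1][present]] = weights
    w = w + w.T
    region_labels = ("LIFG",) + tuple(f"region_{i:03d}" for i in range(1, n))
    conn = Connectome(labels=region_labels, weights=w, target_index=0)
    return conn, labels


@dataclasses.dataclass
class BehaviorGenConfig:
    """Fixed- and random-effect structure of the synthetic trial generator.

    All fixed-effect coefficients act on the natural-log RT scale with
    treatment coding: ``stimulation`` = 1 for the active group, ``session`` =
    1 post-stimulation, ``task`` = 1 for sentence completion (verb generation
    is the reference and carries the intercept). The boundary covariate is
    whatever per-subject value is passed to :func:`generate_trials` (in the
    full pipeline, the zero-centered boundary-controllability rank of the
    target node). Defaults follow the scale of published moderation analyses
    of this design: group sizes 25 active / 16 sham, 50 trials per task per
    session, a -0.003 three-way stimulation x session x boundary coefficient
    and a -0.088 stimulation x session coefficient.
    """

    n_active: int = 25
    n_sham: int = 16
    n_trials: int = 50           # per task per session
    beta_intercept: float = 7.233
    beta_stim: float = -0.030
    beta_session: float = 0.024
    beta_task_sc: float = -0.49          # sentence completion faster on average
    beta_boundary: float = -0.002
    beta_entropy: float = 0.155
    beta_association: float = -0.666
    beta_stim_session: float = -0.088
    beta_stim_boundary: float = 0.003
    beta_session_boundary: float = 0.0
    beta_stim_session_boundary: float = -0.003
    beta_entropy_boundary: float = 0.001
    beta_association_boundary: float = 0.0
    sd_intercept: float = 0.20           # subject random intercept SD (log s)
    sd_slope: float = 0.002              # subject trial-order random slope SD
    sd_resid: float = 0.30               # residual SD on the log-RT scale
    error_rate: float = 0.045            # incorrect-response flag rate
    fast_rate: float = 0.01              # contaminant RT < 200 ms
    slow_rate: float = 0.01              # contaminant RT > 10,000 ms
    entropy_beta: tuple = (2.0, 2.0)     # Beta law for item selection demand
    association_beta: tuple = (2.0, 2.0)  # Beta law for item retrieval demand
    seed: int = 0

    def __post_init__(self):
        for name in ("sd_intercept", "sd_slope", "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("error_rate", "fast_rate", "slow_rate"):
            r = getattr(self, name)
            if not (0 <= r < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.n_active < 1 or self.n_sham < 1 or self.n_trials < 1:
            raise ValueError("group sizes and trial counts must be >= 1")

    @property
    def n_subjects(self) -> int:
        return self.n_active + self.n_sham


_TASKS = ("sentence_completion", "verb_generation")
_SESSIONS = ("pre", "post")


def generate_trials(cfg: BehaviorGenConfig, boundary_values: Sequence[float],
                    modal_values: Sequence[float] | None = None) -> pd.DataFrame:
    """Simulate the long-format trial table for one cohort.

    ``boundary_values`` supplies one controllability covariate per subject
    (active subjects first). Item covariates (entropy, association) are drawn
    per item from Beta laws on [0, 1]. Contaminant trials receive response
    times outside [200, 10,000] ms; error trials are flagged independently.
    """
    boundary_values = np.asarray(boundary_values, dtype=float)
    if boundary_values.shape[0] != cfg.n_subjects:
        raise ValueError(
            f"need one boundary value per subject "
            f"({cfg.n_subjects}), got {boundary_values.shape[0]}"
        )
    if modal_values is not None:
        modal_values = np.asarray(modal_values, dtype=float)
        if modal_values.shape[0] != cfg.n_subjects:
            raise ValueError("modal_values length does not match subject count")
    rng = np.random.default_rng(cfg.seed)
    u0 = rng.normal(0.0, cfg.sd_intercept, cfg.n_subjects)
    u1 = rng.normal(0.0, cfg.sd_slope, cfg.n_subjects)
    rows = []
    item_counter = 0
    for s in range(cfg.n_subjects):
        group = "active" if s < cfg.n_active else "sham"
        stim = 1.0 if group == "active" else 0.0
        b = boundary_values[s]
        for session in _SESSIONS:
            sess = 1.0 if session == "post" else 0.0
            for task in _TASKS:
                tsc = 1.0 if task == "sentence_completion" else 0.0
                ent = rng.beta(*cfg.entropy_beta, cfg.n_trials)
                assoc = rng.beta(*cfg.association_beta, cfg.n_trials)
                lp = (
                    cfg.beta_intercept
                    + cfg.beta_stim * stim
                    + cfg.beta_session * sess
                    + cfg.beta_task_sc * tsc
                    + cfg.beta_boundary * b
                    + cfg.beta_entropy * ent
                    + cfg.beta_association * assoc
                    + cfg.beta_stim_session * stim * sess
                    + cfg.beta_stim_boundary * stim * b
                    + cfg.beta_session_boundary * sess * b
                    + cfg.beta_stim_session_boundary * stim * sess * b
                    + cfg.beta_entropy_boundary * ent * b
                    + cfg.beta_association_boundary * assoc * b
                )
                order = np.arange(1, cfg.n_trials + 1)
                log_rt = lp + u0[s] + u1[s] * order \
                    + rng.normal(0.0, cfg.sd_resid, cfg.n_trials)
                rt = np.exp(log_rt)
                contam = rng.random(cfg.n_trials)
                fast = contam < cfg.fast_rate
                slow = (contam >= cfg.fast_rate) & (contam < cfg.fast_rate + cfg.slow_rate)
                rt[fast] = rng.uniform(50.0, 199.0, fast.sum())
                rt[slow] = rng.uniform(10001.0, 15000.0, slow.sum())
                is_err = rng.random(cfg.n_trials) < cfg.error_rate
                for t in range(cfg.n_trials):
                    rows.append(
                        (
                            f"sub{s:03d}", group, session, task, int(order[t]),
                            f"item{item_counter + t:05d}", ent[t], assoc[t],
                            rt[t], bool(is_err[t]), b,
                            modal_values[s] if modal_values is not None else np.nan,
                        )
                    )
                item_counter += cfg.n_trials
    df = pd.DataFrame(
        rows,
        columns=[
            "subject", "group", "session", "task", "trial_order", "item_id",
            "entropy", "association", "rt_ms", "is_error", "boundary", "modal",
        ],
    )
    if modal_values is None:
        df = df.drop(columns=["modal"])
    return df
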