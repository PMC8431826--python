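"""End-to-end orchestration: networks -> controllability -> behavior models.

A run either loads a user-supplied connectome / trial table or simulates a
cohort (one connectome per subject). For every subject's network the pipeline
stabilizes the adjacency, computes modal controllability, sweeps the
modularity resolution, builds the consensus partition, and ranks boundary
controllability; the target node's zero-centered modal and boundary ranks
become per-subject covariates of the behavioral mixed models. All stage
outputs are TSV; a JSON manifest records the configuration, every derived
seed and the SHA-256 of every output so a run can be reproduced and verified
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (
    GammaSweepConsensus,
    boundary_controllability,
    boundary_table,
    partition_table,
    sweep_table,
)
from .control import ModalControllability, node_metrics_table
from .networks import Connectome, load_connectome, stabilize, write_connectome
from .simulate import BehaviorGenConfig, ConnectomeGenConfig, generate_connectome, generate_trials
from .stats import compare_groups_boundary, fit_model, preprocess

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("nctpipe")

DEFAULT_MODELS = (
    "both_tasks_boundary_tms",
    "sham_session_SC",
    "tms_session_SC",
    "tms_session_boundary_SC",
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either supply input paths (``adjacency_path`` + ``labels_path`` and/or
    ``trials_path``) or leave them unset to simulate a cohort from the
    generator configs. Orchestration sizes (``gamma_step``, ``n_opt``) default
    to a coarser sweep than the single-network module defaults so a full
    per-subject cohort run stays interactive; both are configurable.
    """

    out_dir: str = "nctpipe_run"
    seed: int = 0
    adjacency_path: str | None = None
    labels_path: str | None = None
    volumes_path: str | None = None
    trials_path: str | None = None
    target_label: str = "LIFG"
    stabilize_mode: str = "mean-edge"
    gamma_min: float = 1.0
    gamma_max: float = 4.0
    gamma_step: float = 0.5
    n_opt: int = 20
    models: Sequence[str] = DEFAULT_MODELS
    connectome: dict = dataclasses.field(default_factory=dict)
    behavior: dict = dataclasses.field(default_factory=dict)

    @property
    def gamma_grid(self) -> np.ndarray:
        n = int(round((self.gamma_max - self.gamma_min) / self.gamma_step)) + 1
        return np.round(self.gamma_min + self.gamma_step * np.arange(n), 10)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _network_stage(conn: Connectome, cfg: RunConfig, sweep_seed: int):
    """Stabilize, modal phi, gamma sweep + consensus, boundary ranking."""
    A = stabilize(conn, mode=cfg.stabilize_mode)
    modal = ModalControllability().fit(A)
    sweep = GammaSweepConsensus(
        gammas=cfg.gamma_grid, n_opt=cfg.n_opt, seed=sweep_seed
    ).fit(conn.weights)
    boundary = boundary_controllability(conn.weights, sweep.labels_)
    phi_rank = np.empty(conn.n_nodes, dtype=int)
    phi_rank[np.argsort(-modal.phi_, kind="stable")] = np.arange(1, conn.n_nodes + 1)
    return A, modal, sweep, boundary, phi_rank


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(ss.generate_state(1)[0] % (2 ** 31))
        for name, ss in zip(
            ("connectomes", "sweeps", "behavior"), master.spawn(3)
        )
    }
    manifest: dict = {
        "package": "nctpipe",
        "version": __version__,
        "config": config.to_dict(),
        "seeds": seeds,
        "stages": [],
        "outputs": {},
    }
    outputs: list[Path] = []

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
            log.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
            manifest["stages"].append(name)
            return result
        return deco

    # ---- connectome stage -------------------------------------------------
    @stage("connectome")
    def conns():
        if config.adjacency_path is not None:
            if config.labels_path is None:
                raise ValueError("adjacency_path given without labels_path")
            conn = load_connectome(
                config.adjacency_path, config.labels_path, config.volumes_path,
                target_label=config.target_label,
            )
            if conn.volumes is not None:
                from .networks import normalize_by_volume

                conn = conn.with_weights(
                    normalize_by_volume(conn.weights, conn.volumes)
                )
            return [conn]
        beh = BehaviorGenConfig(**{**config.behavior, "seed": seeds["behavior"]})
        rng = np.random.default_rng(seeds["connectomes"])
        result = []
        for s in range(beh.n_subjects):
            ccfg = ConnectomeGenConfig(
                **{**config.connectome, "seed": int(rng.integers(0, 2 ** 31))}
            )
            result.append(generate_connectome(ccfg)[0])
        return result

    # ---- controllability stage -------------------------------------------
    @stage("controllability")
    def network_results():
        rng = np.random.default_rng(seeds["sweeps"])
        results = []
        for conn in conns:
            results.append(_network_stage(conn, config, int(rng.integers(0, 2 ** 31))))
        return results

    exemplar = conns[0]
    A0, modal0, sweep0, boundary0, _ = network_results[0]
    write_connectome(exemplar, out / "connectome.tsv", out / "labels.txt")
    outputs += [out / "connectome.tsv", out / "labels.txt"]
    _write_tsv(node_metrics_table(exemplar.labels, exemplar.weights, modal0.phi_),
               out / "node_metrics.tsv")
    _write_tsv(sweep_table(sweep0.sweep_result_), out / "gamma_sweep.tsv")
    _write_tsv(partition_table(exemplar.labels, sweep0.sweep_result_.consensus),
               out / "partition.tsv")
    _write_tsv(boundary_table(exemplar.labels, boundary0), out / "boundary.tsv")
    outputs += [out / "node_metrics.tsv", out / "gamma_sweep.tsv",
                out / "partition.tsv", out / "boundary.tsv"]

    # ---- per-subject covariates ------------------------------------------
    @stage("covariates")
    def covariates():
        rows = []
        for i, (conn, (A, modal, sweep, boundary, phi_rank)) in enumerate(
            zip(conns, network_results)
        ):
            t = conn.target_index
            n = conn.n_nodes
            rows.append(
                {
                    "subject": f"sub{i:03d}",
                    "boundary": float(boundary.centered_rank[t]),
                    "modal": float(phi_rank[t] - (n + 1) / 2.0),
                    "selected_gamma": sweep.selected_gamma_,
                }
            )
        return pd.DataFrame(rows)

    # ---- behavior stage ---------------------------------------------------
    @stage("behavior")
    def trials_raw():
        if config.trials_path is not None:
            return pd.read_csv(config.trials_path, sep="\t")
        if config.adjacency_path is not None:
            raise ValueError(
                "no behavioral input: supply trials_path or omit adjacency_path "
                "to simulate a cohort"
            )
        beh = BehaviorGenConfig(**{**config.behavior, "seed": seeds["behavior"]})
        if len(covariates) != beh.n_subjects:
            raise ValueError("covariate rows do not match subject count")
        return generate_trials(
            beh,
            boundary_values=covariates["boundary"].to_numpy(),
            modal_values=covariates["modal"].to_numpy(),
        )

    _write_tsv(covariates, out / "subject_covariates.tsv")
    _write_tsv(trials_raw, out / "trials.tsv")
    outputs += [out / "subject_covariates.tsv", out / "trials.tsv"]

    # ---- preprocessing ----------------------------------------------------
    @stage("preprocess")
    def preprocessed():
        return preprocess(trials_raw)

    clean, report = preprocessed
    _write_tsv(report, out / "exclusion_report.tsv")
    outputs.append(out / "exclusion_report.tsv")

    # ---- model fits -------------------------------------------------------
    @stage("fit")
    def fits():
        results = {}
        fits_dir = out / "fits"
        fits_dir.mkdir(exist_ok=True)
        for model_id in config.models:
            fit = fit_model(clean, model_id)
            tab = fit.fixed_effects.assign(
                converged=fit.converged, n_obs=fit.n_obs, df_method=fit.df_method
            )
            path = fits_dir / f"{model_id}.tsv"
            _write_tsv(tab, path)
            outputs.append(path)
            results[model_id] = fit
        return results

    # ---- post hoc group comparison ---------------------------------------
    @stage("group_comparison")
    def wilcoxon():
        if "group" not in trials_raw.columns or "boundary" not in trials_raw.columns:
            return None
        subj = trials_raw.groupby("subject", observed=True).agg(
            group=("group", "first"), boundary=("boundary", "first")
        )
        if subj["boundary"].isna().any() or subj["group"].nunique() != 2:
            return None
        return compare_groups_boundary(subj["boundary"].to_numpy(),
                                       subj["group"].to_numpy())

    if wilcoxon is not None:
        (out / "group_comparison.json").write_text(
            json.dumps(wilcoxon, indent=2, sort_keys=True) + "\n"
        )
        outputs.append(out / "group_comparison.json")

    manifest["outputs"] = {p.name if p.parent == out else f"fits/{p.name}": _sha256(p)
                           for p in outputs}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
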