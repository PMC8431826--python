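"""Behavioral preprocessing and mixed-effects moderation models.

Response times are cleaned (error trials and responses outside 200-10,000 ms
are excluded), log-transformed, and modeled with linear mixed-effects
regressions: maximum likelihood, a random intercept per subject and a random
slope for trial order per subject. Item demand covariates are median-split
per task for categorical interactions and mean-centered per task when left
continuous for interactions with the controllability covariates. Fixed-effect
tests use Wald statistics with residual degrees of freedom (flagged in the
output, since a Satterthwaite approximation is not available through the
fitting backend used here).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
import yaml

__all__ = [
    "ModelFit",
    "load_registry",
    "preprocess",
    "split_demands",
    "fit_model",
    "compare_groups_boundary",
    "MixedEffectsRT",
]

RT_MIN_MS = 200.0
RT_MAX_MS = 10_000.0

_REQUIRED = ["subject", "group", "session", "task", "trial_order", "rt_ms", "is_error"]


def load_registry() -> dict:
    """Model families (fixed-effect formula, row filter, needed covariates)."""
    text = (importlib.resources.files("nctpipe") / "model_registry.yaml").read_text()
    return yaml.safe_load(text)


def preprocess(trials: pd.DataFrame):
    """Drop error trials and out-of-range RTs; add the log-RT column.

    Responses faster than 200 ms or slower than 10,000 ms are excluded along
    with flagged error trials. Returns ``(clean, report)`` where the report
    counts exclusions by session, task and group.
    """
    missing = [c for c in _REQUIRED if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    bad = (
        trials["is_error"].astype(bool)
        | (trials["rt_ms"] < RT_MIN_MS)
        | (trials["rt_ms"] > RT_MAX_MS)
    )
    report = (
        trials.assign(excluded=bad)
        .groupby(["session", "task", "group"], observed=True)["excluded"]
        .agg(n_total="count", n_excluded="sum")
        .reset_index()
    )
    report["pct_excluded"] = 100.0 * report["n_excluded"] / report["n_total"]
    clean = trials.loc[~bad].copy()
    if clean.empty:
        raise ValueError("no trials remain after exclusion")
    clean["log_rt"] = np.log(clean["rt_ms"])
    return clean, report


def split_demands(trials: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Median-split an item covariate per task and center the continuous form.

    Adds ``<variable>_split`` ("low"/"high"; values at or below the per-task
    median go to "low") and ``<variable>_c`` (per-task mean-centered).
    """
    if variable not in ("entropy", "association"):
        raise ValueError("variable must be 'entropy' or 'association'")
    if variable not in trials.columns:
        raise ValueError(f"column {variable!r} not present")
    out = trials.copy()
    split_col, cent_col = f"{variable}_split", f"{variable}_c"
    out[split_col] = ""
    out[cent_col] = np.nan
    for task, idx in out.groupby("task", observed=True).groups.items():
        vals = out.loc[idx, variable].astype(float)
        if vals.nunique() < 2:
            raise ValueError(f"{variable} is constant within task {task!r}; split undefined")
        med = vals.median()
        out.loc[idx, split_col] = np.where(vals <= med, "low", "high")
        out.loc[idx, cent_col] = vals - vals.mean()
    return out


@dataclasses.dataclass
class ModelFit:
    """Fixed-effect table and diagnostics for one mixed-model family."""

    model_id: str
    fixed_effects: pd.DataFrame          # term, estimate, ci_low, ci_high, df, statistic, p
    random_effect_variances: dict
    n_obs: int
    converged: bool
    df_method: str                       # "residual" fallback is flagged here
    loglike: float

    def __getitem__(self, term: str) -> pd.Series:
        row = self.fixed_effects.loc[self.fixed_effects["term"] == term]
        if row.empty:
            raise KeyError(term)
        return row.iloc[0]


def _derive_columns(df: pd.DataFrame, needs: Sequence[str]) -> pd.DataFrame:
    out = df.copy()
    out["stimulation"] = (out["group"] == "active").astype(float)
    out["session_post"] = (out["session"] == "post").astype(float)
    out["task_sc"] = (out["task"] == "sentence_completion").astype(float)
    for need in needs:
        if need in ("boundary", "modal"):
            if need not in out.columns or out[need].isna().any():
                raise ValueError(f"model requires a {need!r} covariate column")
        elif need.endswith("_split"):
            var = need[: -len("_split")]
            if f"{var}_split" not in out.columns:
                out = split_demands(out, var)
        else:
            raise ValueError(f"unknown covariate requirement {need!r}")
    for var in ("entropy", "association"):
        if f"{var}_split" in out.columns:
            out[f"{var}_high"] = (out[f"{var}_split"] == "high").astype(float)
    return out


class MixedEffectsRT:
    """Registered mixed-effects model of log response times.

    Estimator-style interface: construct with a ``model_id`` from the
    registry, call :meth:`fit` on a preprocessed trial table, then read
    ``result_`` (a :class:`ModelFit`). A thin functional wrapper is
    :func:`fit_model`.

    Parameters
    ----------
    model_id : str
        Key into the model registry.
    drop_slope : bool, default False
        Fit only the random intercept (no trial-order random slope).
    """

    def __init__(self, model_id: str, drop_slope: bool = False):
        self.model_id = model_id
        self.drop_slope = drop_slope

    def get_params(self, deep=True):
        return {"model_id": self.model_id, "drop_slope": self.drop_slope}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, trials: pd.DataFrame):
        registry = load_registry()
        if self.model_id not in registry:
            raise KeyError(
                f"unknown model_id {self.model_id!r}; "
                f"known: {sorted(registry)}"
            )
        spec = registry[self.model_id]
        df = trials
        for col, value in (spec.get("filter") or {}).items():
            key = {"session": "session", "task": "task", "group": "group"}[col]
            df = df.loc[df[key] == value]
        if df.empty:
            raise ValueError(f"no rows left after filtering for {self.model_id!r}")
        df = _derive_columns(df, spec.get("needs") or [])
        if "log_rt" not in df.columns:
            raise ValueError("trial table lacks log_rt; run preprocess first")
        # standardized trial order keeps the random-slope variance on a
        # numerically comfortable scale; fixed effects stay on raw units
        sd = df["trial_order"].std()
        df = df.assign(
            trial_order_z=(df["trial_order"] - df["trial_order"].mean()) / (sd if sd > 0 else 1.0)
        )
        re_formula = "~1" if self.drop_slope else "~trial_order_z"
        formula = f"log_rt ~ {spec['fixed']}"
        model = smf.mixedlm(formula, df, groups=df["subject"], re_formula=re_formula)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=False, method="lbfgs", maxiter=200)
            if not res.converged:
                # one retry from a different optimizer path / start values
                res = model.fit(reml=False)
        fe = res.fe_params
        se = res.bse_fe
        n_obs = int(df.shape[0])
        df_resid = max(n_obs - len(fe), 1)
        tstat = fe / se
        p = 2.0 * scipy.stats.t.sf(np.abs(tstat), df_resid)
        crit = scipy.stats.t.ppf(0.975, df_resid)
        table = pd.DataFrame(
            {
                "term": fe.index,
                "estimate": fe.values,
                "ci_low": fe.values - crit * se.values,
                "ci_high": fe.values + crit * se.values,
                "df": float(df_resid),
                "statistic": tstat.values,
                "p": p,
            }
        ).reset_index(drop=True)
        re_var = {"subject_intercept_var": float(res.cov_re.iloc[0, 0])}
        if not self.drop_slope:
            re_var["trial_order_slope_var"] = float(res.cov_re.iloc[1, 1])
            re_var["intercept_slope_cov"] = float(res.cov_re.iloc[0, 1])
        re_var["residual_var"] = float(res.scale)
        self.result_ = ModelFit(
            model_id=self.model_id,
            fixed_effects=table,
            random_effect_variances=re_var,
            n_obs=n_obs,
            converged=bool(res.converged),
            df_method="residual",
            loglike=float(res.llf),
        )
        self.backend_result_ = res
        return self


def fit_model(trials: pd.DataFrame, model_id: str, drop_slope: bool = False) -> ModelFit:
    """Fit one registered model family; see :class:`MixedEffectsRT`."""
    return MixedEffectsRT(model_id, drop_slope=drop_slope).fit(trials).result_


def compare_groups_boundary(values: Sequence[float], groups: Sequence[str]) -> dict:
    """Wilcoxon (Mann-Whitney) rank-sum comparison of per-subject values.

    Two-sided test of the ``active`` versus ``sham`` group distributions.
    Returns the U statistic of the active group, the two-sided p value and
    the group sizes.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    x = values[groups == "active"]
    y = values[groups == "sham"]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
    return {
        "W": float(res.statistic),
        "p": float(res.pvalue),
        "n_active": int(x.size),
        "n_sham": int(y.size),
    }
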