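"""Robustness and heterogeneity procedures around the ESP estimate.

Three checks are provided, mirroring common practice for survey-based
treatment-effect studies:

* ``refit_excluding`` — drop a rule-defined slice of the sample (e.g.
  farmers over 70, whose age-related health decline could contaminate
  the effect) and re-estimate the full system;
* ``psm_att`` — 1:1 nearest-neighbour propensity score matching, a
  selection-on-observables benchmark for the ESP estimate;
* ``subgroup_att`` — full ESP refit and ATT within sample partitions
  (e.g. working in vs. outside the home village; eastern vs. other
  regions) to expose effect heterogeneity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .esp_probit import ATTReport, ESPData, ESPEstimate, att_esp, fit_esp

__all__ = [
    "PSMOptions",
    "SubgroupSpec",
    "SubgroupResult",
    "RefitResult",
    "psm_att",
    "subgroup_att",
    "refit_excluding",
    "balance_table",
]


@dataclass(frozen=True)
class PSMOptions:
    """1:1 nearest-neighbour matching options.

    The propensity model regresses treatment on the outcome covariates
    (never the instrument).  Matching is greedy in descending treated
    propensity order, without replacement by default; an optional
    caliper discards treated units with no control within the distance.
    """

    model: str = "probit"
    replacement: bool = False
    caliper: float | None = None
    seed: int = 0
    bootstrap_reps: int = 200

    def __post_init__(self) -> None:
        if self.model not in ("probit", "logit"):
            raise ValueError("model must be 'probit' or 'logit'")
        if self.caliper is not None and self.caliper <= 0:
            raise ValueError("caliper must be positive if set")


@dataclass(frozen=True)
class SubgroupSpec:
    """A partition variable and the labels of its levels."""

    variable: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError("need at least two subgroup levels")


@dataclass
class SubgroupResult:
    level: str
    report: ATTReport | None
    estimate: ESPEstimate | None
    n: int
    skipped_reason: str | None = None


@dataclass
class RefitResult:
    estimate: ESPEstimate
    report: ATTReport
    rule: str
    n_removed: int
    n_kept: int


def _propensity(data: ESPData, model: str) -> np.ndarray:
    mod = sm.Probit if model == "probit" else sm.Logit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mod(data.treat, data.X).fit(disp=0, maxiter=200, warn_convergence=False)
    return np.asarray(res.predict(data.X), dtype=float)


def _match(
    score_t: np.ndarray,
    score_c: np.ndarray,
    replacement: bool,
    caliper: float | None,
):
    """Greedy nearest-neighbour pairs; returns (treated_idx, control_idx)."""
    order = np.argsort(-score_t, kind="stable")
    if replacement:
        pairs_t, pairs_c = [], []
        for i in order:
            d = np.abs(score_c - score_t[i])
            j = int(np.argmin(d))
            if caliper is not None and d[j] > caliper:
                continue
            pairs_t.append(i)
            pairs_c.append(j)
        return np.array(pairs_t, int), np.array(pairs_c, int)
    if caliper is None and score_c.size < score_t.size:
        raise ValueError("more treated than controls: matching without replacement impossible")
    avail = np.ones(score_c.size, dtype=bool)
    pairs_t, pairs_c = [], []
    for i in order:
        if not avail.any():
            if caliper is None:
                raise ValueError("ran out of controls while matching without replacement")
            break
        d = np.where(avail, np.abs(score_c - score_t[i]), np.inf)
        j = int(np.argmin(d))
        if caliper is not None and d[j] > caliper:
            continue
        pairs_t.append(i)
        pairs_c.append(j)
        avail[j] = False
    if not pairs_t:
        raise ValueError("empty common support after caliper")
    return np.array(pairs_t, int), np.array(pairs_c, int)


def _psm_point(data: ESPData, options: PSMOptions):
    score = _propensity(data, options.model)
    t = data.treat == 1
    it, ic = np.flatnonzero(t), np.flatnonzero(~t)
    pt, pc = _match(score[it], score[ic], options.replacement, options.caliper)
    y_t = data.y[it[pt]].astype(float)
    y_c = data.y[ic[pc]].astype(float)
    return float(y_t.mean()), float(y_c.mean()), len(pt)


def psm_att(data: ESPData, options: PSMOptions = PSMOptions()) -> ATTReport:
    """PSM ATT: mean outcome of matched treated minus matched controls.

    The SE is a paired bootstrap over villages (propensity refit and
    matching redone in every replicate), honouring the survey's cluster
    structure.
    """
    p_t, p_c, n_matched = _psm_point(data, options)
    se = np.nan
    if options.bootstrap_reps > 0:
        rng = np.random.default_rng(options.seed)
        villages = pd.unique(data.cluster)
        idx_by_v = {v: np.flatnonzero(data.cluster == v) for v in villages}
        draws = []
        for _ in range(options.bootstrap_reps):
            chosen = rng.choice(villages, size=villages.size, replace=True)
            idx = np.concatenate([idx_by_v[v] for v in chosen])
            try:
                bt, bc, _ = _psm_point(data.subset_rows(idx), options)
                draws.append(bt - bc)
            except (ValueError, np.linalg.LinAlgError):
                continue
        if len(draws) >= 10:
            se = float(np.std(draws, ddof=1))
        else:
            warnings.warn("too few successful PSM bootstrap replicates", stacklevel=2)
    return ATTReport.from_probabilities(
        p_treated=p_t,
        p_counterfactual=p_c,
        se=se,
        method="PSM",
        n_treated=n_matched,
        bootstrap_reps=options.bootstrap_reps,
    )


def balance_table(data: ESPData, options: PSMOptions = PSMOptions()) -> pd.DataFrame:
    """Standardized mean differences of X before and after matching."""
    score = _propensity(data, options.model)
    t = data.treat == 1
    it, ic = np.flatnonzero(t), np.flatnonzero(~t)
    pt, pc = _match(score[it], score[ic], options.replacement, options.caliper)
    rows = []
    for j, name in enumerate(data.x_names):
        if name == "const":
            continue
        xt, xc = data.X[it, j], data.X[ic, j]
        pooled = np.sqrt((xt.var(ddof=1) + xc.var(ddof=1)) / 2.0)
        smd_pre = (xt.mean() - xc.mean()) / pooled if pooled > 0 else 0.0
        mt, mc = data.X[it[pt], j], data.X[ic[pc], j]
        smd_post = (mt.mean() - mc.mean()) / pooled if pooled > 0 else 0.0
        rows.append({"variable": name, "smd_pre": smd_pre, "smd_post": smd_post})
    return pd.DataFrame(rows).set_index("variable")


def subgroup_att(
    data: ESPData,
    labels,
    spec: SubgroupSpec,
    fit_kwargs: dict | None = None,
    att_kwargs: dict | None = None,
) -> list[SubgroupResult]:
    """ESP refit + ATT per subgroup level.

    ``labels`` must assign every row to one of ``spec.levels`` (a true
    partition).  Subgroups where the system cannot be fitted (too small,
    one-armed, separated) are reported as skipped rather than crashing
    the run.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != data.n:
        raise ValueError("labels length must match data")
    extra = set(np.unique(labels)) - set(spec.levels)
    if extra:
        raise ValueError(f"labels outside declared levels: {sorted(extra)}")
    results = []
    for level in spec.levels:
        mask = labels == level
        n_level = int(mask.sum())
        if n_level == 0:
            results.append(
                SubgroupResult(level, None, None, 0, skipped_reason="empty subgroup")
            )
            continue
        try:
            sub = data.subset_rows(mask)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = fit_esp(sub, **(fit_kwargs or {}))
                if not est.converged:
                    results.append(
                        SubgroupResult(
                            level, None, None, n_level,
                            skipped_reason="ESP fit did not converge",
                        )
                    )
                    continue
                rep = att_esp(est, sub, **(att_kwargs or {"bootstrap_reps": 0}))
            results.append(SubgroupResult(level, rep, est, n_level))
        except (ValueError, np.linalg.LinAlgError) as exc:
            results.append(
                SubgroupResult(level, None, None, n_level, skipped_reason=str(exc))
            )
    return results


def refit_excluding(
    data: ESPData,
    exclude,
    rule: str = "",
    fit_kwargs: dict | None = None,
    att_kwargs: dict | None = None,
) -> RefitResult:
    """Re-run the ESP pipeline on the sample with ``exclude`` rows dropped.

    ``exclude`` is a boolean mask aligned with the data rows (True =
    drop); ``rule`` records the provenance of the filter in the result.
    """
    exclude = np.asarray(exclude, dtype=bool)
    if exclude.shape[0] != data.n:
        raise ValueError("exclude mask length must match data")
    keep = ~exclude
    sub = data.subset_rows(keep)  # raises if an arm was emptied
    est = fit_esp(sub, **(fit_kwargs or {}))
    rep = att_esp(est, sub, **(att_kwargs or {"bootstrap_reps": 0}))
    return RefitResult(
        estimate=est,
        report=rep,
        rule=rule,
        n_removed=int(exclude.sum()),
        n_kept=int(keep.sum()),
    )
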