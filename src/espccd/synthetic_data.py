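"""Village-clustered synthetic farmer populations with known ground truth.

The survey this pipeline targets (rural household microdata with village
clustering) is restricted, so every downstream stage is exercised on
synthetic populations whose data-generating process is known exactly.

Two generation modes are supported:

``model``
    Outcomes are drawn directly from the latent switching-probit system:
    treatment is 1{gamma'Z + u > 0} with a village-level instrument in
    Z, and both potential outcomes Y1 = 1{beta1'X + eps1 > 0},
    Y0 = 1{beta0'X + eps0 > 0} are recorded for every farmer.  (u, eps1,
    eps0) are trivariate normal with corr(u, eps1) = rho1,
    corr(u, eps0) = rho0 and corr(eps1, eps0) = 0 — the two outcome
    errors are never jointly observed, so this completion is harmless
    for identification and keeps the covariance valid whenever
    rho1^2 + rho0^2 <= 1.  Used for estimator recovery studies.

``structural``
    Work intensity comes from weekly hours (village effect + individual
    noise, flagged by the mean threshold); latent health and income
    levels respond to the work flag; raw indicator columns are emitted
    as noisy monotone transforms of the latent levels so the entropy /
    CCD stages see realistic structure.  Used for end-to-end pipeline
    tests.  Potential outcomes are the balance class computed from the
    latent levels under each work regime.

A shared village random effect enters both weekly hours and the
selection side, which is what makes the leave-one-out village share of
high-intensity workers a relevant instrument.

Default covariate marginals are calibrated to the descriptive statistics
of a national rural labour-force survey (working share about 0.504,
male share 0.544, married 0.919, insured 0.119, and so on); only the
marginal means/spreads are matched — the joint distribution is a
stand-in.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ccd import CCDConfig, classify_balance, coupling_coordination, coupling_degree, coordination_index

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "generate_population",
    "true_att",
    "default_indicator_schema",
    "write_population",
]

# Table-3-style marginal means (binary unless noted)
_DEFAULT_MARGINALS = {
    "gender": 0.544,
    "marriage": 0.919,
    "party": 0.037,
    "insurance": 0.119,
    "internet": 0.443,
    "pop_total_mean": 3.429,
    "pop_total_sd": 2.052,
    "pop_labor_mean": 1.140,
    "pop_labor_sd": 1.446,
    "offfarm": 0.174,
    "sanitary": 0.831,
    "park": 0.468,
    "land": 0.577,
    "eastern": 0.35,
    "native": 0.70,
}

_DEFAULT_GAMMA = {
    "const": -1.55,
    "gender": 0.15,
    "insurance": 0.11,
    "internet": 0.05,
    "lnpop_total": 0.05,
    "iv": 2.59,
}
_DEFAULT_BETA1 = {
    "const": -1.25,
    "gender": -0.04,
    "insurance": 0.18,
    "internet": 0.19,
    "lnpop_total": -0.24,
}
_DEFAULT_BETA0 = {
    "const": -0.95,
    "gender": 0.05,
    "insurance": 0.39,
    "internet": 0.22,
    "lnpop_total": 0.05,
}


@dataclass
class SyntheticConfig:
    """Ground-truth parameters and population layout.

    ``gamma`` names the selection covariates (the last entries may be
    village-level instruments), ``beta1``/``beta0`` the regime outcome
    covariates; both refer to generated columns by name, ``const``
    denoting the intercept.  ``rho1``/``rho0`` are the selection-outcome
    error correlations.  Village sizes are drawn uniformly from
    ``village_size_range`` (min >= 2 so the leave-one-out instrument
    denominator is at least 1).
    """

    n_villages: int = 497
    village_size_range: tuple[int, int] = (4, 13)
    mode: str = "structural"
    gamma: dict = field(default_factory=lambda: dict(_DEFAULT_GAMMA))
    beta1: dict = field(default_factory=lambda: dict(_DEFAULT_BETA1))
    beta0: dict = field(default_factory=lambda: dict(_DEFAULT_BETA0))
    rho1: float = 0.25
    rho0: float = 0.10
    covariate_marginals: dict = field(default_factory=lambda: dict(_DEFAULT_MARGINALS))
    hours_mean: float = 48.0
    hours_village_sd: float = 6.0
    hours_indiv_sd: float = 12.0
    # structural-mode latent levels on the [0, 1] scale
    health_base: float = 0.50
    income_base: float = 0.42
    health_effect: float = -0.10  # shift of health level under high-intensity work
    income_effect: float = 0.03
    factor_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.village_size_range[0] < 2:
            raise ValueError("village_size_range minimum must be >= 2")
        if self.village_size_range[0] > self.village_size_range[1]:
            raise ValueError("village_size_range must be (min, max) with min <= max")
        if not (abs(self.rho1) < 1 and abs(self.rho0) < 1):
            raise ValueError("|rho1| and |rho0| must be < 1")
        if self.rho1**2 + self.rho0**2 > 1.0:
            raise ValueError(
                "rho1^2 + rho0^2 must be <= 1 for a valid trivariate error "
                "covariance with corr(eps1, eps0) = 0"
            )
        if self.mode not in ("model", "structural"):
            raise ValueError("mode must be 'model' or 'structural'")
        if self.n_villages < 2:
            raise ValueError("need at least 2 villages")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["village_size_range"] = list(self.village_size_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["village_size_range"] = tuple(d["village_size_range"])
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth accompanying a generated population.

    Carries the true parameters, the latent error draws (model mode)
    or latent health/income levels (structural mode), and both
    potential outcomes for every farmer.
    """

    params: dict
    Y1: np.ndarray
    Y0: np.ndarray
    u: np.ndarray | None = None
    eps1: np.ndarray | None = None
    eps0: np.ndarray | None = None
    health_latent: np.ndarray | None = None
    income_latent: np.ndarray | None = None

    def to_json(self, path) -> None:
        def conv(x):
            return None if x is None else np.asarray(x).tolist()

        payload = {
            "params": self.params,
            "Y1": conv(self.Y1),
            "Y0": conv(self.Y0),
            "u": conv(self.u),
            "eps1": conv(self.eps1),
            "eps0": conv(self.eps0),
            "health_latent": conv(self.health_latent),
            "income_latent": conv(self.income_latent),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        payload = json.loads(Path(path).read_text())

        def arr(x):
            return None if x is None else np.asarray(x)

        return cls(
            params=payload["params"],
            Y1=np.asarray(payload["Y1"]),
            Y0=np.asarray(payload["Y0"]),
            u=arr(payload["u"]),
            eps1=arr(payload["eps1"]),
            eps0=arr(payload["eps0"]),
            health_latent=arr(payload["health_latent"]),
            income_latent=arr(payload["income_latent"]),
        )


def default_indicator_schema():
    """Schema of the bundled health and livelihood indicator columns."""
    from .entropy_index import IndicatorSchema

    records = [
        # health capital: physical/mental state, habits, illness
        {"name": "self_rated_health", "category": "health", "orientation": "positive"},
        {"name": "mental_distress", "category": "health", "orientation": "negative"},
        {"name": "smoking", "category": "health", "orientation": "negative"},
        {"name": "drinking", "category": "health", "orientation": "negative"},
        {"name": "exercising", "category": "health", "orientation": "positive"},
        {"name": "medical_visits", "category": "health", "orientation": "negative"},
        # livelihood capital: human, natural, physical, financial, social
        {"name": "age", "category": "income", "orientation": "negative"},
        {"name": "education", "category": "income", "orientation": "positive"},
        {"name": "land_area", "category": "income", "orientation": "positive"},
        {"name": "animals", "category": "income", "orientation": "positive"},
        {"name": "machinery", "category": "income", "orientation": "positive"},
        {"name": "cars", "category": "income", "orientation": "positive"},
        {"name": "income_sources", "category": "income", "orientation": "positive"},
        {"name": "property_income", "category": "income", "orientation": "positive"},
        {"name": "social_relations", "category": "income", "orientation": "positive"},
        {"name": "familiarity", "category": "income", "orientation": "positive"},
    ]
    return IndicatorSchema.from_records(records)


def _neg_binomial(rng, mean, sd, size):
    """Integer draws matched to a target mean/SD (NB if overdispersed)."""
    var = sd * sd
    if var <= mean:
        return rng.poisson(mean, size)
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


def _draw_errors(rng, n, rho1, rho0):
    """(u, eps1, eps0) trivariate normal; corr(eps1, eps0) = 0."""
    cov = np.array([[1.0, rho1, rho0], [rho1, 1.0, 0.0], [rho0, 0.0, 1.0]])
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, 3))
    e = z @ L.T
    return e[:, 0], e[:, 1], e[:, 2]


def _design(table: pd.DataFrame, names) -> np.ndarray:
    cols = []
    for name in names:
        if name == "const":
            cols.append(np.ones(len(table)))
        else:
            cols.append(table[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def generate_population(config: SyntheticConfig):
    """Generate a (FarmerTable, TruthRecord) pair; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    m = config.covariate_marginals
    lo, hi = config.village_size_range
    sizes = rng.integers(lo, hi + 1, config.n_villages)
    n = int(sizes.sum())
    village_idx = np.repeat(np.arange(config.n_villages), sizes)

    table = pd.DataFrame(
        {
            "farmer_id": [f"F{i:06d}" for i in range(n)],
            "village_id": [f"V{v:04d}" for v in village_idx],
        }
    )
    for name in ("gender", "marriage", "party", "insurance", "internet"):
        table[name] = (rng.random(n) < m[name]).astype(np.int8)
    table["pop_total"] = 1 + _neg_binomial(rng, m["pop_total_mean"] - 1, m["pop_total_sd"], n)
    table["pop_labor"] = _neg_binomial(rng, m["pop_labor_mean"], m["pop_labor_sd"], n)
    table["lnpop_total"] = np.log1p(table["pop_total"].to_numpy(float))
    table["lnpop_labor"] = np.log1p(table["pop_labor"].to_numpy(float))
    for name in ("offfarm", "sanitary", "park", "land"):  # village-level facilities
        v_flag = (rng.random(config.n_villages) < m[name]).astype(np.int8)
        table[name] = v_flag[village_idx]
    v_east = rng.random(config.n_villages) < m["eastern"]
    table["region"] = np.where(v_east[village_idx], "eastern", "non_eastern")
    table["workplace"] = np.where(rng.random(n) < m["native"], "native", "non_native")
    table["age"] = np.clip(np.round(rng.normal(52.0, 13.0, n)), 16, 90).astype(int)

    # shared village effect: drives hours and (via the instrument) selection
    a_v = rng.standard_normal(config.n_villages)
    hours = (
        config.hours_mean
        + config.hours_village_sd * a_v[village_idx]
        + config.hours_indiv_sd * rng.standard_normal(n)
    )
    table["weekly_hours"] = np.clip(hours, 1.0, None)

    truth_params = {
        "mode": config.mode,
        "gamma": dict(config.gamma),
        "beta1": dict(config.beta1),
        "beta0": dict(config.beta0),
        "rho1": config.rho1,
        "rho0": config.rho0,
        "seed": config.seed,
    }

    if config.mode == "model":
        # village-level instrument on [0, 1], monotone in the hours effect
        from scipy.special import ndtr

        table["iv"] = ndtr(a_v)[village_idx]
        u, eps1, eps0 = _draw_errors(rng, n, config.rho1, config.rho0)
        Z = _design(table, list(config.gamma))
        gam = np.array(list(config.gamma.values()), dtype=float)
        treat = (Z @ gam + u > 0.0).astype(np.int8)
        X1 = _design(table, list(config.beta1))
        X0 = _design(table, list(config.beta0))
        b1 = np.array(list(config.beta1.values()), dtype=float)
        b0 = np.array(list(config.beta0.values()), dtype=float)
        Y1 = (X1 @ b1 + eps1 > 0.0).astype(np.int8)
        Y0 = (X0 @ b0 + eps0 > 0.0).astype(np.int8)
        table["work"] = treat
        table["balanced"] = np.where(treat == 1, Y1, Y0)
        truth = TruthRecord(params=truth_params, Y1=Y1, Y0=Y0, u=u, eps1=eps1, eps0=eps0)
        return table, truth

    # structural mode: hours -> work flag -> latent levels -> indicators
    work = (table["weekly_hours"] > table["weekly_hours"].mean()).astype(np.int8)
    table["work"] = work
    zH = rng.standard_normal(n)
    zI = rng.standard_normal(n)

    def levels(treat_vec):
        h = np.clip(
            config.health_base + config.factor_sd * zH + config.health_effect * treat_vec,
            0.01,
            0.99,
        )
        i = np.clip(
            config.income_base + config.factor_sd * zI + config.income_effect * treat_vec,
            0.01,
            0.99,
        )
        return h, i

    ccd_cfg = CCDConfig()

    def balance(h, i):
        c = coupling_degree(h, i)
        t = coordination_index(h, i, ccd_cfg)
        d = coupling_coordination(c, t, ccd_cfg)
        return classify_balance(d, ccd_cfg)

    h1, i1 = levels(np.ones(n))
    h0, i0 = levels(np.zeros(n))
    Y1 = balance(h1, i1)
    Y0 = balance(h0, i0)
    h_obs, i_obs = levels(work.to_numpy(float))

    clip01 = lambda x: np.clip(x, 0.0, 1.0)  # noqa: E731
    nz = lambda s: rng.normal(0.0, s, n)  # noqa: E731
    table["self_rated_health"] = np.round(1 + 4 * clip01(h_obs + nz(0.12))).astype(int)
    table["mental_distress"] = np.clip(
        np.round(20 + 60 * (1 - h_obs) + nz(5.0)), 20, 80
    ).astype(int)
    table["smoking"] = rng.poisson(8.0 * (1 - h_obs))
    table["drinking"] = np.round(3 * clip01(1 - h_obs + nz(0.15))).astype(int)
    table["exercising"] = rng.poisson(1.0 + 6.0 * h_obs)
    table["medical_visits"] = np.round(3 * clip01((1 - h_obs) - 0.3 + nz(0.15))).astype(int)
    table["education"] = np.round(1 + 10 * clip01(i_obs + nz(0.15))).astype(int)
    table["land_area"] = np.round(5.0 * clip01(i_obs + nz(0.2)), 2)
    table["animals"] = np.round(8 * clip01(i_obs + nz(0.18))).astype(int)
    table["machinery"] = np.round(5 * clip01(i_obs - 0.1 + nz(0.18))).astype(int)
    table["cars"] = (rng.random(n) < clip01(i_obs - 0.1)).astype(np.int8)
    table["income_sources"] = 1 + np.round(4 * clip01(i_obs + nz(0.2))).astype(int)
    table["property_income"] = rng.poisson(2.0 * i_obs)
    table["social_relations"] = np.round(10 * clip01(i_obs + nz(0.2))).astype(int)
    table["familiarity"] = np.round(1 + 4 * clip01(i_obs + 0.2 + nz(0.15))).astype(int)

    truth = TruthRecord(
        params=truth_params,
        Y1=np.asarray(Y1),
        Y0=np.asarray(Y0),
        health_latent=h_obs,
        income_latent=i_obs,
    )
    return table, truth


def true_att(truth: TruthRecord, table: pd.DataFrame) -> float:
    """Ground-truth ATT: mean(Y1 - Y0) over farmers with work = 1."""
    treated = table["work"].to_numpy() == 1
    if treated.sum() == 0:
        raise ValueError("no treated farmers")
    return float(np.mean(truth.Y1[treated].astype(float) - truth.Y0[treated].astype(float)))


def write_population(table: pd.DataFrame, truth: TruthRecord, outdir) -> dict:
    """Write FarmerTable (CSV) and TruthRecord (JSON); returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table_path = outdir / "farmers.csv"
    truth_path = outdir / "truth.json"
    table.to_csv(table_path, index=False)
    truth.to_json(truth_path)
    return {"table": str(table_path), "truth": str(truth_path)}
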