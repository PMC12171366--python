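"""Endogenous switching probit (ESP) estimated by FIML.

The model is a three-equation probit system for a binary outcome under
a binary, self-selected treatment:

* selection:  I* = gamma'Z + u,          I = 1{I* > 0}
* treated:    Y1* = beta1'X + eps1,      Y1 = 1{Y1* > 0}   observed if I = 1
* untreated:  Y0* = beta0'X + eps0,      Y0 = 1{Y0* > 0}   observed if I = 0

(u, eps1) and (u, eps0) are standard bivariate normal with correlations
rho1 and rho0; Z contains X plus at least one excluded instrument.
Nonzero rho means unobservables drive both the treatment choice and the
outcome, which separate probits cannot handle; the system is estimated
jointly by full-information maximum likelihood.  Each observation
contributes one of four cell probabilities, all expressible through the
bivariate normal CDF Phi2:

    I=1, y=1:  Phi2( gamma'Z,  beta1'X;  rho1)
    I=1, y=0:  Phi2( gamma'Z, -beta1'X; -rho1)
    I=0, y=1:  Phi2(-gamma'Z,  beta0'X; -rho0)
    I=0, y=0:  Phi2(-gamma'Z, -beta0'X;  rho0)

The four cells sum to one for any parameter value.  The correlations
are estimated on the atanh scale so the optimization is unconstrained;
standard errors are village-cluster-robust (sandwich).

The treatment effect on the treated (ATT) compares, for each treated
farmer, the probability of a favourable outcome in the treated regime
with the counterfactual untreated-regime probability, both conditioned
on having selected treatment:

    p1_i = Phi2(gamma'Z_i, beta1'X_i; rho1) / Phi(gamma'Z_i)
    p0_i = Phi2(gamma'Z_i, beta0'X_i; rho0) / Phi(gamma'Z_i)
    ATT  = mean(p1_i - p0_i)  over treated i

with the relative change reported as |ATT| / mean(p1_i) * 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr, owens_t

import statsmodels.api as sm

__all__ = [
    "bvn_cdf",
    "ESPData",
    "ESPEstimate",
    "ATTReport",
    "WaldTest",
    "esp_loglik",
    "esp_score_obs",
    "fit_esp",
    "wald_independence_test",
    "att_esp",
    "relative_change",
    "render_estimates",
    "render_att",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)
_RHO_EDGE = 1.0 - 1e-12
_P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# bivariate normal CDF
# ---------------------------------------------------------------------------

def bvn_cdf(a, b, rho):
    """P(U <= a, V <= b) for standard bivariate normal with correlation rho.

    Computed from Owen's T function,

        Phi2(h, k; r) = (Phi(h) + Phi(k)) / 2
                        - T(h, (k - r h)/(h sqrt(1-r^2)))
                        - T(k, (h - r k)/(k sqrt(1-r^2)))
                        - [hk < 0, or hk = 0 and h + k < 0],

    which is accurate to ~1e-15 and fully vectorized.  |rho| = 1 is
    handled as the degenerate comonotone/antimonotone limit.
    """
    a, b, rho = np.broadcast_arrays(
        np.asarray(a, dtype=float), np.asarray(b, dtype=float), np.asarray(rho, dtype=float)
    )
    if np.any(np.isnan(a)) or np.any(np.isnan(b)) or np.any(np.isnan(rho)):
        raise ValueError("bvn_cdf received NaN input")
    if np.any(np.abs(rho) > 1.0):
        raise ValueError("|rho| must not exceed 1")
    out = np.empty(a.shape, dtype=float)
    hi = rho >= _RHO_EDGE
    lo = rho <= -_RHO_EDGE
    mid = ~(hi | lo)
    if np.any(hi):
        out[hi] = ndtr(np.minimum(a[hi], b[hi]))
    if np.any(lo):
        out[lo] = np.clip(ndtr(a[lo]) + ndtr(b[lo]) - 1.0, 0.0, 1.0)
    if np.any(mid):
        out[mid] = _bvn_owens(a[mid], b[mid], rho[mid])
    if out.ndim == 0:
        return float(out)
    return out


def _bvn_owens(h, k, r):
    # replacing exact zeros by +eps reproduces the h=0 / k=0 limits to <1e-12
    eps = 1e-15
    h = np.where(h == 0.0, eps, h)
    k = np.where(k == 0.0, eps, k)
    s = np.sqrt((1.0 - r) * (1.0 + r))
    with np.errstate(divide="ignore", over="ignore"):
        a1 = (k / h - r) / s
        a2 = (h / k - r) / s
    res = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, a1) - owens_t(k, a2)
    res = res - np.where(h * k < 0.0, 0.5, 0.0)
    return np.clip(res, 0.0, 1.0)


def _bvn_pieces(a, b, r):
    """Phi2 and its partial derivatives wrt a, b and rho."""
    s = np.sqrt((1.0 - r) * (1.0 + r))
    p = bvn_cdf(a, b, r)
    phi_a = np.exp(-0.5 * a * a) / _SQRT_2PI
    phi_b = np.exp(-0.5 * b * b) / _SQRT_2PI
    da = phi_a * ndtr((b - r * a) / s)
    db = phi_b * ndtr((a - r * b) / s)
    quad = (a * a - 2.0 * r * a * b + b * b) / (2.0 * s * s)
    dr = np.exp(-quad) / (2.0 * np.pi * s)
    return p, da, db, dr


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

@dataclass
class ESPData:
    """Aligned arrays for the ESP system.

    ``X`` (outcome covariates) and ``Z`` (selection covariates) both
    include an intercept; ``Z`` must strictly contain at least one
    column excluded from ``X`` — the instrument.  ``cluster`` carries
    village identifiers for robust covariance and bootstrap resampling.
    """

    y: np.ndarray
    treat: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    cluster: np.ndarray
    x_names: list[str] = field(default_factory=list)
    z_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y).astype(int)
        self.treat = np.asarray(self.treat).astype(int)
        self.X = np.asarray(self.X, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        self.cluster = np.asarray(self.cluster)
        n = self.y.shape[0]
        if not (self.treat.shape[0] == self.X.shape[0] == self.Z.shape[0] == self.cluster.shape[0] == n):
            raise ValueError("ESPData arrays must share the same length")
        if set(np.unique(self.y)) - {0, 1} or set(np.unique(self.treat)) - {0, 1}:
            raise ValueError("y and treat must be binary 0/1")
        if self.treat.sum() == 0:
            raise ValueError("no treated observations")
        if self.treat.sum() == n:
            raise ValueError("no control observations")
        if self.Z.shape[1] <= self.X.shape[1]:
            raise ValueError("Z must strictly contain an excluded instrument column")
        if not self.x_names:
            self.x_names = [f"x{j}" for j in range(self.X.shape[1])]
        if not self.z_names:
            self.z_names = [f"z{j}" for j in range(self.Z.shape[1])]
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("outcome covariates X are collinear (rank deficient)")
        if np.linalg.matrix_rank(self.Z) < self.Z.shape[1]:
            raise ValueError("selection covariates Z are collinear (rank deficient)")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_treated(self) -> int:
        return int(self.treat.sum())

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        outcome: str,
        treatment: str,
        covariates,
        instrument: str,
        cluster: str,
    ) -> "ESPData":
        """Build from a tidy DataFrame, adding intercepts automatically."""
        covariates = list(covariates)
        cols = [outcome, treatment, instrument, cluster] + covariates
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise KeyError(f"frame lacks columns: {missing}")
        sub = frame[cols].dropna()
        n = len(sub)
        X = np.column_stack([np.ones(n)] + [sub[c].to_numpy(float) for c in covariates])
        Z = np.column_stack([X, sub[instrument].to_numpy(float)])
        return cls(
            y=sub[outcome].to_numpy(),
            treat=sub[treatment].to_numpy(),
            X=X,
            Z=Z,
            cluster=sub[cluster].to_numpy(),
            x_names=["const"] + covariates,
            z_names=["const"] + covariates + [instrument],
        )

    def subset_rows(self, idx) -> "ESPData":
        """New ESPData from a row index or boolean mask (revalidates)."""
        idx = np.asarray(idx)
        return ESPData(
            y=self.y[idx],
            treat=self.treat[idx],
            X=self.X[idx],
            Z=self.Z[idx],
            cluster=self.cluster[idx],
            x_names=list(self.x_names),
            z_names=list(self.z_names),
        )


# ---------------------------------------------------------------------------
# likelihood and score
# ---------------------------------------------------------------------------

def _unpack(params, kz, kx):
    params = np.asarray(params, dtype=float)
    gamma = params[:kz]
    beta1 = params[kz : kz + kx]
    beta0 = params[kz + kx : kz + 2 * kx]
    tau1, tau0 = params[kz + 2 * kx], params[kz + 2 * kx + 1]
    return gamma, beta1, beta0, tau1, tau0


def _cells(params, data: ESPData):
    """Signed (a, b, r) per observation plus regime pieces."""
    gamma, beta1, beta0, tau1, tau0 = _unpack(params, data.Z.shape[1], data.X.shape[1])
    rho1, rho0 = np.tanh(tau1), np.tanh(tau0)
    zi = data.Z @ gamma
    xb = np.where(data.treat == 1, data.X @ beta1, data.X @ beta0)
    s = 2.0 * data.treat - 1.0
    q = 2.0 * data.y - 1.0
    rho = np.where(data.treat == 1, rho1, rho0)
    a = s * zi
    b = q * xb
    r = s * q * rho
    return a, b, r, s, q, rho1, rho0


def esp_loglik(params, data: ESPData) -> float:
    """Total log-likelihood at params = (gamma, beta1, beta0, atanh rho1, atanh rho0)."""
    a, b, r, _, _, _, _ = _cells(params, data)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite linear indices")
    p = np.clip(bvn_cdf(a, b, r), _P_FLOOR, 1.0)
    return float(np.sum(np.log(p)))


def esp_score_obs(params, data: ESPData) -> np.ndarray:
    """Per-observation analytic score matrix, shape (n, n_params)."""
    kz, kx = data.Z.shape[1], data.X.shape[1]
    a, b, r, s, q, rho1, rho0 = _cells(params, data)
    p, da, db, dr = _bvn_pieces(a, b, r)
    inv = 1.0 / np.clip(p, _P_FLOOR, None)
    gl_a = inv * da  # dlogL/da
    gl_b = inv * db
    gl_r = inv * dr
    n = data.n
    score = np.zeros((n, kz + 2 * kx + 2))
    score[:, :kz] = (gl_a * s)[:, None] * data.Z
    t1 = data.treat == 1
    bx = (gl_b * q)[:, None] * data.X
    score[t1, kz : kz + kx] = bx[t1]
    score[~t1, kz + kx : kz + 2 * kx] = bx[~t1]
    # r = s*q*rho, rho = tanh(tau)
    dtau = gl_r * s * q
    score[t1, kz + 2 * kx] = dtau[t1] * (1.0 - rho1**2)
    score[~t1, kz + 2 * kx + 1] = dtau[~t1] * (1.0 - rho0**2)
    return score


# ---------------------------------------------------------------------------
# estimates
# ---------------------------------------------------------------------------

@dataclass
class ESPEstimate:
    """Fitted ESP system with cluster-robust covariance.

    ``params`` and ``vcov`` are on the optimization scale (correlations
    as atanh); ``rho1``/``rho0`` are back-transformed point estimates.
    """

    params: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    n: int
    n_treated: int
    n_clusters: int
    x_names: list[str]
    z_names: list[str]

    @property
    def kz(self) -> int:
        return len(self.z_names)

    @property
    def kx(self) -> int:
        return len(self.x_names)

    @property
    def gamma(self) -> np.ndarray:
        return self.params[: self.kz]

    @property
    def beta1(self) -> np.ndarray:
        return self.params[self.kz : self.kz + self.kx]

    @property
    def beta0(self) -> np.ndarray:
        return self.params[self.kz + self.kx : self.kz + 2 * self.kx]

    @property
    def tau(self) -> np.ndarray:
        return self.params[-2:]

    @property
    def rho1(self) -> float:
        return float(np.tanh(self.params[-2]))

    @property
    def rho0(self) -> float:
        return float(np.tanh(self.params[-1]))

    @property
    def param_names(self) -> list[str]:
        return (
            [f"sel:{n}" for n in self.z_names]
            + [f"treated:{n}" for n in self.x_names]
            + [f"control:{n}" for n in self.x_names]
            + ["atanh_rho1", "atanh_rho0"]
        )

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """CIs on the optimization scale (use tanh on the last two rows)."""
        zcrit = stats.norm.ppf(0.5 + level / 2.0)
        se = self.se()
        return np.column_stack([self.params - zcrit * se, self.params + zcrit * se])

    def summary_frame(self) -> pd.DataFrame:
        se = self.se()
        zstat = np.divide(self.params, se, out=np.full_like(self.params, np.nan), where=se > 0)
        pvals = 2.0 * stats.norm.sf(np.abs(zstat))
        return pd.DataFrame(
            {"estimate": self.params, "se": se, "z": zstat, "p_value": pvals},
            index=self.param_names,
        )


@dataclass(frozen=True)
class WaldTest:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ATTReport:
    """ATT with its decomposition into regime probabilities.

    ``att = p_treated - p_counterfactual`` and ``change_pct`` is the
    relative change |att| / p_treated * 100 — the improvement a treated
    farmer would see in the favourable-outcome probability if switched
    to the untreated regime (when att < 0).
    """

    att: float
    se: float
    p_treated: float
    p_counterfactual: float
    change_pct: float
    method: str = "ESP"
    n_treated: int = 0
    bootstrap_reps: int = 0

    def __post_init__(self) -> None:
        if abs(self.att - (self.p_treated - self.p_counterfactual)) > 1e-12:
            raise ValueError("att must equal p_treated - p_counterfactual")

    @classmethod
    def from_probabilities(
        cls,
        p_treated: float,
        p_counterfactual: float,
        se: float = np.nan,
        method: str = "ESP",
        n_treated: int = 0,
        bootstrap_reps: int = 0,
    ) -> "ATTReport":
        att = p_treated - p_counterfactual
        return cls(
            att=att,
            se=se,
            p_treated=p_treated,
            p_counterfactual=p_counterfactual,
            change_pct=relative_change(att, p_treated),
            method=method,
            n_treated=n_treated,
            bootstrap_reps=bootstrap_reps,
        )

    @property
    def p_value(self) -> float:
        if not np.isfinite(self.se) or self.se <= 0:
            return np.nan
        return float(2.0 * stats.norm.sf(abs(self.att) / self.se))


def relative_change(att: float, p_treated: float) -> float:
    """|att| / p_treated * 100 (percent)."""
    if not p_treated > 0.0:
        raise ValueError("p_treated must be positive")
    return abs(att) / p_treated * 100.0


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _probit_start(y, X, label: str) -> np.ndarray:
    """Separate-probit starting values; falls back to intercept-only."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Probit(y, X).fit(disp=0, maxiter=200, warn_convergence=False)
        coefs = np.asarray(res.params, dtype=float)
        if np.all(np.isfinite(coefs)) and np.max(np.abs(coefs)) < 50.0:
            return coefs
    except Exception:  # noqa: BLE001 - any statsmodels failure falls through
        pass
    warnings.warn(f"probit start for {label} failed; using intercept-only start", stacklevel=3)
    coefs = np.zeros(X.shape[1])
    coefs[0] = stats.norm.ppf(np.clip(np.mean(y), 1e-3, 1 - 1e-3))
    return coefs


def _num_hessian(params, data: ESPData, step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of the total log-likelihood from the analytic score."""
    p = np.asarray(params, dtype=float)
    k = p.size
    H = np.zeros((k, k))
    for j in range(k):
        h = step * max(1.0, abs(p[j]))
        up, dn = p.copy(), p.copy()
        up[j] += h
        dn[j] -= h
        gu = esp_score_obs(up, data).sum(axis=0)
        gd = esp_score_obs(dn, data).sum(axis=0)
        H[:, j] = (gu - gd) / (2.0 * h)
    return 0.5 * (H + H.T)


def _cluster_vcov(params, data: ESPData) -> np.ndarray:
    """Village-cluster-robust sandwich covariance on the atanh scale."""
    H = _num_hessian(params, data)
    Hinv = np.linalg.pinv(-H)
    scores = esp_score_obs(params, data)
    groups = pd.factorize(data.cluster)[0]
    g = np.zeros((groups.max() + 1, scores.shape[1]))
    np.add.at(g, groups, scores)
    n_g = g.shape[0]
    B = g.T @ g * (n_g / max(n_g - 1, 1))
    V = Hinv @ B @ Hinv
    return 0.5 * (V + V.T)


def fit_esp(
    data: ESPData,
    start: np.ndarray | None = None,
    maxiter: int = 300,
    gtol: float = 1e-7,
    compute_vcov: bool = True,
    fix_rho_zero: bool = False,
) -> ESPEstimate:
    """FIML fit of the ESP system by quasi-Newton with analytic score.

    Starts from separate probits with both correlations at zero (their
    exact MLE when rho1 = rho0 = 0, since the likelihood factorizes).
    The mean log-likelihood is maximized by BFGS; the convergence flag
    reflects the optimizer's own status plus a gradient check and is
    reported honestly — a failed fit is returned flagged, not hidden.

    ``fix_rho_zero`` estimates the constrained model with both
    correlations pinned at zero (equivalent to three separate probits);
    useful as the null model for likelihood-ratio comparisons.
    """
    iv_col = data.Z[:, data.X.shape[1]:]
    if np.all(np.ptp(iv_col, axis=0) == 0.0):
        raise ValueError("instrument column is constant")
    for arm, label in ((1, "treated"), (0, "control")):
        y_arm = data.y[data.treat == arm]
        if y_arm.min() == y_arm.max():
            warnings.warn(f"{label} arm has a single outcome value", stacklevel=2)
    if start is None:
        g0 = _probit_start(data.treat, data.Z, "selection")
        b1 = _probit_start(data.y[data.treat == 1], data.X[data.treat == 1], "treated outcome")
        b0 = _probit_start(data.y[data.treat == 0], data.X[data.treat == 0], "control outcome")
        start = np.concatenate([g0, b1, b0, [0.0, 0.0]])
    start = np.asarray(start, dtype=float)
    n = data.n
    k_free = start.size - 2 if fix_rho_zero else start.size

    def expand(p):
        return np.append(p, [0.0, 0.0]) if fix_rho_zero else p

    def neg_mean_ll(p):
        return -esp_loglik(expand(p), data) / n

    def neg_mean_grad(p):
        return -esp_score_obs(expand(p), data).sum(axis=0)[:k_free] / n

    res = optimize.minimize(
        neg_mean_ll,
        start[:k_free],
        jac=neg_mean_grad,
        method="BFGS",
        options={"maxiter": maxiter, "gtol": gtol},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or grad_norm < 1e-5)
    if not converged:
        warnings.warn(
            f"ESP optimization did not converge (|grad|={grad_norm:.2e})", stacklevel=2
        )
    params = expand(res.x)
    if compute_vcov:
        vcov = _cluster_vcov(params, data)
        if fix_rho_zero:
            # constrained sandwich: free block only, tau rows/cols zeroed
            H = _num_hessian(params, data)[:k_free, :k_free]
            Hinv = np.linalg.pinv(-H)
            scores = esp_score_obs(params, data)[:, :k_free]
            groups = pd.factorize(data.cluster)[0]
            g = np.zeros((groups.max() + 1, k_free))
            np.add.at(g, groups, scores)
            n_g = g.shape[0]
            B = g.T @ g * (n_g / max(n_g - 1, 1))
            vcov = np.zeros((params.size, params.size))
            vcov[:k_free, :k_free] = Hinv @ B @ Hinv
    else:
        vcov = np.full((params.size, params.size), np.nan)
    return ESPEstimate(
        params=params,
        vcov=vcov,
        loglik=float(-res.fun * n),
        converged=converged,
        n=n,
        n_treated=data.n_treated,
        n_clusters=int(pd.unique(data.cluster).size),
        x_names=list(data.x_names),
        z_names=list(data.z_names),
    )


def wald_independence_test(est: ESPEstimate) -> WaldTest:
    """Wald chi-square for H0: rho1 = rho0 = 0 (atanh scale, df = 2).

    Rejection indicates correlated unobservables between selection and
    outcomes, i.e. that the switching model is needed.
    """
    tau = est.tau
    V = est.vcov[-2:, -2:]
    if not np.all(np.isfinite(V)):
        raise ValueError("covariance of rho estimates unavailable")
    try:
        stat = float(tau @ np.linalg.solve(V, tau))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance block for rho estimates") from exc
    return WaldTest(statistic=stat, df=2, p_value=float(stats.chi2.sf(stat, 2)))


# ---------------------------------------------------------------------------
# ATT
# ---------------------------------------------------------------------------

def _att_point(params, data: ESPData):
    """(att, p_treated, p_counterfactual) among treated rows."""
    kz, kx = data.Z.shape[1], data.X.shape[1]
    gamma, beta1, beta0, tau1, tau0 = _unpack(params, kz, kx)
    rho1, rho0 = np.tanh(tau1), np.tanh(tau0)
    t = data.treat == 1
    if t.sum() == 0:
        raise ValueError("no treated rows")
    zi = data.Z[t] @ gamma
    denom = np.clip(ndtr(zi), 1e-12, None)
    p1 = bvn_cdf(zi, data.X[t] @ beta1, rho1) / denom
    p0 = bvn_cdf(zi, data.X[t] @ beta0, rho0) / denom
    return float(np.mean(p1 - p0)), float(np.mean(p1)), float(np.mean(p0))


def att_esp(
    est: ESPEstimate,
    data: ESPData,
    bootstrap_reps: int = 500,
    seed: int | None = None,
    refit_kwargs: dict | None = None,
) -> ATTReport:
    """ATT among the treated with a village-cluster bootstrap SE.

    The point estimate uses predicted regime probabilities conditional
    on selection (see module docstring).  The SE resamples villages with
    replacement, refits the system (warm-started at the full-sample
    estimate) and recomputes the ATT; ``bootstrap_reps=0`` skips the SE.
    """
    if not est.converged:
        warnings.warn("ATT computed from a non-converged estimate", stacklevel=2)
    att, p1, p0 = _att_point(est.params, data)
    se = np.nan
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        villages = pd.unique(data.cluster)
        idx_by_v = {v: np.flatnonzero(data.cluster == v) for v in villages}
        draws = []
        kwargs = dict(refit_kwargs or {})
        kwargs.setdefault("gtol", 1e-6)
        for _ in range(bootstrap_reps):
            chosen = rng.choice(villages, size=villages.size, replace=True)
            idx = np.concatenate([idx_by_v[v] for v in chosen])
            try:
                bdata = data.subset_rows(idx)
                best = fit_esp(
                    bdata, start=est.params, compute_vcov=False, **kwargs
                )
                draws.append(_att_point(best.params, bdata)[0])
            except (ValueError, np.linalg.LinAlgError):
                continue
        if len(draws) >= 10:
            se = float(np.std(draws, ddof=1))
        else:
            warnings.warn("too few successful bootstrap replicates for an SE", stacklevel=2)
    return ATTReport.from_probabilities(
        p_treated=p1,
        p_counterfactual=p0,
        se=se,
        method="ESP",
        n_treated=data.n_treated,
        bootstrap_reps=bootstrap_reps,
    )


# ---------------------------------------------------------------------------
# text renderings
# ---------------------------------------------------------------------------

def _starred(value: float, p: float) -> str:
    from .preprocess import significance_stars

    return f"{value:.3f}{significance_stars(p)}"


def render_estimates(est: ESPEstimate, wald: WaldTest | None = None) -> str:
    """Three-column text table: selection, treated regime, control regime."""
    sf = est.summary_frame()
    lines = [
        f"{'Variable':<16}{'Selection':>22}{'Treated regime':>22}{'Control regime':>22}"
    ]
    for name in est.z_names:
        cells = []
        for prefix, names in (
            ("sel", est.z_names),
            ("treated", est.x_names),
            ("control", est.x_names),
        ):
            key = f"{prefix}:{name}"
            if name in names:
                row = sf.loc[key]
                cells.append(f"{_starred(row.estimate, row.p_value)}({row.se:.3f})")
            else:
                cells.append("-")
        lines.append(f"{name:<16}{cells[0]:>22}{cells[1]:>22}{cells[2]:>22}")
    for label, rho, tau_name in (
        ("rho1", est.rho1, "atanh_rho1"),
        ("rho0", est.rho0, "atanh_rho0"),
    ):
        row = sf.loc[tau_name]
        se_nat = row.se * (1.0 - rho**2)  # delta method through tanh
        lines.append(f"{label:<16}{_starred(rho, row.p_value):>22}({se_nat:.3f})")
    if wald is not None:
        lines.append(
            f"Wald test of indep. eqns.  chi2({wald.df}) = {wald.statistic:.3f}"
            f"  (p = {wald.p_value:.3f})"
        )
    lines.append(f"Log pseudolikelihood  {est.loglik:.3f}")
    lines.append(f"Observations  {est.n}  (treated {est.n_treated}, villages {est.n_clusters})")
    return "\n".join(lines)


def render_att(report: ATTReport) -> str:
    """One-line ATT table: regime means, ATT (SE), relative change."""
    from .preprocess import significance_stars

    stars = significance_stars(report.p_value)
    return (
        f"{'Method':<10}{'Treated regime':>16}{'Counterfactual':>16}{'ATT':>18}{'Change (%)':>12}\n"
        f"{report.method:<10}{report.p_treated:>16.3f}{report.p_counterfactual:>16.3f}"
        f"{report.att:>14.3f}{stars}({report.se:.3f}){report.change_pct:>12.3f}"
    )
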