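"""Coupling coordination degree (CCD) scoring.

The CCD framework summarises the joint development of two bounded
subsystem scores — here a composite health index H and a composite
income index I, both in [0, 1].  Three quantities are computed per
observation:

* coupling degree ``C = 2 * sqrt(H * I) / (H + I)`` — how *similar* the
  two subsystems are (1 when equal and positive, 0 when one is zero);
* coordination index ``T = alpha * H + beta * I`` — how *developed* they
  are on average (``alpha + beta = 1``);
* coupling coordination degree ``D`` — either ``C * T`` (``product``
  mode, the default) or ``sqrt(C * T)`` (``sqrt_product`` mode, the form
  most common in the wider CCD literature).

Households with ``D`` at or above a threshold (default 0.5) are classed
as health-income *balanced* (1), the rest as imbalanced (0).

A zero system (H = I = 0) is assigned ``C = 0``: although the limit of C
along the diagonal is 1, a household with no health and no income
capital is treated as uncoupled rather than perfectly coupled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CCDConfig",
    "coupling_degree",
    "coordination_index",
    "coupling_coordination",
    "classify_balance",
    "score_table",
]

_D_FORMULAS = ("product", "sqrt_product")


@dataclass(frozen=True)
class CCDConfig:
    """Weights, D-formula variant and balance threshold.

    ``alpha`` and ``beta`` are the contribution coefficients of health
    and income in the coordination index; the two subsystems are given
    equal status by default (``alpha = beta = 1/2``).
    """

    alpha: float = 0.5
    beta: float = 0.5
    d_formula: str = "product"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if abs(self.alpha + self.beta - 1.0) > 1e-10:
            raise ValueError("alpha + beta must equal 1")
        if self.d_formula not in _D_FORMULAS:
            raise ValueError(f"d_formula must be one of {_D_FORMULAS}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


def _check_unit(name: str, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(np.isnan(x)):
        raise ValueError(f"{name} contains NaN")
    if np.any((x < 0.0) | (x > 1.0)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return x


def coupling_degree(health, income) -> np.ndarray:
    """C = 2 sqrt(H I) / (H + I), with C := 0 when H = I = 0.

    Symmetric in its arguments; equals 1 exactly when H = I > 0.
    """
    h = _check_unit("health", health)
    i = _check_unit("income", income)
    total = h + i
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(total > 0.0, 2.0 * np.sqrt(h * i) / np.where(total > 0, total, 1.0), 0.0)
    return np.clip(c, 0.0, 1.0)


def coordination_index(health, income, config: CCDConfig = CCDConfig()) -> np.ndarray:
    """T = alpha * H + beta * I."""
    h = _check_unit("health", health)
    i = _check_unit("income", income)
    return config.alpha * h + config.beta * i


def coupling_coordination(c, t, config: CCDConfig = CCDConfig()) -> np.ndarray:
    """D from C and T under the configured formula."""
    c = _check_unit("C", c)
    t = _check_unit("T", t)
    prod = c * t
    if config.d_formula == "product":
        return prod
    return np.sqrt(prod)


def classify_balance(d, config: CCDConfig = CCDConfig()) -> np.ndarray:
    """1 where D >= threshold (the boundary counts as balanced), else 0."""
    d = _check_unit("D", d)
    return (d >= config.threshold).astype(np.int8)


def score_table(farmer_id, health, income, config: CCDConfig = CCDConfig()) -> pd.DataFrame:
    """Full per-farmer CCD score table (health, income, C, T, D, balanced)."""
    c = coupling_degree(health, income)
    t = coordination_index(health, income, config)
    d = coupling_coordination(c, t, config)
    return pd.DataFrame(
        {
            "farmer_id": np.asarray(farmer_id),
            "health": np.asarray(health, dtype=float),
            "income": np.asarray(income, dtype=float),
            "C": c,
            "T": t,
            "D": d,
            "balanced": classify_balance(d, config),
        }
    )
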