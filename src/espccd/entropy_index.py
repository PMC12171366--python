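"""Entropy-weighted composite indices.

Builds bounded composite scores (e.g. a household health index or a
livelihood/income index) from a panel of raw indicators.  Each indicator
is min-max normalized with its declared orientation (negative indicators
are reversed), then weighted by the entropy method: indicators whose
normalized shares are spread evenly across households carry little
information (Shannon entropy near 1) and receive small weights, while
concentrated indicators receive large ones.

Given normalized values x'_ij (household i, indicator j, n >= 2 rows):

    p_ij = x'_ij / sum_i x'_ij
    e_j  = -(1 / ln n) * sum_i p_ij ln p_ij      (0 * ln 0 := 0)
    d_j  = 1 - e_j
    w_j  = d_j / sum_j d_j

Weights are nonnegative and sum to one; composite scores are the
weighted sums, bounded in [0, 1].

Zero handling follows the plain convention (no epsilon shift); a
share-smoothing offset is available via ``zero_offset`` for comparison
with implementations that add a small constant before forming shares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Indicator",
    "IndicatorSchema",
    "orient_normalize",
    "entropy_weights",
    "composite_scores",
]

_ORIENTATIONS = ("positive", "negative")


@dataclass(frozen=True)
class Indicator:
    name: str
    category: str = ""
    orientation: str = "positive"

    def __post_init__(self) -> None:
        if self.orientation not in _ORIENTATIONS:
            raise ValueError(
                f"orientation of {self.name!r} must be one of {_ORIENTATIONS}"
            )


@dataclass(frozen=True)
class IndicatorSchema:
    """Ordered indicator declarations: name, category label, orientation."""

    indicators: tuple[Indicator, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [ind.name for ind in self.indicators]
        if len(set(names)) != len(names):
            raise ValueError("indicator names must be unique")

    @property
    def names(self) -> list[str]:
        return [ind.name for ind in self.indicators]

    def orientation(self, name: str) -> str:
        for ind in self.indicators:
            if ind.name == name:
                return ind.orientation
        raise KeyError(name)

    def subset(self, category: str) -> "IndicatorSchema":
        return IndicatorSchema(
            tuple(ind for ind in self.indicators if ind.category == category)
        )

    @classmethod
    def from_records(cls, records) -> "IndicatorSchema":
        return cls(
            tuple(
                Indicator(
                    name=r["name"],
                    category=r.get("category", ""),
                    orientation=r.get("orientation", "positive"),
                )
                for r in records
            )
        )

    @classmethod
    def from_yaml(cls, path) -> "IndicatorSchema":
        with open(path) as fh:
            records = yaml.safe_load(fh)
        return cls.from_records(records)

    def to_yaml(self, path) -> None:
        records = [
            {"name": i.name, "category": i.category, "orientation": i.orientation}
            for i in self.indicators
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(records, fh, sort_keys=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "category": [i.category for i in self.indicators],
                "orientation": [i.orientation for i in self.indicators],
            }
        )


def orient_normalize(panel: pd.DataFrame, schema: IndicatorSchema) -> pd.DataFrame:
    """Min-max normalize each indicator to [0, 1], reversing negative ones.

    Positive orientation: (x - min) / (max - min); negative orientation:
    (max - x) / (max - min).  Constant columns carry no information and
    are mapped to all-zeros with a warning.  Missing values are an
    error — the pipeline is complete-case by design.
    """
    if panel.shape[0] == 0 or panel.shape[1] == 0:
        raise ValueError("empty indicator panel")
    missing = set(schema.names) - set(panel.columns)
    if missing:
        raise KeyError(f"panel lacks declared indicators: {sorted(missing)}")
    out = {}
    for ind in schema.indicators:
        col = panel[ind.name].to_numpy(dtype=float)
        if np.any(np.isnan(col)):
            raise ValueError(f"indicator {ind.name!r} has missing values")
        lo, hi = col.min(), col.max()
        if hi == lo:
            warnings.warn(
                f"indicator {ind.name!r} is constant; normalized to zeros",
                stacklevel=2,
            )
            out[ind.name] = np.zeros_like(col)
            continue
        if ind.orientation == "positive":
            out[ind.name] = (col - lo) / (hi - lo)
        else:
            out[ind.name] = (hi - col) / (hi - lo)
    return pd.DataFrame(out, index=panel.index)


def entropy_weights(normalized: pd.DataFrame, zero_offset: float = 0.0) -> pd.Series:
    """Entropy weights for a normalized panel (values in [0, 1], n >= 2).

    All-zero columns are undefined under the share construction and get
    weight 0 with a warning; if every column is degenerate (zero or
    perfectly uniform) no weighting is possible and an error is raised.
    ``zero_offset`` > 0 switches to shares of ``x + offset``.
    """
    x = normalized.to_numpy(dtype=float)
    n, k = x.shape
    if n < 2:
        raise ValueError("entropy weighting needs at least 2 rows")
    if np.any(np.isnan(x)) or x.min() < 0 or x.max() > 1:
        raise ValueError("normalized panel must lie in [0, 1] with no NaN")
    if zero_offset < 0:
        raise ValueError("zero_offset must be nonnegative")
    x = x + zero_offset
    colsum = x.sum(axis=0)
    d = np.zeros(k)
    for j in range(k):
        if colsum[j] == 0.0:
            warnings.warn(
                f"column {normalized.columns[j]!r} is all zero; weight set to 0",
                stacklevel=2,
            )
            continue
        p = x[:, j] / colsum[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0.0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        e = -plogp.sum() / np.log(n)
        d[j] = 1.0 - e
    d = np.clip(d, 0.0, None)  # e can exceed 1 by rounding on uniform columns
    total = d.sum()
    if total <= 0.0:
        raise ValueError("all columns are degenerate; entropy weights undefined")
    return pd.Series(d / total, index=normalized.columns, name="weight")


def composite_scores(normalized: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Weighted-sum composite score per row, bounded in [0, 1]."""
    if set(weights.index) != set(normalized.columns):
        raise KeyError("weight names do not match panel columns")
    w = weights.reindex(normalized.columns).to_numpy(dtype=float)
    score = normalized.to_numpy(dtype=float) @ w
    return pd.Series(np.clip(score, 0.0, 1.0), index=normalized.index, name="score")
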