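"""Entropy, mutual information and symmetrical uncertainty on discrete data.

This module supplies the relevance machinery that steers the ant-colony
feature selector.  Continuous features are first discretized (equal-width by
default); all information measures are then computed from maximum-likelihood
cell probabilities of the empirical contingency table, in bits (base-2 logs).

The two quantities consumed by the selector are

* ``SU_FC`` — symmetrical uncertainty between a feature and the class label
  (relevance; higher is better), and
* ``SU_FF`` — symmetrical uncertainty between two features (redundancy;
  lower is better),

mapped to heuristic desirabilities ``eta`` via ``1/(1 - SU_FC)`` and
``1/SU_FF`` respectively, with an epsilon clamp where the maps diverge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .table import CategoricalSeries, FeatureTable

__all__ = [
    "DiscretizationScheme",
    "RelevanceProfile",
    "discretize",
    "discretize_feature",
    "entropy",
    "joint_entropy",
    "conditional_entropy",
    "information_factor",
    "symmetrical_uncertainty",
    "relevance_profile",
    "heuristic_fc",
    "heuristic_ff",
]

#: Clamp used where the heuristic maps 1/(1-SU) and 1/SU diverge.
DEFAULT_EPSILON = 1e-6

_TOL = 1e-9  # tolerance when validating SU inputs nominally in [0, 1]


@dataclass
class DiscretizationScheme:
    """How continuous features are binned before entropy estimation.

    ``equal_width`` splits each feature's observed range into ``n_bins`` equal
    intervals; ``equal_frequency`` places cut points at empirical quantiles so
    bins receive near-equal occupancy.  Both are deterministic given the data.
    A constant feature collapses to a single bin under either strategy.
    """

    strategy: Literal["equal_width", "equal_frequency"] = "equal_width"
    n_bins: int = 10
    cut_points: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strategy not in ("equal_width", "equal_frequency"):
            raise ValueError(f"unknown discretization strategy: {self.strategy!r}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")


def _feature_cut_points(values: np.ndarray, scheme: DiscretizationScheme) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return np.empty(0)
    if scheme.strategy == "equal_width":
        cuts = np.linspace(lo, hi, scheme.n_bins + 1)[1:-1]
    else:
        qs = np.linspace(0, 1, scheme.n_bins + 1)[1:-1]
        cuts = np.quantile(values, qs)
    cuts = np.unique(cuts)
    return cuts


def discretize_feature(values: np.ndarray, scheme: DiscretizationScheme) -> CategoricalSeries:
    """Bin one feature into integer codes; monotone in the raw values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty feature")
    cuts = _feature_cut_points(values, scheme)
    codes = np.searchsorted(cuts, values, side="right")
    return CategoricalSeries(codes, n_categories=len(cuts) + 1)


def discretize(table: FeatureTable, scheme: DiscretizationScheme) -> list[CategoricalSeries]:
    """Discretize every feature column; returns one series per feature.

    The fitted cut points are recorded on ``scheme.cut_points`` so the same
    binning can be reapplied or inspected.
    """
    if table.n_samples < 1:
        raise ValueError("empty table")
    scheme.cut_points = [_feature_cut_points(table.X[:, j], scheme) for j in range(table.n_features)]
    out = []
    for j, cuts in enumerate(scheme.cut_points):
        codes = np.searchsorted(cuts, table.X[:, j], side="right")
        out.append(CategoricalSeries(codes, n_categories=len(cuts) + 1))
    return out


def entropy(s: CategoricalSeries) -> float:
    """Shannon entropy H(X) in bits from maximum-likelihood probabilities."""
    counts = np.bincount(s.codes, minlength=s.n_categories)
    p = counts[counts > 0] / s.codes.size
    return float(-(p * np.log2(p)).sum())


def _pair_codes(a: CategoricalSeries, b: CategoricalSeries) -> CategoricalSeries:
    if len(a) != len(b):
        raise ValueError("series lengths differ")
    joint = a.codes * b.n_categories + b.codes
    return CategoricalSeries(joint, a.n_categories * b.n_categories)


def joint_entropy(a: CategoricalSeries, b: CategoricalSeries) -> float:
    """Joint entropy H(X, Y) in bits from the empirical joint distribution."""
    return entropy(_pair_codes(a, b))


def conditional_entropy(a: CategoricalSeries, given_b: CategoricalSeries) -> float:
    """Conditional entropy H(X | Y) = H(X, Y) - H(Y), in bits."""
    return joint_entropy(a, given_b) - entropy(given_b)


def information_factor(a: CategoricalSeries, b: CategoricalSeries) -> float:
    """Mutual information I(X, Y) = H(X) - H(X | Y), in bits.

    Zero iff the empirical joint factorizes (the variables are empirically
    independent); symmetric in its arguments.  Tiny negative values from
    floating-point cancellation are clipped to zero.
    """
    value = entropy(a) - conditional_entropy(a, b)
    return max(value, 0.0)


def symmetrical_uncertainty(a: CategoricalSeries, b: CategoricalSeries) -> float:
    """SU(X, Y) = 2 I(X, Y) / (H(X) + H(Y)), normalized to [0, 1].

    Values near one mean the variables are strongly dependent; near zero,
    independent.  When both variables are constant the denominator vanishes
    and SU is defined as 0 (constants carry no information).
    """
    ha, hb = entropy(a), entropy(b)
    denom = ha + hb
    if denom == 0.0:
        return 0.0
    su = 2.0 * information_factor(a, b) / denom
    return float(min(max(su, 0.0), 1.0))


@dataclass
class RelevanceProfile:
    """Feature-class and feature-feature symmetrical uncertainties.

    ``su_fc[i]`` is SU between feature i and the class label; ``su_ff[i, j]``
    is SU between features i and j.  ``su_ff`` is symmetric with unit
    diagonal for non-constant features.
    """

    su_fc: np.ndarray
    su_ff: np.ndarray

    def __post_init__(self) -> None:
        self.su_fc = np.asarray(self.su_fc, dtype=float)
        self.su_ff = np.asarray(self.su_ff, dtype=float)
        f = self.su_fc.size
        if self.su_ff.shape != (f, f):
            raise ValueError("su_ff must be F x F matching su_fc")
        if not np.allclose(self.su_ff, self.su_ff.T, atol=1e-12):
            raise ValueError("su_ff must be symmetric")
        for arr in (self.su_fc, self.su_ff):
            if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
                raise ValueError("SU values must lie in [0, 1]")

    @property
    def n_features(self) -> int:
        return self.su_fc.size

    def to_json(self, path: str | Path) -> None:
        payload = {"su_fc": self.su_fc.tolist(), "su_ff": self.su_ff.tolist()}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "RelevanceProfile":
        payload = json.loads(Path(path).read_text())
        return cls(np.array(payload["su_fc"]), np.array(payload["su_ff"]))


def relevance_profile(
    table: FeatureTable,
    scheme: DiscretizationScheme | None = None,
    *,
    include_ff: bool = True,
) -> RelevanceProfile:
    """Compute SU_FC for every feature and (optionally) the SU_FF matrix.

    ``include_ff=False`` skips the O(F^2) feature-feature pass and leaves an
    identity-diagonal zero matrix; selection modes that only use feature-class
    relevance do not need the full pairwise matrix.
    """
    y = table.require_labels()
    scheme = scheme or DiscretizationScheme()
    series = discretize(table, scheme)
    f = table.n_features
    su_fc = np.array([symmetrical_uncertainty(s, y) for s in series])
    su_ff = np.zeros((f, f))
    if include_ff:
        entropies = [entropy(s) for s in series]
        for i in range(f):
            su_ff[i, i] = 1.0 if entropies[i] > 0 else 0.0
            for j in range(i + 1, f):
                su_ff[i, j] = su_ff[j, i] = symmetrical_uncertainty(series[i], series[j])
    else:
        np.fill_diagonal(su_ff, [1.0 if entropy(s) > 0 else 0.0 for s in series])
    return RelevanceProfile(su_fc=su_fc, su_ff=su_ff)


def _check_unit_interval(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.size and (values.min() < -_TOL or values.max() > 1 + _TOL):
        raise ValueError(f"{name} entries must lie in [0, 1]")
    return np.clip(values, 0.0, 1.0)


def heuristic_fc(su_fc: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Relevance desirability eta_i = 1 / (1 - SU_FC_i).

    Strictly increasing in SU_FC and >= 1; as SU_FC approaches 1 the map
    diverges, so SU_FC is clamped at ``1 - epsilon`` (a perfectly
    class-determined feature gets desirability ``1/epsilon``).
    """
    su = _check_unit_interval(su_fc, "su_fc")
    return 1.0 / (1.0 - np.minimum(su, 1.0 - epsilon))


def heuristic_ff(su_ff: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Redundancy desirability eta_ij = 1 / SU_FF_ij.

    Strictly decreasing in SU_FF: near-duplicate feature pairs (SU -> 1) are
    undesirable, unrelated pairs desirable.  SU_FF is clamped below at
    ``epsilon`` where the map diverges.
    """
    su = _check_unit_interval(su_ff, "su_ff")
    return 1.0 / np.maximum(su, epsilon)
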