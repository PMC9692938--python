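"""Ant colony optimization over feature subsets.

Features are nodes of a fully connected graph.  Each ant starts on a random
node and grows a fixed-size subset by repeatedly applying the pseudo-random
proportional rule: with probability ``q0`` it greedily takes the unvisited
node maximizing ``tau^alpha * eta^beta`` (pheromone times heuristic
desirability), otherwise it samples proportionally to those weights.  After
all ants finish an iteration, every subset is scored — by inverse
cross-validated classifier error (wrapper mode) or by its mean heuristic
desirability (filter mode) — and each ant deposits its score on the features
it visited, after global evaporation by ``1 - rho``:

    tau_i(t+1) = (1 - rho) * tau_i(t) + sum_ants delta_tau_i

The heuristic desirability ``eta`` comes from symmetrical uncertainty:
feature-class relevance (``fc``), feature-feature non-redundancy relative to
the last visited node (``ff``), or a combination that divides relevance by
one plus redundancy (``combined``).

All randomness flows through a single seeded generator, so a run is a pure
function of its inputs and configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .evaluation import ClassifierSpec, cross_val_error
from .info_theory import (
    DEFAULT_EPSILON,
    DiscretizationScheme,
    RelevanceProfile,
    heuristic_fc,
    heuristic_ff,
    relevance_profile,
)
from .table import FeatureTable

__all__ = [
    "ACOConfig",
    "PheromoneState",
    "AntTour",
    "SubsetScore",
    "SelectionResult",
    "init_pheromone",
    "node_desirability",
    "transition_probabilities",
    "choose_next",
    "construct_tour",
    "evaluate_subset",
    "update_pheromone",
    "run_aco",
    "random_subset_baseline",
]

HEURISTIC_MODES = ("fc", "ff", "combined")
DEPOSIT_MODES = ("wrapper", "filter")

#: Floor on the cross-validation error in wrapper scoring; a perfectly
#: separable subset therefore deposits at most 1/1e-3 = 1000.
MIN_CV_ERROR = 1e-3


@dataclass
class ACOConfig:
    """Tunable knobs of the selector.

    alpha, beta
        Exponents weighting pheromone versus heuristic desirability in the
        transition rule.
    rho
        Evaporation rate in (0, 1); each iteration retains ``1 - rho`` of the
        existing pheromone before deposits.
    q0
        Greediness threshold in [0, 1]: the fraction of steps resolved by
        argmax rather than probabilistic sampling.
    subset_size
        Tour length k (features per ant).  ``None`` defaults to
        ``ceil(F / 10)`` at run time.
    heuristic_mode
        ``fc`` (class relevance), ``ff`` (pairwise non-redundancy) or
        ``combined``.
    deposit_mode
        ``wrapper`` (inverse cross-validated error) or ``filter`` (mean
        heuristic desirability).
    acs_convention
        The transition rule is implemented as printed in the source model
        (q < q0 selects the greedy branch); setting this flag flips the
        inequality to the canonical ant-colony-system direction.
    """

    alpha: float = 1.0
    beta: float = 1.0
    rho: float = 0.1
    q0: float = 0.8
    n_ants: int = 20
    n_iterations: int = 50
    subset_size: int | None = None
    heuristic_mode: str = "fc"
    deposit_mode: str = "wrapper"
    seed: int = 0
    epsilon: float = DEFAULT_EPSILON
    acs_convention: bool = False
    cv_folds: int = 5
    classifier: ClassifierSpec | None = None
    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie strictly in (0, 1)")
        if not 0 <= self.q0 <= 1:
            raise ValueError("q0 must lie in [0, 1]")
        if self.n_ants < 1 or self.n_iterations < 1:
            raise ValueError("n_ants and n_iterations must be positive")
        if self.subset_size is not None and self.subset_size < 1:
            raise ValueError("subset_size must be positive")
        if self.heuristic_mode not in HEURISTIC_MODES:
            raise ValueError(f"heuristic_mode must be one of {HEURISTIC_MODES}")
        if self.deposit_mode not in DEPOSIT_MODES:
            raise ValueError(f"deposit_mode must be one of {DEPOSIT_MODES}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    def resolve_subset_size(self, n_features: int) -> int:
        k = self.subset_size if self.subset_size is not None else math.ceil(n_features / 10)
        if k > n_features:
            raise ValueError(f"subset_size {k} exceeds feature count {n_features}")
        return k

    def as_dict(self) -> dict:
        out = {
            k: v
            for k, v in self.__dict__.items()
            if k != "classifier"
        }
        out["classifier"] = self.classifier.describe() if self.classifier else None
        return out


@dataclass
class PheromoneState:
    """Per-feature pheromone trail, strictly positive, with iteration count."""

    tau: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau.ndim != 1 or self.tau.size < 1:
            raise ValueError("tau must be a non-empty vector")
        if not np.all(np.isfinite(self.tau)) or self.tau.min() <= 0:
            raise ValueError("pheromone values must be finite and strictly positive")
        if self.iteration < 0:
            raise ValueError("iteration must be non-negative")


@dataclass
class AntTour:
    """Ordered distinct feature indices visited by one ant."""

    visited: list[int]

    def __post_init__(self) -> None:
        if len(set(self.visited)) != len(self.visited):
            raise ValueError("tour revisits a node")


@dataclass(frozen=True)
class SubsetScore:
    """Quality of one subset: deposit value plus the CV error if measured."""

    value: float
    cv_error: float | None = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("subset score must be strictly positive")


@dataclass
class SelectionResult:
    """Outcome of a selection run: the winning subset and its trajectory."""

    best_subset: list[int]
    best_score: float
    history: list[float]
    final_tau: np.ndarray
    seed: int
    config: dict = field(default_factory=dict)
    best_cv_error: float | None = None

    def as_dict(self) -> dict:
        return {
            "best_subset": [int(i) for i in self.best_subset],
            "best_score": self.best_score,
            "best_cv_error": self.best_cv_error,
            "history": list(self.history),
            "final_tau": np.asarray(self.final_tau).tolist(),
            "seed": self.seed,
            "config": self.config,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))


def init_pheromone(n_features: int) -> PheromoneState:
    """Uniform initial trail: every feature starts at pheromone 1."""
    if n_features < 1:
        raise ValueError("need at least one feature")
    return PheromoneState(tau=np.ones(n_features), iteration=0)


def node_desirability(
    tau: np.ndarray, eta: np.ndarray, alpha: float, beta: float
) -> np.ndarray:
    """Elementwise ``|tau|^alpha * |eta|^beta`` — the transition-rule weight."""
    tau = np.asarray(tau, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if tau.shape != eta.shape:
        raise ValueError("tau and eta must have the same length")
    return np.abs(tau) ** alpha * np.abs(eta) ** beta


def _visited_mask(visited: Sequence[int] | AntTour, n: int) -> np.ndarray:
    idx = visited.visited if isinstance(visited, AntTour) else list(visited)
    mask = np.zeros(n, dtype=bool)
    if idx:
        mask[np.asarray(idx, dtype=int)] = True
    return mask


def transition_probabilities(
    desirability: np.ndarray, visited: Sequence[int] | AntTour
) -> np.ndarray:
    """Normalize desirability over unvisited nodes; visited nodes get 0."""
    d = np.asarray(desirability, dtype=float)
    mask = _visited_mask(visited, d.size)
    if mask.all():
        raise ValueError("all nodes already visited")
    weights = np.where(mask, 0.0, d)
    total = weights.sum()
    if total <= 0:
        raise ValueError("total desirability over unvisited nodes is zero")
    return weights / total


def choose_next(
    desirability: np.ndarray,
    visited: Sequence[int] | AntTour,
    q0: float,
    rng: np.random.Generator,
    acs_convention: bool = False,
) -> int:
    """Pseudo-random proportional rule: greedy argmax or proportional draw.

    A uniform q is drawn; ``q < q0`` takes the greedy branch (as printed in
    the source transition rule; flipped when ``acs_convention``).  Greedy
    ties break to the lowest index.
    """
    d = np.asarray(desirability, dtype=float)
    mask = _visited_mask(visited, d.size)
    if mask.all():
        raise ValueError("all nodes already visited")
    q = rng.random()
    greedy = (q < q0) if not acs_convention else (q >= q0)
    if greedy:
        masked = np.where(mask, -np.inf, d)
        return int(np.argmax(masked))
    p = transition_probabilities(d, visited)
    return int(rng.choice(d.size, p=p))


class _HeuristicEngine:
    """Per-step eta vectors for each heuristic mode, from a relevance profile."""

    def __init__(self, profile: RelevanceProfile, mode: str, epsilon: float) -> None:
        self.mode = mode
        self.epsilon = epsilon
        self.su_ff = profile.su_ff
        self.eta_fc = heuristic_fc(profile.su_fc, epsilon)

    def step_eta(self, last_node: int | None) -> np.ndarray:
        if self.mode == "fc" or last_node is None:
            return self.eta_fc
        if self.mode == "ff":
            return heuristic_ff(self.su_ff[last_node], self.epsilon)
        # combined: relevance damped by redundancy with the last visited node
        return self.eta_fc / (1.0 + self.su_ff[last_node])

    def static_desirability(self) -> np.ndarray:
        """Per-node desirability used for filter-mode subset scoring."""
        if self.mode == "fc":
            return self.eta_fc
        f = self.su_ff.shape[0]
        off_diag = self.su_ff[~np.eye(f, dtype=bool)].reshape(f, f - 1) if f > 1 else np.zeros((f, 0))
        mean_redundancy = off_diag.mean(axis=1) if f > 1 else np.zeros(f)
        if self.mode == "ff":
            return 1.0 / np.maximum(mean_redundancy, self.epsilon)
        return self.eta_fc / (1.0 + mean_redundancy)


def construct_tour(
    state: PheromoneState,
    engine: _HeuristicEngine,
    config: ACOConfig,
    rng: np.random.Generator,
    subset_size: int,
) -> AntTour:
    """Grow one ant's subset: random start, then k-1 transition-rule steps."""
    n = state.tau.size
    if subset_size > n:
        raise ValueError("subset_size exceeds number of features")
    visited = [int(rng.integers(n))]
    while len(visited) < subset_size:
        eta = engine.step_eta(visited[-1])
        d = node_desirability(state.tau, eta, config.alpha, config.beta)
        visited.append(choose_next(d, visited, config.q0, rng, config.acs_convention))
    return AntTour(visited=visited)


def evaluate_subset(
    table: FeatureTable,
    subset: Sequence[int],
    config: ACOConfig,
    desirability: np.ndarray | None = None,
    cv_seed: int | None = None,
) -> SubsetScore:
    """Score a subset for pheromone deposit.

    Wrapper mode: stratified k-fold CV error of the evaluation classifier on
    the restricted table; deposit = 1/max(error, 1e-3).  Filter mode: mean
    static heuristic desirability of the subset's nodes.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("cannot score an empty subset")
    if config.deposit_mode == "wrapper":
        err = cross_val_error(
            table,
            subset,
            spec=config.classifier,
            folds=config.cv_folds,
            seed=config.seed if cv_seed is None else cv_seed,
        )
        return SubsetScore(value=1.0 / max(err, MIN_CV_ERROR), cv_error=err)
    if desirability is None:
        profile = relevance_profile(
            table,
            DiscretizationScheme(n_bins=config.n_bins),
            include_ff=config.heuristic_mode != "fc",
        )
        desirability = _HeuristicEngine(
            profile, config.heuristic_mode, config.epsilon
        ).static_desirability()
    return SubsetScore(value=float(np.mean(np.asarray(desirability)[subset])))


def update_pheromone(
    state: PheromoneState,
    tours: Sequence[AntTour],
    scores: Sequence[SubsetScore],
    rho: float,
) -> PheromoneState:
    """Evaporate by ``1 - rho`` then add every ant's deposit on its tour."""
    if not 0 < rho < 1:
        raise ValueError("rho must lie strictly in (0, 1)")
    if len(tours) != len(scores):
        raise ValueError("tours and scores must align")
    tau = (1.0 - rho) * state.tau
    for tour, score in zip(tours, scores):
        tau[np.asarray(tour.visited, dtype=int)] += score.value
    return PheromoneState(tau=tau, iteration=state.iteration + 1)


def run_aco(
    table: FeatureTable,
    config: ACOConfig,
    profile: RelevanceProfile | None = None,
) -> SelectionResult:
    """Run the full selection loop and return the best subset found.

    Per iteration: every ant builds a tour, each tour is scored, the global
    best is tracked (so the history is non-decreasing), and all ants deposit
    on their tours after evaporation.  Identical inputs and seed give an
    identical result.  Wrapper CV scores are cached per subset — scoring is
    deterministic within a run, so the cache only removes repeated work.
    """
    table.require_labels()
    n_features = table.n_features
    k = config.resolve_subset_size(n_features)
    if profile is None:
        profile = relevance_profile(
            table,
            DiscretizationScheme(n_bins=config.n_bins),
            include_ff=config.heuristic_mode != "fc",
        )
    engine = _HeuristicEngine(profile, config.heuristic_mode, config.epsilon)
    static_desirability = engine.static_desirability()
    rng = np.random.default_rng(config.seed)
    cv_seed = int(rng.integers(2**31))
    state = init_pheromone(n_features)

    best_subset: tuple[int, ...] | None = None
    best = None
    history: list[float] = []
    cache: dict[tuple[int, ...], SubsetScore] = {}

    for _ in range(config.n_iterations):
        tours: list[AntTour] = []
        scores: list[SubsetScore] = []
        for _ant in range(config.n_ants):
            tour = construct_tour(state, engine, config, rng, k)
            key = tuple(sorted(tour.visited))
            score = cache.get(key)
            if score is None:
                score = evaluate_subset(
                    table, key, config, desirability=static_desirability, cv_seed=cv_seed
                )
                cache[key] = score
            tours.append(tour)
            scores.append(score)
            if best is None or score.value > best.value:
                best = score
                best_subset = key
        state = update_pheromone(state, tours, scores, config.rho)
        history.append(best.value)

    assert best is not None and best_subset is not None
    return SelectionResult(
        best_subset=list(best_subset),
        best_score=best.value,
        best_cv_error=best.cv_error,
        history=history,
        final_tau=state.tau,
        seed=config.seed,
        config=config.as_dict(),
    )


def random_subset_baseline(
    n_features: int, k: int, rng: np.random.Generator
) -> list[int]:
    """Uniform k-subset of features without replacement (comparison baseline)."""
    if k > n_features:
        raise ValueError("k exceeds number of features")
    return sorted(int(i) for i in rng.choice(n_features, size=k, replace=False))
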