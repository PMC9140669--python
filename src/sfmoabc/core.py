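"""The SFMOABC optimizer: a multi-objective artificial bee colony search
for two-locus epistasis, guided by a Barabasi-Albert scale-free network.

Each food source is a candidate SNP pair encoded as a continuous position
in [1, n_snps]^k and decoded to distinct column indices.  Every iteration
the population is re-sorted by fitness and re-mapped onto the network's
node ids, so the current best m0 solutions sit on the hub nodes ("elite"
sources) and the rest on the peripheral nodes ("normal" sources).  Normal
sources drift toward the highest-degree neighbor of their node; elite
sources add a random-jump term to avoid hub collapse; every candidate is
paired with its opposition point (mirrored through the search bounds) and
the better of the two competes greedily with the incumbent.  Onlooker
bees re-update sources selected by roulette on fitness, and a single
scout per iteration replaces the most stagnant source once its trail
counter exceeds ``limit``.

Scores are memoized per unordered SNP pair: ``n_evaluations`` counts
actual objective computations (cache misses), while candidate-level
accounting (``iteration_candidate_evals``) tracks the classic ABC budget
of 4N + scout requests per iteration (2N + scout for the single-objective
baselines).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genotype_data import GenotypeDataset
from .objectives import (
    ContingencyTable,
    association_p_value,
    fitness,
    k2_log_score,
    mutual_information,
)
from .scalefree import ScaleFreeNetwork, build_ba_network, max_degree_neighbor

__all__ = [
    "FoodSource",
    "SearchConfig",
    "SolutionRecord",
    "SearchResult",
    "Evaluator",
    "decode_position",
    "initialize_population",
    "update_normal",
    "update_elite",
    "opposition",
    "greedy_step",
    "selection_probabilities",
    "onlooker_phase",
    "scout_phase",
    "run",
    "run_single_objective",
]

OBJECTIVES = ("multi", "mi_only", "k2_only")


@dataclass
class SearchConfig:
    """Search hyperparameters (defaults follow the small-scale protocol:
    100 bees, 50 iterations, limit 10, m0 = 3 hubs, 2 links per node)."""

    n_sources: int = 100
    max_iter: int = 50
    limit: int = 10
    m0: int = 3
    n_links: int = 2
    order: int = 2
    seed: int = 0
    objective: str = "multi"
    top_k_report: int = 10

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}")
        if self.n_sources < self.m0:
            raise ValueError("n_sources must be >= m0")
        if self.limit < 1 or self.max_iter < 1:
            raise ValueError("limit and max_iter must be >= 1")
        if not (1 <= self.n_links < self.m0):
            raise ValueError("need 1 <= n_links < m0")


@dataclass
class FoodSource:
    """One candidate SNP combination and its cached objective values."""

    position: np.ndarray  # decoded grid point in [1, n_snps]^k
    combo: tuple[int, ...]  # sorted 0-based column indices
    mi: float
    k2log: float
    fit: float
    value: float  # selection value under the active objective
    trail: int = 0


@dataclass(frozen=True)
class SolutionRecord:
    combo: tuple[int, ...]
    mi: float
    k2log: float
    fit: float
    p_value: float


@dataclass
class SearchResult:
    """Outcome of one search run.

    ``ranked`` lists every distinct combination ever evaluated, best
    first under the run's objective; ``n_evaluations`` is the number of
    distinct objective computations actually performed.
    """

    ranked: list[SolutionRecord]
    best_trace: list[float]
    n_evaluations: int
    seed: int
    objective: str = "multi"
    n_candidate_evaluations: int = 0
    iteration_candidate_evals: list[int] = field(default_factory=list)
    iteration_scout_fired: list[bool] = field(default_factory=list)

    @property
    def best(self) -> SolutionRecord:
        return self.ranked[0]


class Evaluator:
    """Memoizing objective evaluator over unordered SNP combinations."""

    def __init__(self, ds: GenotypeDataset, objective: str = "multi") -> None:
        if objective not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}")
        self.genotypes = np.ascontiguousarray(ds.genotypes, dtype=np.int64)
        self.phenotype = np.ascontiguousarray(ds.phenotype, dtype=np.int64)
        self.n_snps = ds.n_snps
        self.objective = objective
        self.cache: dict[tuple[int, ...], tuple[float, float, float, float]] = {}
        self.n_computed = 0  # distinct objective computations
        self.n_requests = 0  # candidate evaluations incl. cache hits
        self.best_value = -np.inf

    def counts_for(self, combo: tuple[int, ...]) -> ContingencyTable:
        code = np.zeros(len(self.phenotype), dtype=np.int64)
        for c in combo:
            code = code * 3 + self.genotypes[:, c]
        k = len(combo)
        flat = np.bincount(code * 2 + self.phenotype, minlength=2 * 3**k)
        return ContingencyTable(flat.reshape(3**k, 2))

    def score(self, combo: tuple[int, ...]) -> tuple[float, float, float, float]:
        """(mi, k2log, fit, value) for a sorted 0-based combo."""
        self.n_requests += 1
        rec = self.cache.get(combo)
        if rec is None:
            t = self.counts_for(combo)
            mi = mutual_information(t)
            k2 = k2_log_score(t)
            fit = fitness(mi, k2)
            if self.objective == "multi":
                value = fit
            elif self.objective == "mi_only":
                value = mi
            else:  # k2_only: decreasing transform so selection favors low K2log
                value = 1.0 / (1.0 + k2)
            rec = (mi, k2, fit, value)
            self.cache[combo] = rec
            self.n_computed += 1
            if value > self.best_value:
                self.best_value = value
        return rec

    def ranked_records(self) -> list[SolutionRecord]:
        order = sorted(self.cache.items(), key=lambda kv: (-kv[1][3], kv[0]))
        return [
            SolutionRecord(
                combo=combo,
                mi=mi,
                k2log=k2,
                fit=fit,
                p_value=association_p_value(self.counts_for(combo)),
            )
            for combo, (mi, k2, fit, _) in order
        ]


def decode_position(position: np.ndarray, n_snps: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Map a continuous position onto distinct 1-based SNP grid indices.

    Each coordinate is rounded half-up and clamped to [1, n_snps]; when a
    coordinate collides with an earlier one, the later coordinate is
    redrawn uniformly until distinct.  ``position`` is overwritten with
    the decoded integers; the returned tuple keeps coordinate order.
    """
    vals = np.clip(np.floor(np.asarray(position, dtype=float) + 0.5), 1, n_snps)
    vals = vals.astype(np.int64)
    seen: set[int] = set()
    for j, v in enumerate(vals):
        v = int(v)
        while v in seen:
            v = int(rng.integers(1, n_snps + 1))
        seen.add(v)
        vals[j] = v
    position[:] = vals
    return tuple(int(v) for v in vals)


def _make_source(position: np.ndarray, ev: Evaluator, rng: np.random.Generator) -> FoodSource:
    pos = np.asarray(position, dtype=float).copy()
    grid = decode_position(pos, ev.n_snps, rng)
    combo = tuple(sorted(g - 1 for g in grid))
    mi, k2, fit, value = ev.score(combo)
    return FoodSource(position=pos, combo=combo, mi=mi, k2log=k2, fit=fit, value=value)


def _uniform_source(ev: Evaluator, cfg: SearchConfig, rng: np.random.Generator) -> FoodSource:
    lb, ub = 1.0, float(ev.n_snps)
    pos = lb + rng.random(cfg.order) * (ub - lb)
    return _make_source(pos, ev, rng)


def _sort_population(pop: list[FoodSource]) -> None:
    pop.sort(key=lambda s: (-s.value, s.combo))


def initialize_population(
    ds: GenotypeDataset,
    cfg: SearchConfig,
    rng: Optional[np.random.Generator] = None,
    ev: Optional[Evaluator] = None,
) -> tuple[list[FoodSource], ScaleFreeNetwork]:
    """Draw, evaluate and fitness-sort N food sources, then build the BA
    network whose node count matches; source ranked r sits on node id r,
    so the top m0 sources occupy the hubs (elite food sources)."""
    if ds.n_snps < 2 * cfg.order:
        raise ValueError(
            f"need n_snps >= {2 * cfg.order} for distinct order-{cfg.order} combos"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if ev is None:
        ev = Evaluator(ds, cfg.objective)
    pop = [_uniform_source(ev, cfg, rng) for _ in range(cfg.n_sources)]
    _sort_population(pop)
    net = build_ba_network(
        cfg.n_sources, cfg.m0, cfg.n_links, seed=int(rng.integers(2**31))
    )
    return pop, net


def update_normal(
    src: FoodSource,
    neighbor_best: FoodSource,
    ev: Evaluator,
    rng: np.random.Generator,
) -> FoodSource:
    """Normal-source move: v_j = x_j + U(0,1) (x_nei,j - x_j), one
    independent uniform draw per dimension."""
    r = rng.random(len(src.position))
    v = src.position + r * (neighbor_best.position - src.position)
    return _make_source(v, ev, rng)


def update_elite(
    src: FoodSource,
    neighbor_best: FoodSource,
    ev: Evaluator,
    rng: np.random.Generator,
    lb: float,
    ub: float,
) -> FoodSource:
    """Elite-source move adds a random jump away from a uniformly drawn
    point of the solution space:
    v_j = x_j + U(-1,1) (x_j - x_k,j) + U(0,1) (x_nei,j - x_j)."""
    k = len(src.position)
    x_rand = lb + rng.random(k) * (ub - lb)
    v = (
        src.position
        + rng.uniform(-1.0, 1.0, k) * (src.position - x_rand)
        + rng.random(k) * (neighbor_best.position - src.position)
    )
    return _make_source(v, ev, rng)


def opposition(v: np.ndarray, lb: float, ub: float) -> np.ndarray:
    """Opposition-based learning point u_j = ub + lb - v_j."""
    return (ub + lb) - np.asarray(v, dtype=float)


def greedy_step(src: FoodSource, v: FoodSource, u: FoodSource) -> FoodSource:
    """Pick the better of candidate and opposed candidate (ties favor the
    opposed point), then compare with the incumbent: strict improvement
    replaces it and resets trail, otherwise trail increments."""
    winner = v if v.value > u.value else u
    if winner.value > src.value:
        winner.trail = 0
        return winner
    src.trail += 1
    return src


def selection_probabilities(values: np.ndarray) -> np.ndarray:
    """Roulette probabilities P_i = value_i / sum(values); uniform when
    every value is zero."""
    v = np.asarray(values, dtype=float)
    total = v.sum()
    if total <= 0:
        return np.full(len(v), 1.0 / len(v))
    return v / total


def _neighbor_source(pop: list[FoodSource], net: ScaleFreeNetwork, node: int) -> FoodSource:
    # edgeless stub networks (test mode) degrade to a self-neighbor,
    # collapsing the network term of the update
    if not net.adjacency.get(node):
        return pop[node - 1]
    return pop[max_degree_neighbor(net, node) - 1]


def _update_at(
    pop: list[FoodSource],
    idx: int,
    net: ScaleFreeNetwork,
    ev: Evaluator,
    cfg: SearchConfig,
    rng: np.random.Generator,
) -> None:
    """One employed-bee style update of the source on node idx+1:
    elite/normal move, opposition pair, greedy replacement."""
    node = idx + 1
    src = pop[idx]
    nbr = _neighbor_source(pop, net, node)
    lb, ub = 1.0, float(ev.n_snps)
    if node <= cfg.m0:
        v = update_elite(src, nbr, ev, rng, lb, ub)
    else:
        v = update_normal(src, nbr, ev, rng)
    u = _make_source(opposition(v.position, lb, ub), ev, rng)
    pop[idx] = greedy_step(src, v, u)


def onlooker_phase(
    pop: list[FoodSource],
    net: ScaleFreeNetwork,
    ev: Evaluator,
    cfg: SearchConfig,
    rng: np.random.Generator,
) -> None:
    """Cycle over sources; whenever U(0,1) > P_i the unselected source i is
    re-updated exactly as in the employed phase.  Exactly N update events
    are performed, then the phase ends."""
    probs = selection_probabilities([s.value for s in pop])
    n = len(pop)
    i, t = 0, 0
    while t < n:
        if rng.random() > probs[i]:
            _update_at(pop, i, net, ev, cfg, rng)
            t += 1
        i = (i + 1) % n


def scout_phase(
    pop: list[FoodSource],
    ev: Evaluator,
    cfg: SearchConfig,
    rng: np.random.Generator,
) -> bool:
    """Examine only the single most-stagnant source (max trail, ties to the
    smallest index); replace it with a fresh uniform draw once its trail
    exceeds ``limit`` — even if the replacement is worse.  Returns whether
    a replacement happened."""
    h = max(range(len(pop)), key=lambda i: (pop[i].trail, -i))
    if pop[h].trail > cfg.limit:
        pop[h] = _uniform_source(ev, cfg, rng)
        return True
    return False


def run(ds: GenotypeDataset, cfg: SearchConfig) -> SearchResult:
    """Run the full SFMOABC search (or a single-objective baseline when
    ``cfg.objective`` is not ``multi``).

    Per iteration: re-sort the population by fitness and re-map it onto
    the immutable network (top m0 on the hubs); employed phase; onlooker
    phase; scout phase.  Fully reproducible from ``cfg.seed``.
    """
    if cfg.objective != "multi":
        return run_single_objective(ds, cfg)
    rng = np.random.default_rng(cfg.seed)
    ev = Evaluator(ds, cfg.objective)
    pop, net = initialize_population(ds, cfg, rng, ev)
    net_hash = net.structural_hash()

    best_trace: list[float] = []
    iter_evals: list[int] = []
    scouts: list[bool] = []
    for _ in range(cfg.max_iter):
        _sort_population(pop)
        start = ev.n_requests
        for idx in range(cfg.n_sources):
            _update_at(pop, idx, net, ev, cfg, rng)
        onlooker_phase(pop, net, ev, cfg, rng)
        scouts.append(scout_phase(pop, ev, cfg, rng))
        iter_evals.append(ev.n_requests - start)
        best_trace.append(ev.best_value)

    if net.structural_hash() != net_hash:
        raise RuntimeError("scale-free network mutated during the search")
    return SearchResult(
        ranked=ev.ranked_records(),
        best_trace=best_trace,
        n_evaluations=ev.n_computed,
        seed=cfg.seed,
        objective=cfg.objective,
        n_candidate_evaluations=ev.n_requests,
        iteration_candidate_evals=iter_evals,
        iteration_scout_fired=scouts,
    )


def _abc_update_at(
    pop: list[FoodSource],
    idx: int,
    ev: Evaluator,
    rng: np.random.Generator,
) -> None:
    """Classic ABC move v_j = x_j + U(-1,1) (x_j - x_k,j) with a random
    peer k != i; no network, no opposition; strict greedy."""
    src = pop[idx]
    k = int(rng.integers(len(pop) - 1))
    if k >= idx:
        k += 1
    peer = pop[k]
    r = rng.uniform(-1.0, 1.0, len(src.position))
    v = _make_source(src.position + r * (src.position - peer.position), ev, rng)
    if v.value > src.value:
        v.trail = 0
        pop[idx] = v
    else:
        src.trail += 1


def run_single_objective(ds: GenotypeDataset, cfg: SearchConfig) -> SearchResult:
    """Single-objective ABC baseline (ABC_MI or ABC_K2): same phase
    structure as the main search but with the classic peer-difference
    update, no scale-free network and no opposition point."""
    if cfg.objective == "multi":
        raise ValueError("run_single_objective needs objective mi_only or k2_only")
    if ds.n_snps < 2 * cfg.order:
        raise ValueError(
            f"need n_snps >= {2 * cfg.order} for distinct order-{cfg.order} combos"
        )
    rng = np.random.default_rng(cfg.seed)
    ev = Evaluator(ds, cfg.objective)
    pop = [_uniform_source(ev, cfg, rng) for _ in range(cfg.n_sources)]
    _sort_population(pop)

    best_trace: list[float] = []
    iter_evals: list[int] = []
    scouts: list[bool] = []
    for _ in range(cfg.max_iter):
        _sort_population(pop)
        start = ev.n_requests
        for idx in range(cfg.n_sources):
            _abc_update_at(pop, idx, ev, rng)
        probs = selection_probabilities([s.value for s in pop])
        n = len(pop)
        i, t = 0, 0
        while t < n:
            if rng.random() > probs[i]:
                _abc_update_at(pop, i, ev, rng)
                t += 1
            i = (i + 1) % n
        scouts.append(scout_phase(pop, ev, cfg, rng))
        iter_evals.append(ev.n_requests - start)
        best_trace.append(ev.best_value)

    return SearchResult(
        ranked=ev.ranked_records(),
        best_trace=best_trace,
        n_evaluations=ev.n_computed,
        seed=cfg.seed,
        objective=cfg.objective,
        n_candidate_evaluations=ev.n_requests,
        iteration_candidate_evals=iter_evals,
        iteration_scout_fired=scouts,
    )
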