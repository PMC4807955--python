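"""Harmony-search screening over all SNP pairs with a tabu registry.

The screening stage keeps two fixed-size harmony memories: HM1 ordered by
the K2 score, HM2 by the Gini score.  Each iteration improvises a candidate
pair (harmony-memory consideration with pitch adjustment, else a uniform
random pair), and a tabu registry over all C(N,2) pairs guarantees that no
pair is ever scored twice: a candidate that was already visited is replaced
by a nearby unvisited pair found by a short random walk along a doubly
linked list of unvisited pairs.  With the evaluation budget set to C(N,2)
the run degenerates to an exhaustive scan, so both per-criterion optima are
found with certainty.

Pairs are 0-based ``(low, high)`` tuples internally; the classic triangular
linearization is defined on 1-based indices (as it is usually written) with
thin wrappers converting at the boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .data import GenotypeDataset, build_contingency
from .scoring import ScoredModel, gini_score, is_better, k2_neglog_score

__all__ = [
    "SearchConfig",
    "HarmonyMemory",
    "TabuRegistry",
    "SearchExhausted",
    "ScreeningResult",
    "pair_to_linear",
    "linear_to_pair",
    "draw_bw",
    "improvise",
    "local_search_unvisited",
    "fhsa_run",
]


class SearchExhausted(RuntimeError):
    """Every one of the C(N,2) pairs has been visited; nothing left to score."""


@dataclass(frozen=True)
class SearchConfig:
    """Tunable parameters of the screening stage.

    Defaults follow the standard benchmark setting: harmony-memory
    consideration rate 0.9, pitch-adjustment rate 0.35, two memories of 100
    harmonies, and a 4500-evaluation budget for 100-SNP data.  ``alpha0`` is
    the base significance level handed to the testing stage.
    """

    hmcr: float = 0.9
    par: float = 0.35
    hms1: int = 100
    hms2: int = 100
    mmes: int = 4500
    seed: int = 0
    alpha0: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.hmcr <= 1.0 and 0.0 <= self.par <= 1.0):
            raise ValueError("HMCR and PAR must lie in [0, 1]")
        if self.hms1 < 1 or self.hms2 < 1:
            raise ValueError("harmony memory sizes must be >= 1")
        if self.mmes < 1:
            raise ValueError("evaluation budget MMEs must be >= 1")
        if not 0.0 < self.alpha0 <= 1.0:
            raise ValueError("alpha0 must lie in (0, 1]")

    def with_seed(self, seed: int) -> "SearchConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# Pair <-> linear index (triangular linearization, 1-based)


def pair_to_linear(i: int, j: int, n: int) -> int:
    """Map a 1-based pair (i < j) to its linear index in 1..C(n,2).

    ``k = n(i-1) - i(i-1)/2 + (j - i)`` walks the upper triangle in row-major
    order; it is a bijection onto {1, ..., C(n,2)}.
    """
    if not (1 <= i < j <= n):
        raise ValueError(f"need 1 <= i < j <= n, got i={i}, j={j}, n={n}")
    return n * (i - 1) - i * (i - 1) // 2 + (j - i)


def linear_to_pair(k: int, n: int) -> tuple[int, int]:
    """Inverse of :func:`pair_to_linear` (1-based pair for linear index k)."""
    m = n * (n - 1) // 2
    if not 1 <= k <= m:
        raise ValueError(f"linear index {k} out of range 1..{m}")
    # row i satisfies f(i) < k <= f(i+1) with f(i) = (i-1)(2n-i)/2; solve the
    # quadratic for a float estimate, then correct by +-1.
    i = int((2 * n + 1 - math.sqrt((2 * n - 1) ** 2 - 8 * (k - 1))) / 2)
    i = max(1, min(i, n - 1))
    while n * (i - 1) - i * (i - 1) // 2 >= k:
        i -= 1
    while n * i - (i + 1) * i // 2 < k:
        i += 1
    j = i + k - (n * (i - 1) - i * (i - 1) // 2)
    return i, j


def pair_index0(pair: tuple[int, int], n: int) -> int:
    """Linear index of a 0-based canonical pair."""
    a, b = pair
    return pair_to_linear(a + 1, b + 1, n)


def linear_to_pair0(k: int, n: int) -> tuple[int, int]:
    """0-based canonical pair at linear index k."""
    i, j = linear_to_pair(k, n)
    return i - 1, j - 1


# ---------------------------------------------------------------------------
# Harmony memory


class HarmonyMemory:
    """Fixed-capacity pool of scored pairs ordered by one criterion.

    ``criterion`` selects which fitness value ("k2" or "gini") orders this
    memory.  Replacement is strict: a candidate enters only if its score is
    strictly better than the current worst, which avoids churn on ties.
    Duplicate pairs are rejected (the tabu registry makes them impossible in
    a normal run).
    """

    def __init__(self, capacity: int, criterion: str):
        if criterion not in ("k2", "gini"):
            raise ValueError(f"unknown criterion {criterion!r}")
        self.capacity = int(capacity)
        self.criterion = criterion
        self.entries: list[ScoredModel] = []
        self._pairs: set[tuple[int, int]] = set()

    def score_of(self, model: ScoredModel) -> float:
        return model.k2_neglog if self.criterion == "k2" else model.gini

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return tuple(pair) in self._pairs

    @property
    def pairs(self) -> set[tuple[int, int]]:
        return set(self._pairs)

    @property
    def best_index(self) -> int:
        return min(range(len(self.entries)), key=lambda i: self.score_of(self.entries[i]))

    @property
    def worst_index(self) -> int:
        return max(range(len(self.entries)), key=lambda i: self.score_of(self.entries[i]))

    @property
    def best(self) -> ScoredModel:
        return self.entries[self.best_index]

    @property
    def worst(self) -> ScoredModel:
        return self.entries[self.worst_index]

    def add(self, model: ScoredModel) -> None:
        """Insert during initialization; memory must not be full."""
        if len(self.entries) >= self.capacity:
            raise ValueError("harmony memory is full; use consider()")
        if model.pair in self._pairs:
            raise ValueError(f"duplicate pair {model.pair} in memory")
        self.entries.append(model)
        self._pairs.add(model.pair)

    def consider(self, model: ScoredModel) -> bool:
        """Replace the worst entry if ``model`` strictly beats it."""
        if model.pair in self._pairs:
            return False
        if len(self.entries) < self.capacity:
            self.add(model)
            return True
        w = self.worst_index
        if is_better(self.score_of(model), self.score_of(self.entries[w])):
            self._pairs.discard(self.entries[w].pair)
            self.entries[w] = model
            self._pairs.add(model.pair)
            return True
        return False


# ---------------------------------------------------------------------------
# Tabu registry over all C(N,2) pairs


class TabuRegistry:
    """Visited/unvisited bookkeeping with a doubly linked unvisited list.

    Linear indices 1..C(N,2) form a circular doubly linked list; marking an
    index visited unlinks it in O(1) while its stale pointers keep aiming at
    its former neighbors, so a walk starting from a visited index reaches the
    live (unvisited) list after following successors.  Memory cost is two
    int32 arrays plus a bit-like visited flag per pair, O(C(N,2)).
    """

    def __init__(self, n_snps: int):
        if n_snps < 2:
            raise ValueError("need at least two SNPs")
        self.n_snps = int(n_snps)
        m = n_snps * (n_snps - 1) // 2
        self.n_pairs = m
        self.visited = np.zeros(m + 1, dtype=bool)
        self.next = np.roll(np.arange(m + 1, dtype=np.int64), -1)
        self.prev = np.roll(np.arange(m + 1, dtype=np.int64), 1)
        # close the circle over 1..m, skipping the unused slot 0
        self.next[m] = 1
        self.prev[1] = m
        self.remaining = m

    def is_visited(self, k: int) -> bool:
        return bool(self.visited[k])

    def mark_visited(self, k: int) -> None:
        if self.visited[k]:
            raise ValueError(f"linear index {k} already visited")
        self.next[self.prev[k]] = self.next[k]
        self.prev[self.next[k]] = self.prev[k]
        self.visited[k] = True
        self.remaining -= 1

    def seek_unvisited(self, k: int) -> int:
        """Nearest unvisited index at or after ``k`` (following successors)."""
        if self.remaining == 0:
            raise SearchExhausted("all pairs visited")
        hops = []
        while self.visited[k]:
            hops.append(k)
            k = int(self.next[k])
        for h in hops:  # path compression keeps later walks short
            self.next[h] = k
        return k


def draw_bw(remaining: int, rng: np.random.Generator, size: int | None = None):
    """Random walk length for the local search: floor(min(10, max(u*#E, 1))).

    ``remaining`` is #E, the number of still-unvisited pairs; the step is an
    integer in [1, 10], biased large while most of the table is unvisited and
    shrinking toward 1 as it empties.  ``size`` draws a whole vector at once.
    """
    if remaining < 1:
        raise SearchExhausted("no unvisited pairs left")
    u = rng.random(size)
    bw = np.minimum(10.0, np.maximum(u * remaining, 1.0))
    out = np.floor(bw).astype(np.int64)
    return int(out) if size is None else out


def local_search_unvisited(
    reg: TabuRegistry, k: int, rng: np.random.Generator
) -> int:
    """Nearby never-visited linear index, reached by a short random walk.

    From ``k`` (skipped forward to the live list if already visited) the walk
    takes BW hops along the unvisited linked list in a fair-coin direction,
    wrapping at the ends.  Never returns a visited index; raises
    :class:`SearchExhausted` when nothing is left.
    """
    start = reg.seek_unvisited(k)
    bw = draw_bw(reg.remaining, rng)
    forward = rng.random() < 0.5
    links = reg.next if forward else reg.prev
    node = start
    for _ in range(bw):
        node = int(links[node])
    return node


# ---------------------------------------------------------------------------
# Improvisation


def _ceil_draw(rng: np.random.Generator, n: int) -> int:
    """ceil(rand(0,1) * n) clamped to 1..n (rand may be exactly 0)."""
    return min(n, max(1, math.ceil(rng.random() * n)))


def improvise(
    hm1: HarmonyMemory,
    hm2: HarmonyMemory,
    cfg: SearchConfig,
    n_snps: int,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Generate a new candidate pair from the two memories.

    Per locus dimension: with probability HMCR a harmony is drawn uniformly
    from the concatenation of HM1 and HM2 and its locus copied, then with
    probability PAR the value is pitch-adjusted by
    ``(rand - 0.5) * |best_dim - random_harmony_dim|`` of the source memory;
    otherwise the locus is uniform over 1..N.  The raw (possibly fractional)
    values are rounded, clamped to [1, N], repaired on duplicate loci by
    redrawing the second, and canonicalized ascending.  Returned 0-based.
    """
    if len(hm1) == 0 or len(hm2) == 0:
        raise ValueError("both harmony memories must be populated")
    n1, n2 = len(hm1), len(hm2)
    values: list[float] = []
    for dim in range(2):
        if rng.random() < cfg.hmcr:
            a = _ceil_draw(rng, n1 + n2)
            if a <= n1:
                mem, idx = hm1, a - 1
            else:
                mem, idx = hm2, a - n1 - 1
            v = float(mem.entries[idx].pair[dim] + 1)
            if rng.random() < cfg.par:
                r = _ceil_draw(rng, len(mem)) - 1
                best = mem.best.pair[dim] + 1
                other = mem.entries[r].pair[dim] + 1
                v += (rng.random() - 0.5) * abs(best - other)
        else:
            v = float(_ceil_draw(rng, n_snps))
        values.append(v)

    a_ = min(n_snps, max(1, round(values[0])))
    b_ = min(n_snps, max(1, round(values[1])))
    while b_ == a_:
        b_ = _ceil_draw(rng, n_snps)
    if a_ > b_:
        a_, b_ = b_, a_
    return a_ - 1, b_ - 1


# ---------------------------------------------------------------------------
# Full screening run


@dataclass
class ScreeningResult:
    """Outcome of one screening run."""

    hm1: HarmonyMemory
    hm2: HarmonyMemory
    mes: int
    trace: list[tuple[int, int]] = field(default_factory=list)
    stop_reason: str = ""
    seed: int = 0

    def candidate_pairs(self) -> list[tuple[int, int]]:
        """Deduplicated union HM1 ∪ HM2, in first-seen order."""
        seen: dict[tuple[int, int], None] = {}
        for mem in (self.hm1, self.hm2):
            for entry in mem.entries:
                seen.setdefault(entry.pair, None)
        return list(seen)


def _evaluate(ds: GenotypeDataset, pair: tuple[int, int]) -> ScoredModel:
    table = build_contingency(ds, pair)
    return ScoredModel(pair, k2_neglog_score(table), gini_score(table))


def fhsa_run(
    ds: GenotypeDataset,
    cfg: SearchConfig,
    truth_pair: tuple[int, int] | None = None,
    early_stop: bool = False,
) -> ScreeningResult:
    """Run the full screening stage on a dataset.

    Both memories are filled with random never-visited pairs, then the loop
    improvises, reroutes already-visited candidates through the local search,
    scores each new pair once under both criteria (one model evaluation),
    and updates each memory by worst-replacement under its own criterion.
    Stops at the evaluation budget or when every pair has been visited.

    ``early_stop`` terminates the run as soon as ``truth_pair`` enters either
    memory — a benchmark-harness option for evaluation-count statistics when
    the causal pair is known; it is off in normal use.

    Deterministic given ``cfg.seed``.
    """
    n = ds.n_snps
    if n < 2:
        raise ValueError("need at least two SNPs to search pairs")
    reg = TabuRegistry(n)
    mmes = cfg.mmes
    if mmes > reg.n_pairs:
        warnings.warn(
            f"MMEs {mmes} exceeds the {reg.n_pairs} available pairs; clamping",
            stacklevel=2,
        )
        mmes = reg.n_pairs
    rng = np.random.default_rng(cfg.seed)
    # keep initialization from starving one memory when C(N,2) is small
    cap = max(1, reg.n_pairs // 2)
    hms1, hms2 = min(cfg.hms1, cap), min(cfg.hms2, cap)
    if (hms1, hms2) != (cfg.hms1, cfg.hms2):
        warnings.warn(
            f"harmony memory sizes clamped to {hms1}/{hms2} for {reg.n_pairs} pairs",
            stacklevel=2,
        )
    hm1 = HarmonyMemory(hms1, "k2")
    hm2 = HarmonyMemory(hms2, "gini")
    truth = tuple(sorted(truth_pair)) if truth_pair is not None else None

    trace: list[tuple[int, int]] = []
    mes = 0
    stop_reason = ""

    def evaluate_at(k: int) -> ScoredModel:
        nonlocal mes
        pair = linear_to_pair0(k, n)
        reg.mark_visited(k)
        model = _evaluate(ds, pair)
        trace.append(pair)
        mes += 1
        return model

    def truth_found() -> bool:
        return (
            early_stop
            and truth is not None
            and (truth in hm1 or truth in hm2)
        )

    # 1) random initialization through the registry (never repeats a pair).
    # Each initial model is afterwards offered to the other memory as well:
    # the registry forbids re-evaluation, so a pair seen only at HM1's
    # initialization must still be able to enter HM2 (and vice versa) for
    # the full-budget run to be exhaustive under both criteria.
    init_models: list[ScoredModel] = []
    for mem in (hm1, hm2):
        while len(mem) < mem.capacity and reg.remaining > 0 and mes < mmes:
            model = evaluate_at(
                reg.seek_unvisited(int(rng.integers(1, reg.n_pairs + 1)))
            )
            mem.add(model)
            init_models.append(model)
    if len(hm1) and len(hm2):
        for model in init_models:
            hm1.consider(model)
            hm2.consider(model)
    if truth_found():
        return ScreeningResult(hm1, hm2, mes, trace, "early_stop", cfg.seed)

    if len(hm1) == 0 or len(hm2) == 0:
        # budget or table exhausted before both memories saw an entry
        reason = "exhausted" if reg.remaining == 0 else "mmes_reached"
        return ScreeningResult(hm1, hm2, mes, trace, reason, cfg.seed)

    # 2) improvisation loop
    while mes < mmes and reg.remaining > 0:
        cand = improvise(hm1, hm2, cfg, n, rng)
        k = pair_index0(cand, n)
        if reg.is_visited(k):
            k = local_search_unvisited(reg, k, rng)
        model = evaluate_at(k)
        hm1.consider(model)
        hm2.consider(model)
        if truth_found():
            stop_reason = "early_stop"
            break

    if not stop_reason:
        stop_reason = "exhausted" if reg.remaining == 0 else "mmes_reached"
    return ScreeningResult(hm1, hm2, mes, trace, stop_reason, cfg.seed)
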