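"""Monte Carlo simulation of somatic-mutation accumulation in a crown.

Each replicate follows the generative model directly:

1. allocate segment times by the exponential tilt;
2. draw a Poisson number of mutation events on every internode segment,
   with mean ``m * 2*G*mu * t_s`` (the whole ASC population's supply);
3. propagate each event through its ``B_s`` lateral-branch bottlenecks and
   the terminal founder draw.  Entering a lateral branch (probability
   ``1/m`` per bottleneck) fixes the mutation in that entire lateral
   subtree; the terminal draw adds the main-axis tip with probability
   ``1/m``.

ASC identity is not tracked: sampling events are exchangeable and each
succeeds with net probability ``1/m``.  Along the continuation axis the
mutant stays exactly one of the ``m`` ASCs; fixation inside a newly founded
meristem is instantaneous for a single founder and, in the polyclonal mode
(``founders_per_branch = k > 1``), is realized in two stages — mutant among
the ``k`` sampled founders with probability ``k/m``, then surviving
within-meristem drift with probability ``1/k`` — leaving the net entry
probability ``1/m`` unchanged.

Two draw modes are provided.  ``per_mutation`` (default, used for all
expectations) gives every event independent Bernoulli draws.
``shared_founder`` draws one founder index per branch point per replicate,
shared by all co-segmental events — the more mechanistic reading; the two
modes agree in expectation but may differ in replicate-level variance.

Randomness uses one root seed with independent per-replicate substreams
(``SeedSequence`` spawn keys), so replicate ``r`` is invariant to the total
replicate count and identical configs reproduce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .crown import CrownTopology, TimeAllocation, allocate_time, make_crown, resolve_tilt
from .burden import MutationParams

__all__ = [
    "SimulatorConfig",
    "MutationEvent",
    "ReplicateResult",
    "SimulationResult",
    "StatSummary",
    "propagate_mutation",
    "run_replicate",
    "run_simulation",
    "summarize_replicates",
]

DRAW_MODES = ("per_mutation", "shared_founder")

# per-tip burden vectors are materialized only up to this depth
MAX_TRACKED_DEPTH = 16


@dataclass(frozen=True)
class SimulatorConfig:
    """Full parameterization of one simulation experiment."""

    depth: int
    genome_size: float
    mu: float
    asc_count: int
    tilt: float | str
    total_time: float
    replicates: int = 300
    founders_per_branch: int = 1  # k; k=1 is the single-ASC bottleneck
    draw_mode: str = "per_mutation"
    seed: int = 0
    track_tip_vector: bool = False
    record_events: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "tilt", resolve_tilt(self.tilt))
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        k, m = self.founders_per_branch, self.asc_count
        if not 1 <= k <= m:
            raise ValueError(f"founders_per_branch must satisfy 1 <= k <= m, got k={k}, m={m}")
        if self.draw_mode not in DRAW_MODES:
            raise ValueError(f"draw_mode must be one of {DRAW_MODES}")
        if self.draw_mode == "shared_founder" and k > 1:
            raise ValueError("polyclonal founding (k > 1) requires draw_mode='per_mutation'")
        if self.track_tip_vector and self.depth > MAX_TRACKED_DEPTH:
            raise ValueError(f"per-tip vectors are tracked only for depth <= {MAX_TRACKED_DEPTH}")
        # construct eagerly to validate
        MutationParams(self.genome_size, self.mu, self.asc_count)
        make_crown(self.depth)

    @property
    def params(self) -> MutationParams:
        return MutationParams(self.genome_size, self.mu, self.asc_count)

    @property
    def topology(self) -> CrownTopology:
        return make_crown(self.depth)

    @property
    def allocation(self) -> TimeAllocation:
        return allocate_time(self.depth, self.tilt, self.total_time)


@dataclass(frozen=True)
class MutationEvent:
    """One simulated mutation and the tips that inherit it."""

    level: int
    segment: int
    event_id: int
    carrying_tips: frozenset[int]


def propagate_mutation(
    origin: tuple[int, int],
    topo: CrownTopology,
    m: int,
    k: int = 1,
    rng: np.random.Generator | None = None,
) -> frozenset[int]:
    """Propagate one mutation from its origin segment to the crown tips.

    Walks the continuation path from ``origin`` to its main-axis tip.  At
    each of the ``B_s`` lateral branch points the mutation enters the lateral
    child with net probability ``1/m`` (two-stage ``k/m * 1/k`` for ``k > 1``)
    and then fixes in all tips of that lateral subtree; the terminal draw
    adds the main-axis tip with probability ``1/m``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 1 <= k <= m:
        raise ValueError(f"require 1 <= k <= m, got k={k}, m={m}")
    s, i = origin
    b = topo.bottlenecks(s)

    def success() -> bool:
        if k == 1:
            return rng.random() < 1.0 / m
        return (rng.random() < k / m) and (rng.random() < 1.0 / k)

    tips: set[int] = set()
    for j in range(1, b + 1):
        if success():
            start, size = topo.lateral_block(s, i, j)
            tips.update(range(start, start + size))
    if success():
        tips.add(topo.main_axis_tip(s, i))
    return frozenset(tips)


@dataclass
class ReplicateResult:
    """Burden statistics of a single replicate."""

    unique_count: int
    total_tip_occurrences: int
    n_events: int
    mean_tip_burden: float
    per_tip_burden: np.ndarray | None = None
    events: list[MutationEvent] | None = None


def _success_matrix(
    cfg: SimulatorConfig,
    rng: np.random.Generator,
    n_events: int,
    level: int,
    seg_idx: np.ndarray,
    node_founders: list[np.ndarray] | None,
    tip_founders: np.ndarray | None,
) -> np.ndarray:
    """Boolean (n_events, B+1) matrix: lateral draws j=1..B then terminal."""
    b = cfg.depth - level
    m, k = cfg.asc_count, cfg.founders_per_branch
    if cfg.draw_mode == "per_mutation":
        if k == 1:
            return rng.random((n_events, b + 1)) < 1.0 / m
        sampled = rng.random((n_events, b + 1)) < k / m
        fixed = rng.random((n_events, b + 1)) < 1.0 / k
        return sampled & fixed
    # shared_founder: one founder label per branch point per replicate,
    # compared against each event's own ASC label
    assert node_founders is not None and tip_founders is not None
    labels = rng.integers(0, m, n_events)
    succ = np.empty((n_events, b + 1), dtype=bool)
    for j in range(1, b + 1):
        node_level = level + j - 1
        node_idx = seg_idx * 2 ** (j - 1)
        succ[:, j - 1] = node_founders[node_level][node_idx] == labels
    succ[:, b] = tip_founders[seg_idx * 2**b] == labels
    return succ


def run_replicate(config: SimulatorConfig, rng: np.random.Generator) -> ReplicateResult:
    """Simulate one replicate of the full crown under ``config``."""
    topo = config.topology
    d = config.depth
    n_tips = 2**d
    times = config.allocation.times
    supply = config.asc_count * config.params.supply_rate  # m * 2*G*mu

    node_founders = tip_founders = None
    if config.draw_mode == "shared_founder":
        node_founders = [rng.integers(0, config.asc_count, 2**lvl) for lvl in range(d)]
        tip_founders = rng.integers(0, config.asc_count, n_tips)

    unique = 0
    occurrences = 0
    n_events = 0
    diff = np.zeros(n_tips + 1, dtype=np.int64) if config.track_tip_vector else None
    events: list[MutationEvent] | None = [] if config.record_events else None

    for s in range(d + 1):
        counts = rng.poisson(supply * times[s], 2**s)
        n_s = int(counts.sum())
        if n_s == 0:
            continue
        n_events += n_s
        seg_idx = np.repeat(np.arange(2**s, dtype=np.int64), counts)
        b = d - s
        succ = _success_matrix(config, rng, n_s, s, seg_idx, node_founders, tip_founders)

        unique += int(succ.any(axis=1).sum())
        # lateral subtree at draw j holds 2**(b-j) tips; terminal draw adds 1
        block_sizes = np.concatenate([2 ** np.arange(b - 1, -1, -1), [1]]).astype(np.int64)
        occurrences += int((succ * block_sizes).sum())

        if diff is not None:
            for j in range(1, b + 1):
                hit = succ[:, j - 1]
                if not hit.any():
                    continue
                size = 2 ** (b - j)
                starts = (seg_idx[hit] * 2**j + 1) * size
                np.add.at(diff, starts, 1)
                np.add.at(diff, starts + size, -1)
            hit = succ[:, b]
            if hit.any():
                starts = seg_idx[hit] * 2**b
                np.add.at(diff, starts, 1)
                np.add.at(diff, starts + 1, -1)
        if events is not None:
            for row in range(n_s):
                i = int(seg_idx[row])
                tips: set[int] = set()
                for j in range(1, b + 1):
                    if succ[row, j - 1]:
                        start, size = topo.lateral_block(s, i, j)
                        tips.update(range(start, start + size))
                if succ[row, b]:
                    tips.add(topo.main_axis_tip(s, i))
                events.append(
                    MutationEvent(
                        level=s, segment=i, event_id=len(events), carrying_tips=frozenset(tips)
                    )
                )

    per_tip = np.cumsum(diff[:-1]) if diff is not None else None
    return ReplicateResult(
        unique_count=unique,
        total_tip_occurrences=occurrences,
        n_events=n_events,
        mean_tip_burden=occurrences / n_tips,
        per_tip_burden=per_tip,
        events=events,
    )


@dataclass(frozen=True)
class StatSummary:
    """Cross-replicate summary of one scalar statistic."""

    mean: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    expected: float | None = None
    z: float | None = None


@dataclass
class SimulationResult:
    """Per-replicate burden statistics plus cross-replicate summaries."""

    config: SimulatorConfig
    unique_counts: np.ndarray
    total_tip_occurrences: np.ndarray
    mean_tip_burdens: np.ndarray
    n_events: np.ndarray
    per_tip_burden_mean: np.ndarray | None = None
    events: list[list[MutationEvent]] | None = None
    summaries: dict[str, StatSummary] = field(default_factory=dict)


def _replicate_rng(seed: int, spawn_prefix: tuple[int, ...], rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(*spawn_prefix, rep)))


def run_simulation(
    config: SimulatorConfig,
    expectations: dict[str, float] | None = None,
    _spawn_prefix: tuple[int, ...] = (),
) -> SimulationResult:
    """Run all replicates of ``config`` and summarize them.

    ``expectations`` may map statistic names (``unique_count``,
    ``total_tip_occurrences``, ``mean_tip_burden``) to analytic values; the
    summaries then carry z-scores against them.
    """
    reps = config.replicates
    unique = np.zeros(reps, dtype=np.int64)
    occ = np.zeros(reps, dtype=np.int64)
    mean_tip = np.zeros(reps)
    nev = np.zeros(reps, dtype=np.int64)
    tip_sum = np.zeros(2**config.depth) if config.track_tip_vector else None
    all_events: list[list[MutationEvent]] | None = [] if config.record_events else None

    for r in range(reps):
        rng = _replicate_rng(config.seed, _spawn_prefix, r)
        res = run_replicate(config, rng)
        unique[r] = res.unique_count
        occ[r] = res.total_tip_occurrences
        mean_tip[r] = res.mean_tip_burden
        nev[r] = res.n_events
        if tip_sum is not None:
            tip_sum += res.per_tip_burden
        if all_events is not None:
            all_events.append(res.events)

    result = SimulationResult(
        config=config,
        unique_counts=unique,
        total_tip_occurrences=occ,
        mean_tip_burdens=mean_tip,
        n_events=nev,
        per_tip_burden_mean=tip_sum / reps if tip_sum is not None else None,
        events=all_events,
    )
    result.summaries = summarize_replicates(result, expectations)
    return result


def _summarize(values: np.ndarray, expected: float | None = None) -> StatSummary:
    values = np.asarray(values, dtype=float)
    n = values.size
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    lo, hi = (np.quantile(values, [0.025, 0.975]) if n > 1 else (mean, mean))
    z = None
    if expected is not None:
        z = float((mean - expected) / se) if se and se > 0 else (0.0 if mean == expected else float("inf"))
    return StatSummary(
        mean=mean, se=se, ci_low=float(lo), ci_high=float(hi), n=n,
        expected=expected, z=z,
    )


def summarize_replicates(
    results: SimulationResult | Sequence[ReplicateResult],
    expectations: dict[str, float] | None = None,
) -> dict[str, StatSummary]:
    """Aggregate per-replicate statistics: mean, standard error, empirical
    95% interval, and z-scores against supplied analytic expectations."""
    if isinstance(results, SimulationResult):
        arrays = {
            "unique_count": results.unique_counts,
            "total_tip_occurrences": results.total_tip_occurrences,
            "mean_tip_burden": results.mean_tip_burdens,
        }
    else:
        results = list(results)
        if not results:
            raise ValueError("cannot summarize zero replicates")
        arrays = {
            "unique_count": np.array([r.unique_count for r in results]),
            "total_tip_occurrences": np.array([r.total_tip_occurrences for r in results]),
            "mean_tip_burden": np.array([r.mean_tip_burden for r in results]),
        }
    if next(iter(arrays.values())).size == 0:
        raise ValueError("cannot summarize zero replicates")
    expectations = expectations or {}
    return {
        name: _summarize(vals, expectations.get(name)) for name, vals in arrays.items()
    }
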