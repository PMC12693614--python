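"""Closed-form sampling probabilities and expected somatic-mutation burdens.

Each shoot apical meristem layer carries ``m`` apical stem cells (ASCs),
each mutating as a Poisson process with rate ``2*G*mu`` (haploid genome size
``G``, per-base per-unit-time rate ``mu``, diploid factor 2).  At every
branch point exactly one of the ``m`` ASC lineages founds the new lateral
meristem, and the terminal organ is founded by one more uniform draw, so a
mutation born on a segment with ``B_s`` bottlenecks above it survives to at
least one tip with probability ``p_det(s) = 1 - (1 - 1/m)**(B_s + 1)``.

The burden expectations follow by linearity:

* per tip:            ``E[S_tip] = 2*G*mu*T`` (architecture-free),
* summed over tips:   ``E[S_crown_tips] = 2*G*mu*2**D*T`` (m- and
  allocation-free),
* unique mutations:   ``E[S_crown_unique] = 2*G*mu*m*T * A(lam)``, where the
  architectural factor ``A(lam) = sum_s 2**s * w_s(lam) * p_det(s)`` is the
  only place branching architecture enters.

``A`` ranges from the stick-tree limit ``1 - (1 - 1/m)**(D+1)`` to the
star-tree limit ``2**D / m``; their ratio can span orders of magnitude, which
is the architectural buffering effect this package quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crown import STAR, STICK, CrownTopology, TimeAllocation, allocate_time, tilt_weights

__all__ = [
    "MutationParams",
    "ArchitecturalSummary",
    "BurdenExpectations",
    "lateral_entry_prob",
    "detection_prob",
    "expected_tips_per_mutation",
    "sampling_profile",
    "expected_per_tip_burden",
    "expected_crown_tips_burden",
    "architectural_factor",
    "expected_crown_unique_burden",
    "burden_expectations",
]


@dataclass(frozen=True)
class MutationParams:
    """Mutational supply parameters of a single meristem layer."""

    genome_size: float  # haploid base pairs, G
    mu: float  # mutations per base per unit time
    asc_count: int = 3  # apical stem cells per layer, m

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if int(self.asc_count) != self.asc_count or self.asc_count < 1:
            raise ValueError("asc_count must be an integer >= 1")
        object.__setattr__(self, "asc_count", int(self.asc_count))

    @property
    def supply_rate(self) -> float:
        """Per-ASC mutation rate per unit time, ``2*G*mu`` (diploid)."""
        return 2.0 * self.genome_size * self.mu


def _miss_prob(m: int, k: int) -> float:
    """``(1 - 1/m)**k`` computed via log1p for stability at large ``k``."""
    if int(m) != m or m < 1:
        raise ValueError(f"asc count m must be an integer >= 1, got {m}")
    if k < 0:
        raise ValueError(f"draw count must be non-negative, got {k}")
    if k == 0:
        return 1.0
    if m == 1:
        return 0.0
    return math.exp(k * math.log1p(-1.0 / m))


def lateral_entry_prob(m: int, bottlenecks: int) -> float:
    """Probability ``q_s`` that a mutation enters at least one lateral branch
    among its ``B_s`` bottleneck draws: ``1 - (1 - 1/m)**B_s``."""
    return 1.0 - _miss_prob(m, bottlenecks)


def detection_prob(m: int, bottlenecks: int) -> float:
    """Probability ``p_det(s)`` that a mutation reaches at least one tip via
    any of its ``B_s + 1`` draws: ``1 - (1 - 1/m)**(B_s + 1)``.

    Equivalently ``q_s + (1 - q_s)/m``: lateral entry, or no lateral entry
    followed by success at the terminal founder draw.
    """
    return 1.0 - _miss_prob(m, bottlenecks + 1)


def expected_tips_per_mutation(m: int, bottlenecks: int) -> float:
    """Expected number of tips that inherit a mutation with ``B_s``
    bottlenecks above it: ``2**B_s / m``.

    The lateral subtrees entered at draws ``j = 1..B_s`` contribute disjoint
    blocks of ``2**(B_s - j)`` tips, the terminal draw one more; each draw
    succeeds with probability ``1/m``.
    """
    if int(m) != m or m < 1:
        raise ValueError(f"asc count m must be an integer >= 1, got {m}")
    if bottlenecks < 0:
        raise ValueError("bottlenecks must be non-negative")
    return 2.0**bottlenecks / m


def sampling_profile(topo: CrownTopology | int, m: int) -> pd.DataFrame:
    """Per-level sampling profile: bottlenecks, ``q_s``, ``p_det(s)`` and
    expected tips per mutation, one row per segment level."""
    depth = topo.depth if isinstance(topo, CrownTopology) else int(topo)
    levels = np.arange(depth + 1)
    b = depth - levels
    return pd.DataFrame(
        {
            "level": levels,
            "bottlenecks": b,
            "lateral_entry": [lateral_entry_prob(m, int(x)) for x in b],
            "detection": [detection_prob(m, int(x)) for x in b],
            "expected_tips": [expected_tips_per_mutation(m, int(x)) for x in b],
        }
    )


def expected_per_tip_burden(params: MutationParams, alloc: TimeAllocation) -> float:
    """Expected mutation burden of a single sequenced tip: ``2*G*mu*T``.

    The per-segment supply ``m*2*G*mu*t_s`` is thinned by the terminal
    founder probability ``1/m``; summing ``2*G*mu*t_s`` over the path gives a
    value independent of both the tilt and the ASC count.
    """
    return params.supply_rate * alloc.total_time


def expected_crown_tips_burden(
    params: MutationParams, topo: CrownTopology, alloc: TimeAllocation
) -> float:
    """Expected total mutation occurrences summed over all crown tips:
    ``2*G*mu*2**D*T`` — proportional to tip count times path time, and
    independent of ``m`` and of how time is allocated."""
    if topo.depth != alloc.depth:
        raise ValueError("allocation depth does not match topology depth")
    return params.supply_rate * 2.0**topo.depth * alloc.total_time


@dataclass(frozen=True)
class ArchitecturalSummary:
    """Architectural factor ``A`` with its limits and fold-change ratios."""

    factor: float  # A(lam)
    stick_limit: float  # A at lam -> -inf
    star_limit: float  # A at lam -> +inf
    ratio_star_stick: float
    ratio_to_uniform: float  # R(lam) = A(lam) / A(0)

    @property
    def log10_ratio_star_stick(self) -> float:
        return math.log10(self.ratio_star_stick)

    @property
    def log10_ratio_to_uniform(self) -> float:
        return math.log10(self.ratio_to_uniform)


def architectural_factor(
    topo: CrownTopology | int, alloc: TimeAllocation | float | str, m: int
) -> ArchitecturalSummary:
    """Compute ``A(lam) = sum_s 2**s * w_s(lam) * p_det(s)`` and its summary.

    ``alloc`` may be a :class:`TimeAllocation` or a bare tilt value.  The
    factor is always evaluated from the actual weight vector (sentinels
    included); the stick/star limits are the closed forms, reported alongside
    for the convexity bound ``A(stick) <= A(lam) <= A(star)``.
    """
    depth = topo.depth if isinstance(topo, CrownTopology) else int(topo)
    if isinstance(alloc, TimeAllocation):
        if alloc.depth != depth:
            raise ValueError("allocation depth does not match topology depth")
        weights = alloc.weights
    else:
        weights = tilt_weights(depth, alloc)
    if int(m) != m or m < 1:
        raise ValueError(f"asc count m must be an integer >= 1, got {m}")

    levels = np.arange(depth + 1)
    pdet = np.array([detection_prob(m, depth - int(s)) for s in levels])
    factor = float(np.sum(2.0**levels * weights * pdet))

    stick = detection_prob(m, depth)  # 1 - (1 - 1/m)**(D+1)
    star = 2.0**depth / m
    uniform = float(np.sum(2.0**levels * pdet)) / (depth + 1)
    return ArchitecturalSummary(
        factor=factor,
        stick_limit=stick,
        star_limit=star,
        ratio_star_stick=star / stick,
        ratio_to_uniform=factor / uniform,
    )


def expected_crown_unique_burden(
    params: MutationParams, topo: CrownTopology, alloc: TimeAllocation
) -> float:
    """Expected number of unique mutations present in at least one tip:
    ``2*G*mu*m*T * A(lam)``.

    Each level supplies ``2**s * m * 2*G*mu*t_s`` Poisson events and each
    event is seen somewhere in the crown with probability ``p_det(s)``; no
    ``1/m`` thinning applies because uniqueness counts an event once however
    many tips inherit it.
    """
    if topo.depth != alloc.depth:
        raise ValueError("allocation depth does not match topology depth")
    summary = architectural_factor(topo, alloc, params.asc_count)
    return params.supply_rate * params.asc_count * alloc.total_time * summary.factor


@dataclass(frozen=True)
class BurdenExpectations:
    """The three closed-form burden expectations for one parameter set."""

    per_tip: float
    crown_tips: float
    crown_unique: float

    def __post_init__(self) -> None:
        if self.crown_unique > self.crown_tips * (1 + 1e-12):
            raise ValueError("crown_unique cannot exceed crown_tips")


def burden_expectations(
    params: MutationParams, topo: CrownTopology, alloc: TimeAllocation
) -> BurdenExpectations:
    """All three expectations at once (convenience for tables and the CLI)."""
    return BurdenExpectations(
        per_tip=expected_per_tip_burden(params, alloc),
        crown_tips=expected_crown_tips_burden(params, topo, alloc),
        crown_unique=expected_crown_unique_burden(params, topo, alloc),
    )
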