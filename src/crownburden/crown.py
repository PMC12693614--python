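"""Balanced binary crown architecture and developmental time allocation.

A tree crown is modeled as a perfectly balanced binary tree of depth ``D``:
level ``s`` (``0..D``) holds ``2**s`` internode segments, and every
root-to-tip developmental path traverses exactly ``D + 1`` segments, one per
level.  A mutation arising on a segment at level ``s`` must pass
``B_s = D - s`` lateral-branch bottlenecks (plus one terminal founder draw)
to reach a crown tip.

Total developmental time ``T`` is split across segment levels by an
exponential tilt: ``w_s(lam) = exp(lam*s) / sum_r exp(lam*r)``.  Large
negative tilt concentrates time on the basal segment (a "stick" tree), zero
tilt is uniform, and large positive tilt concentrates time on the terminal
segments (a "star" tree).  The infinite limits are represented by the exact
sentinels :data:`STICK` and :data:`STAR`, never by large floats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STICK",
    "STAR",
    "CrownTopology",
    "TimeAllocation",
    "make_crown",
    "assign_branch_orders",
    "resolve_tilt",
    "tilt_weights",
    "allocate_time",
    "to_newick",
]

#: Sentinel for the stick-tree limit (tilt -> -infinity): all time basal.
STICK = "stick"
#: Sentinel for the star-tree limit (tilt -> +infinity): all time terminal.
STAR = "star"


def resolve_tilt(tilt: float | str) -> float | str:
    """Normalize a tilt value to a finite float or a sentinel.

    Accepts a finite real, the strings ``"stick"``/``"star"`` (case
    insensitive), a numeric string, or ``+-inf`` (mapped to the sentinels).
    NaN is rejected.
    """
    if isinstance(tilt, str):
        token = tilt.strip().lower()
        if token in (STICK, STAR):
            return token
        try:
            tilt = float(token)
        except ValueError:
            raise ValueError(
                f"tilt must be a real number or 'stick'/'star', got {tilt!r}"
            ) from None
    if isinstance(tilt, (int, float, np.integer, np.floating)):
        value = float(tilt)
        if math.isnan(value):
            raise ValueError("tilt must not be NaN")
        if math.isinf(value):
            return STICK if value < 0 else STAR
        return value
    raise TypeError(f"tilt must be a real number or 'stick'/'star', got {tilt!r}")


@dataclass(frozen=True)
class CrownTopology:
    """A perfectly balanced binary crown of depth ``depth``.

    Segments are addressed by ``(level s, index i)`` with ``0 <= i < 2**s``;
    tips by integers ``0 .. 2**depth - 1``.  The topology is implicit: all
    structural queries are arithmetic on addresses.  Child convention:
    the continuation child of segment ``(s, i)`` is ``(s+1, 2i)`` and the
    lateral child is ``(s+1, 2i+1)``, so a tip's index read as bits records
    the lateral turns on its path and the leftmost descendant of any segment
    is its main-axis tip.
    """

    depth: int
    #: Per-level branch-order arrays, filled by :func:`assign_branch_orders`.
    orders: tuple[np.ndarray, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if int(self.depth) != self.depth or self.depth < 0:
            raise ValueError(f"depth must be a non-negative integer, got {self.depth}")
        object.__setattr__(self, "depth", int(self.depth))

    @property
    def n_tips(self) -> int:
        return 2**self.depth

    @property
    def n_segments(self) -> int:
        return 2 ** (self.depth + 1) - 1

    def segment_count(self, level: int) -> int:
        self._check_level(level)
        return 2**level

    def bottlenecks(self, level: int) -> int:
        """Number of lateral branch points above a level-``level`` segment."""
        self._check_level(level)
        return self.depth - level

    def branch_order(self, level: int, index: int) -> int:
        """Branch order of segment ``(level, index)``.

        The basal segment has order 0; a continuation child keeps its
        parent's order and a lateral child increments it, so the order is
        the popcount of the segment index.
        """
        self._check_segment(level, index)
        return int(index).bit_count()

    def children(self, level: int, index: int) -> tuple[tuple[int, int], tuple[int, int]]:
        """(continuation child, lateral child) of an internal segment."""
        self._check_segment(level, index)
        if level >= self.depth:
            raise ValueError("terminal segments have no children")
        return (level + 1, 2 * index), (level + 1, 2 * index + 1)

    def subtree_tip_range(self, level: int, index: int) -> tuple[int, int]:
        """Half-open range of tip indices descending from ``(level, index)``."""
        self._check_segment(level, index)
        size = 2 ** (self.depth - level)
        return index * size, (index + 1) * size

    def main_axis_tip(self, level: int, index: int) -> int:
        """Tip reached by always taking the continuation child."""
        return self.subtree_tip_range(level, index)[0]

    def lateral_block(self, level: int, index: int, j: int) -> tuple[int, int]:
        """Tip block fixed if a mutation from ``(level, index)`` enters the
        lateral branch at its ``j``-th bottleneck (``j = 1 .. B_s``).

        Returns ``(start, size)``: the lateral subtree holds
        ``2**(B_s - j)`` contiguous tips.
        """
        b = self.bottlenecks(level)
        if not 1 <= j <= b:
            raise ValueError(f"bottleneck index j={j} outside 1..{b}")
        size = 2 ** (b - j)
        start = (index * 2**j + 1) * size
        return start, size

    def _check_level(self, level: int) -> None:
        if not 0 <= level <= self.depth:
            raise ValueError(f"level {level} outside 0..{self.depth}")

    def _check_segment(self, level: int, index: int) -> None:
        self._check_level(level)
        if not 0 <= index < 2**level:
            raise ValueError(f"segment index {index} outside 0..{2**level - 1}")


def make_crown(depth: int) -> CrownTopology:
    """Build a balanced binary crown of the given depth (``depth >= 0``)."""
    return CrownTopology(depth)


def assign_branch_orders(topo: CrownTopology) -> CrownTopology:
    """Return a copy of ``topo`` with per-level branch-order arrays filled.

    Orders are the popcount of the segment index (continuation = keep,
    lateral = increment); the basal segment has order 0.
    """
    orders = tuple(
        np.bitwise_count(np.arange(2**s, dtype=np.uint64)).astype(np.int64)
        for s in range(topo.depth + 1)
    )
    return CrownTopology(topo.depth, orders=orders)


def tilt_weights(depth: int, tilt: float | str) -> np.ndarray:
    """Time-allocation weights ``w_s(lam)`` for levels ``0..depth``.

    Finite tilt uses a max-shifted softmax of ``lam * s`` (stable for
    ``|lam| * depth`` large); the sentinels return the exact limit vectors.
    """
    if int(depth) != depth or depth < 0:
        raise ValueError(f"depth must be a non-negative integer, got {depth}")
    depth = int(depth)
    tilt = resolve_tilt(tilt)
    w = np.zeros(depth + 1)
    if tilt == STICK:
        w[0] = 1.0
    elif tilt == STAR:
        w[depth] = 1.0
    else:
        logits = tilt * np.arange(depth + 1, dtype=float)
        logits -= logits.max()
        e = np.exp(logits)
        w = e / e.sum()
    return w


@dataclass(frozen=True)
class TimeAllocation:
    """Developmental time split across segment levels of a crown.

    ``times[s] = total_time * weights[s]``; every segment at a level shares
    the same duration.
    """

    depth: int
    tilt: float | str
    total_time: float
    weights: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.total_time <= 0:
            raise ValueError(f"total_time must be positive, got {self.total_time}")
        if len(self.weights) != self.depth + 1:
            raise ValueError("weights length must equal depth + 1")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


def allocate_time(
    topo: CrownTopology | int, tilt: float | str, total_time: float
) -> TimeAllocation:
    """Allocate total developmental time across the crown's segment levels."""
    depth = topo.depth if isinstance(topo, CrownTopology) else int(topo)
    if total_time <= 0:
        raise ValueError(f"total_time must be positive, got {total_time}")
    w = tilt_weights(depth, tilt)
    return TimeAllocation(
        depth=depth,
        tilt=resolve_tilt(tilt),
        total_time=float(total_time),
        weights=w,
        times=w * float(total_time),
    )


def to_newick(
    topo: CrownTopology,
    alloc: TimeAllocation | None = None,
    label_internal: bool = False,
) -> str:
    """Serialize the crown as a rooted Newick string.

    Tips are labeled ``T<tip index>``; internal nodes optionally
    ``N<level>.<index>``.  With an allocation, branch lengths are the
    per-level segment durations, so every root-to-tip path length sums to
    the total developmental time.
    """
    if alloc is not None and alloc.depth != topo.depth:
        raise ValueError("allocation depth does not match topology depth")

    def length(s: int) -> str:
        return "" if alloc is None else f":{alloc.times[s]:.12g}"

    def render(s: int, i: int) -> str:
        if s == topo.depth:
            return f"T{i}{length(s)}"
        left = render(s + 1, 2 * i)
        right = render(s + 1, 2 * i + 1)
        label = f"N{s}.{i}" if label_internal else ""
        return f"({left},{right}){label}{length(s)}"

    return render(0, 0) + ";"
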