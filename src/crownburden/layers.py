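"""SAM layer structure and variant-allele-frequency detection thresholds.

The shoot apical meristem is stratified into three histological layers
(L1, L2, L3) that develop semi-independently: they share the crown
architecture, genome size and ASC count, but may accumulate mutations at
different per-base rates ``mu_k``.  Bulk-sequenced organs mix the layers in
tissue fractions ``alpha_k`` (summing to 1), so a layer-``k`` mutation
appears at variant allele frequency ``f_k = alpha_k / 2`` in diploid tissue.
A variant caller with minimum allele-frequency threshold ``phi`` sees the
layer only if ``alpha_k >= 2*phi`` — an all-or-nothing indicator
``delta_k(phi)``, not a read-level noise model.

Expected detected unique burden:

    E[detected] = 2*G*m*T * A(lam) * sum_k delta_k(phi) * mu_k

which is linear in each visible layer's rate and piecewise constant,
nonincreasing in ``phi`` with breakpoints at ``alpha_k / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .burden import architectural_factor
from .crown import CrownTopology, TimeAllocation
from .simulate import SimulationResult, SimulatorConfig, StatSummary, _summarize, run_simulation

__all__ = [
    "LayerModel",
    "LayeredSimulationResult",
    "detect_indicator",
    "expected_detected_unique",
    "simulate_layered",
]

N_LAYERS = 3


def detect_indicator(alpha: float, phi: float) -> int:
    """1 if a layer with tissue fraction ``alpha`` clears a VAF threshold
    ``phi`` (``alpha >= 2*phi``, boundary inclusive), else 0."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if not 0.0 <= phi <= 0.5:
        raise ValueError(f"phi must be in [0, 0.5], got {phi}")
    return 1 if alpha >= 2.0 * phi else 0


@dataclass(frozen=True)
class LayerModel:
    """Three-layer mixing fractions, per-layer rates and a VAF threshold."""

    alphas: tuple[float, float, float]
    mus: tuple[float, float, float]
    phi: float = 0.0

    def __post_init__(self) -> None:
        if len(self.alphas) != N_LAYERS or len(self.mus) != N_LAYERS:
            raise ValueError(f"exactly {N_LAYERS} layers are modeled")
        object.__setattr__(self, "alphas", tuple(float(a) for a in self.alphas))
        object.__setattr__(self, "mus", tuple(float(u) for u in self.mus))
        if any(not 0.0 <= a <= 1.0 for a in self.alphas):
            raise ValueError("layer fractions must lie in [0, 1]")
        if abs(sum(self.alphas) - 1.0) > 1e-9:
            raise ValueError("layer fractions must sum to 1")
        if any(u < 0 for u in self.mus):
            raise ValueError("layer mutation rates must be non-negative")
        if not 0.0 <= self.phi <= 0.5:
            raise ValueError("phi must lie in [0, 0.5]")

    @property
    def vafs(self) -> tuple[float, float, float]:
        """Variant allele frequencies ``f_k = alpha_k / 2`` in diploid bulk."""
        return tuple(a / 2.0 for a in self.alphas)

    def indicators(self, phi: float | None = None) -> tuple[int, int, int]:
        p = self.phi if phi is None else phi
        return tuple(detect_indicator(a, p) for a in self.alphas)


def expected_detected_unique(
    layers: LayerModel,
    topo: CrownTopology,
    alloc: TimeAllocation,
    genome_size: float,
    m: int,
) -> float:
    """Expected unique mutations detected in bulk across visible layers:
    ``2*G*m*T * A(lam) * sum_k delta_k(phi) * mu_k``.

    At ``phi = 0`` every layer is visible and the all-layer sum is
    recovered.
    """
    if topo.depth != alloc.depth:
        raise ValueError("allocation depth does not match topology depth")
    a = architectural_factor(topo, alloc, m).factor
    visible_rate = sum(d * u for d, u in zip(layers.indicators(), layers.mus))
    return 2.0 * genome_size * m * alloc.total_time * a * visible_rate


@dataclass
class LayeredSimulationResult:
    """Per-layer simulations plus the bulk-detected unique count."""

    layer_results: list[SimulationResult]
    indicators: tuple[int, int, int]
    detected_unique: np.ndarray  # per replicate, summed over visible layers
    summary: StatSummary


def simulate_layered(
    configs: Sequence[SimulatorConfig],
    layers: LayerModel,
    expected: float | None = None,
) -> LayeredSimulationResult:
    """Run the three layer simulations on a shared architecture.

    The configs must differ only in ``mu`` (one per layer, matching
    ``layers.mus``).  Layer processes are independent — disjoint event sets,
    so no mutation is double-counted across layers — and the detected unique
    count per replicate sums the visible layers' unique counts.
    """
    if len(configs) != N_LAYERS:
        raise ValueError(f"exactly {N_LAYERS} layer configs are required")
    base = configs[0]
    for cfg, mu_k in zip(configs, layers.mus):
        if replace(cfg, mu=base.mu) != base:
            raise ValueError("layer configs must differ only in mu")
        if cfg.mu != mu_k:
            raise ValueError("layer config rates must match layers.mus")

    indicators = layers.indicators()
    # distinct substream prefix per layer keeps the event sets independent
    results = [
        run_simulation(cfg, _spawn_prefix=(layer_idx,))
        for layer_idx, cfg in enumerate(configs)
    ]
    detected = np.zeros(base.replicates, dtype=np.int64)
    for d, res in zip(indicators, results):
        if d:
            detected += res.unique_counts
    return LayeredSimulationResult(
        layer_results=results,
        indicators=indicators,
        detected_unique=detected,
        summary=_summarize(detected, expected),
    )
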