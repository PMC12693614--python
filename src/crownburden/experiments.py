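"""Reproducible experiment harness: parameter sweeps, theory-vs-simulation
validation tables, architectural fold-change tables, and small fully
materialized fixtures.

Every run that writes files also writes a JSON manifest capturing the fully
resolved configuration, seed and package version; re-running from a manifest
reproduces the outputs byte-identically.  Tables are long-format,
header-first, tab-delimited TSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burden import (
    MutationParams,
    architectural_factor,
    burden_expectations,
    expected_crown_unique_burden,
)
from .crown import allocate_time, make_crown, resolve_tilt, to_newick
from .simulate import SimulatorConfig, run_simulation

__all__ = [
    "ExperimentSpec",
    "analytic_table",
    "sweep_table",
    "run_validation_experiment",
    "run_foldchange_tables",
    "generate_fixture",
    "write_manifest",
    "run_from_manifest",
    "write_tsv",
]

logger = logging.getLogger("crownburden")

#: |z| above this flags a theory/simulation cell as failed (conservative for
#: multi-cell grids).
Z_THRESHOLD = 4.0

MAX_FIXTURE_DEPTH = 6


def _tilt_str(tilt: float | str) -> str:
    tilt = resolve_tilt(tilt)
    return tilt if isinstance(tilt, str) else repr(tilt)


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a long-format, header-first, tab-delimited, UTF-8 table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")
    return path


def analytic_table(
    depth: int,
    m: int,
    tilt: float | str,
    total_time: float,
    genome_size: float,
    mu: float,
) -> pd.DataFrame:
    """One-row table of every closed-form quantity for one parameter set."""
    topo = make_crown(depth)
    alloc = allocate_time(topo, tilt, total_time)
    params = MutationParams(genome_size, mu, m)
    exp = burden_expectations(params, topo, alloc)
    arch = architectural_factor(topo, alloc, m)
    return pd.DataFrame(
        [
            {
                "depth": depth,
                "m": m,
                "tilt": _tilt_str(tilt),
                "total_time": total_time,
                "genome_size": genome_size,
                "mu": mu,
                "per_tip": exp.per_tip,
                "crown_tips": exp.crown_tips,
                "crown_unique": exp.crown_unique,
                "A": arch.factor,
                "A_stick": arch.stick_limit,
                "A_star": arch.star_limit,
                "ratio_star_stick": arch.ratio_star_stick,
                "R": arch.ratio_to_uniform,
            }
        ]
    )


def sweep_table(
    depths: list[int],
    m_values: list[int],
    tilts: list[float | str],
    total_time: float,
    genome_size: float,
    mu: float,
) -> pd.DataFrame:
    """Long-format analytic sweep: one row per (depth, m, tilt) combination."""
    rows = [
        analytic_table(d, m, t, total_time, genome_size, mu)
        for d in depths
        for m in m_values
        for t in tilts
    ]
    if not rows:
        raise ValueError("sweep grid is empty")
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class ExperimentSpec:
    """Grid specification for a theory-vs-simulation validation run."""

    depths: tuple[int, ...]
    m_values: tuple[int, ...]
    tilts: tuple[float | str, ...]
    genome_size: float
    mu: float
    total_time: float
    replicates: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "depths", tuple(int(d) for d in self.depths))
        object.__setattr__(self, "m_values", tuple(int(m) for m in self.m_values))
        object.__setattr__(self, "tilts", tuple(resolve_tilt(t) for t in self.tilts))
        if not (self.depths and self.m_values and self.tilts):
            raise ValueError("experiment grid must be non-empty")
        combos = [(d, m, t) for d in self.depths for m in self.m_values for t in self.tilts]
        if len(set(combos)) != len(combos):
            raise ValueError("grid combinations must be unique")

    @property
    def grid(self) -> list[tuple[int, int, float | str]]:
        return [(d, m, t) for d in self.depths for m in self.m_values for t in self.tilts]


def run_validation_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Compare simulated mean unique burden with its closed form on a grid.

    One row per (depth, m, tilt) cell: analytic expectation, simulated mean,
    SE, empirical 95% interval, z-score and a pass flag (|z| <= 4).  Each
    cell uses an independent, reproducible substream of the spec seed.
    """
    rows = []
    for cell_idx, (d, m, tilt) in enumerate(spec.grid):
        topo = make_crown(d)
        alloc = allocate_time(topo, tilt, spec.total_time)
        params = MutationParams(spec.genome_size, spec.mu, m)
        expected = expected_crown_unique_burden(params, topo, alloc)
        cfg = SimulatorConfig(
            depth=d,
            genome_size=spec.genome_size,
            mu=spec.mu,
            asc_count=m,
            tilt=tilt,
            total_time=spec.total_time,
            replicates=spec.replicates,
            seed=spec.seed,
        )
        logger.info("validation cell depth=%d m=%d tilt=%s", d, m, tilt)
        res = run_simulation(cfg, {"unique_count": expected}, _spawn_prefix=(cell_idx,))
        s = res.summaries["unique_count"]
        rows.append(
            {
                "depth": d,
                "m": m,
                "tilt": _tilt_str(tilt),
                "replicates": spec.replicates,
                "analytic_unique": expected,
                "sim_mean": s.mean,
                "sim_se": s.se,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "z": s.z,
                "passed": bool(abs(s.z) <= Z_THRESHOLD) if s.z is not None else True,
            }
        )
    return pd.DataFrame(rows)


def run_foldchange_tables(
    depths: list[int],
    m_values: list[int],
    tilts: list[float],
    fixed_m: int = 3,
    fixed_depth: int = 5,
) -> dict[str, pd.DataFrame]:
    """Analytic fold-change tables for the architectural factor.

    Returns three long-format tables: ``star_stick`` — star/stick ratio
    against depth for each m (with log10); ``tilt_by_depth`` — R(tilt) for
    each depth at ``fixed_m``; ``tilt_by_m`` — R(tilt) for each m at
    ``fixed_depth``.
    """
    if not (depths and m_values and tilts):
        raise ValueError("fold-change grids must be non-empty")
    star_stick = pd.DataFrame(
        [
            {
                "depth": d,
                "m": m,
                "ratio_star_stick": (a := architectural_factor(d, 0.0, m)).ratio_star_stick,
                "log10_ratio_star_stick": a.log10_ratio_star_stick,
            }
            for d in depths
            for m in m_values
        ]
    )
    tilt_by_depth = pd.DataFrame(
        [
            {
                "depth": d,
                "m": fixed_m,
                "tilt": t,
                "R": (a := architectural_factor(d, t, fixed_m)).ratio_to_uniform,
                "log10_R": a.log10_ratio_to_uniform,
            }
            for d in depths
            for t in tilts
        ]
    )
    tilt_by_m = pd.DataFrame(
        [
            {
                "depth": fixed_depth,
                "m": m,
                "tilt": t,
                "R": (a := architectural_factor(fixed_depth, t, m)).ratio_to_uniform,
                "log10_R": a.log10_ratio_to_uniform,
            }
            for m in m_values
            for t in tilts
        ]
    )
    return {"star_stick": star_stick, "tilt_by_depth": tilt_by_depth, "tilt_by_m": tilt_by_m}


def write_manifest(path: str | Path, command: str, config: dict, seed: int | None) -> Path:
    """Record the fully resolved configuration of a run as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "package": "crownburden",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": config,
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def generate_fixture(
    depth: int,
    seed: int,
    outdir: str | Path,
    m: int = 3,
    tilt: float | str = 0.0,
    total_time: float = 25.0,
    genome_size: float = 4.0e8,
    mu: float = 5.0e-10,
) -> dict[str, Path]:
    """Write a small, seeded, fully materialized single-replicate example.

    Produces a Newick crown with branch lengths, a per-event mutation table
    (with carried tip blocks), a per-tip burden table, an analytic summary
    JSON and a manifest.  Refused above depth 6 to keep fixtures small.
    """
    if depth > MAX_FIXTURE_DEPTH:
        raise ValueError(f"fixtures are limited to depth <= {MAX_FIXTURE_DEPTH}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    topo = make_crown(depth)
    alloc = allocate_time(topo, tilt, total_time)
    cfg = SimulatorConfig(
        depth=depth,
        genome_size=genome_size,
        mu=mu,
        asc_count=m,
        tilt=tilt,
        total_time=total_time,
        replicates=1,
        seed=seed,
        track_tip_vector=True,
        record_events=True,
    )
    res = run_simulation(cfg)
    events = res.events[0]

    paths: dict[str, Path] = {}
    nwk = outdir / "crown.nwk"
    nwk.write_text(to_newick(topo, alloc, label_internal=True) + "\n", encoding="utf-8")
    paths["newick"] = nwk

    event_df = pd.DataFrame(
        [
            {
                "event_id": e.event_id,
                "level": e.level,
                "segment": e.segment,
                "n_tips": len(e.carrying_tips),
                "tips": ",".join(map(str, sorted(e.carrying_tips))),
            }
            for e in events
        ],
        columns=["event_id", "level", "segment", "n_tips", "tips"],
    )
    paths["events"] = write_tsv(event_df, outdir / "events.tsv")

    tip_df = pd.DataFrame(
        {
            "tip": [f"T{i}" for i in range(topo.n_tips)],
            "burden": res.per_tip_burden_mean.astype(int),
        }
    )
    paths["tip_burden"] = write_tsv(tip_df, outdir / "tip_burden.tsv")

    params = MutationParams(genome_size, mu, m)
    exp = burden_expectations(params, topo, alloc)
    arch = architectural_factor(topo, alloc, m)
    summary = {
        "analytic": {
            "per_tip": exp.per_tip,
            "crown_tips": exp.crown_tips,
            "crown_unique": exp.crown_unique,
            "A": arch.factor,
        },
        "simulated": {
            "n_events": int(res.n_events[0]),
            "unique_count": int(res.unique_counts[0]),
            "total_tip_occurrences": int(res.total_tip_occurrences[0]),
        },
    }
    spath = outdir / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    paths["summary"] = spath

    paths["manifest"] = write_manifest(
        outdir / "manifest.json",
        "fixture",
        {
            "depth": depth,
            "m": m,
            "tilt": _tilt_str(tilt),
            "total_time": total_time,
            "genome_size": genome_size,
            "mu": mu,
            "outdir": str(outdir),
        },
        seed,
    )
    return paths


def run_from_manifest(manifest_path: str | Path, outdir: str | Path | None = None) -> dict:
    """Re-execute a recorded run; outputs are byte-identical to the original.

    Supports ``fixture`` and ``validate`` manifests.
    """
    manifest_path = Path(manifest_path)
    doc = json.loads(manifest_path.read_text(encoding="utf-8"))
    command = doc["command"]
    cfg = doc["config"]
    if command == "fixture":
        target = Path(outdir) if outdir is not None else Path(cfg["outdir"])
        paths = generate_fixture(
            depth=cfg["depth"],
            seed=doc["seed"],
            outdir=target,
            m=cfg["m"],
            tilt=cfg["tilt"],
            total_time=cfg["total_time"],
            genome_size=cfg["genome_size"],
            mu=cfg["mu"],
        )
        return {"command": command, "paths": paths}
    if command == "validate":
        spec = ExperimentSpec(
            depths=tuple(cfg["depths"]),
            m_values=tuple(cfg["m_values"]),
            tilts=tuple(cfg["tilts"]),
            genome_size=cfg["genome_size"],
            mu=cfg["mu"],
            total_time=cfg["total_time"],
            replicates=cfg["replicates"],
            seed=doc["seed"],
        )
        table = run_validation_experiment(spec)
        if outdir is not None:
            write_tsv(table, Path(outdir) / "validation.tsv")
        return {"command": command, "table": table}
    raise ValueError(f"manifest command {command!r} cannot be re-run")
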