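"""Desk-scale reproductions of the canonical computational experiments.

Each experiment is specified by a :class:`SweepSpec` and returns a
:class:`SweepResult` holding a tidy table (one row per grid point per
replicate) plus metadata.  Scales default to values that run on a laptop in
minutes; the qualitative structure of the results (non-monotone dependence
of tumour mass on the switching rate into motility, agreement between the
analytic and continuum speeds, the critical apoptosis threshold) is already
present at these sizes.
"""

from __future__ import annotations

import logging
import pathlib
from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .params import LatticeGeometry, ModelRates, save_config, validate
from .ib import run, seed_single_cell
from .continuum import propagation_speed, NoFrontError
from .waves import (
    WaveSpeedQuery,
    critical_apoptosis,
    critical_exponent,
    minimal_wave_speed,
)
from .ctmc import state_distribution

logger = logging.getLogger("gogrow")

__all__ = [
    "SweepSpec",
    "SweepResult",
    "mass_heatmap",
    "speed_comparison",
    "figure7_curves",
    "make_fixtures",
]


@dataclass
class SweepSpec:
    """What to vary, what to hold fixed, what to measure."""

    grids: dict[str, np.ndarray]
    rates: ModelRates = dc_field(default_factory=ModelRates)
    geometry: LatticeGeometry = dc_field(default_factory=LatticeGeometry)
    observable: str = "mass"
    t_end: float = 25.0
    replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.grids or any(len(g) == 0 for g in self.grids.values()):
            raise ValueError("parameter grids must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SweepResult:
    table: pd.DataFrame
    meta: dict[str, Any]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SweepResult":
        return cls(table=pd.read_csv(path), meta={})


def _log_run(name: str, spec: SweepSpec) -> None:
    logger.info(
        "%s: rates=%s geometry=d%d L%d t_end=%g replicates=%d seed=%d version=%s",
        name,
        spec.rates.as_dict(),
        spec.geometry.d,
        spec.geometry.L,
        spec.t_end,
        spec.replicates,
        spec.seed,
        __version__,
    )


def mass_heatmap(spec: SweepSpec) -> SweepResult:
    """Tumour mass at fixed time over a (k_p, k_m) grid, from a single P-cell.

    Independent replicate streams are spawned from the root seed.
    Boundary-truncated replicates are excluded (their mass is biased low by
    the closed walls) and counted in the metadata."""
    if set(spec.grids) != {"k_p", "k_m"}:
        raise ValueError("mass_heatmap needs grids for exactly k_p and k_m")
    _log_run("mass_heatmap", spec)
    validate(spec.rates, spec.geometry)
    init = seed_single_cell(spec.geometry)
    rows = []
    excluded = 0
    root = np.random.SeedSequence(spec.seed)
    for i, k_p in enumerate(spec.grids["k_p"]):
        for j, k_m in enumerate(spec.grids["k_m"]):
            rates = spec.rates.replace(k_p=float(k_p), k_m=float(k_m))
            streams = root.spawn(1)[0].spawn(spec.replicates)  # unique per cell
            for rep, ss in enumerate(streams):
                traj = run(
                    init,
                    rates,
                    t_end=spec.t_end,
                    checkpoints=[spec.t_end],
                    seed=np.random.default_rng(ss),
                )
                if traj.truncated_at is not None:
                    excluded += 1
                    continue
                rows.append(
                    {
                        "k_p": float(k_p),
                        "k_m": float(k_m),
                        "replicate": rep,
                        "mass": int(traj.mass[-1]),
                    }
                )
    if excluded:
        logger.warning("mass_heatmap: excluded %d boundary-truncated replicates",
                       excluded)
    table = pd.DataFrame(rows)
    return SweepResult(
        table=table,
        meta={"observable": "mass", "t_end": spec.t_end, "excluded": excluded},
    )


def speed_comparison(
    spec: SweepSpec, sources: tuple[str, ...] = ("continuum", "analytic"),
    window: tuple[float, float] = (25.0, 50.0), n_sites: int = 600,
) -> SweepResult:
    """Front speeds from several sources over a one-parameter grid.

    Sources: "analytic" (minimal wave speed from the origin spectrum) and
    "continuum" (fitted master-equation front speed).  The table carries one
    row per grid point per source, plus the relative deviation from the
    analytic value where both are present; a vanished front is recorded as
    NaN speed."""
    if len(spec.grids) != 1:
        raise ValueError("speed_comparison sweeps exactly one parameter")
    (param, grid), = spec.grids.items()
    _log_run("speed_comparison", spec)
    rows = []
    for value in grid:
        rates = spec.rates.replace(**{param: float(value)})
        c_star = minimal_wave_speed(WaveSpeedQuery(rates=rates))
        for source in sources:
            if source == "analytic":
                speed = c_star
            elif source == "continuum":
                try:
                    speed = propagation_speed(
                        rates, n_sites=n_sites, window=window
                    ).speed
                except NoFrontError:
                    speed = np.nan
            else:
                raise ValueError(f"unknown source {source!r}")
            rows.append(
                {
                    param: float(value),
                    "source": source,
                    "speed": speed,
                    "rel_dev": abs(speed - c_star) / c_star
                    if c_star > 0 and np.isfinite(speed)
                    else np.nan,
                }
            )
    return SweepResult(
        table=pd.DataFrame(rows),
        meta={"observable": "front_speed", "param": param, "window": window},
    )


def figure7_curves(spec: SweepSpec) -> SweepResult:
    """Wave speed as a function of one of alpha, nu or mu.

    For the apoptosis sweep the metadata additionally reports the critical
    rate mu_c and the fitted critical exponent of the speed's vanishing."""
    if len(spec.grids) != 1:
        raise ValueError("figure7_curves sweeps exactly one parameter")
    (param, grid), = spec.grids.items()
    if param not in ("alpha", "nu", "mu"):
        raise ValueError("vary one of alpha, nu, mu")
    _log_run("figure7_curves", spec)
    rows = []
    for value in grid:
        rates = spec.rates.replace(**{param: float(value)})
        c = minimal_wave_speed(WaveSpeedQuery(rates=rates)) if rates.alpha > 0 else 0.0
        rows.append({param: float(value), "c_star": c})
    meta: dict[str, Any] = {"observable": "c_star", "param": param}
    if param == "mu":
        meta["mu_c"] = critical_apoptosis(
            spec.rates.alpha, spec.rates.k_p, spec.rates.k_m
        )
        crit = critical_exponent(spec.rates)
        meta["beta"] = crit.beta
    return SweepResult(table=pd.DataFrame(rows), meta=meta)


# Canonical configurations.  The three front scenarios span the qualitative
# regimes: no switching to motility, balanced switching, and
# migration-biased switching.
BASELINE = ModelRates(alpha=1.0, nu=5.0, mu=0.01, k_p=1.0, k_m=1.0)
SCENARIOS = {
    "proliferation_only": ModelRates(alpha=1.0, nu=5.0, mu=0.01, k_p=0.0, k_m=0.0),
    "balanced_switching": ModelRates(alpha=1.0, nu=5.0, mu=0.01, k_p=1.0, k_m=1.0),
    "migration_biased": ModelRates(alpha=1.0, nu=5.0, mu=0.01, k_p=1.0, k_m=2.0),
}
#: Reference case for exact-CTMC validation: 1-D, 3 sites, single central
#: P-cell, one cell cycle.
CTMC_CASE = {
    "rates": ModelRates(alpha=1.0, nu=1.0, mu=0.1, k_p=0.2, k_m=0.5),
    "L": 3,
    "t": 1.0,
}


def make_fixtures(outdir, seed: int = 0) -> dict[str, pathlib.Path]:
    """Write the canonical configs and the exact CTMC reference distribution.

    Emits ``baseline.yaml``, one YAML config per front scenario, and
    ``ctmc_reference.csv`` (the exact 27-configuration distribution for the
    3-site validation case, computed by matrix exponential)."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, pathlib.Path] = {}
    geom = LatticeGeometry(d=2, L=200)
    path = outdir / "baseline.yaml"
    save_config(path, BASELINE, geom, seed=seed)
    written["baseline"] = path
    for name, rates in SCENARIOS.items():
        path = outdir / f"{name}.yaml"
        save_config(path, rates, LatticeGeometry(d=1, L=600), seed=seed)
        written[name] = path
    case = CTMC_CASE
    init = seed_single_cell(LatticeGeometry(d=1, L=case["L"]))
    dist = state_distribution(case["rates"], case["L"], case["t"], init.grid)
    table = pd.DataFrame(
        {"state_index": np.arange(dist.size), "probability": dist}
    )
    path = outdir / "ctmc_reference.csv"
    table.to_csv(path, index=False)
    written["ctmc_reference"] = path
    logger.info("wrote %d fixture files to %s", len(written), outdir)
    return written
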