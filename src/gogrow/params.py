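"""Parameter and geometry types shared by the simulator and the analysis.

The model describes glioblastoma cells on a lattice that switch between a
proliferative (P) and a migratory (M) phenotype.  Five non-negative rates
define the cell-level dynamics, all expressed per cell cycle (the internal
time unit; a cell cycle is roughly 24 h):

``alpha``
    division rate of P-cells.  Setting the time unit to the cell cycle makes
    ``alpha = 1`` the canonical baseline.
``nu``
    jump rate of M-cells (one attempted jump of one cell diameter).
``mu``
    apoptosis rate, identical for both phenotypes.
``k_p``
    switching rate M -> P (into the proliferative state).
``k_m``
    switching rate P -> M (into the migratory state).

Lengths are measured in cell diameters, i.e. the lattice spacing is ``a = 1``.
Conversions to hours or micrometres are presentation-level concerns and are
deliberately kept out of the numerics.
"""

from __future__ import annotations

import json
import math
import pathlib
import warnings
from dataclasses import dataclass, replace, asdict
from typing import Any, Mapping

import yaml

__all__ = [
    "ModelRates",
    "LatticeGeometry",
    "DiffusionConstants",
    "ParameterWarning",
    "validate",
    "diffusion_constants",
    "load_config",
    "save_config",
    "SWITCH_RATE_SOFT_MAX",
]

#: Phenotypic switching is not observed faster than roughly once per hour;
#: with a 24 h cell cycle that caps plausible switching rates at 24 per cycle.
SWITCH_RATE_SOFT_MAX = 24.0

RATE_FIELDS = ("alpha", "nu", "mu", "k_p", "k_m")


class ParameterWarning(UserWarning):
    """Soft violation of a biologically motivated parameter bound."""


@dataclass(frozen=True)
class ModelRates:
    """The five cell-level rates, in units of 1/cell-cycle."""

    alpha: float = 1.0
    nu: float = 5.0
    mu: float = 0.01
    k_p: float = 0.0
    k_m: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def replace(self, **kwargs: float) -> "ModelRates":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LatticeGeometry:
    """A d-dimensional cubic lattice of linear size L with spacing a.

    The neighbourhood is von Neumann: each interior site has 2d neighbours.
    The spacing is fixed at one cell diameter; it is carried explicitly only
    so that derived quantities state their units.
    """

    d: int = 2
    L: int = 200
    a: float = 1.0

    @property
    def n_sites(self) -> int:
        return self.L**self.d

    @property
    def shape(self) -> tuple[int, ...]:
        return (self.L,) * self.d

    @property
    def center(self) -> tuple[int, ...]:
        return (self.L // 2,) * self.d


@dataclass(frozen=True)
class DiffusionConstants:
    """Per-axis diffusion constants, in cell-diameter^2 per cell cycle.

    ``D_alpha = alpha * a**2 / (2 d)`` is the diffusion-like constant of
    proliferation-driven spread and ``D_nu = nu * a**2 / (2 d)`` that of
    migration.  The 1/(2d) factor makes these *per-axis* constants: motion
    tangential to a planar front does not advance it, so a d-dimensional
    simulation is compared against the 1-D analysis through these values.
    """

    D_alpha: float
    D_nu: float


def validate(rates: ModelRates, geom: LatticeGeometry | None = None) -> list[str]:
    """Check hard invariants and collect soft warnings.

    Raises ``ValueError`` naming the offending field for any negative rate or
    an unsupported geometry.  Switching rates above ``SWITCH_RATE_SOFT_MAX``
    are biologically implausible (faster than hourly) but not forbidden: a
    ``ParameterWarning`` is emitted and the message returned.
    """
    for name in RATE_FIELDS:
        value = getattr(rates, name)
        if not math.isfinite(value):
            raise ValueError(f"rate {name!r} must be finite, got {value!r}")
        if value < 0:
            raise ValueError(f"rate {name!r} must be >= 0, got {value!r}")
    msgs: list[str] = []
    for name in ("k_p", "k_m"):
        value = getattr(rates, name)
        if value > SWITCH_RATE_SOFT_MAX:
            msg = (
                f"switching rate {name}={value:g} exceeds {SWITCH_RATE_SOFT_MAX:g} "
                "per cell cycle (faster than the ~1 h switching floor)"
            )
            warnings.warn(msg, ParameterWarning, stacklevel=2)
            msgs.append(msg)
    if geom is not None:
        if geom.d not in (1, 2, 3):
            raise ValueError(f"dimension d must be 1, 2 or 3, got {geom.d!r}")
        if geom.L < 3:
            raise ValueError(f"lattice size L must be >= 3, got {geom.L!r}")
        if geom.a != 1.0:
            raise ValueError("lattice spacing is fixed to 1 cell diameter")
    return msgs


def diffusion_constants(
    rates: ModelRates, geom: LatticeGeometry | int = 1
) -> DiffusionConstants:
    """Per-axis diffusion constants ``D = rate * a**2 / (2 d)``.

    ``geom`` may be a :class:`LatticeGeometry` or simply the dimension d.
    """
    if isinstance(geom, int):
        geom = LatticeGeometry(d=geom, L=3)
    validate(rates, geom)
    factor = geom.a**2 / (2 * geom.d)
    return DiffusionConstants(D_alpha=rates.alpha * factor, D_nu=rates.nu * factor)


# ---------------------------------------------------------------------------
# Configuration files
# ---------------------------------------------------------------------------

CONFIG_KEYS = ("alpha", "nu", "mu", "k_p", "k_m", "dimension", "lattice_size", "seed")


def config_to_objects(
    cfg: Mapping[str, Any],
) -> tuple[ModelRates, LatticeGeometry, int | None]:
    rates = ModelRates(
        **{k: float(cfg[k]) for k in RATE_FIELDS if k in cfg}
    )
    geom = LatticeGeometry(
        d=int(cfg.get("dimension", 2)), L=int(cfg.get("lattice_size", 200))
    )
    seed = cfg.get("seed")
    validate(rates, geom)
    return rates, geom, None if seed is None else int(seed)


def load_config(path: str | pathlib.Path) -> tuple[ModelRates, LatticeGeometry, int | None]:
    """Read a JSON or YAML configuration file.

    Recognised keys: ``alpha, nu, mu, k_p, k_m, dimension, lattice_size,
    seed``; rates are per cell cycle, lengths in cell diameters.  JSON is a
    subset of YAML, so a single parser handles both.
    """
    text = pathlib.Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"config file {path} does not contain a mapping")
    unknown = set(cfg) - set(CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return config_to_objects(cfg)


def save_config(
    path: str | pathlib.Path,
    rates: ModelRates,
    geom: LatticeGeometry | None = None,
    seed: int | None = None,
) -> None:
    """Write a configuration file; format chosen by extension (.json else YAML)."""
    path = pathlib.Path(path)
    cfg: dict[str, Any] = rates.as_dict()
    if geom is not None:
        cfg["dimension"] = geom.d
        cfg["lattice_size"] = geom.L
    if seed is not None:
        cfg["seed"] = seed
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
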