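"""Physical component models for shared-line infusion setups.

A multi-infusion setup is assembled from syringes (which carry the
mechanical compliance of the system), tubing segments, a mixing
manifold (which defines the shared dead volume), and a vascular-access
catheter.  This module holds the component types, converts tube
geometry to hydraulic resistance and internal volume, and ships a
catalog of commonly used commercial components with documented default
parameters.

Geometry-to-hydraulics conversions assume fully developed laminar flow
in a cylindrical tube (Hagen-Poiseuille), which is an excellent
approximation at clinical infusion Reynolds numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from .units import (
    M_PER_MM,
    ML_PER_M3,
    PAS_PER_MPAS,
    resistance_si_to_clinical,
)

__all__ = [
    "TubeGeometry",
    "CatheterSpec",
    "SyringeSpec",
    "MixingPointSpec",
    "poiseuille_resistance",
    "tube_volume",
    "catalog_lookup",
    "catalog_names",
    "load_catalog",
    "DEFAULT_VISCOSITY_MPAS",
]

#: water-like infusate at room temperature; override per branch for
#: viscous solutions (e.g. lipid emulsions)
DEFAULT_VISCOSITY_MPAS = 1.0


class InvalidParameterError(ValueError):
    """A physical parameter is outside its valid domain."""


class CatalogLookupError(KeyError):
    """Requested component is not in the catalog."""


@dataclass(frozen=True)
class TubeGeometry:
    """Cylindrical tube: length in metres, inner diameter in millimetres."""

    length_m: float
    inner_diameter_mm: float

    def __post_init__(self) -> None:
        if self.length_m <= 0:
            raise InvalidParameterError(f"tube length must be > 0, got {self.length_m}")
        if self.inner_diameter_mm <= 0:
            raise InvalidParameterError(
                f"inner diameter must be > 0, got {self.inner_diameter_mm}"
            )

    @property
    def volume_ml(self) -> float:
        return tube_volume(self)


@dataclass(frozen=True)
class CatheterSpec:
    """A vascular access catheter.

    ``french_size`` is the French gauge (1 Fr = 1/3 mm *outer*
    diameter); the hydraulically relevant inner diameter is
    product-specific and carried by ``geometry``.
    """

    name: str
    french_size: float
    geometry: TubeGeometry
    viscosity_mpas: float = DEFAULT_VISCOSITY_MPAS

    def __post_init__(self) -> None:
        if self.french_size <= 0:
            raise InvalidParameterError("french_size must be > 0")
        if self.viscosity_mpas <= 0:
            raise InvalidParameterError("viscosity must be > 0")

    @property
    def resistance_mbar_h_per_ml(self) -> float:
        return poiseuille_resistance(self.geometry, self.viscosity_mpas)

    @property
    def volume_ml(self) -> float:
        return tube_volume(self.geometry)


@dataclass(frozen=True)
class SyringeSpec:
    """A syringe and its mechanical compliance.

    ``compliance_ml_per_mbar`` lumps every compressible element of the
    branch (dominated by the air-filled rubber plunger tip) into a
    single stored-volume-per-pressure coefficient.  Zero denotes an
    idealized rigid syringe.
    """

    name: str
    nominal_volume_ml: float
    compliance_ml_per_mbar: float

    def __post_init__(self) -> None:
        if self.nominal_volume_ml <= 0:
            raise InvalidParameterError("nominal_volume_ml must be > 0")
        if self.compliance_ml_per_mbar < 0:
            raise InvalidParameterError("compliance must be >= 0")


@dataclass(frozen=True)
class MixingPointSpec:
    """Mixing manifold; ``dead_volume_ml`` is the shared volume between
    the mixing point and the vascular access device."""

    name: str
    dead_volume_ml: float

    def __post_init__(self) -> None:
        if self.dead_volume_ml < 0:
            raise InvalidParameterError("dead_volume_ml must be >= 0")


def poiseuille_resistance(geometry: TubeGeometry, viscosity_mpas: float) -> float:
    """Hagen-Poiseuille resistance of a cylindrical tube, in mbar*h/mL.

    R = 128 * mu * L / (pi * d**4); halving the diameter multiplies the
    resistance by 16, which is why very thin catheters dominate the
    pressure budget of a shared-line setup.

    Parameters
    ----------
    geometry
        Tube length and inner diameter.
    viscosity_mpas
        Dynamic viscosity of the infusate in mPa*s.
    """
    if viscosity_mpas <= 0:
        raise InvalidParameterError(f"viscosity must be > 0, got {viscosity_mpas}")
    mu = viscosity_mpas * PAS_PER_MPAS
    d = geometry.inner_diameter_mm * M_PER_MM
    r_si = 128.0 * mu * geometry.length_m / (math.pi * d**4)
    return resistance_si_to_clinical(r_si)


def tube_volume(geometry: TubeGeometry) -> float:
    """Internal volume of a cylindrical tube in mL."""
    r_m = geometry.inner_diameter_mm * M_PER_MM / 2.0
    return math.pi * r_m**2 * geometry.length_m * ML_PER_M3


# ---------------------------------------------------------------------------
# Component catalog
# ---------------------------------------------------------------------------
# Defaults mirror a typical neonatal/adult shared-line setup.  Inner
# diameters and the syringe compliance are manufacturer-undisclosed and
# are documented engineering estimates; every value can be overridden
# via a user catalog file (see load_catalog).

_DATA_FILE = Path(__file__).parent / "data" / "catalog.yaml"

_CATALOG: dict[str, object] | None = None


def _build_entry(kind: str, cfg: dict) -> object:
    if kind == "catheter":
        return CatheterSpec(
            name=cfg["name"],
            french_size=cfg["french_size"],
            geometry=TubeGeometry(cfg["length_m"], cfg["inner_diameter_mm"]),
        )
    if kind == "syringe":
        return SyringeSpec(
            name=cfg["name"],
            nominal_volume_ml=cfg["nominal_volume_ml"],
            compliance_ml_per_mbar=cfg["compliance_ml_per_mbar"],
        )
    if kind == "mixing_point":
        return MixingPointSpec(name=cfg["name"], dead_volume_ml=cfg["dead_volume_ml"])
    if kind == "tubing":
        return TubeGeometry(cfg["length_m"], cfg["inner_diameter_mm"])
    raise InvalidParameterError(f"unknown catalog entry kind: {kind!r}")


def load_catalog(path: str | Path | None = None) -> dict[str, object]:
    """Load a component catalog from a YAML file.

    The file maps component labels to ``{kind: ..., <fields>}``
    records; see the packaged ``data/catalog.yaml`` for the schema.
    Returns a dict of validated component specs keyed by label.
    """
    raw = yaml.safe_load(Path(path or _DATA_FILE).read_text())
    catalog: dict[str, object] = {}
    for label, cfg in raw.items():
        cfg = dict(cfg)
        kind = cfg.pop("kind")
        cfg.setdefault("name", label)
        catalog[label] = _build_entry(kind, cfg)
    return catalog


def _default_catalog() -> dict[str, object]:
    global _CATALOG
    if _CATALOG is None:
        _CATALOG = load_catalog()
    return _CATALOG


def catalog_names() -> list[str]:
    """Labels of all built-in catalog entries."""
    return sorted(_default_catalog())


def catalog_lookup(name: str):
    """Return the component spec registered under ``name``.

    Raises
    ------
    CatalogLookupError
        If the label is unknown; the message lists available entries.
    """
    catalog = _default_catalog()
    try:
        return catalog[name]
    except KeyError:
        available = ", ".join(sorted(catalog))
        raise CatalogLookupError(
            f"unknown component {name!r}; available: {available}"
        ) from None


def with_overrides(spec, **kwargs):
    """Copy of a component spec with selected fields replaced."""
    return replace(spec, **kwargs)
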