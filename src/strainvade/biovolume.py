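"""Biovolume-based biomass and particulate C:N:P stoichiometry.

Microscopy censuses report cell abundance, mean cell dimensions and an
assigned geometric solid per species.  Cell volume follows the standard
phytoplankton biovolume conventions for that solid; biomass is abundance ×
cell volume at unit density (1 g cm⁻³, the fresh-weight convention), and
community shares are species biomass over total biomass.  Particulate C, N
and P masses convert to molar ratios against the Redfield reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

#: g mol⁻¹
ATOMIC_MASS = {"C": 12.011, "N": 14.007, "P": 30.974}

#: canonical marine-plankton stoichiometry, used as nutrient-limitation reference
REDFIELD_CN = 6.6
REDFIELD_CP = 106.0

#: 1 μm³ of cell volume at density 1 g cm⁻³ weighs 10⁻⁶ μg
_UG_PER_UM3 = 1e-6

#: dimensions (by key) each shape requires: d = diameter, l = length, w = width
SHAPE_DIMENSIONS = {
    "sphere": ("d",),
    "prolate_spheroid": ("d", "l"),
    "cylinder": ("d", "l"),
    "double_cone": ("d", "l"),
    "ellipsoid": ("d", "l", "w"),
}


@dataclass
class ShapeSpec:
    """Geometric model of a cell: shape name plus the required dimensions (μm)."""

    species_id: str
    shape: str
    dimensions: dict[str, float]

    def __post_init__(self) -> None:
        if self.shape not in SHAPE_DIMENSIONS:
            raise ValueError(
                f"unknown shape {self.shape!r}; known: {sorted(SHAPE_DIMENSIONS)}"
            )
        required = SHAPE_DIMENSIONS[self.shape]
        missing = [k for k in required if k not in self.dimensions
                   or self.dimensions[k] is None
                   or (isinstance(self.dimensions[k], float)
                       and math.isnan(self.dimensions[k]))]
        if missing:
            raise ValueError(
                f"{self.species_id}: shape {self.shape!r} needs dimension(s) "
                f"{missing}"
            )
        for k in required:
            if self.dimensions[k] <= 0:
                raise ValueError(f"{self.species_id}: dimension {k!r} must be > 0")


@dataclass
class CnpMeasurement:
    """Particulate elemental masses of one sample (μg)."""

    sample_id: str
    C_mass: float
    N_mass: float
    P_mass: float

    def __post_init__(self) -> None:
        for name in ("C_mass", "N_mass", "P_mass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")


def cell_volume(spec: ShapeSpec) -> float:
    """Cell volume in μm³ from the assigned geometric solid.

    sphere πd³/6; cylinder π(d/2)²·l; prolate spheroid (π/6)·d²·l;
    ellipsoid (π/6)·d·l·w; double cone (π/12)·d²·l.
    """
    dims = spec.dimensions
    d = dims.get("d")
    l = dims.get("l")
    w = dims.get("w")
    if spec.shape == "sphere":
        return math.pi * d**3 / 6.0
    if spec.shape == "cylinder":
        return math.pi * (d / 2.0) ** 2 * l
    if spec.shape == "prolate_spheroid":
        return math.pi / 6.0 * d**2 * l
    if spec.shape == "ellipsoid":
        return math.pi / 6.0 * d * l * w
    if spec.shape == "double_cone":
        return math.pi / 12.0 * d**2 * l
    raise ValueError(f"unknown shape {spec.shape!r}")  # pragma: no cover


def biomass(abundance_per_ml: float, volume_um3: float) -> float:
    """Biomass in μg ml⁻¹: abundance × cell volume at unit density."""
    if abundance_per_ml < 0:
        raise ValueError("abundance must be ≥ 0")
    return abundance_per_ml * volume_um3 * _UG_PER_UM3


def census_to_biomass(census: pd.DataFrame) -> pd.DataFrame:
    """Convert a census table to biomass and community shares.

    Expects columns ``sample_id, species_id, abundance_per_ml, shape,
    dim_d_um, dim_l_um, dim_w_um`` (dimension columns blank where the shape
    does not use them).  Returns a frame with ``biomass_ug_ml`` and the
    within-sample ``share``.
    """
    required = {"sample_id", "species_id", "abundance_per_ml", "shape"}
    missing = required - set(census.columns)
    if missing:
        raise ValueError(f"census table missing column(s): {sorted(missing)}")
    rows = []
    for _, row in census.iterrows():
        dims = {}
        for key, col in (("d", "dim_d_um"), ("l", "dim_l_um"), ("w", "dim_w_um")):
            v = row.get(col)
            if v is not None and not pd.isna(v):
                dims[key] = float(v)
        spec = ShapeSpec(str(row["species_id"]), str(row["shape"]), dims)
        b = biomass(float(row["abundance_per_ml"]), cell_volume(spec))
        rows.append(
            {"sample_id": row["sample_id"], "species_id": row["species_id"],
             "biomass_ug_ml": b}
        )
    out = pd.DataFrame(rows)
    totals = out.groupby("sample_id")["biomass_ug_ml"].transform("sum")
    out["share"] = out["biomass_ug_ml"].where(totals == 0, out["biomass_ug_ml"] / totals)
    out.loc[totals == 0, "share"] = float("nan")
    return out


def molar_cnp(m: CnpMeasurement) -> dict[str, float]:
    """Molar C:N, C:P and N:P ratios from particulate elemental masses.

    Any common mass unit works — the ratios are unit-free.  A zero
    denominator leaves the affected ratio NaN.
    """
    moles = {e: getattr(m, f"{e}_mass") / ATOMIC_MASS[e] for e in ("C", "N", "P")}
    nan = float("nan")
    return {
        "C:N": moles["C"] / moles["N"] if moles["N"] > 0 else nan,
        "C:P": moles["C"] / moles["P"] if moles["P"] > 0 else nan,
        "N:P": moles["N"] / moles["P"] if moles["P"] > 0 else nan,
    }


def cnp_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Vectorised molar ratios for a table with columns sample_id, C_ug, N_ug, P_ug."""
    out = []
    for _, row in measurements.iterrows():
        m = CnpMeasurement(str(row["sample_id"]),
                           float(row["C_ug"]), float(row["N_ug"]), float(row["P_ug"]))
        ratios = molar_cnp(m)
        out.append({"sample_id": m.sample_id, "CN": ratios["C:N"],
                    "CP": ratios["C:P"], "NP": ratios["N:P"]})
    return pd.DataFrame(out, columns=["sample_id", "CN", "CP", "NP"])
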