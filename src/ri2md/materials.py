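"""Material constants and Lorentz-Lorenz conversions.

A solute species is characterised by two specific quantities, both in mL/g:
its refraction per gram ``R`` (specific refractivity) and its partial
specific volume (PSV) ``theta``.  Under volume additivity the solute mass
density is ``1/theta`` and its refractive index follows from the
Lorentz-Lorenz (Clausius-Mossotti) relation

    R = (1/rho) * (n**2 - 1) / (n**2 + 2).

The module ships a small table of literature constants (water, triolein,
milk components, soybean oil, a few phospholipid fatty acids) used by the
mixture and Monte-Carlo modules; every entry records its provenance and can
be overridden by user-supplied configuration.

Units package-wide: densities g/mL, specific volumes and refractions per
gram mL/g, concentrations g/mL, refractive indices dimensionless.  All
constants are single-wavelength effective values; no dispersion or
temperature corrections are applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Solvent",
    "Material",
    "MaterialTable",
    "WATER",
    "lorentz_lorenz_factor",
    "refraction_per_gram",
    "ri_from_material",
    "load_material_table",
    "default_table",
]


def lorentz_lorenz_factor(n):
    """Return (n^2 - 1)/(n^2 + 2), the molar-refraction fraction of an RI."""
    n = np.asarray(n, dtype=float)
    return (n * n - 1.0) / (n * n + 2.0)


def _inverse_lorentz_lorenz_factor(f):
    return np.sqrt((1.0 + 2.0 * f) / (1.0 - f))


def refraction_per_gram(n, rho):
    """Refraction per gram R (mL/g) from refractive index and mass density.

    Parameters
    ----------
    n : float or array
        Refractive index, >= 1.
    rho : float or array
        Mass density in g/mL, > 0.
    """
    n = np.asarray(n, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("mass density must be positive")
    if np.any(n < 1):
        raise ValueError("refractive index must be >= 1")
    out = lorentz_lorenz_factor(n) / rho
    return out.item() if out.ndim == 0 else out

def ri_from_material(R, rho):
    """Refractive index from refraction per gram R (mL/g) and density (g/mL).

    Inverts the Lorentz-Lorenz relation; requires ``R * rho < 1`` (the pole
    of the closed form marks nonphysical refractivity).
    """
    R = np.asarray(R, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(R < 0):
        raise ValueError("refraction per gram must be non-negative")
    prod = R * rho
    if np.any(prod >= 1):
        raise ValueError("nonphysical refractivity: R * rho must be < 1")
    out = _inverse_lorentz_lorenz_factor(prod)
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class Solvent:
    """Solvent optical and mass properties, treated as exactly known."""

    n1: float = 1.3330
    rho1: float = 0.997

    def __post_init__(self):
        if not self.n1 > 1:
            raise ValueError("solvent refractive index must exceed 1")
        if not self.rho1 > 0:
            raise ValueError("solvent density must be positive")


#: Water at ~23 degC. The density is the standard literature value; the RI is
#: the sodium-D value customarily used for visible-light refractometry.
WATER = Solvent(n1=1.3330, rho1=0.997)


@dataclass
class Material:
    """One solute (or solvent) species.

    Parameters are the refraction per gram ``R`` and PSV ``theta`` with
    optional standard deviations.  ``alpha_ref`` optionally caches a
    directly-measured (or directly-tabulated) Biot RI increment referenced to
    a particular solvent RI, so that printed increments survive round-trips
    through (R, theta) without numerical drift.
    """

    name: str
    R: float
    theta: float
    dR: float = 0.0
    dtheta: float = 0.0
    provenance: str = ""
    alpha_ref: tuple | None = field(default=None, repr=False)  # (alpha, dalpha, n1)

    def __post_init__(self):
        if not self.theta > 0:
            raise ValueError(f"{self.name}: PSV must be positive")
        if self.R < 0:
            raise ValueError(f"{self.name}: refraction per gram must be non-negative")
        if self.R / self.theta >= 1.0:
            raise ValueError(
                f"{self.name}: R/theta must be < 1 for a real refractive index"
            )
        if self.dR < 0 or self.dtheta < 0:
            raise ValueError(f"{self.name}: standard deviations must be >= 0")

    @property
    def rho(self) -> float:
        """Mass density 1/theta (g/mL), assuming volume additivity."""
        return 1.0 / self.theta

    @property
    def n(self) -> float:
        """Refractive index from the Lorentz-Lorenz relation."""
        return float(ri_from_material(self.R, self.rho))

    @classmethod
    def from_optical(cls, name, n, rho, dn=0.0, drho=0.0, provenance=""):
        """Build a material from measured (n, rho); sds propagated linearly."""
        R = float(refraction_per_gram(n, rho))
        theta = 1.0 / rho
        # dR/dn = f'(n)/rho, dR/drho = -R/rho; dtheta/drho = -1/rho^2
        fp = 6.0 * n / (n * n + 2.0) ** 2
        dR = math.hypot(fp / rho * dn, R / rho * drho)
        dtheta = drho / rho**2
        return cls(name, R, theta, dR, dtheta, provenance)

    @classmethod
    def from_biot_increment(
        cls, name, alpha, theta, n1=WATER.n1, dalpha=0.0, dtheta=0.0, provenance=""
    ):
        """Build a material from a Biot RI increment and PSV.

        The species RI is ``n2 = n1 + alpha/theta`` (Biot rule inverted for a
        pure solute) and R follows from the Lorentz-Lorenz relation.
        """
        n2 = n1 + alpha / theta
        R = theta * float(lorentz_lorenz_factor(n2))
        fp = 6.0 * n2 / (n2 * n2 + 2.0) ** 2
        dR = math.hypot(
            fp * dalpha,
            (float(lorentz_lorenz_factor(n2)) - fp * alpha / theta) * dtheta,
        )
        mat = cls(name, R, theta, dR, dtheta, provenance)
        mat.alpha_ref = (float(alpha), float(dalpha), float(n1))
        return mat

    def biot_increment(self, solvent: Solvent = WATER) -> tuple[float, float]:
        """Return (alpha, dalpha) in mL/g for this material in ``solvent``.

        Uses the cached tabulated increment when it was given for the same
        solvent RI; otherwise computes ``theta * (n - n1)`` with first-order
        propagation of (dR, dtheta).
        """
        if self.alpha_ref is not None and abs(self.alpha_ref[2] - solvent.n1) < 1e-9:
            return self.alpha_ref[0], self.alpha_ref[1]
        n2 = self.n
        alpha = self.theta * (n2 - solvent.n1)
        # n2 = n(R, 1/theta): dn/dR = rho/f'(n); dn/dtheta = -rho/theta*R*rho/f'(n)
        fp = 6.0 * n2 / (n2 * n2 + 2.0) ** 2
        dn_dR = self.rho / fp
        dn_dtheta = -self.R / (self.theta**2) / fp
        dalpha = math.hypot(
            self.theta * dn_dR * self.dR,
            ((n2 - solvent.n1) + self.theta * dn_dtheta) * self.dtheta,
        )
        return float(alpha), float(dalpha)


class MaterialTable:
    """A validated mapping of unique labels to :class:`Material` entries."""

    def __init__(self, entries: Mapping[str, Material] | None = None):
        self.entries: dict[str, Material] = {}
        for name, mat in (entries or {}).items():
            self.add(mat if mat.name == name else Material(**{**mat.__dict__, "name": name}))

    def add(self, material: Material):
        if material.name in self.entries:
            raise ValueError(f"duplicate material label {material.name!r}")
        self.entries[material.name] = material

    def __getitem__(self, name: str) -> Material:
        try:
            return self.entries[name]
        except KeyError:
            raise KeyError(
                f"unknown material {name!r}; available: {sorted(self.entries)}"
            ) from None

    def __contains__(self, name):
        return name in self.entries

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "name": m.name,
                "R": m.R,
                "dR": m.dR,
                "theta": m.theta,
                "dtheta": m.dtheta,
                "n": m.n,
                "rho": m.rho,
                "provenance": m.provenance,
            }
            for m in self
        ]
        return pd.DataFrame(rows, columns=["name", "R", "dR", "theta", "dtheta", "n", "rho", "provenance"])

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    def to_mapping(self) -> dict:
        out = {}
        for m in self:
            entry = {"R": m.R, "theta": m.theta}
            if m.dR:
                entry["dR"] = m.dR
            if m.dtheta:
                entry["dtheta"] = m.dtheta
            if m.provenance:
                entry["provenance"] = m.provenance
            if m.alpha_ref is not None:
                entry["alpha"], entry["dalpha"], entry["n1"] = m.alpha_ref
                del entry["R"]  # alpha/theta entries round-trip through the increment
            out[m.name] = entry
        return out

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_mapping(), sort_keys=True))


def _material_from_entry(name: str, entry: Mapping) -> Material:
    if not isinstance(entry, Mapping):
        raise ValueError(f"material {name!r}: entry must be a mapping, got {type(entry).__name__}")
    prov = str(entry.get("provenance", ""))
    keys = set(entry)
    try:
        if "alpha" in keys:
            if "theta" not in keys:
                raise ValueError("an 'alpha' entry also needs 'theta'")
            return Material.from_biot_increment(
                name,
                float(entry["alpha"]),
                float(entry["theta"]),
                n1=float(entry.get("n1", WATER.n1)),
                dalpha=float(entry.get("dalpha", 0.0)),
                dtheta=float(entry.get("dtheta", 0.0)),
                provenance=prov,
            )
        if "n" in keys and "rho" in keys:
            return Material.from_optical(
                name,
                float(entry["n"]),
                float(entry["rho"]),
                dn=float(entry.get("dn", 0.0)),
                drho=float(entry.get("drho", 0.0)),
                provenance=prov,
            )
        if "R" in keys and "theta" in keys:
            return Material(
                name,
                float(entry["R"]),
                float(entry["theta"]),
                dR=float(entry.get("dR", 0.0)),
                dtheta=float(entry.get("dtheta", 0.0)),
                provenance=prov,
            )
    except (TypeError, ValueError) as exc:
        raise ValueError(f"material {name!r}: {exc}") from None
    raise ValueError(
        f"material {name!r}: specify either (R, theta), (n, rho) or (alpha, theta)"
    )


def load_material_table(source) -> MaterialTable:
    """Load a :class:`MaterialTable` from a YAML file path or a mapping.

    Each entry may specify ``(R, theta)`` directly, ``(n, rho)`` (converted
    through the Lorentz-Lorenz relation and ``theta = 1/rho``) or
    ``(alpha, theta)`` (a Biot increment referenced to ``n1``, default
    water).  Optional keys: dR/dtheta/dn/drho/dalpha sds and ``provenance``.
    """
    if isinstance(source, Mapping):
        mapping = source
    else:
        with open(source) as fh:
            mapping = yaml.safe_load(fh) or {}
        if not isinstance(mapping, Mapping):
            raise ValueError(f"{source}: material table must be a mapping")
    table = MaterialTable()
    for name, entry in mapping.items():
        table.add(_material_from_entry(str(name), entry))
    return table


def default_table() -> MaterialTable:
    """The bundled literature table (see data/materials.yaml for citations)."""
    ref = resources.files("ri2md").joinpath("data/materials.yaml")
    with resources.as_file(ref) as path:
        return load_material_table(path)
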