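"""Deterministic mixture model linking refractive index and mass density.

The binary model: a solute of concentration ``c2`` (g/mL), PSV ``theta`` and
Biot RI increment ``alpha`` dissolved in a solvent of density ``rho1`` and RI
``n1``.  Under volume additivity

    rho = rho1 * (1 - c2*theta) + c2,          delta_n = alpha * c2,

which combine into the affine relation

    rho(delta_n) = delta_n/alpha + rho1 * (1 - theta*delta_n/alpha)

with slope d(rho)/dn = (1 - rho1*theta)/alpha.  Complex solutes are absorbed
into the same form through mass-averaged effective parameters (alpha_eff,
theta_eff).  Besides the Biot (arithmetic volume-fraction) rule the module
supports the Lorentz-Lorenz and Wiener mixing rules through generic numeric
inversion of n(c2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .materials import (
    Material,
    Solvent,
    WATER,
    lorentz_lorenz_factor,
    ri_from_material,
)

__all__ = [
    "ComponentSpec",
    "SoluteComposition",
    "EffectiveParams",
    "NegativeConcentrationWarning",
    "rho_from_concentration",
    "contrast_from_concentration",
    "alpha_biot",
    "rho_from_contrast",
    "biot_mix",
    "lorentz_lorenz_mix",
    "wiener_mix",
    "mass_from_volume_weights",
    "effective_params",
    "binary_effective_theta",
    "binary_effective_alpha",
    "decoupling_fraction",
    "alpha_wiener_dilute",
    "rho_from_contrast_generic",
]

MIXING_RULES = ("biot", "lorentz_lorenz", "wiener")


class NegativeConcentrationWarning(UserWarning):
    """A measured RI contrast implies a (slightly) negative concentration."""


@dataclass(frozen=True)
class ComponentSpec:
    """Distributional description of one solute constituent.

    The Biot RI increment and PSV are modelled as independent normals with
    the given means and standard deviations (sd 0 = exactly known, i.e. a
    delta distribution); this is the parametrisation consumed by the
    uncertainty-propagation and Monte-Carlo modules.
    """

    name: str
    alpha: float
    theta: float
    d_alpha: float = 0.0
    d_theta: float = 0.0

    def __post_init__(self):
        if not self.theta > 0:
            raise ValueError(f"{self.name}: PSV must be positive")
        if self.d_alpha < 0 or self.d_theta < 0:
            raise ValueError(f"{self.name}: standard deviations must be >= 0")
        if self.d_theta >= self.theta / 5:
            raise ValueError(
                f"{self.name}: d_theta must be well below theta for the normal "
                "PSV model to stay physical"
            )

    @classmethod
    def from_material(cls, material: Material, solvent: Solvent = WATER):
        alpha, d_alpha = material.biot_increment(solvent)
        return cls(material.name, alpha, material.theta, d_alpha, material.dtheta)


@dataclass
class EffectiveParams:
    """Effective RI increment and PSV of a composite solute (mL/g)."""

    alpha_eff: float
    theta_eff: float
    d_alpha_eff: float = 0.0
    d_theta_eff: float = 0.0

    def __post_init__(self):
        if not self.theta_eff > 0:
            raise ValueError("effective PSV must be positive")
        if self.d_alpha_eff < 0 or self.d_theta_eff < 0:
            raise ValueError("standard deviations must be >= 0")


def _check_fractions(x, name="volume fractions"):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"{name} must be non-negative")
    if abs(x.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {x.sum()!r})")
    return x


@dataclass
class SoluteComposition:
    """A composite solute: materials with relative volume fractions x_j.

    The weights are relative volume fractions within the solute (the share
    of solute voxelinos of each constituent), not fractions of the total
    sample volume.
    """

    components: list[tuple[Material, float]]
    solvent: Solvent = WATER

    def __post_init__(self):
        if not self.components:
            raise ValueError("composition needs at least one component")
        _check_fractions([x for _, x in self.components], "relative volume fractions")

    @property
    def x(self) -> np.ndarray:
        return np.array([x for _, x in self.components])

    @property
    def thetas(self) -> np.ndarray:
        return np.array([m.theta for m, _ in self.components])

    @property
    def refractions(self) -> np.ndarray:
        return np.array([m.R for m, _ in self.components])

    @property
    def alphas(self) -> np.ndarray:
        """Biot increments of the components in the composition's solvent."""
        return np.array([m.biot_increment(self.solvent)[0] for m, _ in self.components])

    def mass_fractions(self) -> np.ndarray:
        return mass_from_volume_weights(self.x, self.thetas)

    def effective(self) -> EffectiveParams:
        """Mass-averaged effective (alpha_eff, theta_eff); means only."""
        y = self.mass_fractions()
        alpha_eff, theta_eff = effective_params(y, self.alphas, self.thetas)
        return EffectiveParams(alpha_eff, theta_eff)

    def effective_refraction(self) -> float:
        """Mass-averaged refraction per gram of the solute (mL/g)."""
        return float(self.mass_fractions() @ self.refractions)


def rho_from_concentration(c2, theta, rho1):
    """Solution mass density (g/mL) at solute concentration c2 (g/mL)."""
    c2 = np.asarray(c2, dtype=float)
    if np.any(c2 < 0):
        raise ValueError("concentration must be non-negative")
    if np.any(c2 * theta > 1.0 + 1e-12):
        raise ValueError(
            "c2*theta > 1: solute volume exceeds sample volume under additivity"
        )
    out = rho1 * (1.0 - c2 * theta) + c2
    return out.item() if out.ndim == 0 else out


def contrast_from_concentration(c2, alpha):
    """RI contrast delta_n = alpha * c2 of a solution (Biot rule)."""
    c2 = np.asarray(c2, dtype=float)
    if np.any(c2 < 0):
        raise ValueError("concentration must be non-negative")
    out = alpha * c2
    return out.item() if out.ndim == 0 else out


def alpha_biot(theta, n2, n1=WATER.n1):
    """Biot RI increment alpha = theta * (n2 - n1) in mL/g."""
    if not theta > 0:
        raise ValueError("PSV must be positive")
    return theta * (n2 - n1)


def rho_from_contrast(dn, alpha, theta, rho1):
    """Mass density (g/mL) from RI contrast via the affine Biot relation.

    Negative contrasts (possible through measurement noise) produce a
    :class:`NegativeConcentrationWarning` but are still evaluated, keeping
    pipelines over noisy tomograms total.
    """
    if alpha == 0:
        raise ValueError("alpha = 0: density and RI are decoupled, model degenerate")
    dn = np.asarray(dn, dtype=float)
    c2 = dn / alpha
    if np.any(c2 < 0):
        warnings.warn(
            "RI contrast implies negative concentration; extrapolating the "
            "affine relation",
            NegativeConcentrationWarning,
            stacklevel=2,
        )
    if np.any(c2 * theta > 1.0 + 1e-12):
        raise ValueError("implied solute volume exceeds sample volume")
    out = c2 + rho1 * (1.0 - theta * c2)
    return out.item() if out.ndim == 0 else out


def biot_mix(phis, ns):
    """Volume-fraction-weighted arithmetic mean of component RIs."""
    phis = _check_fractions(phis)
    ns = np.asarray(ns, dtype=float)
    if phis.shape != ns.shape:
        raise ValueError("phis and ns must have the same length")
    return float(phis @ ns)


def lorentz_lorenz_mix(phis, ns):
    """Lorentz-Lorenz mixing: volume-average of (n^2-1)/(n^2+2)."""
    phis = _check_fractions(phis)
    ns = np.asarray(ns, dtype=float)
    f = float(phis @ lorentz_lorenz_factor(ns))
    return float(np.sqrt((1.0 + 2.0 * f) / (1.0 - f)))


def wiener_mix(phi2, n2, n1):
    """Wiener effective-medium rule for a solute fraction phi2 in a solvent."""
    if not 0 <= phi2 <= 1:
        raise ValueError("phi2 must lie in [0, 1]")
    rhs = phi2 * (n2 * n2 - n1 * n1) / (n2 * n2 + 2.0 * n1 * n1)
    # solve (n^2 - n1^2)/(n^2 + 2 n1^2) = rhs for n
    n_sq = n1 * n1 * (1.0 + 2.0 * rhs) / (1.0 - rhs)
    return float(np.sqrt(n_sq))


def mass_from_volume_weights(x, thetas):
    """Mass fractions y_j from relative volume fractions x_j and PSVs.

    Equal-volume voxelinos of constituent j each carry mass v0/theta_j, so
    y_j is proportional to x_j/theta_j.
    """
    x = _check_fractions(x)
    thetas = np.asarray(thetas, dtype=float)
    if np.any(thetas <= 0):
        raise ValueError("PSVs must be positive")
    w = x / thetas
    return w / w.sum()


def effective_params(y, alphas, thetas):
    """Mass-averaged effective parameters (alpha_eff, theta_eff)."""
    y = _check_fractions(y, "mass fractions")
    alphas = np.asarray(alphas, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    return float(y @ alphas), float(y @ thetas)


def binary_effective_theta(x_lip, theta_a, theta_b):
    """Effective PSV of a binary solute at lipid volume fraction x_lip.

    Mass averaging with equal-volume voxelinos makes theta_eff the
    volume-weighted harmonic mean; component b is the lipid.
    """
    x_lip = np.asarray(x_lip, dtype=float)
    if np.any((x_lip < 0) | (x_lip > 1)):
        raise ValueError("x_lip must lie in [0, 1]")
    out = 1.0 / (x_lip / theta_b + (1.0 - x_lip) / theta_a)
    return out.item() if out.ndim == 0 else out


def binary_effective_alpha(x_lip, comp_a, comp_b):
    """Effective RI increment of a binary solute; comp = (alpha, theta)."""
    alpha_a, theta_a = comp_a
    alpha_b, theta_b = comp_b
    x_lip = np.asarray(x_lip, dtype=float)
    te = binary_effective_theta(x_lip, theta_a, theta_b)
    out = te * (x_lip * alpha_b / theta_b + (1.0 - x_lip) * alpha_a / theta_a)
    return out if np.ndim(out) else float(out)


def decoupling_fraction(theta_p, theta_lip, rho1):
    """Lipid volume fraction x* at which density decouples from RI.

    Solves theta_eff(x*) = 1/rho1 in closed form; at that composition the
    slope d(rho)/d(delta_n) vanishes for every solvent fraction.
    """
    target = 1.0 / rho1
    lo, hi = sorted((theta_p, theta_lip))
    if not (lo <= target <= hi):
        raise ValueError(
            "composition cannot decouple: 1/rho1 is outside the PSV range "
            f"[{lo}, {hi}]"
        )
    # 1/theta_eff = x/theta_lip + (1-x)/theta_p = rho1
    denom = 1.0 / theta_lip - 1.0 / theta_p
    if denom == 0:
        raise ValueError("equal PSVs: theta_eff is independent of composition")
    return float((rho1 - 1.0 / theta_p) / denom)


def alpha_wiener_dilute(R, theta, n1=WATER.n1):
    """RI increment in the dilute limit of the Wiener mixing rule (mL/g).

    The solute RI ``n2`` follows from (R, rho=1/theta) via Lorentz-Lorenz;
    the increment is (3/2) * theta * n1 * (n2^2-n1^2)/(n2^2+2*n1^2), the
    c2 -> 0 derivative of the full Wiener rule.
    """
    n2 = ri_from_material(R, 1.0 / theta)
    return float(
        1.5 * theta * n1 * (n2 * n2 - n1 * n1) / (n2 * n2 + 2.0 * n1 * n1)
    )


def _contrast_of_concentration(rule, c2, composition: SoluteComposition):
    """delta_n(c2) for a mixing rule, composition reduced to effective solute."""
    solv = composition.solvent
    eff = composition.effective()
    phi2 = c2 * eff.theta_eff
    if rule == "biot":
        n2 = solv.n1 + eff.alpha_eff / eff.theta_eff
        return biot_mix([1.0 - phi2, phi2], [solv.n1, n2]) - solv.n1
    R_eff = composition.effective_refraction()
    n2 = float(ri_from_material(R_eff, 1.0 / eff.theta_eff))
    if rule == "lorentz_lorenz":
        return lorentz_lorenz_mix([1.0 - phi2, phi2], [solv.n1, n2]) - solv.n1
    if rule == "wiener":
        return wiener_mix(phi2, n2, solv.n1) - solv.n1
    raise ValueError(f"unknown mixing rule {rule!r}; choose from {MIXING_RULES}")


def rho_from_contrast_generic(dn, rule, composition: SoluteComposition, solvent=None):
    """Mass density from RI contrast under an arbitrary mixing rule.

    Numerically inverts the rule's monotone n(c2) on c2 in [0, 1/theta_eff]
    (bracketed root-finding, 1e-12 tolerance in c2) and substitutes the
    concentration into the volume-additive density relation.  For
    ``rule="biot"`` this agrees with :func:`rho_from_contrast` to 1e-10.
    """
    if solvent is not None and solvent != composition.solvent:
        composition = SoluteComposition(composition.components, solvent)
    solv = composition.solvent
    eff = composition.effective()
    c_max = 1.0 / eff.theta_eff
    dn_arr = np.atleast_1d(np.asarray(dn, dtype=float))
    dn_max = _contrast_of_concentration(rule, c_max, composition)
    out = np.empty_like(dn_arr)
    for i, d in enumerate(dn_arr):
        if d < -1e-12 or d > dn_max + 1e-12:
            raise ValueError(
                f"contrast {d} outside the attainable range [0, {dn_max:.6g}] "
                f"for rule {rule!r}"
            )
        c2 = brentq(
            lambda c: _contrast_of_concentration(rule, c, composition) - d,
            0.0,
            c_max,
            xtol=1e-12,
        )
        out[i] = rho_from_concentration(c2, eff.theta_eff, solv.rho1)
    return out[0] if np.ndim(dn) == 0 else out
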