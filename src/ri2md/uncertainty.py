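"""Closed-form Gaussian propagation of uncertainty for the mixture model.

For a binary solute (component a = protein-like, component b = lipid-like)
dispersed in a solvent, the per-voxel effective parameters, solvent volume
fraction, RI and mass density all fluctuate.  This module provides the
closed-form standard deviations:

* effective parameters: a mixture-distribution spread reduced by 1/sqrt(Ns)
  (central-limit behaviour over the Ns solute voxelinos of a voxel) plus a
  composition term driven by voxel-to-voxel lipid-fraction fluctuations,
* solvent volume fraction: a counting term decaying as 1/sqrt(N0) plus a
  plateau from solute-mass and composition inhomogeneity,
* RI and density: Gaussian propagation through n = n1 + (1-phi1)*
  alpha_eff/theta_eff and the volume-additive density relation, neglecting
  correlations between the propagated quantities.

Every closed form here is validated against the per-voxelino Monte-Carlo
simulator (voxel_mc), which remains the authority where the independence
assumptions bite; see the methods note for the regimes where the neglected
correlations matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .materials import Solvent, WATER
from .mixture import ComponentSpec, binary_effective_alpha, binary_effective_theta

__all__ = [
    "InhomogeneityParams",
    "PropagatedUncertainty",
    "combine_uncertainties",
    "mixture_spread",
    "delta_eff_single",
    "binary_partials",
    "mean_effective",
    "delta_eff_total",
    "delta_phi1",
    "delta_n",
    "delta_rho",
    "propagate",
]

NS_MODELS = ("binomial", "mass_fluctuation", "fixed")


@dataclass
class InhomogeneityParams:
    """Voxel discretisation and inhomogeneity parameters.

    x_lip is the relative lipid volume fraction of the solute; d_x_lip its
    voxel-to-voxel SD; d_ms_rel the relative SD of the solute mass per voxel;
    N0 the number of voxelinos per voxel.  ns_model picks how the solute
    voxelino count fluctuates: 'binomial' (equilibrium occupancy),
    'mass_fluctuation' (solute mass and composition modulate the solute
    volume) or 'fixed' (deterministic count).
    """

    phi1_mean: float
    x_lip_mean: float = 0.0
    d_x_lip: float = 0.0
    d_ms_rel: float = 0.0
    N0: int = 1000
    ns_model: str = "mass_fluctuation"

    def __post_init__(self):
        if not 0 <= self.phi1_mean < 1:
            raise ValueError("phi1_mean must lie in [0, 1)")
        if not 0 <= self.x_lip_mean <= 1:
            raise ValueError("x_lip_mean must lie in [0, 1]")
        if self.d_x_lip < 0 or self.d_ms_rel < 0:
            raise ValueError("spread parameters must be >= 0")
        if self.N0 < 1:
            raise ValueError("N0 must be >= 1")
        if self.ns_model not in NS_MODELS:
            raise ValueError(f"ns_model must be one of {NS_MODELS}")
        if self.N0 * (1.0 - self.phi1_mean) < 1:
            raise ValueError("mean number of solute voxelinos N0*(1-phi1) must be >= 1")

    @property
    def n_solute(self) -> float:
        """Mean number of solute voxelinos per voxel."""
        return self.N0 * (1.0 - self.phi1_mean)


@dataclass
class PropagatedUncertainty:
    """All propagated standard deviations with per-channel breakdowns.

    Each total equals the root sum of squares of its ``components`` entry.
    """

    d_theta_eff: float
    d_alpha_eff: float
    d_phi1: float
    d_n: float
    d_rho: float
    components: dict[str, dict[str, float]] = field(default_factory=dict)


def combine_uncertainties(sys, stat):
    """Total uncertainty sqrt(sys^2 + stat^2) of systematic and statistical parts."""
    sys = np.asarray(sys, dtype=float)
    stat = np.asarray(stat, dtype=float)
    if np.any(sys < 0) or np.any(stat < 0):
        raise ValueError("uncertainty components must be >= 0")
    out = np.hypot(sys, stat)
    return out.item() if out.ndim == 0 else out


def mixture_spread(components, x):
    """Mean and SD of a weighted mixture of univariate distributions.

    ``components`` is a list of (mean, sd); ``x`` the mixture weights.
    Standard two-moment formula: var = sum x_j (sd_j^2 + mu_j^2) - mean^2.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must be non-negative and sum to 1")
    mus = np.array([m for m, _ in components], dtype=float)
    sds = np.array([s for _, s in components], dtype=float)
    if np.any(sds < 0):
        raise ValueError("component sds must be >= 0")
    mean = float(x @ mus)
    var = float(x @ (sds**2 + mus**2)) - mean**2
    return mean, math.sqrt(max(var, 0.0))


def delta_eff_single(sd0, Ns):
    """Central-limit reduction sd0/sqrt(Ns) of a per-voxelino spread."""
    if Ns < 1:
        raise ValueError("Ns must be >= 1")
    return sd0 / math.sqrt(Ns)


def mean_effective(x_lip, comp_a: ComponentSpec, comp_b: ComponentSpec):
    """Mean effective (alpha_eff, theta_eff) of the binary solute at x_lip."""
    theta_eff = float(binary_effective_theta(x_lip, comp_a.theta, comp_b.theta))
    alpha_eff = float(
        binary_effective_alpha(x_lip, (comp_a.alpha, comp_a.theta), (comp_b.alpha, comp_b.theta))
    )
    return alpha_eff, theta_eff


def binary_partials(x_lip, comp_a: ComponentSpec, comp_b: ComponentSpec):
    """(d theta_eff/d x_lip, d alpha_eff/d x_lip) of the binary solute.

    Closed forms from the harmonic-mean effective PSV; validated against
    central finite differences in the test-suite.
    """
    th_a, th_b = comp_a.theta, comp_b.theta
    al_a, al_b = comp_a.alpha, comp_b.alpha
    theta_eff = float(binary_effective_theta(x_lip, th_a, th_b))
    dtheta_dx = -(theta_eff**2) * (1.0 / th_b - 1.0 / th_a)
    ratio = x_lip * al_b / th_b + (1.0 - x_lip) * al_a / th_a
    dalpha_dx = dtheta_dx * ratio + theta_eff * (al_b / th_b - al_a / th_a)
    return float(dtheta_dx), float(dalpha_dx)


def _spreads0(params, comp_a, comp_b):
    """Per-voxelino mixture spreads (theta, alpha) at the mean composition."""
    x = np.array([1.0 - params.x_lip_mean, params.x_lip_mean])
    _, s_theta = mixture_spread([(comp_a.theta, comp_a.d_theta), (comp_b.theta, comp_b.d_theta)], x)
    _, s_alpha = mixture_spread([(comp_a.alpha, comp_a.d_alpha), (comp_b.alpha, comp_b.d_alpha)], x)
    return s_theta, s_alpha


def delta_eff_total(params: InhomogeneityParams, comp_a: ComponentSpec, comp_b: ComponentSpec):
    """(d_theta_eff, d_alpha_eff): mixture spread over Ns plus composition term."""
    s_theta0, s_alpha0 = _spreads0(params, comp_a, comp_b)
    ns = params.n_solute
    dth_dx, dal_dx = binary_partials(params.x_lip_mean, comp_a, comp_b)
    d_theta = math.hypot(delta_eff_single(s_theta0, ns), dth_dx * params.d_x_lip)
    d_alpha = math.hypot(delta_eff_single(s_alpha0, ns), dal_dx * params.d_x_lip)
    return d_theta, d_alpha


def delta_phi1(params: InhomogeneityParams, comp_a: ComponentSpec, comp_b: ComponentSpec):
    """SD of the solvent volume fraction, per the chosen solute-count model.

    'fixed' has no count fluctuation; 'binomial' only the counting term;
    'mass_fluctuation' adds the solute-mass and composition plateau terms
    that persist for N0 -> infinity.
    """
    if params.ns_model == "fixed":
        return 0.0
    phi1 = params.phi1_mean
    s_theta0, _ = _spreads0(params, comp_a, comp_b)
    _, theta_eff = mean_effective(params.x_lip_mean, comp_a, comp_b)
    counting = math.sqrt(
        (phi1 + (s_theta0 / theta_eff) ** 2) / (params.N0 * (1.0 - phi1))
    )
    if params.ns_model == "binomial":
        return (1.0 - phi1) * counting
    dth_dx, _ = binary_partials(params.x_lip_mean, comp_a, comp_b)
    plateau = math.hypot(params.d_ms_rel, dth_dx * params.d_x_lip / theta_eff)
    return (1.0 - phi1) * math.hypot(counting, plateau)


def _n_partials(params, comp_a, comp_b, solvent):
    alpha_eff, theta_eff = mean_effective(params.x_lip_mean, comp_a, comp_b)
    phi2 = 1.0 - params.phi1_mean
    dn_dphi1 = -alpha_eff / theta_eff
    dn_dalpha = phi2 / theta_eff
    dn_dtheta = -phi2 * alpha_eff / theta_eff**2
    return dn_dphi1, dn_dalpha, dn_dtheta


def delta_n(params: InhomogeneityParams, comp_a: ComponentSpec, comp_b: ComponentSpec,
            solvent: Solvent = WATER):
    """SD of the voxel RI by Gaussian propagation (correlations neglected)."""
    return propagate(params, comp_a, comp_b, solvent).d_n


def delta_rho(params: InhomogeneityParams, comp_a: ComponentSpec, comp_b: ComponentSpec,
              solvent: Solvent = WATER):
    """SD of the voxel mass density by Gaussian propagation."""
    return propagate(params, comp_a, comp_b, solvent).d_rho


def propagate(params: InhomogeneityParams, comp_a: ComponentSpec, comp_b: ComponentSpec,
              solvent: Solvent = WATER) -> PropagatedUncertainty:
    """All propagated SDs with per-channel variance breakdowns."""
    s_theta0, s_alpha0 = _spreads0(params, comp_a, comp_b)
    ns = params.n_solute
    dth_dx, dal_dx = binary_partials(params.x_lip_mean, comp_a, comp_b)
    comp_theta = {
        "voxelino_spread": delta_eff_single(s_theta0, ns),
        "composition": abs(dth_dx) * params.d_x_lip,
    }
    comp_alpha = {
        "voxelino_spread": delta_eff_single(s_alpha0, ns),
        "composition": abs(dal_dx) * params.d_x_lip,
    }
    d_theta_eff = math.hypot(*comp_theta.values())
    d_alpha_eff = math.hypot(*comp_alpha.values())

    _, theta_eff = mean_effective(params.x_lip_mean, comp_a, comp_b)
    alpha_eff, _ = mean_effective(params.x_lip_mean, comp_a, comp_b)
    phi1 = params.phi1_mean
    if params.ns_model == "fixed":
        comp_phi1 = {"counting": 0.0, "solute_mass": 0.0, "composition": 0.0}
    else:
        counting = (1.0 - phi1) * math.sqrt(
            (phi1 + (s_theta0 / theta_eff) ** 2) / (params.N0 * (1.0 - phi1))
        )
        comp_phi1 = {"counting": counting, "solute_mass": 0.0, "composition": 0.0}
        if params.ns_model == "mass_fluctuation":
            comp_phi1["solute_mass"] = (1.0 - phi1) * params.d_ms_rel
            comp_phi1["composition"] = (1.0 - phi1) * abs(dth_dx) * params.d_x_lip / theta_eff
    d_phi1 = math.sqrt(sum(v * v for v in comp_phi1.values()))

    dn_dphi1, dn_dalpha, dn_dtheta = _n_partials(params, comp_a, comp_b, solvent)
    comp_n = {
        "phi1": abs(dn_dphi1) * d_phi1,
        "alpha_eff": abs(dn_dalpha) * d_alpha_eff,
        "theta_eff": abs(dn_dtheta) * d_theta_eff,
    }
    d_n = math.sqrt(sum(v * v for v in comp_n.values()))

    comp_rho = {
        "phi1": abs((theta_eff * solvent.rho1 - 1.0) / theta_eff) * d_phi1,
        "theta_eff": abs((phi1 - 1.0) / theta_eff**2) * d_theta_eff,
    }
    d_rho = math.sqrt(sum(v * v for v in comp_rho.values()))

    return PropagatedUncertainty(
        d_theta_eff=d_theta_eff,
        d_alpha_eff=d_alpha_eff,
        d_phi1=d_phi1,
        d_n=d_n,
        d_rho=d_rho,
        components={
            "d_theta_eff": comp_theta,
            "d_alpha_eff": comp_alpha,
            "d_phi1": comp_phi1,
            "d_n": comp_n,
            "d_rho": comp_rho,
        },
    )
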