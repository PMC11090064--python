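"""Concentration-series fitting and dilution/pycnometry bookkeeping.

The experimental side of the model: a dilution series of a complex solute
is measured by refractometry (RI contrast delta_n versus concentration) and
pycnometry (density versus concentration).  Weighted least squares of

    delta_n = alpha * c        (through the origin)
    rho = rho1 + (1 - rho1*theta) * c     (intercept fixed at rho1)

yield the effective RI increment and PSV with propagated uncertainties.
Fitted parameters can then be confronted with composition-based predictions
under different RI mixing rules.  A synthetic-series generator makes the
whole module testable without laboratory data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .materials import Solvent, WATER, ri_from_material
from .mixture import (
    SoluteComposition,
    contrast_from_concentration,
    lorentz_lorenz_factor,
    rho_from_concentration,
)

__all__ = [
    "ConcentrationSeries",
    "LinearFit",
    "FitResult",
    "pycnometer_volume",
    "density_from_pycnometry",
    "dilution_concentration",
    "fit_alpha",
    "fit_theta",
    "fit_series",
    "compare_mixing_rules",
    "generate_synthetic_series",
]


def pycnometer_volume(m_w, m_pyc, rho_w=WATER.rho1):
    """Pycnometer volume (mL) from the water-filled and empty masses (g)."""
    if rho_w <= 0:
        raise ValueError("water density must be positive")
    if m_w <= m_pyc:
        raise ValueError("filled mass must exceed the empty pycnometer mass")
    return (m_w - m_pyc) / rho_w


def density_from_pycnometry(m, m_pyc, v_pyc):
    """Sample density (g/mL) from the filled mass and calibrated volume."""
    if v_pyc <= 0:
        raise ValueError("pycnometer volume must be positive")
    if m < m_pyc:
        raise ValueError("filled mass cannot be below the empty mass")
    return (m - m_pyc) / v_pyc


def dilution_concentration(m_k, m_wk, y1_k, rho_k):
    """Solute concentration (g/mL) of a diluted stock sample.

    ``m_k`` grams of stock (water mass fraction ``y1_k``) are diluted with
    ``m_wk`` grams of water; ``rho_k`` is the measured density of the
    dilution.  The solute mass fraction is y_s = m_k*(1-y1_k)/(m_k+m_wk)
    and c_s = y_s * rho_k.
    """
    if m_k <= 0 or m_wk < 0:
        raise ValueError("sample mass must be > 0 and added water >= 0")
    if not 0 <= y1_k <= 1:
        raise ValueError("water mass fraction must lie in [0, 1]")
    y_s = m_k * (1.0 - y1_k) / (m_k + m_wk)
    return y_s * rho_k


@dataclass
class ConcentrationSeries:
    """A dilution series of (c, delta_n +- sd, rho +- sd) points."""

    c: np.ndarray
    dn: np.ndarray | None = None
    dn_sd: np.ndarray | None = None
    rho: np.ndarray | None = None
    rho_sd: np.ndarray | None = None
    solvent: Solvent = field(default_factory=lambda: WATER)
    n_reps: int = 1

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=float)
        if np.any(self.c < 0):
            raise ValueError("concentrations must be non-negative")
        for name in ("dn", "dn_sd", "rho", "rho_sd"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if val.shape != self.c.shape:
                    raise ValueError(f"{name} must match the concentration grid")
                if name.endswith("_sd") and np.any(val < 0):
                    raise ValueError(f"{name} must be >= 0")
                setattr(self, name, val)

    @classmethod
    def from_csv(cls, path, solvent: Solvent = WATER) -> "ConcentrationSeries":
        """Read a series from CSV with columns c, dn[, dn_sd], rho[, rho_sd]."""
        df = pd.read_csv(path, comment="#")
        if "c" not in df.columns:
            raise ValueError(f"{path}: a 'c' column (g/mL) is required")
        get = lambda col: df[col].to_numpy(dtype=float) if col in df.columns else None
        return cls(
            c=df["c"].to_numpy(dtype=float),
            dn=get("dn"),
            dn_sd=get("dn_sd"),
            rho=get("rho"),
            rho_sd=get("rho_sd"),
            solvent=solvent,
        )

    def to_dataframe(self) -> pd.DataFrame:
        data = {"c": self.c}
        for name in ("dn", "dn_sd", "rho", "rho_sd"):
            if getattr(self, name) is not None:
                data[name] = getattr(self, name)
        return pd.DataFrame(data)

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class LinearFit:
    """One fitted parameter with its residuals and goodness statistic."""

    value: float
    sd: float
    residuals: np.ndarray
    chi2: float
    dof: int


@dataclass
class FitResult:
    """Joint (alpha, theta) fit of a concentration series."""

    alpha: LinearFit | None
    theta: LinearFit | None
    solvent: Solvent

    @property
    def alpha_hat(self):
        return self.alpha.value if self.alpha else None

    @property
    def theta_hat(self):
        return self.theta.value if self.theta else None

    def to_dict(self) -> dict:
        out = {}
        for name, f in (("alpha", self.alpha), ("theta", self.theta)):
            if f is not None:
                out[name] = {
                    "value": f.value,
                    "sd": f.sd,
                    "chi2": f.chi2,
                    "dof": f.dof,
                    "residuals": f.residuals.tolist(),
                }
        return out


def _weighted_slope(x, y, sd):
    """Weighted LS slope of y = b*x with its standard deviation."""
    if np.all(x == 0):
        raise ValueError("all concentrations are zero; slope is undefined")
    if x.size < 2:
        raise ValueError("need at least two points to estimate a slope and its sd")
    known_sd = sd is not None and np.all(sd > 0)
    w = 1.0 / sd**2 if known_sd else np.ones_like(x)
    sxx = float(w @ (x * x))
    b = float(w @ (x * y)) / sxx
    resid = y - b * x
    chi2 = float(w @ resid**2)
    dof = x.size - 1
    if known_sd:
        sd_b = math.sqrt(1.0 / sxx)
    else:
        # scale from residual scatter when no per-point sds are given
        sd_b = math.sqrt(max(chi2, 0.0) / dof / sxx) if dof > 0 else float("nan")
    return b, sd_b, resid, chi2, dof


def fit_alpha(series: ConcentrationSeries) -> LinearFit:
    """Weighted least-squares RI increment: delta_n = alpha*c through the origin."""
    if series.dn is None:
        raise ValueError("series has no RI-contrast data")
    b, sd, resid, chi2, dof = _weighted_slope(series.c, series.dn, series.dn_sd)
    return LinearFit(b, sd, resid, chi2, dof)


def fit_theta(series: ConcentrationSeries, rho1=None, fix_intercept=True) -> LinearFit:
    """Weighted least-squares PSV from rho = rho1 + (1 - rho1*theta)*c.

    The intercept is fixed at the (precisely known) solvent density by
    default; ``fix_intercept=False`` frees it as a diagnostic, in which case
    the reported parameter is still the PSV from the fitted slope.
    """
    if series.rho is None:
        raise ValueError("series has no density data")
    rho1 = series.solvent.rho1 if rho1 is None else float(rho1)
    if fix_intercept:
        b, sd_b, resid, chi2, dof = _weighted_slope(series.c, series.rho - rho1, series.rho_sd)
    else:
        x, y = series.c, series.rho
        known_sd = series.rho_sd is not None and np.all(series.rho_sd > 0)
        w = 1.0 / series.rho_sd**2 if known_sd else np.ones_like(x)
        if x.size < 3:
            raise ValueError("free-intercept fit needs at least three points")
        W = float(w.sum())
        xbar = float(w @ x) / W
        ybar = float(w @ y) / W
        sxx = float(w @ (x - xbar) ** 2)
        b = float(w @ ((x - xbar) * (y - ybar))) / sxx
        a = ybar - b * xbar
        resid = y - a - b * x
        chi2 = float(w @ resid**2)
        dof = x.size - 2
        sd_b = math.sqrt(1.0 / sxx) if known_sd else math.sqrt(chi2 / dof / sxx)
    theta = (1.0 - b) / rho1
    return LinearFit(theta, sd_b / rho1, resid, chi2, dof)


def fit_series(series: ConcentrationSeries, rho1=None, fix_intercept=True) -> FitResult:
    """Fit both the RI increment and the PSV of a series (where data exist)."""
    alpha = fit_alpha(series) if series.dn is not None else None
    theta = fit_theta(series, rho1, fix_intercept) if series.rho is not None else None
    if alpha is None and theta is None:
        raise ValueError("series has neither RI-contrast nor density data")
    return FitResult(alpha, theta, series.solvent)


def _implied_solute_ri(rule, alpha, theta, n1):
    """Solute RI consistent with a fitted (alpha, theta) under a mixing rule."""
    if rule == "biot":
        return n1 + alpha / theta
    if rule == "wiener":
        f_w = 2.0 * alpha / (3.0 * n1 * theta)
        if not -0.5 < f_w < 1:
            raise ValueError("increment outside the Wiener-invertible range")
        return float(np.sqrt(n1 * n1 * (1.0 + 2.0 * f_w) / (1.0 - f_w)))
    if rule == "lorentz_lorenz":
        fp = 6.0 * n1 / (n1 * n1 + 2.0) ** 2
        f2 = float(lorentz_lorenz_factor(n1)) + alpha * fp / theta
        if not f2 < 1:
            raise ValueError("increment outside the Lorentz-Lorenz-invertible range")
        return float(np.sqrt((1.0 + 2.0 * f2) / (1.0 - f2)))
    raise ValueError(f"unknown mixing rule {rule!r}")


def compare_mixing_rules(fit: FitResult, composition: SoluteComposition,
                         solvent: Solvent | None = None) -> pd.DataFrame:
    """Rank mixing rules by how well they tie the fit to the composition.

    For each rule the fitted (alpha_hat, theta_hat) imply a solute RI; the
    chemical composition predicts one independently (Biot: from the
    effective increment; Lorentz-Lorenz/Wiener: from the mass-averaged
    refraction per gram).  Rules are ranked by the absolute discrepancy.
    Inversion failures are flagged per rule rather than fatal.
    """
    if fit.alpha is None or fit.theta is None:
        raise ValueError("mixing-rule comparison needs both alpha and theta fits")
    solvent = solvent or fit.solvent
    eff = composition.effective()
    n2_ll = float(
        ri_from_material(composition.effective_refraction(), 1.0 / eff.theta_eff)
    )
    predicted = {
        "biot": solvent.n1 + eff.alpha_eff / eff.theta_eff,
        "lorentz_lorenz": n2_ll,
        "wiener": n2_ll,
    }
    rows = []
    for rule, n2_pred in predicted.items():
        try:
            n2_imp = _implied_solute_ri(rule, fit.alpha.value, fit.theta.value, solvent.n1)
            rows.append(
                {"rule": rule, "n2_implied": n2_imp, "n2_predicted": n2_pred,
                 "discrepancy": abs(n2_imp - n2_pred), "error": ""}
            )
        except ValueError as exc:
            rows.append(
                {"rule": rule, "n2_implied": np.nan, "n2_predicted": n2_pred,
                 "discrepancy": np.inf, "error": str(exc)}
            )
    df = pd.DataFrame(rows).sort_values("discrepancy", ignore_index=True)
    return df


_DEFAULT_C_GRID = np.linspace(0.02, 0.16, 8)


def generate_synthetic_series(
    alpha,
    theta,
    rho1=WATER.rho1,
    c_grid=None,
    noise_dn=5e-4,
    noise_rho=1e-3,
    seed=0,
    solvent: Solvent | None = None,
) -> ConcentrationSeries:
    """Synthetic concentration series from the volume-additive Biot model.

    Emulates a refractometer/pycnometer dilution experiment: exact model
    values plus independent Gaussian noise with the stated per-point sds
    (defaults: 5e-4 on delta_n, 1e-3 g/mL on rho, typical of Abbe
    refractometry and ~5 mL pycnometry).  Reproducible given ``seed``.
    """
    if noise_dn < 0 or noise_rho < 0:
        raise ValueError("noise levels must be >= 0")
    c = np.asarray(_DEFAULT_C_GRID if c_grid is None else c_grid, dtype=float)
    solvent = solvent or Solvent(WATER.n1, rho1)
    rng = np.random.default_rng(seed)
    dn = contrast_from_concentration(c, alpha)
    rho = rho_from_concentration(c, theta, rho1)
    if noise_dn > 0:
        dn = dn + rng.normal(0.0, noise_dn, c.shape)
    if noise_rho > 0:
        rho = rho + rng.normal(0.0, noise_rho, c.shape)
    return ConcentrationSeries(
        c=c,
        dn=dn,
        dn_sd=np.full(c.shape, noise_dn),
        rho=rho,
        rho_sd=np.full(c.shape, noise_rho),
        solvent=solvent,
    )
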