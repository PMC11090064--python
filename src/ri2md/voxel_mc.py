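"""Voxel/voxelino Monte-Carlo simulator of correlative (rho, delta_n) clouds.

The sample volume is discretised into Nv voxels, each subdivided into N0
equal "voxelinos"; a voxelino holds exactly one constituent (solvent or one
solute species).  Per voxel the simulator draws

1. a solvent volume fraction phi1 from a truncated normal on [0, 1],
2. relative solute weights (binary case: the lipid fraction x_lip, also
   truncated-normal),
3. the solute voxelino count Ns (binomial occupancy, a solute-mass /
   composition-modulated count, or a fixed count),
4. per-voxelino (alpha_i, theta_i) from the component distributions,

and assembles the voxel density from mass conservation and the voxel RI
from the Biot rule over voxelinos (equivalently n1 + (1-phi1)*
alpha_eff/theta_eff) or, optionally, the Lorentz-Lorenz rule.

For large per-voxel counts explicit per-voxelino draws are replaced by
sampling the per-voxel sums (sum 1/theta_i, sum alpha_i/theta_i, sum of the
Lorentz-Lorenz fractions) from their normal approximation with moments
computed by Gauss-Hermite quadrature — distributionally equivalent by the
central limit theorem; the exact path is retained and serves as the oracle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .materials import Solvent, WATER, lorentz_lorenz_factor
from .mixture import ComponentSpec

__all__ = [
    "MixtureSpec",
    "VoxelEnsemble",
    "MarginalSummary",
    "sample_truncated_normal",
    "sample_voxel",
    "simulate",
    "marginal_summary",
    "confidence_contours",
]

NS_MODELS = ("binomial", "mass_fluctuation", "fixed")
#: per-component count above which the CLT fast path is used by default
_CLT_THRESHOLD = 10_000


def sample_truncated_normal(mu, sigma, lo=0.0, hi=1.0, size=None, rng=None):
    """Samples of a normal(mu, sigma) truncated to [lo, hi] via inverse CDF.

    sigma = 0 returns the (clipped) constant mu.  If the interval carries
    less than 1e-12 of the untruncated probability mass the parameters are
    rejected as nonphysical.
    """
    if lo >= hi:
        raise ValueError("lo must be < hi")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if sigma == 0:
        val = min(max(mu, lo), hi)
        return val if size is None else np.full(size, val)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    if stats.norm.cdf(b) - stats.norm.cdf(a) < 1e-12:
        raise ValueError(
            f"truncated normal T({mu}, {sigma}) has negligible mass in [{lo}, {hi}]"
        )
    u = rng.random(size)
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


@dataclass
class MixtureSpec:
    """Full description of a simulated sample.

    ``weights`` are the mean relative volume fractions of the solute
    components; in a binary system ``x_sd`` makes the weight of the *last*
    component (the lipid, by convention) fluctuate voxel-to-voxel as a
    truncated normal.  ``phi1`` is (mean, sd) of the solvent fraction.
    """

    components: list[ComponentSpec]
    weights: list[float]
    phi1_mean: float
    phi1_sd: float = 0.0
    x_sd: float = 0.0
    N0: int = 1000
    ns_model: str = "binomial"
    d_ms_rel: float = 0.0
    rule: str = "biot"
    solvent: Solvent = field(default_factory=lambda: WATER)
    Nv: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not self.components:
            raise ValueError("need at least one solute component")
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.components) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must match components, be >= 0 and sum to 1")
        if self.x_sd < 0 or self.phi1_sd < 0 or self.d_ms_rel < 0:
            raise ValueError("spread parameters must be >= 0")
        if self.x_sd > 0 and len(self.components) != 2:
            raise ValueError("a fluctuating composition (x_sd > 0) requires a binary solute")
        if not 0 <= self.phi1_mean <= 1:
            raise ValueError("phi1_mean must lie in [0, 1]")
        if self.N0 < 1 or self.Nv < 1:
            raise ValueError("N0 and Nv must be >= 1")
        if self.ns_model not in NS_MODELS:
            raise ValueError(f"ns_model must be one of {NS_MODELS}")
        if self.rule not in ("biot", "lorentz_lorenz"):
            raise ValueError("rule must be 'biot' or 'lorentz_lorenz'")

    # -- serialisation ----------------------------------------------------
    def to_mapping(self) -> dict:
        return {
            "solvent": {"n1": self.solvent.n1, "rho1": self.solvent.rho1},
            "components": [asdict(c) for c in self.components],
            "weights": list(map(float, self.weights)),
            "phi1": {"mean": self.phi1_mean, "sd": self.phi1_sd},
            "x_sd": self.x_sd,
            "N0": self.N0,
            "Nv": self.Nv,
            "ns_model": self.ns_model,
            "d_ms_rel": self.d_ms_rel,
            "rule": self.rule,
            "seed": self.seed,
        }

    @classmethod
    def from_mapping(cls, m: dict) -> "MixtureSpec":
        solv = m.get("solvent", {})
        comps = []
        for c in m["components"]:
            c = dict(c)
            if "n" in c and "rho" in c:  # optical constants: convert
                from .materials import Material

                mat = Material.from_optical(
                    c.get("name", "component"), float(c["n"]), float(c["rho"]),
                    dn=float(c.get("dn", 0.0)), drho=float(c.get("drho", 0.0)),
                )
                comps.append(ComponentSpec.from_material(mat, Solvent(**solv) if solv else WATER))
            else:
                comps.append(
                    ComponentSpec(
                        name=str(c.get("name", f"component{len(comps)}")),
                        alpha=float(c["alpha"]),
                        theta=float(c["theta"]),
                        d_alpha=float(c.get("d_alpha", 0.0)),
                        d_theta=float(c.get("d_theta", 0.0)),
                    )
                )
        phi1 = m.get("phi1", {})
        return cls(
            components=comps,
            weights=[float(x) for x in m["weights"]],
            phi1_mean=float(phi1.get("mean", m.get("phi1_mean", 0.9))),
            phi1_sd=float(phi1.get("sd", m.get("phi1_sd", 0.0))),
            x_sd=float(m.get("x_sd", 0.0)),
            N0=int(m.get("N0", 1000)),
            ns_model=str(m.get("ns_model", "binomial")),
            d_ms_rel=float(m.get("d_ms_rel", 0.0)),
            rule=str(m.get("rule", "biot")),
            solvent=Solvent(float(solv.get("n1", WATER.n1)), float(solv.get("rho1", WATER.rho1))),
            Nv=int(m.get("Nv", 1000)),
            seed=int(m.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "MixtureSpec":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_mapping(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class VoxelEnsemble:
    """Paired per-voxel samples with their latent draws."""

    spec: MixtureSpec
    rho: np.ndarray
    n: np.ndarray
    dn: np.ndarray
    phi1: np.ndarray  # realised solvent fraction 1 - Ns/N0
    x: np.ndarray  # drawn weight of the last (lipid) component
    Ns: np.ndarray
    alpha_eff: np.ndarray  # realised per-voxel effective increments
    theta_eff: np.ndarray

    def __post_init__(self):
        nv = len(self.rho)
        for name in ("n", "dn", "phi1", "x", "Ns", "alpha_eff", "theta_eff"):
            if len(getattr(self, name)) != nv:
                raise ValueError(f"field {name} length mismatch")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rho": self.rho,
                "n": self.n,
                "dn": self.dn,
                "phi1": self.phi1,
                "x_lip": self.x,
                "Ns": self.Ns,
                "alpha_eff": self.alpha_eff,
                "theta_eff": self.theta_eff,
            }
        )

    def summary(self) -> dict:
        return {
            "rho": marginal_summary(self.rho).to_dict(),
            "n": marginal_summary(self.n).to_dict(),
            "dn": marginal_summary(self.dn).to_dict(),
        }


@dataclass
class MarginalSummary:
    """Median with central 68% and 95% intervals of a marginal sample."""

    median: float
    ci68: tuple[float, float]
    ci95: tuple[float, float]

    def __post_init__(self):
        if not (self.ci68[0] <= self.median <= self.ci68[1]):
            raise ValueError("median must lie inside the 68% interval")
        if not (self.ci95[0] <= self.ci68[0] and self.ci68[1] <= self.ci95[1]):
            raise ValueError("68% interval must nest inside the 95% interval")

    def to_dict(self) -> dict:
        return {"median": self.median, "ci68": list(self.ci68), "ci95": list(self.ci95)}


def marginal_summary(samples) -> MarginalSummary:
    """Median and central 68/95% quantile intervals of a sample."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 10:
        raise ValueError("need at least 10 samples for a marginal summary")
    qs = np.percentile(samples, [2.275, 15.865, 50.0, 84.135, 97.725])
    return MarginalSummary(
        median=float(qs[2]),
        ci68=(float(qs[1]), float(qs[3])),
        ci95=(float(qs[0]), float(qs[4])),
    )


# ----------------------------------------------------------------------
# per-component voxelino-sum moments (CLT fast path)


@lru_cache(maxsize=128)
def _component_moments(comp: ComponentSpec, n1: float, order: int = 40):
    """Mean vector and covariance of (1/theta, alpha/theta, LL fraction).

    Moments of the nonlinear transforms of the independent normals
    (alpha, theta) computed by 2-D Gauss-Hermite quadrature; degenerate
    (sd = 0) axes collapse to a single node.
    """
    nodes, w = np.polynomial.hermite_e.hermegauss(order)
    w = w / w.sum()
    th_nodes = comp.theta + comp.d_theta * nodes if comp.d_theta > 0 else np.array([comp.theta])
    th_w = w if comp.d_theta > 0 else np.array([1.0])
    al_nodes = comp.alpha + comp.d_alpha * nodes if comp.d_alpha > 0 else np.array([comp.alpha])
    al_w = w if comp.d_alpha > 0 else np.array([1.0])
    if np.any(th_nodes <= 0):
        keep = th_nodes > 0  # physically a truncated PSV; tail mass is negligible
        th_nodes, th_w = th_nodes[keep], th_w[keep] / th_w[keep].sum()
    TH, AL = np.meshgrid(th_nodes, al_nodes, indexing="ij")
    W = np.outer(th_w, al_w)
    g = np.stack(
        [1.0 / TH, AL / TH, lorentz_lorenz_factor(n1 + AL / TH)], axis=-1
    )  # (nt, na, 3)
    mean = np.einsum("ij,ijk->k", W, g)
    centred = g - mean
    cov = np.einsum("ij,ijk,ijl->kl", W, centred, centred)
    return mean, cov, np.linalg.cholesky(cov + 1e-30 * np.eye(3))


def _component_counts(Ns, weights, x_draw, rng):
    """Multinomial split of Ns solute voxelinos over components.

    ``x_draw`` (Nv,) overrides the last component's weight in the binary
    case; sequential conditional binomials keep everything vectorised.
    """
    nv = len(Ns)
    k = len(weights)
    probs = np.tile(np.asarray(weights, dtype=float), (nv, 1))
    if x_draw is not None:
        probs[:, -1] = x_draw
        probs[:, 0] = 1.0 - x_draw
    counts = np.zeros((nv, k), dtype=np.int64)
    remaining = Ns.astype(np.int64).copy()
    remaining_p = np.ones(nv)
    for j in range(k - 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(remaining_p > 0, probs[:, j] / remaining_p, 0.0)
        counts[:, j] = rng.binomial(remaining, np.clip(p, 0.0, 1.0))
        remaining -= counts[:, j]
        remaining_p -= probs[:, j]
    counts[:, -1] = remaining
    return counts


def _voxelino_sums_exact(counts, comps, n1, rng, need_ll):
    """Exact per-voxel sums of (1/theta, alpha/theta[, LL fraction])."""
    nv = counts.shape[0]
    s1 = np.zeros(nv)
    s2 = np.zeros(nv)
    s3 = np.zeros(nv) if need_ll else None
    for j, comp in enumerate(comps):
        tot = int(counts[:, j].sum())
        if tot == 0:
            continue
        idx = np.repeat(np.arange(nv), counts[:, j])
        theta = rng.normal(comp.theta, comp.d_theta, tot)
        for _ in range(100):
            bad = theta <= 1e-9
            if not bad.any():
                break
            theta[bad] = rng.normal(comp.theta, comp.d_theta, int(bad.sum()))
        else:
            raise RuntimeError(f"{comp.name}: could not draw a positive PSV in 100 attempts")
        alpha = rng.normal(comp.alpha, comp.d_alpha, tot)
        inv_t = 1.0 / theta
        s1 += np.bincount(idx, weights=inv_t, minlength=nv)
        s2 += np.bincount(idx, weights=alpha * inv_t, minlength=nv)
        if need_ll:
            s3 += np.bincount(
                idx, weights=lorentz_lorenz_factor(n1 + alpha * inv_t), minlength=nv
            )
    return s1, s2, s3


def _voxelino_sums_clt(counts, comps, n1, rng, need_ll):
    """CLT approximation: per-component sums drawn from multivariate normals."""
    nv = counts.shape[0]
    s = np.zeros((nv, 3))
    for j, comp in enumerate(comps):
        mean, _, chol = _component_moments(comp, n1)
        nj = counts[:, j].astype(float)[:, None]
        z = rng.standard_normal((nv, 3))
        s += nj * mean + np.sqrt(nj) * (z @ chol.T)
    s1, s2, s3 = s[:, 0], s[:, 1], s[:, 2]
    return s1, s2, (s3 if need_ll else None)


def simulate(spec: MixtureSpec, nv=None, seed=None, method="auto") -> VoxelEnsemble:
    """Simulate a voxel ensemble; bit-for-bit reproducible given (spec, seed).

    ``method``: 'exact' draws every voxelino, 'clt' samples the per-voxel
    sums from their normal approximation, 'auto' switches to 'clt' when the
    mean per-voxel solute count exceeds 10^4.
    """
    nv = spec.Nv if nv is None else int(nv)
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    solv = spec.solvent
    need_ll = spec.rule == "lorentz_lorenz"

    phi1_base = np.atleast_1d(
        sample_truncated_normal(spec.phi1_mean, spec.phi1_sd, 0.0, 1.0, nv, rng)
    )
    x_draw = None
    if spec.x_sd > 0:
        x_draw = np.atleast_1d(
            sample_truncated_normal(spec.weights[-1], spec.x_sd, 0.0, 1.0, nv, rng)
        )

    thetas = np.array([c.theta for c in spec.components])
    w_mean = np.asarray(spec.weights, dtype=float)
    theta_eff_mean = 1.0 / float(w_mean @ (1.0 / thetas))
    if spec.ns_model == "fixed":
        Ns = np.round(spec.N0 * (1.0 - phi1_base)).astype(np.int64)
    elif spec.ns_model == "binomial":
        Ns = rng.binomial(spec.N0, 1.0 - phi1_base)
    else:  # mass_fluctuation: solute mass and composition modulate the count
        gain = rng.normal(1.0, spec.d_ms_rel, nv) if spec.d_ms_rel > 0 else np.ones(nv)
        if x_draw is not None:
            w_vox = np.tile(w_mean, (nv, 1))
            w_vox[:, -1] = x_draw
            w_vox[:, 0] = 1.0 - x_draw
            theta_eff_x = 1.0 / (w_vox @ (1.0 / thetas))
        else:
            theta_eff_x = np.full(nv, theta_eff_mean)
        p = (1.0 - phi1_base) * gain * theta_eff_x / theta_eff_mean
        Ns = rng.binomial(spec.N0, np.clip(p, 0.0, 1.0))
    Ns = np.clip(Ns, 0, spec.N0)

    counts = _component_counts(Ns, w_mean, x_draw, rng)
    mean_count = float(Ns.mean())
    if method == "auto":
        method = "clt" if mean_count > _CLT_THRESHOLD else "exact"
    if method == "exact":
        s1, s2, s3 = _voxelino_sums_exact(counts, spec.components, solv.n1, rng, need_ll)
    elif method == "clt":
        s1, s2, s3 = _voxelino_sums_clt(counts, spec.components, solv.n1, rng, need_ll)
    else:
        raise ValueError("method must be 'auto', 'exact' or 'clt'")

    phi1_real = 1.0 - Ns / spec.N0
    c_s = s1 / spec.N0  # solute concentration: mass per voxel volume
    rho = c_s + solv.rho1 * phi1_real
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_eff = np.where(s1 > 0, Ns / np.where(s1 > 0, s1, 1.0), theta_eff_mean)
        alpha_eff = np.where(s1 > 0, s2 / np.where(s1 > 0, s1, 1.0), 0.0)
    if need_ll:
        f_vox = phi1_real * float(lorentz_lorenz_factor(solv.n1)) + s3 / spec.N0
        n = np.sqrt((1.0 + 2.0 * f_vox) / (1.0 - f_vox))
    else:
        n = solv.n1 + s2 / spec.N0
    dn = n - solv.n1

    x_real = counts[:, -1] / np.maximum(Ns, 1) if len(spec.components) > 1 else np.ones(nv)
    return VoxelEnsemble(
        spec=spec,
        rho=rho,
        n=n,
        dn=dn,
        phi1=phi1_real,
        x=(x_draw if x_draw is not None else x_real),
        Ns=Ns,
        alpha_eff=alpha_eff,
        theta_eff=theta_eff,
    )


def sample_voxel(spec: MixtureSpec, rng=None):
    """Draw a single voxel; returns (rho, n, latents dict).

    Equivalent to one row of :func:`simulate` with the exact per-voxelino
    path.
    """
    seed = rng if not isinstance(rng, np.random.Generator) else rng.integers(2**31)
    ens = simulate(spec, nv=1, seed=int(seed) if seed is not None else 0, method="exact")
    latents = {
        "phi1": float(ens.phi1[0]),
        "x": float(ens.x[0]),
        "Ns": int(ens.Ns[0]),
        "alpha_eff": float(ens.alpha_eff[0]),
        "theta_eff": float(ens.theta_eff[0]),
    }
    return float(ens.rho[0]), float(ens.n[0]), latents


def confidence_contours(x, y, levels=(0.68, 0.95), grid_size=256):
    """Highest-density contours of a 2-D sample via Gaussian KDE.

    Returns {level: [polyline, ...]} where each polyline is an (m, 2) array;
    iso-density thresholds are chosen so the enclosed probability mass of
    the KDE equals each level.  Scott's bandwidth rule, 256x256 grid.
    """
    from contourpy import contour_generator

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 100:
        raise ValueError("need at least 100 paired samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError(
            "degenerate (zero-variance) axis; use marginal_summary instead"
        )
    kde = stats.gaussian_kde(np.vstack([x, y]))
    pad_x = 3.0 * np.std(x) * kde.factor + 0.1 * np.ptp(x)
    pad_y = 3.0 * np.std(y) * kde.factor + 0.1 * np.ptp(y)
    gx = np.linspace(x.min() - pad_x, x.max() + pad_x, grid_size)
    gy = np.linspace(y.min() - pad_y, y.max() + pad_y, grid_size)
    GX, GY = np.meshgrid(gx, gy)
    dens = kde(np.vstack([GX.ravel(), GY.ravel()])).reshape(GX.shape)
    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat) * cell
    total = cum[-1]
    gen = contour_generator(x=GX, y=GY, z=dens)
    out = {}
    for lvl in levels:
        idx = np.searchsorted(cum, lvl * total)
        idx = min(idx, flat.size - 1)
        thresh = flat[idx]
        out[lvl] = [np.asarray(line) for line in gen.lines(thresh)]
    return out
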