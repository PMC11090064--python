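"""Sequence-based protein refractivity, PSV and RI-increment calculation.

A protein's refraction per gram ``R_p`` and PSV ``theta_p`` are the
mass-weighted averages of per-residue values over its amino-acid
composition (weights: residue count times dehydrated residue mass).  The
protein RI follows from (R_p, 1/theta_p) through the Lorentz-Lorenz
relation, from which two RI increments are computed: the Biot increment
``alpha_B = theta_p * (n_p - n1)`` and the Wiener dilute-limit increment
``alpha_W``.  Aggregating many proteins yields the bivariate (alpha, theta)
distribution of a proteome, summarised by univariate normal fits.

Conventions: residue averaging uses dehydrated masses (amino acid minus one
water); the terminal-water correction is not applied (negligible for
chain lengths typical of proteomes).  Non-standard letters (B, J, O, U, X,
Z) are skipped with a warning and excluded from the weight normalisation.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from scipy import stats

from .materials import Solvent, WATER, lorentz_lorenz_factor, ri_from_material
from .mixture import alpha_biot, alpha_wiener_dilute

__all__ = [
    "ResidueTable",
    "ProteinRecord",
    "EnsembleStats",
    "HUMAN_RESIDUE_FREQUENCIES",
    "read_fasta",
    "protein_props",
    "protein_alpha",
    "analyze_records",
    "ensemble_stats",
    "synthetic_proteome",
]

_AVOGADRO_ML = 0.6022140857  # converts A^3/molecule to mL/mol when divided by g/mol
_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Average amino-acid composition of the human proteome (fraction of
#: residues), from public proteome-wide statistics; used by the synthetic
#: proteome generator.
HUMAN_RESIDUE_FREQUENCIES = {
    "A": 0.0701, "R": 0.0564, "N": 0.0359, "D": 0.0474, "C": 0.0230,
    "Q": 0.0477, "E": 0.0710, "G": 0.0658, "H": 0.0263, "I": 0.0433,
    "L": 0.0997, "K": 0.0572, "M": 0.0213, "F": 0.0365, "P": 0.0631,
    "S": 0.0833, "T": 0.0536, "W": 0.0122, "Y": 0.0266, "V": 0.0596,
}


@dataclass
class ResidueTable:
    """Per-residue dehydrated mass (g/mol), refraction per gram and PSV (mL/g)."""

    mass: dict[str, float]
    R: dict[str, float]
    theta: dict[str, float]

    def __post_init__(self):
        for d in (self.mass, self.R, self.theta):
            if set(d) != set(_STANDARD_AA):
                missing = set(_STANDARD_AA) - set(d)
                raise ValueError(f"residue table must cover the 20 standard amino acids; missing {sorted(missing)}")
        for aa in _STANDARD_AA:
            if min(self.mass[aa], self.R[aa], self.theta[aa]) <= 0:
                raise ValueError(f"residue {aa}: all parameters must be positive")
            if not 0.4 < self.theta[aa] < 1.2:
                raise ValueError(f"residue {aa}: PSV {self.theta[aa]} outside the (0.4, 1.2) mL/g sanity band")

    @classmethod
    def from_yaml(cls, source, n1: float = WATER.n1) -> "ResidueTable":
        """Load a residue table from YAML (path or mapping).

        Entries carry mass (g/mol), volume_A3 and dndc_wiener (mL/g); PSV is
        volume*NA/mass and R is recovered by inverting the Wiener
        dilute-limit increment through the Lorentz-Lorenz relation.
        Alternatively an entry may state R and theta directly.
        """
        if isinstance(source, Mapping):
            raw = source
        else:
            with open(source) as fh:
                raw = yaml.safe_load(fh)
        mass, R, theta = {}, {}, {}
        for aa, entry in raw.items():
            aa = str(aa).upper()
            mass[aa] = float(entry["mass"])
            if "R" in entry and "theta" in entry:
                R[aa], theta[aa] = float(entry["R"]), float(entry["theta"])
                continue
            th = float(entry["volume_A3"]) * _AVOGADRO_ML / mass[aa]
            dndc = float(entry["dndc_wiener"])
            # invert alpha_W = 3/2 * theta * n1 * F_W for the residue RI
            f_w = 2.0 * dndc / (3.0 * th * n1)
            n_res = np.sqrt(n1 * n1 * (1.0 + 2.0 * f_w) / (1.0 - f_w))
            theta[aa] = th
            R[aa] = th * float(lorentz_lorenz_factor(n_res))
        return cls(mass, R, theta)

    @classmethod
    def default(cls) -> "ResidueTable":
        ref = resources.files("ri2md").joinpath("data/residues.yaml")
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    R_p: float
    theta_p: float
    alpha_W: float
    alpha_B: float


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA (plain or gzipped) into ordered (id, sequence) pairs.

    Sequences are uppercased and '*' stop characters stripped.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        first = fh.read(1)
        if first and first != ">":
            raise ValueError(f"{path}: line 1: not FASTA (expected '>', got {first!r})")
        fh.seek(0)
        records = [
            (rec.id, str(rec.seq).upper().replace("*", ""))
            for rec in SeqIO.parse(fh, "fasta")
        ]
    return records


def protein_props(sequence: str, table: ResidueTable | None = None) -> tuple[float, float]:
    """Mass-weighted (R_p, theta_p) of a protein sequence, both mL/g."""
    table = table or _default_table()
    seq = sequence.upper().replace("*", "")
    counts = {aa: seq.count(aa) for aa in _STANDARD_AA}
    n_scored = sum(counts.values())
    if n_scored == 0:
        raise ValueError("sequence contains no scorable standard residues")
    n_skipped = len(seq) - n_scored
    if n_skipped:
        warnings.warn(
            f"skipping {n_skipped} non-standard residue(s); they are excluded "
            "from the mass-weight normalisation",
            stacklevel=2,
        )
    w = np.array([counts[aa] * table.mass[aa] for aa in _STANDARD_AA])
    w = w / w.sum()
    R_p = float(w @ np.array([table.R[aa] for aa in _STANDARD_AA]))
    theta_p = float(w @ np.array([table.theta[aa] for aa in _STANDARD_AA]))
    return R_p, theta_p


def protein_alpha(R_p, theta_p, solvent: Solvent = WATER, rule: str = "biot") -> float:
    """RI increment (mL/g) of a protein from its (R_p, theta_p).

    ``rule="biot"`` uses alpha = theta_p * (n_p - n1); ``rule="wiener_dilute"``
    the dilute limit of the Wiener mixing rule.
    """
    if rule == "biot":
        n_p = float(ri_from_material(R_p, 1.0 / theta_p))
        return float(alpha_biot(theta_p, n_p, solvent.n1))
    if rule == "wiener_dilute":
        return alpha_wiener_dilute(R_p, theta_p, solvent.n1)
    raise ValueError(f"unknown rule {rule!r}; choose 'biot' or 'wiener_dilute'")


_TABLE_CACHE: ResidueTable | None = None


def _default_table() -> ResidueTable:
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        _TABLE_CACHE = ResidueTable.default()
    return _TABLE_CACHE


def analyze_records(
    records: Iterable[tuple[str, str]],
    table: ResidueTable | None = None,
    solvent: Solvent = WATER,
) -> pd.DataFrame:
    """Per-protein properties for (id, sequence) pairs.

    Returns a DataFrame with columns id, length, R_p, theta_p, alpha_W,
    alpha_B; unscorable sequences are dropped with a warning.
    """
    table = table or _default_table()
    rows = []
    for pid, seq in records:
        try:
            R_p, theta_p = protein_props(seq, table)
        except ValueError:
            warnings.warn(f"record {pid!r} has no scorable residues; dropped", stacklevel=2)
            continue
        rows.append(
            {
                "id": pid,
                "length": len(seq),
                "R_p": R_p,
                "theta_p": theta_p,
                "alpha_W": protein_alpha(R_p, theta_p, solvent, "wiener_dilute"),
                "alpha_B": protein_alpha(R_p, theta_p, solvent, "biot"),
            }
        )
    return pd.DataFrame(rows, columns=["id", "length", "R_p", "theta_p", "alpha_W", "alpha_B"])


@dataclass
class EnsembleStats:
    """Normal-fit summary of a proteome's (alpha, theta) cloud."""

    samples: np.ndarray  # (n, 2) columns alpha, theta
    alpha_mean: float
    alpha_sd: float
    theta_mean: float
    theta_sd: float
    n_proteins: int
    mean: np.ndarray  # bivariate mean
    cov: np.ndarray  # bivariate covariance
    #: Mahalanobis radii enclosing 68%/95% probability of a bivariate normal
    ellipse_radii: dict[float, float]

    def to_dict(self) -> dict:
        return {
            "n_proteins": self.n_proteins,
            "alpha": {"mean": self.alpha_mean, "sd": self.alpha_sd},
            "theta": {"mean": self.theta_mean, "sd": self.theta_sd},
            "bivariate": {
                "mean": self.mean.tolist(),
                "cov": self.cov.tolist(),
                "ellipse_radii": {str(k): v for k, v in self.ellipse_radii.items()},
            },
        }


def ensemble_stats(samples) -> EnsembleStats:
    """Univariate normal fits and bivariate contour parameters of (alpha, theta).

    ``samples`` is an iterable of (alpha, theta) pairs or a DataFrame with
    alpha_B/theta_p columns; maximum-likelihood normal fits give mean =
    sample mean and sd = (biased) sample sd per axis.
    """
    if isinstance(samples, pd.DataFrame):
        arr = samples[["alpha_B", "theta_p"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(samples) if not isinstance(samples, np.ndarray) else samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("samples must be pairs (alpha, theta)")
    if arr.shape[0] < 2:
        raise ValueError("need at least two records for ensemble statistics")
    mu_a, sd_a = stats.norm.fit(arr[:, 0])
    mu_t, sd_t = stats.norm.fit(arr[:, 1])
    cov = np.cov(arr, rowvar=False)
    radii = {lvl: float(np.sqrt(stats.chi2.ppf(lvl, df=2))) for lvl in (0.68, 0.95)}
    return EnsembleStats(
        samples=arr,
        alpha_mean=float(mu_a),
        alpha_sd=float(sd_a),
        theta_mean=float(mu_t),
        theta_sd=float(sd_t),
        n_proteins=arr.shape[0],
        mean=arr.mean(axis=0),
        cov=np.atleast_2d(cov),
        ellipse_radii=radii,
    )


def synthetic_proteome(
    n_proteins: int = 500,
    seed: int | np.random.Generator = 0,
    frequencies: Mapping[str, float] = HUMAN_RESIDUE_FREQUENCIES,
    median_length: int = 375,
    length_sigma: float = 0.6,
    min_length: int = 50,
) -> list[tuple[str, str]]:
    """Generate a synthetic proteome with a prescribed residue composition.

    Synthetic stand-in for a downloaded reference proteome: residues are
    drawn i.i.d. from ``frequencies`` (default: average human proteome
    composition) and chain lengths from a log-normal with the given median,
    emulating the length spread of real proteomes.  Real proteomes have
    correlated residue usage within proteins; this generator does not, so
    per-protein spreads are narrower than in real data while composition-mean
    quantities are preserved.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aas = np.array(list(frequencies))
    p = np.array([frequencies[a] for a in aas], dtype=float)
    p = p / p.sum()
    lengths = np.maximum(
        min_length,
        np.round(np.exp(rng.normal(np.log(median_length), length_sigma, n_proteins))).astype(int),
    )
    return [
        (f"SYN{i:05d}", "".join(rng.choice(aas, size=L, p=p)))
        for i, L in enumerate(lengths)
    ]
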