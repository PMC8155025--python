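"""Distribution-learning metrics for generated molecule sets.

Validity, uniqueness and novelty follow the GuacaMol conventions: uniqueness
and novelty are computed on valid molecules only, after canonical
deduplication, so duplicate spam cannot inflate either score.  The
KL-divergence score averages exp(-KL) between dataset and generated
distributions of a pinned physiochemical descriptor set; the Fréchet score
is a pluggable hook that needs a caller-supplied embedder.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import entropy, gaussian_kde, rankdata
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem import DataStructs
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "MetricReport",
    "validity",
    "uniqueness",
    "novelty",
    "kld_score",
    "frechet_hook",
    "spearman_matrix",
    "KLD_CONTINUOUS_DESCRIPTORS",
    "KLD_DISCRETE_DESCRIPTORS",
]

# descriptor set pinned so reports are self-describing
KLD_CONTINUOUS_DESCRIPTORS = {
    "BertzCT": Descriptors.BertzCT,
    "MolLogP": Crippen.MolLogP,
    "MolWt": Descriptors.MolWt,
    "TPSA": Descriptors.TPSA,
}
KLD_DISCRETE_DESCRIPTORS = {
    "NumHAcceptors": rdMolDescriptors.CalcNumHBA,
    "NumHDonors": rdMolDescriptors.CalcNumHBD,
    "NumRotatableBonds": rdMolDescriptors.CalcNumRotatableBonds,
    "NumAliphaticRings": rdMolDescriptors.CalcNumAliphaticRings,
    "NumAromaticRings": rdMolDescriptors.CalcNumAromaticRings,
}


@dataclass
class MetricReport:
    """Scores for one generated set plus the provenance of its generation."""

    validity: float
    uniqueness: float
    novelty: float
    kld_score: float | None = None
    frechet_score: float | None = None
    n_evaluated: int = 10_000
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("validity", "uniqueness", "novelty", "kld_score", "frechet_score"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0 + 1e-9:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.n_evaluated <= 0:
            raise ValueError("n_evaluated must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    def to_csv_row(self) -> str:
        cols = ["validity", "uniqueness", "novelty", "kld_score", "frechet_score"]
        return ",".join(
            "" if getattr(self, c) is None else f"{getattr(self, c):.6f}" for c in cols
        )


def _valid_canonical(smiles_list: list[str]) -> list[str]:
    out = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is not None and mol.GetNumAtoms() > 0:
            out.append(Chem.MolToSmiles(mol))
    return out


def validity(smiles_list: list[str]) -> float:
    """Fraction of molecules passing the parse-and-sanitize contract."""
    if not smiles_list:
        raise ValueError("empty SMILES list")
    return len(_valid_canonical(smiles_list)) / len(smiles_list)


def uniqueness(smiles_list: list[str]) -> float:
    """Distinct canonical forms among valid molecules / valid molecules."""
    if not smiles_list:
        raise ValueError("empty SMILES list")
    valid = _valid_canonical(smiles_list)
    if not valid:
        warnings.warn("uniqueness undefined on a list with no valid molecules; reporting 0")
        return 0.0
    return len(set(valid)) / len(valid)


def novelty(smiles_list: list[str], dataset_canonical_set: set[str]) -> float:
    """Fraction of distinct valid canonical molecules absent from the dataset."""
    if not smiles_list:
        raise ValueError("empty SMILES list")
    distinct = set(_valid_canonical(smiles_list))
    if not distinct:
        warnings.warn("novelty undefined on a list with no valid molecules; reporting 0")
        return 0.0
    return len(distinct - dataset_canonical_set) / len(distinct)


# ---------------------------------------------------------------------------
# KL-divergence score
# ---------------------------------------------------------------------------

def _continuous_kldiv(x_ref: np.ndarray, x_gen: np.ndarray) -> float:
    grid = np.linspace(
        min(x_ref.min(), x_gen.min()) - 1e-6, max(x_ref.max(), x_gen.max()) + 1e-6, 1000
    )
    try:
        p = gaussian_kde(x_ref)(grid) + 1e-10
        q = gaussian_kde(x_gen)(grid) + 1e-10
        return float(entropy(p, q))
    except linalg.LinAlgError:
        return _discrete_kldiv(x_ref, x_gen)  # degenerate: smoothed histogram
    except ValueError:
        return _discrete_kldiv(x_ref, x_gen)


def _discrete_kldiv(x_ref: np.ndarray, x_gen: np.ndarray) -> float:
    lo = min(x_ref.min(), x_gen.min())
    hi = max(x_ref.max(), x_gen.max())
    if lo == hi:
        return 0.0
    bins = np.linspace(lo, hi, 11)
    p, _ = np.histogram(x_ref, bins=bins, density=True)
    q, _ = np.histogram(x_gen, bins=bins, density=True)
    return float(entropy(p + 1e-10, q + 1e-10))


def _max_internal_similarities(mols, cap: int = 1000) -> np.ndarray:
    """Per-molecule maximum Tanimoto similarity to the rest of the sample.

    The O(n^2) similarity matrix is computed on at most ``cap`` molecules,
    taken after a canonical sort so the statistic stays order-invariant.
    """
    mols = sorted(mols, key=Chem.MolToSmiles)[:cap]
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    fps = [gen.GetFingerprint(m) for m in mols]
    out = np.zeros(len(fps))
    for i, fp in enumerate(fps):
        sims = DataStructs.BulkTanimotoSimilarity(fp, fps[:i] + fps[i + 1:])
        out[i] = max(sims) if sims else 0.0
    return out


def kld_score(generated_smiles: list[str], dataset_smiles: list[str]) -> float:
    """Average of exp(-KL) over physiochemical descriptor distributions.

    KL is estimated dataset->generated per descriptor: Gaussian KDE on a
    common grid for continuous descriptors, a 10-bin smoothed histogram for
    discrete counts, plus the distribution of each molecule's maximum
    internal Tanimoto similarity.
    """
    gen_mols = [Chem.MolFromSmiles(s) for s in generated_smiles]
    ref_mols = [Chem.MolFromSmiles(s) for s in dataset_smiles]
    gen_mols = [m for m in gen_mols if m is not None]
    ref_mols = [m for m in ref_mols if m is not None]
    if len(gen_mols) < 100 or len(ref_mols) < 100:
        raise ValueError("kld_score needs at least 100 valid molecules on each side")
    kldivs = []
    for name, fn in KLD_CONTINUOUS_DESCRIPTORS.items():
        x_ref = np.array([fn(m) for m in ref_mols], dtype=float)
        x_gen = np.array([fn(m) for m in gen_mols], dtype=float)
        kldivs.append(_continuous_kldiv(x_ref, x_gen))
    for name, fn in KLD_DISCRETE_DESCRIPTORS.items():
        x_ref = np.array([fn(m) for m in ref_mols], dtype=float)
        x_gen = np.array([fn(m) for m in gen_mols], dtype=float)
        kldivs.append(_discrete_kldiv(x_ref, x_gen))
    sim_ref = _max_internal_similarities(ref_mols)
    sim_gen = _max_internal_similarities(gen_mols)
    kldivs.append(_continuous_kldiv(sim_ref, sim_gen))
    return float(np.mean(np.exp(-np.array(kldivs))))


# ---------------------------------------------------------------------------
# Fréchet hook
# ---------------------------------------------------------------------------

def frechet_hook(
    generated_smiles: list[str],
    dataset_smiles: list[str],
    embedder=None,
) -> dict:
    """Fréchet distance between Gaussian fits of two embedding clouds.

    ``embedder`` maps a SMILES list to an (n, d) array (e.g. ChemNet
    activations at full scale).  Without one the result is an explicit
    ``{"status": "not computed"}`` -- never a silent zero.  The score maps
    the distance to (0, 1] as exp(-0.2 * distance).
    """
    if embedder is None:
        return {"status": "not computed", "reason": "no embedder supplied"}
    x = np.atleast_2d(np.asarray(embedder(generated_smiles), dtype=float))
    y = np.atleast_2d(np.asarray(embedder(dataset_smiles), dtype=float))
    if x.shape[0] < 2 or y.shape[0] < 2:
        raise ValueError("need at least two embeddings per side")
    if x.ndim == 2 and x.shape[0] == 1:
        x = x.T
    mu_x, mu_y = x.mean(axis=0), y.mean(axis=0)
    cov_x = np.atleast_2d(np.cov(x, rowvar=False))
    cov_y = np.atleast_2d(np.cov(y, rowvar=False))
    diff = mu_x - mu_y
    covmean = linalg.sqrtm(cov_x @ cov_y)
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    dist = float(diff @ diff + np.trace(cov_x + cov_y - 2.0 * covmean))
    dist = max(dist, 0.0)  # clip tiny negative round-off
    return {"status": "computed", "distance": dist, "score": float(np.exp(-0.2 * dist))}


# ---------------------------------------------------------------------------
# metric correlation analysis
# ---------------------------------------------------------------------------

def spearman_matrix(runs: pd.DataFrame | dict) -> pd.DataFrame:
    """Pairwise Spearman rank correlation between metric columns.

    ``runs`` holds one row per generation setting and one column per metric
    (>= 3 rows).  Ties get average ranks; a constant column yields NaN
    ("missing") against every other metric; the diagonal is exactly 1.
    """
    df = pd.DataFrame(runs)
    if len(df) < 3:
        raise ValueError("need at least 3 runs to correlate metrics")
    cols = list(df.columns)
    ranks = {c: rankdata(df[c].to_numpy(dtype=float)) for c in cols}
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if i >= j:
                continue
            ra, rb = ranks[a], ranks[b]
            if np.std(ra) == 0 or np.std(rb) == 0:
                rho = np.nan
                warnings.warn(f"constant metric column in ({a!r}, {b!r}); correlation missing")
            else:
                rho = float(np.corrcoef(ra, rb)[0, 1])
            out.iloc[i, j] = out.iloc[j, i] = rho
    return out
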