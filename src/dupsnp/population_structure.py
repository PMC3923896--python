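"""Population-level SNP summaries, IBS distances and classical MDS.

Given called genotypes and population labels this module computes
per-population minor-allele frequencies and sharing (Venn) counts, a
genome-wide identity-by-state distance matrix, and a classical
(metric, Torgerson) multidimensional scaling of that matrix whose first
two dimensions separate populations of distinct origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .synthetic_data import MISSING, PopulationPanel

__all__ = [
    "MDSConfiguration",
    "population_maf",
    "segregating_counts",
    "venn_sharing",
    "ibs_distance",
    "ibs_distance_matrix",
    "classical_mds",
]


@dataclass
class MDSConfiguration:
    coordinates: pd.DataFrame  # samples x dimensions
    eigenvalues: np.ndarray  # non-increasing


def population_maf(
    genotypes: pd.DataFrame,
    panel: PopulationPanel,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-population MAF per SNP over called genotypes.

    ``genotypes`` is markers x samples with 0/1/2 codes (-1 missing).
    ``samples`` restricts the computation (e.g. to unrelated parents).
    Populations with zero called genotypes at a SNP get NaN.
    """
    if samples is not None:
        genotypes = genotypes[[s for s in samples if s in genotypes.columns]]
    pops: dict[str, list[str]] = {}
    for s in panel.samples:
        if s.id in genotypes.columns:
            pops.setdefault(s.population, []).append(s.id)
    out = {}
    for pop, ids in pops.items():
        sub = genotypes[ids].to_numpy(dtype=float)
        called = sub >= 0
        n_called = called.sum(axis=1)
        b_count = np.where(called, sub, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq_b = b_count / (2 * n_called)
        maf = np.minimum(freq_b, 1 - freq_b)
        maf[n_called == 0] = np.nan
        out[pop] = maf
    return pd.DataFrame(out, index=genotypes.index)


def segregating_counts(maf: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Counts of SNPs segregating per population at MAF != 0 and MAF > threshold."""
    rows = {}
    for pop in maf.columns:
        m = maf[pop]
        rows[pop] = {
            "segregating": int((m > 0).sum()),
            f"maf_gt_{threshold}": int((m > threshold).sum()),
        }
    return pd.DataFrame(rows).T


def venn_sharing(maf: pd.DataFrame, threshold: float = 0.05) -> dict[str, int]:
    """Counts of SNPs segregating (MAF > threshold) in each exact subset of
    populations; keys are '+'-joined sorted population names, plus 'none'."""
    seg = maf > threshold
    pops = list(maf.columns)
    out: dict[str, int] = {}
    exact = seg.apply(lambda row: "+".join(sorted(p for p in pops if row[p])) or "none", axis=1)
    for key, cnt in exact.value_counts().items():
        out[key] = int(cnt)
    for r in range(1, len(pops) + 1):
        for combo in combinations(sorted(pops), r):
            out.setdefault("+".join(combo), 0)
    out.setdefault("none", 0)
    return out


def ibs_distance(gi: np.ndarray, gj: np.ndarray) -> float:
    """IBS distance between two genotype vectors (0/1/2 codes, -1 missing).

    Per SNP the shared-allele count s is 2 - |gi - gj| (0, 1 or 2);
    similarity is mean(s)/2 over SNPs non-missing in both, distance is
    1 - similarity (Plink DST-compatible).
    """
    gi = np.asarray(gi, dtype=float)
    gj = np.asarray(gj, dtype=float)
    ok = (gi != MISSING) & (gj != MISSING)
    if not ok.any():
        raise ValueError("no overlapping non-missing SNPs for this pair")
    shared = 2.0 - np.abs(gi[ok] - gj[ok])
    return float(1.0 - shared.mean() / 2.0)


def ibs_distance_matrix(genotypes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric IBS distance matrix over samples (columns of the input).

    Returns (distances, per-pair non-missing SNP counts).  Vectorized over
    the 0/1/2 coding: |gi - gj| summed over non-missing SNPs.
    """
    g = genotypes.to_numpy(dtype=np.int16).T  # samples x snps
    samples = list(genotypes.columns)
    n = len(samples)
    valid = g != MISSING
    gm = np.where(valid, g, 0).astype(np.int32)
    dist = np.zeros((n, n))
    counts = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        diff = np.abs(gm[i] - gm) * both
        n_ok = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = diff.sum(axis=1) / (2.0 * n_ok)
        dist[i] = np.where(n_ok > 0, d, np.nan)
        counts[i] = n_ok
    np.fill_diagonal(dist, 0.0)
    return (
        pd.DataFrame(dist, index=samples, columns=samples),
        pd.DataFrame(counts, index=samples, columns=samples),
    )


def classical_mds(distances: pd.DataFrame, k: int = 2) -> MDSConfiguration:
    """Torgerson scaling: double-center the squared distances and embed on
    the top-k eigenvectors scaled by sqrt(eigenvalue).

    Negative eigenvalues (non-Euclidean distances) are truncated; if fewer
    than k positive eigenvalues exist the dimensionality is reduced with a
    warning.  Sign convention: each dimension's largest-magnitude loading
    is made positive so results are reproducible.
    """
    import warnings

    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    c = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * c @ (d**2) @ c
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(eigval.max(), 0) * 1e-12
    n_pos = int(positive.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; reducing dimensions from {k}",
            stacklevel=2,
        )
        k = max(n_pos, 1)
    coords = eigvec[:, :k] * np.sqrt(np.maximum(eigval[:k], 0.0))
    for dim in range(k):
        lead = np.argmax(np.abs(coords[:, dim]))
        if coords[lead, dim] < 0:
            coords[:, dim] *= -1
    frame = pd.DataFrame(
        coords,
        index=distances.index,
        columns=[f"dim{i + 1}" for i in range(k)],
    )
    return MDSConfiguration(coordinates=frame, eigenvalues=eigval[:k])
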