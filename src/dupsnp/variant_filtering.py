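"""Candidate-SNP filters for array design in a duplicated genome.

The filters mirror the discovery pipeline of a salmonid SNP-array design:

* RR-Seq candidates lose haploid-heterozygous sites (PSVs), then sites with
  low pooled allele frequency or read depth, then repeat-masked sites;
* RAD-Seq candidates lose sites with two or more Mendelian errors or
  significant segregation distortion in any family;
* RNA-Seq candidates keep only transversions with predicted MAF >= 0.1;
* finally array content is selected from probe-direction recommendations
  with a capacity-fill stage.

Every filter returns a :class:`FilterResult` partition: ``kept`` plus
``removed`` with a single machine-readable reason per record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterResult",
    "RepeatMask",
    "FamilyGenotypeTable",
    "filter_haploid_heterozygotes",
    "apply_rr_filters",
    "is_transversion",
    "apply_rna_filters",
    "count_mendelian_errors",
    "segregation_distortion_test",
    "apply_rad_filters",
    "mask_repeats",
    "select_array_content",
    "run_rr_pipeline",
]

_NUCS = frozenset("ACGT")
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}

# genotype codes follow synthetic_data: 0=AA, 1=AB, 2=BB, -1 missing
_GAMETES = {0: (0,), 1: (0, 1), 2: (1,)}


@dataclass
class FilterResult:
    """Exhaustive, exclusive partition of a candidate table."""

    kept: pd.DataFrame
    removed: pd.DataFrame  # carries a "reason" column

    def __post_init__(self) -> None:
        if "reason" not in self.removed.columns and len(self.removed):
            raise ValueError("removed records must carry a reason column")

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


@dataclass
class RepeatMask:
    """Per-contig repeat intervals, 0-based half-open, merged and sorted."""

    intervals: dict[str, np.ndarray]  # contig -> (n, 2) array of [start, end)

    @classmethod
    def from_frame(cls, bed: pd.DataFrame) -> "RepeatMask":
        out: dict[str, np.ndarray] = {}
        for contig, grp in bed.groupby("contig"):
            arr = grp[["start", "end"]].to_numpy(dtype=np.int64)
            if np.any(arr[:, 0] >= arr[:, 1]):
                raise ValueError(f"empty or inverted interval on {contig!r}")
            arr = arr[np.argsort(arr[:, 0])]
            merged = [arr[0].tolist()]
            for s, e in arr[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[str(contig)] = np.asarray(merged, dtype=np.int64)
        return cls(intervals=out)

    def contains(self, contig: str, zero_based_pos: int) -> bool:
        arr = self.intervals.get(contig)
        if arr is None:
            return False
        i = np.searchsorted(arr[:, 0], zero_based_pos, side="right") - 1
        return i >= 0 and zero_based_pos < arr[i, 1]


@dataclass
class FamilyGenotypeTable:
    """Per-family genotypes for markers: family -> genotype frame.

    Each frame is markers x individuals with int codes (0/1/2, -1 missing).
    ``parents`` maps family -> (sire column, dam column).  An optional
    ``qualities`` frame of the same shape masks low-confidence genotypes.
    """

    genotypes: dict[str, pd.DataFrame]
    parents: dict[str, tuple[str, str]]
    qualities: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fam, (sire, dam) in self.parents.items():
            cols = self.genotypes[fam].columns
            if sire not in cols or dam not in cols:
                raise ValueError(f"family {fam!r} is missing a genotyped parent")

    def masked(self, family: str, gq_threshold: float | None) -> pd.DataFrame:
        """Genotypes with quality <= threshold set to missing."""
        geno = self.genotypes[family]
        gq = self.qualities.get(family)
        if gq is None or gq_threshold is None:
            return geno
        return geno.where(gq > gq_threshold, other=-1).astype(geno.dtypes.iloc[0])


# ---------------------------------------------------------------------------
# RR-Seq filters
# ---------------------------------------------------------------------------


def filter_haploid_heterozygotes(
    candidates: pd.DataFrame, gq_threshold: float = 20.0
) -> FilterResult:
    """Remove candidates called heterozygous in the haploid sample.

    A confident heterozygous call in a haploid individual cannot be allelic
    variation — it is a fixed difference between collapsed paralogues — so
    such sites are removed as PSVs.  Only calls with genotype quality
    strictly above ``gq_threshold`` count; missing haploid calls are kept.
    """
    het = (candidates["haploid_call"] == "het") & (
        candidates["haploid_gq"] > gq_threshold
    )
    removed = candidates[het].copy()
    removed["reason"] = "haploid_het_psv"
    return FilterResult(kept=candidates[~het].copy(), removed=removed)


def apply_rr_filters(candidates: pd.DataFrame) -> FilterResult:
    """Frequency/depth filter: remove pooled AF <= 0.1 or depth <= 10."""
    af = pd.to_numeric(candidates["pooled_af"], errors="coerce")
    dp = pd.to_numeric(candidates["depth"], errors="coerce")
    unscorable = af.isna() | dp.isna()
    low = (af <= 0.1) | (dp <= 10)
    removed = candidates[unscorable | low].copy()
    reasons = np.where(unscorable[unscorable | low], "unscorable", "low_freq_or_depth")
    removed["reason"] = reasons
    kept = candidates[~(unscorable | low)].copy()
    return FilterResult(kept=kept, removed=removed)


# ---------------------------------------------------------------------------
# RNA-Seq filters
# ---------------------------------------------------------------------------


def is_transversion(ref: str, alt: str) -> bool:
    """True unless the substitution is a transition (A<->G or C<->T)."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _NUCS or alt not in _NUCS:
        raise ValueError(f"non-nucleotide allele: {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt alleles must differ")
    return frozenset((ref, alt)) not in _TRANSITIONS


def apply_rna_filters(candidates: pd.DataFrame, maf_threshold: float = 0.1) -> FilterResult:
    """Keep transversions with predicted MAF >= threshold (inclusive)."""
    af = pd.to_numeric(candidates["pooled_af"], errors="coerce")
    maf = np.minimum(af, 1 - af)
    tv = candidates.apply(lambda r: is_transversion(r["ref"], r["alt"]), axis=1)
    if len(candidates) == 0:
        tv = pd.Series(dtype=bool)
    unscorable = af.isna()
    keep = tv & (maf >= maf_threshold) & ~unscorable
    removed = candidates[~keep].copy()
    reason = np.where(
        unscorable[~keep],
        "unscorable",
        np.where(~tv[~keep], "transition", "low_maf"),
    )
    removed["reason"] = reason
    return FilterResult(kept=candidates[keep].copy(), removed=removed)


# ---------------------------------------------------------------------------
# RAD-Seq filters (family based)
# ---------------------------------------------------------------------------


def count_mendelian_errors(
    families: FamilyGenotypeTable,
    family: str,
    marker: str | None = None,
    gq_threshold: float | None = None,
) -> pd.Series | int:
    """Count trio-incompatible offspring genotypes per marker in a family.

    An offspring genotype is an error when no pair of parental gametes can
    produce it under bi-allelic autosomal inheritance.  Missing genotypes
    (offspring or either parent) never count.
    """
    if family not in families.parents:
        raise ValueError(f"family {family!r} has no recorded parents")
    geno = families.masked(family, gq_threshold)
    sire_col, dam_col = families.parents[family]
    offspring = [c for c in geno.columns if c not in (sire_col, dam_col)]

    sire = geno[sire_col].to_numpy()
    dam = geno[dam_col].to_numpy()
    counts = np.zeros(len(geno), dtype=int)
    # feasible offspring genotype sets per (sire, dam) pair
    for i in range(len(geno)):
        s, d = int(sire[i]), int(dam[i])
        if s < 0 or d < 0:
            continue
        feasible = {gs + gd for gs in _GAMETES[s] for gd in _GAMETES[d]}
        for c in offspring:
            o = int(geno[c].iloc[i])
            if o >= 0 and o not in feasible:
                counts[i] += 1
    out = pd.Series(counts, index=geno.index, name="mendelian_errors")
    if marker is not None:
        return int(out.loc[marker])
    return out


def segregation_distortion_test(
    families: FamilyGenotypeTable,
    family: str,
    marker: str,
    gq_threshold: float | None = None,
) -> tuple[float, str]:
    """Chi-square goodness-of-fit of offspring ratios in one family.

    AB x (AA or BB) expects 1:1 over the two possible offspring classes;
    AB x AB expects 1:2:1.  Uninformative crosses (no heterozygous parent,
    or a missing parent) return p = 1 with an "uninformative" flag.
    Offspring genotypes that are Mendelian-impossible for the cross are
    excluded from the table (they are counted by the error filter instead).
    """
    geno = families.masked(family, gq_threshold)
    sire_col, dam_col = families.parents[family]
    offspring = [c for c in geno.columns if c not in (sire_col, dam_col)]
    s = int(geno.at[marker, sire_col])
    d = int(geno.at[marker, dam_col])
    if s < 0 or d < 0 or 1 not in (s, d):
        return 1.0, "uninformative"
    obs_raw = [int(geno.at[marker, c]) for c in offspring]
    obs_raw = [g for g in obs_raw if g >= 0]

    if s == 1 and d == 1:
        classes, weights = (0, 1, 2), (0.25, 0.5, 0.25)
    else:
        hom = d if s == 1 else s  # the homozygous parent (0 or 2)
        if hom == 0:
            classes, weights = (0, 1), (0.5, 0.5)
        else:
            classes, weights = (1, 2), (0.5, 0.5)
    obs = [sum(1 for g in obs_raw if g == c) for c in classes]
    n = sum(obs)
    if n == 0:
        return 1.0, "uninformative"
    expected = [w * n for w in weights]
    chi2 = sum((o - e) ** 2 / e for o, e in zip(obs, expected))
    p = float(stats.chi2.sf(chi2, df=len(classes) - 1))
    return p, "ok"


def apply_rad_filters(
    candidates: pd.DataFrame,
    families: FamilyGenotypeTable,
    alpha: float = 0.05,
    max_errors: int = 2,
    gq_threshold: float = 20.0,
    marker_column: str = "id",
) -> FilterResult:
    """Remove candidates with >= 2 Mendelian errors or distortion p < alpha
    in any single family.  Genotypes with quality <= ``gq_threshold`` are
    treated as missing before counting.
    """
    err_by_family = {
        fam: count_mendelian_errors(families, fam, gq_threshold=gq_threshold)
        for fam in families.genotypes
    }
    reasons: dict[str, str] = {}
    for _, row in candidates.iterrows():
        marker = row[marker_column]
        for fam in families.genotypes:
            errs = err_by_family[fam]
            if marker in errs.index and int(errs.loc[marker]) >= max_errors:
                reasons[marker] = "mendelian_errors"
                break
            if marker in families.genotypes[fam].index:
                p, flag = segregation_distortion_test(
                    families, fam, marker, gq_threshold=gq_threshold
                )
                if flag == "ok" and p < alpha:
                    reasons[marker] = "segregation_distortion"
                    break
    removed_mask = candidates[marker_column].isin(reasons)
    removed = candidates[removed_mask].copy()
    removed["reason"] = [reasons[m] for m in removed[marker_column]]
    return FilterResult(kept=candidates[~removed_mask].copy(), removed=removed)


# ---------------------------------------------------------------------------
# repeat masking
# ---------------------------------------------------------------------------


def mask_repeats(candidates: pd.DataFrame, mask: RepeatMask) -> FilterResult:
    """Remove candidates whose 0-based position (pos - 1) falls inside a
    repeat interval on the same contig.  Candidate positions are 1-based
    (VCF convention); mask intervals are 0-based half-open (BED).
    Candidates on contigs absent from the mask are kept with a warning.
    """
    import warnings

    in_repeat = np.zeros(len(candidates), dtype=bool)
    unknown: set[str] = set()
    for i, (contig, pos) in enumerate(zip(candidates["contig"], candidates["pos"])):
        if contig not in mask.intervals:
            unknown.add(str(contig))
            continue
        in_repeat[i] = mask.contains(str(contig), int(pos) - 1)
    if unknown:
        warnings.warn(
            f"{len(unknown)} contig(s) absent from repeat mask; candidates kept",
            stacklevel=2,
        )
    removed = candidates[in_repeat].copy()
    removed["reason"] = "repeat_masked"
    return FilterResult(kept=candidates[~in_repeat].copy(), removed=removed)


# ---------------------------------------------------------------------------
# array content selection
# ---------------------------------------------------------------------------

_BASE_PAIRS = {
    frozenset(["recommended"]),
    frozenset(["recommended", "neutral"]),
    frozenset(["neutral"]),
}


def select_array_content(candidates: pd.DataFrame, capacity: int) -> pd.DataFrame:
    """Select array content from probe-direction recommendations.

    Base set: candidates whose two direction recommendations are
    (recommended, recommended), (recommended, neutral) or
    (neutral, neutral).  A lone "recommended" direction also qualifies even
    when its partner is "not recommended" (the recommended probe itself is
    tiled).  Remaining capacity is filled, in order, by

    1. candidates discovered in more than one sequencing experiment with a
       low conversion score (``multi_source`` flag),
    2. candidates mapping to two reference locations with conversion score
       strictly over 0.6 (``dual_mapping`` flag),
    3. previously verified candidates with a non-zero conversion score
       (``previously_verified`` flag),

    with deterministic tie-breaks by descending conversion score then id.

    Expected columns: id, direction_fwd, direction_rev, conversion_score,
    and the boolean flags multi_source, dual_mapping, previously_verified.
    """
    fwd = candidates["direction_fwd"]
    rev = candidates["direction_rev"]
    base_mask = (fwd == "recommended") | (rev == "recommended") | (
        (fwd == "neutral") & (rev == "neutral")
    )
    base = candidates[base_mask]
    if capacity < len(base):
        raise ValueError(
            f"capacity {capacity} below base set size {len(base)}; truncation forbidden"
        )
    selected = [base]
    remaining = capacity - len(base)
    pool = candidates[~base_mask]
    fill_stages = [
        ("multi_source", pool["multi_source"].astype(bool)),
        (
            "dual_mapping",
            pool["dual_mapping"].astype(bool) & (pool["conversion_score"] > 0.6),
        ),
        (
            "previously_verified",
            pool["previously_verified"].astype(bool) & (pool["conversion_score"] > 0),
        ),
    ]
    chosen_ids: set = set(base["id"])
    for _, mask in fill_stages:
        if remaining <= 0:
            break
        stage = pool[mask & ~pool["id"].isin(chosen_ids)]
        stage = stage.sort_values(
            ["conversion_score", "id"], ascending=[False, True]
        ).head(remaining)
        chosen_ids.update(stage["id"])
        selected.append(stage)
        remaining -= len(stage)
    return pd.concat(selected).copy()


# ---------------------------------------------------------------------------
# staged RR pipeline with a per-stage ledger
# ---------------------------------------------------------------------------


def run_rr_pipeline(
    candidates: pd.DataFrame,
    mask: RepeatMask | None = None,
    gq_threshold: float = 20.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PSV exclusion -> frequency/depth -> repeat mask, with a counts ledger.

    Returns (kept candidates, ledger frame with one row per stage).
    """
    ledger_rows = []
    stage1 = filter_haploid_heterozygotes(candidates, gq_threshold)
    ledger_rows.append(
        {"stage": "haploid_het_psv", "input": len(candidates), "removed": stage1.n_removed}
    )
    stage2 = apply_rr_filters(stage1.kept)
    ledger_rows.append(
        {"stage": "freq_depth", "input": stage1.n_kept, "removed": stage2.n_removed}
    )
    kept = stage2.kept
    if mask is not None:
        stage3 = mask_repeats(kept, mask)
        ledger_rows.append(
            {"stage": "repeat_mask", "input": len(kept), "removed": stage3.n_removed}
        )
        kept = stage3.kept
    ledger = pd.DataFrame(ledger_rows)
    ledger["output"] = ledger["input"] - ledger["removed"]
    return kept, ledger
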