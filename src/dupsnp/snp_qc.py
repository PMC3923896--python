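"""Probeset QC classification and the array accounting ledger.

Each probeset is placed in exactly one of six categories:

* PolyHighRes — passes all QC, polymorphic with well-resolved clusters;
* MonoHighRes — passes all QC except a minor allele in >= 2 samples;
* CallRateBelowThreshold — genotype call rate under 97%;
* NoMinorHomozygote — passes QC but only two clusters are observed;
* OTV — off-target-variant cluster detected;
* Other — everything else (including unresolvable cluster quality).

Downstream analyses retain PolyHighRes and NoMinorHomozygote only.  A
final pedigree-based filter drops any SNP showing a Mendelian error in
the pedigreed samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import GENOTYPE_CODES, Pedigree

__all__ = [
    "SNPMetrics",
    "QCThresholds",
    "compute_snp_metrics",
    "classify_snp",
    "pedigree_mendelian_filter",
    "best_probeset_per_snp",
    "qc_ledger",
    "ledger_arithmetic",
    "classify_calls_table",
    "RETAINED_CATEGORIES",
    "CATEGORY_RANK",
]

RETAINED_CATEGORIES = ("PolyHighRes", "NoMinorHomozygote")
# higher rank = preferred when choosing the best probeset for a SNP
CATEGORY_RANK = {
    "PolyHighRes": 5,
    "NoMinorHomozygote": 4,
    "MonoHighRes": 3,
    "CallRateBelowThreshold": 2,
    "OTV": 1,
    "Other": 0,
}


@dataclass
class SNPMetrics:
    n_samples: int
    n_called: int
    counts: dict[str, int]  # AA/AB/BB counts among called samples
    call_rate: float
    minor_allele: str | None  # "A" or "B"
    minor_allele_samples: int  # samples carrying >= 1 minor allele
    maf: float
    separation: float  # min standardized distance between adjacent cluster means
    has_otv: bool
    flagged: bool = False  # zero called samples


@dataclass
class QCThresholds:
    call_rate: float = 0.97
    min_minor_samples: int = 2
    min_separation: float = 3.0


def compute_snp_metrics(calls: pd.DataFrame) -> SNPMetrics:
    """Summarize one probeset's calls frame (columns: call, optional
    contrast) into the metrics the category rules consume."""
    n = len(calls)
    called = calls[calls["call"].isin(["AA", "AB", "BB"])]
    n_called = len(called)
    counts = {g: int((called["call"] == g).sum()) for g in ("AA", "AB", "BB")}
    call_rate = n_called / n if n else 0.0
    has_otv = bool((calls["call"] == "OTV").any())
    if n_called == 0:
        return SNPMetrics(
            n_samples=n,
            n_called=0,
            counts=counts,
            call_rate=0.0,
            minor_allele=None,
            minor_allele_samples=0,
            maf=0.0,
            separation=0.0,
            has_otv=has_otv,
            flagged=True,
        )
    n_a = 2 * counts["AA"] + counts["AB"]
    n_b = 2 * counts["BB"] + counts["AB"]
    if n_b <= n_a:
        minor, minor_samples = "B", counts["BB"] + counts["AB"]
        maf = n_b / (2 * n_called)
    else:
        minor, minor_samples = "A", counts["AA"] + counts["AB"]
        maf = n_a / (2 * n_called)

    separation = np.inf
    if "contrast" in calls.columns:
        means, sds = [], []
        for g in ("AA", "AB", "BB"):
            vals = called.loc[called["call"] == g, "contrast"]
            if len(vals):
                means.append(float(vals.mean()))
                sds.append(float(vals.std(ddof=0)) if len(vals) > 1 else 0.0)
        if len(means) >= 2:
            order = np.argsort(means)
            pooled = max(float(np.mean(sds)), 1e-3)
            gaps = np.diff(np.asarray(means)[order]) / pooled
            separation = float(gaps.min())
    return SNPMetrics(
        n_samples=n,
        n_called=n_called,
        counts=counts,
        call_rate=call_rate,
        minor_allele=minor,
        minor_allele_samples=minor_samples,
        maf=maf,
        separation=separation,
        has_otv=has_otv,
    )


def classify_snp(metrics: SNPMetrics, thresholds: QCThresholds | None = None) -> str:
    """Apply the six-category decision rules in fixed order."""
    t = thresholds or QCThresholds()
    if metrics.has_otv:
        return "OTV"
    if metrics.flagged or metrics.call_rate < t.call_rate:
        return "CallRateBelowThreshold"
    if np.isfinite(metrics.separation) and metrics.separation < t.min_separation:
        return "Other"
    if metrics.minor_allele_samples < t.min_minor_samples:
        return "MonoHighRes"
    # only two clusters observed: the minor-homozygote cluster is absent
    minor_hom = "BB" if metrics.minor_allele == "B" else "AA"
    if metrics.counts[minor_hom] == 0 and metrics.maf > 0:
        return "NoMinorHomozygote"
    return "PolyHighRes"


def pedigree_mendelian_filter(
    calls: pd.DataFrame, pedigree: Pedigree
) -> pd.Series:
    """Pass/fail per SNP: fail on any trio-incompatible genotype.

    ``calls`` is a long frame (probeset_id, sample_id, call).  Samples not
    in the pedigree, and pedigree members without genotypes, are ignored;
    with no scoreable trios a SNP passes vacuously.
    """
    gametes = {0: (0,), 1: (0, 1), 2: (1,)}
    code = {**GENOTYPE_CODES, "NoCall": -1, "OTV": -1}
    wide = calls.pivot_table(
        index="probeset_id", columns="sample_id", values="call", aggfunc="first"
    )
    trios = [
        (t.id, t.sire, t.dam)
        for t in pedigree.trios()
        if t.id in wide.columns and t.sire in wide.columns and t.dam in wide.columns
    ]
    result = {}
    for snp, row in wide.iterrows():
        ok = True
        for off, sire, dam in trios:
            s = code.get(row[sire], -1)
            d = code.get(row[dam], -1)
            o = code.get(row[off], -1)
            if s < 0 or d < 0 or o < 0:
                continue
            feasible = {gs + gd for gs in gametes[s] for gd in gametes[d]}
            if o not in feasible:
                ok = False
                break
        result[snp] = ok
    return pd.Series(result, name="mendelian_pass")


def best_probeset_per_snp(qc: pd.DataFrame) -> pd.DataFrame:
    """Keep one probeset per SNP: highest category rank, then call rate,
    then cluster separation, then probeset id for determinism.

    Expects columns: snp_id, probeset_id, category, call_rate, separation.
    """
    ranked = qc.assign(_rank=qc["category"].map(CATEGORY_RANK))
    ranked = ranked.sort_values(
        ["snp_id", "_rank", "call_rate", "separation", "probeset_id"],
        ascending=[True, False, False, False, True],
    )
    return ranked.groupby("snp_id", sort=True).head(1).drop(columns="_rank")


def qc_ledger(qc: pd.DataFrame, source_column: str = "source") -> pd.DataFrame:
    """Array accounting table: per-source counts at each filtering stage.

    Rows: total candidates; low-quality clusters (CallRateBelowThreshold +
    OTV + Other); monomorphic (MonoHighRes); high-quality polymorphic
    (PolyHighRes + NoMinorHomozygote); Mendelian error (retained categories
    failing the pedigree filter); final filtered.  Column consistency
    (final = total - lowquality - monomorphic - mendelian) is asserted.

    Expects columns: category, mendelian_pass and a source column.
    """
    low_quality = {"CallRateBelowThreshold", "OTV", "Other"}
    rows = {}
    sources = list(pd.unique(qc[source_column]))
    for src in sources + ["Total"]:
        sub = qc if src == "Total" else qc[qc[source_column] == src]
        total = len(sub)
        lowq = int(sub["category"].isin(low_quality).sum())
        mono = int((sub["category"] == "MonoHighRes").sum())
        poly = int(sub["category"].isin(RETAINED_CATEGORIES).sum())
        mend = int(
            (sub["category"].isin(RETAINED_CATEGORIES) & ~sub["mendelian_pass"]).sum()
        )
        final = poly - mend
        if final != total - lowq - mono - mend:
            raise ValueError(f"inconsistent ledger counts for source {src!r}")
        rows[src] = {
            "total_candidates": total,
            "low_quality_clusters": lowq,
            "monomorphic": mono,
            "high_quality_polymorphic": poly,
            "mendelian_error": mend,
            "final_filtered": final,
        }
    return pd.DataFrame(rows)


def ledger_arithmetic(
    total: int, low_quality: int, monomorphic: int, mendelian: int
) -> dict[str, int]:
    """Array accounting from stage counts: polymorphic survivors and the
    final filtered total, with the same consistency relation enforced by
    :func:`qc_ledger` (final = total - lowquality - monomorphic - mendelian)."""
    poly = total - low_quality - monomorphic
    final = poly - mendelian
    if final != total - low_quality - monomorphic - mendelian:
        raise ValueError("inconsistent ledger counts")
    return {
        "total_candidates": total,
        "low_quality_clusters": low_quality,
        "monomorphic": monomorphic,
        "high_quality_polymorphic": poly,
        "mendelian_error": mendelian,
        "final_filtered": final,
    }


def classify_calls_table(
    calls: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    pedigree: Pedigree | None = None,
) -> pd.DataFrame:
    """Classify every probeset in a long calls frame; returns a QC frame
    with category, call rate, MAF, separation and mendelian_pass."""
    thresholds = thresholds or QCThresholds()
    mend = (
        pedigree_mendelian_filter(calls, pedigree)
        if pedigree is not None
        else None
    )
    rows = []
    for ps, grp in calls.groupby("probeset_id", sort=True):
        m = compute_snp_metrics(grp)
        cat = classify_snp(m, thresholds)
        rows.append(
            {
                "probeset_id": ps,
                "category": cat,
                "call_rate": m.call_rate,
                "maf": m.maf,
                "minor_allele_samples": m.minor_allele_samples,
                "separation": m.separation if np.isfinite(m.separation) else np.nan,
                "mendelian_pass": bool(mend.get(ps, True)) if mend is not None else True,
            }
        )
    return pd.DataFrame(rows)
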