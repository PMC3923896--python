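"""Readers and writers for the pipeline's standard text formats.

Candidate variants travel as minimal VCF (CHROM POS ID REF ALT QUAL
FILTER INFO with DP/AF) or TSV; pedigrees as 6-column PED text; repeat
masks as BED (0-based half-open); intensities and truth labels as TSV.
Validation errors carry line numbers and offending values.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synthetic_data import Individual, Pedigree

__all__ = [
    "write_candidates_vcf",
    "read_candidates_vcf",
    "write_candidates_tsv",
    "read_candidates_tsv",
    "write_ped",
    "read_ped",
    "read_bed",
    "write_intensities_tsv",
    "read_intensities_tsv",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=dupsnp
##INFO=<ID=DP,Number=1,Type=Integer,Description="Pooled read depth">
##INFO=<ID=AF,Number=A,Type=Float,Description="Pooled alternate allele frequency">
##INFO=<ID=SRC,Number=1,Type=String,Description="Discovery experiment">
"""


def write_candidates_vcf(candidates: pd.DataFrame, path: str | Path) -> None:
    """Write a candidate table as minimal VCF (positions 1-based)."""
    path = Path(path)
    contigs = pd.unique(candidates["contig"])
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        ordered = candidates.sort_values(["contig", "pos"], kind="stable")
        for _, r in ordered.iterrows():
            info = f"DP={int(r['depth'])};AF={float(r['pooled_af']):.6g}"
            if "source" in r.index and pd.notna(r["source"]):
                info += f";SRC={r['source']}"
            fh.write(
                f"{r['contig']}\t{int(r['pos'])}\t{r['id']}\t{r['ref']}\t{r['alt']}"
                f"\t.\t.\t{info}\n"
            )


def read_candidates_vcf(path: str | Path) -> pd.DataFrame:
    """Read a minimal VCF back into a candidate frame (via cyvcf2)."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        if not v.ALT:
            raise ValueError(f"record {v.ID or v.POS} has no ALT allele")
        rows.append(
            {
                "id": v.ID or f"{v.CHROM}_{v.POS}",
                "contig": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": v.ALT[0],
                "depth": v.INFO.get("DP"),
                "pooled_af": v.INFO.get("AF"),
                "source": v.INFO.get("SRC"),
            }
        )
    return pd.DataFrame(rows).set_index("id", drop=False)


def write_candidates_tsv(candidates: pd.DataFrame, path: str | Path) -> None:
    candidates.to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if "id" in frame.columns:
        frame = frame.set_index("id", drop=False)
    return frame


def write_ped(pedigree: Pedigree, path: str | Path) -> None:
    pedigree.to_ped_frame().to_csv(path, sep="\t", index=False, header=False)


def read_ped(path: str | Path) -> Pedigree:
    """Read 6-column PED text (family, id, sire, dam, sex, phenotype)."""
    sex_name = {1: "male", 2: "female"}
    inds: list[Individual] = []
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 columns, got {len(parts)}")
            fam, iid, sire, dam, sex, _ = parts[:6]
            inds.append(
                Individual(
                    id=iid,
                    sire=None if sire == "0" else sire,
                    dam=None if dam == "0" else dam,
                    family=fam,
                    sex=sex_name.get(int(sex), "unknown"),
                )
            )
    try:
        return Pedigree(individuals=inds)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read 3+ column BED; rejects empty/inverted intervals with line info."""
    rows = []
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{ln}: empty or inverted interval [{start},{end})"
                )
            rows.append({"contig": contig, "start": start, "end": end})
    return pd.DataFrame(rows)


def write_intensities_tsv(intensities: pd.DataFrame, path: str | Path) -> None:
    cols = ["probeset_id", "probe_replicate", "sample_id", "signal_A", "signal_B"]
    intensities[cols].to_csv(path, sep="\t", index=False)


def read_intensities_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    required = {"probeset_id", "sample_id", "signal_A", "signal_B"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing intensity columns {sorted(missing)}")
    if "probe_replicate" not in frame.columns:
        frame["probe_replicate"] = 1
    return frame
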