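"""End-to-end orchestration: simulate -> filter -> call -> qc -> map ->
popstruct -> sex, with one seed, per-stage manifests and TSV outputs.

The default scenario mirrors the validation design of a salmon array
study: a 96-sample panel (farmed Scottish, farmed Norwegian and wild
populations plus two reference families of 10 offspring), five
chromosomes of sire-phase-informative markers, candidate variants with a
PSV admixture screened by a haploid sample, three-cluster intensities
with MSV/OTV anomalies, and 87 Y-specific probes.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    io,
    linkage_grouping,
    population_structure,
    sexing,
    snp_qc,
    synthetic_data,
    variant_filtering,
)
from .synthetic_data import ClusterGeometry, GenotypeMatrix

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "substream"]


def substream(seed: int, name: str) -> int:
    """Named, reproducible child seed below 2**31."""
    return int(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class PipelineConfig:
    seed: int = 1
    # scenario sizes
    n_chromosomes: int = 5
    markers_per_chromosome: int = 400
    marker_spacing_bp: int = 50_000
    n_families: int = 2
    n_offspring: int = 10
    populations: dict[str, int] = field(
        default_factory=lambda: {
            "farmed_scottish": 23,
            "farmed_norwegian_1": 8,
            "farmed_norwegian_2": 8,
            "wild": 33,
        }
    )
    divergence: dict[str, float] = field(
        default_factory=lambda: {
            "farmed_scottish": 0.05,
            "farmed_norwegian_1": 0.08,
            "farmed_norwegian_2": 0.08,
            "wild": 0.12,
        }
    )
    # candidate simulation
    n_candidate_sites: int = 2000
    psv_fraction: float = 0.2
    depth_mean: int = 30
    error_rate: float = 0.0
    # intensities
    msv_fraction: float = 0.05
    otv_fraction: float = 0.05
    # Y probes
    n_y_probes: int = 87
    y_male_level: float = 10.0
    y_female_level: float = 2.0
    y_noise_sd: float = 0.5
    # thresholds (printed-value defaults)
    gq_threshold: float = 20.0
    min_pooled_af: float = 0.1
    min_depth: int = 10
    distortion_alpha: float = 0.05
    call_rate_threshold: float = 0.97
    min_minor_samples: int = 2
    maf_threshold: float = 0.05
    confidence_threshold: float = 0.95
    # stage toggles
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "simulate": True,
            "filter": True,
            "call": True,
            "qc": True,
            "map": True,
            "popstruct": True,
            "sex": True,
        }
    )

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)


@dataclass
class RunManifest:
    parameters: dict
    stages: list[dict] = field(default_factory=list)
    version: str = "0.1.0"

    def record(self, stage: str, n_in: int, n_out: int, **extra) -> None:
        self.stages.append(
            {
                "stage": stage,
                "input_records": int(n_in),
                "output_records": int(n_out),
                "timestamp": time.time(),
                **extra,
            }
        )

    def to_json(self) -> str:
        return json.dumps({"parameters": self.parameters, "stages": self.stages,
                           "version": self.version}, indent=1, default=str)


def _marker_map(config: PipelineConfig) -> dict[str, np.ndarray]:
    return {
        f"chr{c + 1}": (np.arange(config.markers_per_chromosome) + 1)
        * config.marker_spacing_bp
        for c in range(config.n_chromosomes)
    }


def _population_genotypes(
    config: PipelineConfig,
    marker_ids: pd.Index,
    panel: synthetic_data.PopulationPanel,
    seed: int,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Hardy-Weinberg genotypes for non-pedigree samples from drifted
    population frequencies; returns (frame, ancestral freqs)."""
    rng = np.random.default_rng(seed)
    n = len(marker_ids)
    ancestral = rng.uniform(0.1, 0.9, size=n)
    pop_freqs = synthetic_data._population_freqs(ancestral, panel.divergence, rng)
    cols = {}
    for s in panel.samples:
        f = pop_freqs[s.population]
        cols[s.id] = rng.binomial(2, f).astype(np.int8)
    return pd.DataFrame(cols, index=marker_ids), ancestral


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Execute the enabled stages in order, writing outputs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(parameters=asdict(config))
    on = config.stages

    genome = panel = pedigree = None
    candidates = truth_cand = None
    family_geno = truth_fam = None
    intensities = truth_int = None
    calls = qc = None
    full_geno: pd.DataFrame | None = None

    try:
        if on.get("simulate", True):
            genome = synthetic_data.make_genome(
                n_contigs=50, mean_length=20_000, duplicated_fraction=0.25,
                seed=substream(config.seed, "genome"),
            )
            panel = synthetic_data.make_panel(
                config.populations, config.divergence, haploid_sample=True,
                seed=substream(config.seed, "panel"),
            )
            pedigree = synthetic_data.make_pedigree(
                config.n_families, config.n_offspring,
                seed=substream(config.seed, "pedigree"),
            )
            candidates, truth_cand = synthetic_data.simulate_candidate_variants(
                genome, panel, config.n_candidate_sites,
                psv_fraction=config.psv_fraction, depth_mean=config.depth_mean,
                error_rate=config.error_rate,
                seed=substream(config.seed, "candidates"),
            )
            marker_map = _marker_map(config)
            family_geno, truth_fam = synthetic_data.simulate_family_genotypes(
                pedigree, marker_map, male_recomb=0.0,
                seed=substream(config.seed, "families"),
            )
            pop_geno, _ = _population_genotypes(
                config, family_geno.marker_ids, panel,
                substream(config.seed, "populations"),
            )
            full_geno = pd.concat([family_geno.genotypes, pop_geno], axis=1)
            io.write_candidates_vcf(candidates, outdir / "candidates.vcf")
            io.write_candidates_tsv(candidates, outdir / "candidates.tsv")
            io.write_ped(pedigree, outdir / "pedigree.ped")
            truth_cand.candidate_class.to_csv(outdir / "truth_candidates.tsv", sep="\t")
            manifest.record("simulate", 0, len(candidates))

        if on.get("filter", True) and candidates is not None:
            kept, ledger = variant_filtering.run_rr_pipeline(
                candidates, gq_threshold=config.gq_threshold
            )
            ledger.to_csv(outdir / "filter_ledger.tsv", sep="\t", index=False)
            io.write_candidates_tsv(kept, outdir / "candidates_filtered.tsv")
            manifest.record("filter", len(candidates), len(kept))
            candidates = kept

        if on.get("call", True) and full_geno is not None:
            from . import genotype_clustering

            intensities, truth_int = synthetic_data.simulate_intensities(
                full_geno,
                geometry=ClusterGeometry(),
                msv_fraction=config.msv_fraction,
                otv_fraction=config.otv_fraction,
                seed=substream(config.seed, "intensities"),
            )
            io.write_intensities_tsv(intensities, outdir / "intensities.tsv")
            calls = genotype_clustering.call_intensity_table(
                intensities, otv=True,
                confidence_threshold=config.confidence_threshold,
            )
            calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
            manifest.record(
                "call", intensities["probeset_id"].nunique(),
                calls["probeset_id"].nunique(),
            )

        if on.get("qc", True) and calls is not None:
            thresholds = snp_qc.QCThresholds(
                call_rate=config.call_rate_threshold,
                min_minor_samples=config.min_minor_samples,
            )
            qc = snp_qc.classify_calls_table(calls, thresholds, pedigree)
            qc.to_csv(outdir / "snp_qc.tsv", sep="\t", index=False)
            retained = qc[
                qc["category"].isin(snp_qc.RETAINED_CATEGORIES) & qc["mendelian_pass"]
            ]
            manifest.record("qc", len(qc), len(retained))
            qc_retained_ids = set(retained["probeset_id"])
        else:
            qc_retained_ids = None

        if on.get("map", True) and calls is not None and pedigree is not None:
            called_geno = _calls_to_genotype_matrix(calls, family_geno)
            if qc_retained_ids is not None:
                keep = [m for m in called_geno.marker_ids if m in qc_retained_ids]
                called_geno = GenotypeMatrix(
                    genotypes=called_geno.genotypes.loc[keep],
                    markers=called_geno.markers.loc[keep],
                )
            anchors = _pick_anchors(called_geno, pedigree)
            groups = linkage_grouping.assign_chromosomes(
                called_geno, pedigree, anchors
            )
            groups.to_csv(outdir / "linkage_groups.tsv", sep="\t")
            per_chrom = (
                groups.dropna(subset=["chromosome"])
                .groupby("chromosome")
                .size()
                .rename("n_snps")
            )
            per_chrom.to_csv(outdir / "snps_per_chromosome.tsv", sep="\t")
            manifest.record(
                "map", len(groups), int(groups["chromosome"].notna().sum())
            )

        if on.get("popstruct", True) and full_geno is not None:
            unrelated = [s.id for s in panel.samples if s.ploidy == 2]
            parents = [
                i.id for i in pedigree.individuals if i.sire is None and i.dam is None
            ]
            cols = [c for c in full_geno.columns if c in set(unrelated) | set(parents)]
            maf = population_structure.population_maf(full_geno, panel)
            maf.to_csv(outdir / "population_maf.tsv", sep="\t")
            venn = population_structure.venn_sharing(maf, config.maf_threshold)
            (outdir / "venn_sharing.json").write_text(json.dumps(venn, indent=1))
            dist, _ = population_structure.ibs_distance_matrix(full_geno[cols])
            dist.to_csv(outdir / "ibs_distances.tsv", sep="\t")
            mds = population_structure.classical_mds(dist, k=2)
            mds.coordinates.to_csv(outdir / "mds_coordinates.tsv", sep="\t")
            manifest.record("popstruct", len(full_geno), len(cols))

        if on.get("sex", True) and panel is not None:
            y_table, truth_y = synthetic_data.simulate_y_probe_intensities(
                panel, n_probes=config.n_y_probes,
                male_level=config.y_male_level,
                female_level=config.y_female_level,
                noise_sd=config.y_noise_sd,
                seed=substream(config.seed, "yprobes"),
            )
            y_table.to_csv(outdir / "y_intensities.tsv", sep="\t", index=False)
            sex_calls = sexing.call_sex_from_y_probes(y_table)
            sex_calls.to_csv(outdir / "sex_calls.tsv", sep="\t", index=False)
            conc = sexing.concordance(sex_calls, truth_y.sample_sex)
            (outdir / "sex_concordance.json").write_text(
                json.dumps({"concordance": conc, "n_known": int(len(truth_y.sample_sex))})
            )
            manifest.record("sex", len(y_table), len(sex_calls), concordance=conc)
    finally:
        (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _calls_to_genotype_matrix(
    calls: pd.DataFrame, family_geno: GenotypeMatrix | None
) -> GenotypeMatrix:
    """Pivot called genotypes back into a marker x sample int matrix."""
    code = {"AA": 0, "AB": 1, "BB": 2}
    wide = calls.pivot_table(
        index="probeset_id", columns="sample_id", values="call", aggfunc="first"
    )
    geno = wide.apply(lambda col: col.map(lambda v: code.get(v, -1))).astype(np.int8)
    if family_geno is not None:
        markers = family_geno.markers.reindex(geno.index)
    else:
        markers = pd.DataFrame(index=geno.index, columns=["chrom", "pos"])
    return GenotypeMatrix(genotypes=geno, markers=markers)


def _pick_anchors(
    genotypes: GenotypeMatrix, pedigree: synthetic_data.Pedigree
) -> dict[str, str]:
    """One sire-informative anchor marker per chromosome (known labels)."""
    trans = linkage_grouping.select_sire_informative(genotypes, pedigree)
    informative = set(trans.marker_ids)
    anchors: dict[str, str] = {}
    for mk, row in genotypes.markers.iterrows():
        chrom = row["chrom"]
        if pd.isna(chrom) or chrom in anchors.values():
            continue
        if mk in informative:
            anchors[mk] = chrom
    return anchors
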