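"""Synthetic data generators for the duplicated-genome SNP-array pipeline.

Every generator is a pure function of its arguments (including ``seed``)
and returns, alongside the simulated tables, the ground-truth labels needed
to score the downstream operators.  The generators emulate the statistical
structure of a salmonid SNP-array study:

* a genome in which a configurable fraction of sequence exists in
  paralogous duplicate copies (the residue of an ancestral whole-genome
  duplication), so that a fixed difference between paralogues masquerades
  as a SNP (a paralogous sequence variant, PSV);
* a discovery panel that includes one *haploid* individual whose apparent
  heterozygosity is diagnostic of paralogy;
* pedigreed families in which the sire transmits whole chromosomes without
  recombination, while the dam recombines at a normal female rate;
* two-channel array intensities with three genotype clusters in
  contrast/size space, plus shifted multi-site-variant (MSV) clusters and a
  low-intensity off-target-variant (OTV) cluster;
* populations drifted apart from shared ancestral allele frequencies; and
* Y-specific probes whose intensity is bimodal by sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "ParalogPair",
    "Sample",
    "PopulationPanel",
    "Pedigree",
    "Individual",
    "TruthLabels",
    "GenotypeMatrix",
    "ClusterGeometry",
    "make_genome",
    "make_panel",
    "make_pedigree",
    "simulate_candidate_variants",
    "simulate_family_genotypes",
    "simulate_intensities",
    "simulate_y_probe_intensities",
]

# Genotypes are coded as the count of the B allele: 0=AA, 1=AB, 2=BB, -1=missing.
MISSING = -1
GENOTYPE_NAMES = {0: "AA", 1: "AB", 2: "BB", MISSING: "NN"}
GENOTYPE_CODES = {v: k for k, v in GENOTYPE_NAMES.items()}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParalogPair:
    """A pair of duplicated regions; coordinates are 0-based half-open."""

    contig_a: str
    start_a: int
    end_a: int
    contig_b: str
    start_b: int
    end_b: int


@dataclass
class GenomeModel:
    contigs: list[tuple[str, int]]
    duplicated_pairs: list[ParalogPair]
    seed: int

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.contigs)

    def duplicated_fraction_realized(self) -> float:
        """Fraction of total sequence inside either member of a paralog pair."""
        dup = sum(
            (p.end_a - p.start_a) + (p.end_b - p.start_b)
            for p in self.duplicated_pairs
        )
        return dup / self.total_length if self.total_length else 0.0


@dataclass(frozen=True)
class Sample:
    id: str
    population: str
    sex: str  # "male" | "female" | "unknown"
    ploidy: int = 2


@dataclass
class PopulationPanel:
    """Samples with population labels plus per-population drift parameters.

    ``divergence`` maps each population label to a Balding–Nichols style
    drift parameter F in (0, 1): present-day population frequencies are
    beta-distributed around the shared ancestral frequency with variance
    F * p * (1 - p).
    """

    samples: list[Sample]
    divergence: dict[str, float]

    def __post_init__(self) -> None:
        labels = {s.population for s in self.samples}
        missing = labels - set(self.divergence)
        if missing:
            raise ValueError(f"no divergence parameter for populations: {sorted(missing)}")
        for label, f in self.divergence.items():
            if not 0 < f < 1:
                raise ValueError(f"divergence for {label!r} must be in (0,1), got {f}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def population_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.id == sample_id:
                return s.population
        raise KeyError(sample_id)


@dataclass(frozen=True)
class Individual:
    id: str
    sire: str | None
    dam: str | None
    family: str
    sex: str = "unknown"


@dataclass
class Pedigree:
    individuals: list[Individual]

    def __post_init__(self) -> None:
        ids = {i.id for i in self.individuals}
        for ind in self.individuals:
            for parent in (ind.sire, ind.dam):
                if parent is not None and parent not in ids:
                    raise ValueError(
                        f"individual {ind.id!r} names unknown parent {parent!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {i.id: (i.sire, i.dam) for i in self.individuals}

        def ancestors(x: str, seen: set[str]) -> None:
            for p in parents.get(x, (None, None)):
                if p is None:
                    continue
                if p in seen:
                    raise ValueError(f"pedigree cycle involving {p!r}")
                ancestors(p, seen | {p})

        for i in self.individuals:
            ancestors(i.id, {i.id})

    def families(self) -> dict[str, list[Individual]]:
        out: dict[str, list[Individual]] = {}
        for ind in self.individuals:
            out.setdefault(ind.family, []).append(ind)
        return out

    def trios(self) -> list[Individual]:
        """Individuals with both parents present in the pedigree."""
        return [i for i in self.individuals if i.sire is not None and i.dam is not None]

    def to_ped_frame(self) -> pd.DataFrame:
        sex_code = {"male": 1, "female": 2, "unknown": 0}
        return pd.DataFrame(
            {
                "family": [i.family for i in self.individuals],
                "id": [i.id for i in self.individuals],
                "sire": [i.sire or "0" for i in self.individuals],
                "dam": [i.dam or "0" for i in self.individuals],
                "sex": [sex_code.get(i.sex, 0) for i in self.individuals],
                "phenotype": [-9] * len(self.individuals),
            }
        )


@dataclass
class TruthLabels:
    """Ground truth emitted by the generators, one table per aspect."""

    candidate_class: pd.Series | None = None  # index snp id -> {"snp","psv","error"}
    probeset_class: pd.Series | None = None  # index probeset id -> {"plain","msv","otv"}
    otv_samples: dict[str, set[str]] = field(default_factory=dict)
    marker_chromosome: pd.Series | None = None  # index marker id -> chromosome
    true_genotypes: pd.DataFrame | None = None  # marker x sample, int codes
    sample_sex: pd.Series | None = None  # index sample id -> {"male","female"}


@dataclass
class GenotypeMatrix:
    """Called/true genotypes: markers x samples, int codes (0/1/2, -1 missing)."""

    genotypes: pd.DataFrame  # index marker id, columns sample id, dtype int8
    markers: pd.DataFrame  # index marker id, columns [chrom, pos]

    def __post_init__(self) -> None:
        if not self.genotypes.index.equals(self.markers.index):
            raise ValueError("genotype and marker tables disagree on marker ids")

    @property
    def marker_ids(self) -> pd.Index:
        return self.genotypes.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.genotypes.columns


@dataclass
class ClusterGeometry:
    """Three-cluster geometry in contrast/size space (A-positive convention)."""

    contrast_means: tuple[float, float, float] = (1.5, 0.0, -1.5)  # AA, AB, BB
    size_mean: float = 10.0
    contrast_sd: float = 0.12
    size_sd: float = 0.12
    replicate_sd: float = 0.05  # probe-replicate jitter around the sample point
    msv_contrast_shift: float = 0.75  # shift toward the fixed paralogue's allele
    otv_size_offset: float = 2.0  # OTV cluster sits this far below the size mean
    min_separation: float = 0.5

    def __post_init__(self) -> None:
        aa, ab, bb = self.contrast_means
        if not (aa > ab > bb):
            raise ValueError("contrast means must be ordered AA > AB > BB")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def make_genome(
    n_contigs: int,
    mean_length: int = 10_000,
    duplicated_fraction: float = 0.25,
    seed: int = 0,
) -> GenomeModel:
    """Draw a contig set and carve paralogous region pairs out of it.

    Each contig contributes a duplicated region pair covering (in total)
    ``duplicated_fraction`` of its length: one region in the first half of
    the contig paired with an equally sized region in the second half.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if not 0 <= duplicated_fraction <= 1:
        raise ValueError("duplicated_fraction must be in [0, 1]")
    if mean_length <= 0:
        raise ValueError("mean_length must be positive")
    rng = np.random.default_rng(seed)
    # contig lengths: gamma around the mean, floored so every contig can hold a SNP
    lengths = np.maximum(rng.gamma(shape=4.0, scale=mean_length / 4.0, size=n_contigs), 200)
    lengths = lengths.astype(int)
    contigs = [(f"contig{i + 1}", int(l)) for i, l in enumerate(lengths)]

    pairs: list[ParalogPair] = []
    if duplicated_fraction > 0:
        for name, length in contigs:
            half = length // 2
            region = int(round(duplicated_fraction * length / 2))
            if region < 1:
                continue
            region = min(region, half)
            # jitter the placement inside each half when there is slack
            slack_a = half - region
            slack_b = (length - half) - region
            start_a = int(rng.integers(0, slack_a + 1)) if slack_a > 0 else 0
            start_b = half + (int(rng.integers(0, slack_b + 1)) if slack_b > 0 else 0)
            pairs.append(
                ParalogPair(name, start_a, start_a + region, name, start_b, start_b + region)
            )
    return GenomeModel(contigs=contigs, duplicated_pairs=pairs, seed=seed)


def make_panel(
    pop_sizes: dict[str, int],
    divergence: dict[str, float] | None = None,
    haploid_sample: bool = False,
    sex_ratio: float = 0.5,
    seed: int = 0,
) -> PopulationPanel:
    """Build a sample panel with population labels, sexes and optional haploid.

    The default divergence of 0.05 per population is a typical F_ST-scale
    drift for recently separated farmed/wild salmon strains.
    """
    rng = np.random.default_rng(seed)
    divergence = dict(divergence or {})
    samples: list[Sample] = []
    for pop, n in pop_sizes.items():
        divergence.setdefault(pop, 0.05)
        for i in range(n):
            sex = "male" if rng.random() < sex_ratio else "female"
            samples.append(Sample(id=f"{pop}_{i + 1}", population=pop, sex=sex, ploidy=2))
    if haploid_sample:
        pop = next(iter(pop_sizes))
        samples.append(Sample(id="haploid_1", population=pop, sex="unknown", ploidy=1))
    return PopulationPanel(samples=samples, divergence=divergence)


def make_pedigree(
    n_families: int = 2,
    n_offspring: int = 10,
    seed: int = 0,
) -> Pedigree:
    """Reference-family pedigree: each family has a sire, a dam and offspring."""
    rng = np.random.default_rng(seed)
    inds: list[Individual] = []
    for f in range(1, n_families + 1):
        fam = f"fam{f}"
        inds.append(Individual(id=f"{fam}_sire", sire=None, dam=None, family=fam, sex="male"))
        inds.append(Individual(id=f"{fam}_dam", sire=None, dam=None, family=fam, sex="female"))
        for o in range(1, n_offspring + 1):
            sex = "male" if rng.random() < 0.5 else "female"
            inds.append(
                Individual(
                    id=f"{fam}_off{o}",
                    sire=f"{fam}_sire",
                    dam=f"{fam}_dam",
                    family=fam,
                    sex=sex,
                )
            )
    return Pedigree(individuals=inds)


def _population_freqs(
    ancestral: np.ndarray, divergence: dict[str, float], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Balding–Nichols drift: p_pop ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    out = {}
    for pop, f in divergence.items():
        a = ancestral * (1 - f) / f
        b = (1 - ancestral) * (1 - f) / f
        out[pop] = rng.beta(np.maximum(a, 1e-6), np.maximum(b, 1e-6))
    return out


def simulate_candidate_variants(
    genome: GenomeModel,
    panel: PopulationPanel,
    n_sites: int,
    psv_fraction: float = 0.2,
    depth_mean: int = 30,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthLabels]:
    """Simulate a candidate-variant table mixing true SNPs with PSVs.

    True SNPs segregate in the panel at Balding–Nichols-drifted population
    frequencies; PSV sites are fixed differences between collapsed
    paralogous regions, so *every* diploid shows a heterozygous pileup and,
    critically, so does the haploid sample (its reads sample both
    paralogues).  Read depths are Poisson around ``depth_mean``; base calls
    flip with probability ``error_rate``.

    Returns the candidate table (one row per site) and truth labels.
    """
    if not 0 <= psv_fraction <= 1:
        raise ValueError("psv_fraction must be in [0, 1]")
    if depth_mean < 1:
        raise ValueError("depth_mean must be >= 1")
    if not panel.samples:
        raise ValueError("panel has no samples")
    rng = np.random.default_rng(seed)

    nucleotides = np.array(list("ACGT"))
    contig_names = [c for c, _ in genome.contigs]
    contig_lengths = np.array([l for _, l in genome.contigs], dtype=float)
    contig_idx = rng.choice(
        len(contig_names), size=n_sites, p=contig_lengths / contig_lengths.sum()
    )
    positions = (rng.random(n_sites) * contig_lengths[contig_idx]).astype(int) + 1

    is_psv = rng.random(n_sites) < psv_fraction
    ancestral = rng.uniform(0.05, 0.95, size=n_sites)
    pop_freqs = _population_freqs(ancestral, panel.divergence, rng)

    diploids = [s for s in panel.samples if s.ploidy == 2]
    haploids = [s for s in panel.samples if s.ploidy == 1]
    haploid = haploids[0] if haploids else None

    rows = []
    truth_class = []
    sources = rng.choice(["RR", "RAD", "RNA"], size=n_sites, p=[0.3, 0.3, 0.4])
    for i in range(n_sites):
        ref, alt = rng.choice(nucleotides, size=2, replace=False)
        site_freq = {pop: pop_freqs[pop][i] for pop in pop_freqs}

        # pooled read sampling over the diploid panel
        depth = max(1, int(rng.poisson(depth_mean)))
        if is_psv[i]:
            # collapsed paralogues: half the reads carry each "allele"
            alt_frac = 0.5
        else:
            # each read drawn from a random panel member's true genotype
            mean_freq = float(np.mean([site_freq[s.population] for s in diploids]))
            alt_frac = mean_freq
        alt_reads = rng.binomial(depth, alt_frac)
        if error_rate > 0:
            flips_to_alt = rng.binomial(depth - alt_reads, error_rate)
            flips_to_ref = rng.binomial(alt_reads, error_rate)
            alt_reads = alt_reads + flips_to_alt - flips_to_ref
        pooled_af = alt_reads / depth

        # haploid genotype call
        hap_call, hap_gq = "missing", 0.0
        if haploid is not None:
            hdepth = max(1, int(rng.poisson(depth_mean)))
            if is_psv[i]:
                n_alt = rng.binomial(hdepth, 0.5)
            else:
                hap_allele = rng.random() < site_freq[haploid.population]
                n_alt = hdepth if hap_allele else 0
            if error_rate > 0:
                n_alt += rng.binomial(hdepth - n_alt, error_rate)
                n_alt -= rng.binomial(min(n_alt, hdepth), error_rate)
                n_alt = int(np.clip(n_alt, 0, hdepth))
            n_ref = hdepth - n_alt
            minor = min(n_ref, n_alt)
            major = hdepth - minor
            # likelihood call: hom treats minor reads as errors, het as a
            # 50/50 draw from two collapsed paralogues
            e = max(error_rate, 1e-4)
            log_hom = major * np.log(1 - e) + minor * np.log(e)
            log_het = hdepth * np.log(0.5)
            hap_call = "het" if (log_het > log_hom and minor >= 2) else "hom"
            hap_gq = min(abs(log_hom - log_het) * 10 / np.log(10), 99.0)

        rows.append(
            {
                "id": f"snp{i + 1}",
                "contig": contig_names[contig_idx[i]],
                "pos": int(positions[i]),
                "ref": str(ref),
                "alt": str(alt),
                "source": str(sources[i]),
                "pooled_af": pooled_af,
                "depth": depth,
                "haploid_call": hap_call,
                "haploid_gq": round(hap_gq, 2),
                "conversion_score": float(rng.beta(2.0, 2.0)),
                "ancestral_freq": float(ancestral[i]),
            }
        )
        truth_class.append("psv" if is_psv[i] else "snp")

    table = pd.DataFrame(rows).set_index("id", drop=False)
    truth = TruthLabels(
        candidate_class=pd.Series(truth_class, index=table.index, name="truth_class")
    )
    return table, truth


def simulate_family_genotypes(
    pedigree: Pedigree,
    marker_map: dict[str, np.ndarray],
    male_recomb: float = 0.0,
    female_recomb_per_mb: float = 1.0,
    founder_freq: float | np.ndarray = 0.5,
    genotyping_error: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, TruthLabels]:
    """Drop genotypes through a pedigree with sex-specific recombination.

    ``marker_map`` maps chromosome name -> sorted 1-based bp positions.
    With ``male_recomb`` = 0 each offspring inherits one intact sire
    haplotype per chromosome; with probability ``male_recomb`` a single
    crossover is placed uniformly instead.  Dam transmissions recombine as
    a Poisson process at ``female_recomb_per_mb`` crossovers per megabase.
    Output is Mendelian-consistent by construction unless
    ``genotyping_error`` > 0.
    """
    for chrom, pos in marker_map.items():
        pos = np.asarray(pos)
        if pos.ndim != 1 or len(pos) == 0:
            raise ValueError(f"chromosome {chrom!r} has no marker positions")
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"marker positions on {chrom!r} must be sorted")
    rng = np.random.default_rng(seed)

    chroms = list(marker_map)
    marker_ids: list[str] = []
    marker_chrom: list[str] = []
    marker_pos: list[int] = []
    for chrom in chroms:
        for j, p in enumerate(np.asarray(marker_map[chrom])):
            marker_ids.append(f"{chrom}_m{j + 1}")
            marker_chrom.append(chrom)
            marker_pos.append(int(p))
    n_markers = len(marker_ids)
    freqs = np.broadcast_to(np.asarray(founder_freq, dtype=float), (n_markers,)).copy()

    # haplotypes: individual -> (hap0, hap1) arrays over all markers (0/1 = A/B)
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chrom_slices: dict[str, slice] = {}
    start = 0
    for chrom in chroms:
        n = len(np.asarray(marker_map[chrom]))
        chrom_slices[chrom] = slice(start, start + n)
        start += n

    def founder_haps() -> tuple[np.ndarray, np.ndarray]:
        return (
            (rng.random(n_markers) < freqs).astype(np.int8),
            (rng.random(n_markers) < freqs).astype(np.int8),
        )

    def transmit(parent: str, is_sire: bool) -> np.ndarray:
        h0, h1 = haplotypes[parent]
        gamete = np.empty(n_markers, dtype=np.int8)
        for chrom in chroms:
            sl = chrom_slices[chrom]
            pos = np.asarray(marker_map[chrom], dtype=float)
            phase = int(rng.integers(2))
            src = np.full(len(pos), phase, dtype=np.int8)
            if is_sire:
                if male_recomb > 0 and rng.random() < male_recomb:
                    cut = rng.uniform(pos[0], pos[-1]) if len(pos) > 1 else pos[0]
                    src[pos > cut] = 1 - phase
            else:
                length_mb = (pos[-1] - pos[0]) / 1e6 if len(pos) > 1 else 0.0
                n_cross = rng.poisson(female_recomb_per_mb * length_mb)
                for _ in range(n_cross):
                    cut = rng.uniform(pos[0], pos[-1])
                    src[pos > cut] = 1 - src[pos > cut]
            chrom_gamete = np.where(src == 0, h0[sl], h1[sl])
            gamete[sl] = chrom_gamete
        return gamete

    # topological fill: founders first, then individuals whose parents are done
    remaining = list(pedigree.individuals)
    while remaining:
        progressed = False
        for ind in list(remaining):
            sire_ok = ind.sire is None or ind.sire in haplotypes
            dam_ok = ind.dam is None or ind.dam in haplotypes
            if not (sire_ok and dam_ok):
                continue
            if ind.sire is None and ind.dam is None:
                haplotypes[ind.id] = founder_haps()
            else:
                pat = (
                    transmit(ind.sire, is_sire=True)
                    if ind.sire is not None
                    else founder_haps()[0]
                )
                mat = (
                    transmit(ind.dam, is_sire=False)
                    if ind.dam is not None
                    else founder_haps()[0]
                )
                haplotypes[ind.id] = (pat, mat)
            remaining.remove(ind)
            progressed = True
        if not progressed:
            raise ValueError("pedigree is not resolvable (cycle or missing parents)")

    sample_ids = [i.id for i in pedigree.individuals]
    geno = np.empty((n_markers, len(sample_ids)), dtype=np.int8)
    for j, sid in enumerate(sample_ids):
        h0, h1 = haplotypes[sid]
        geno[:, j] = h0 + h1
    true_geno = geno.copy()
    if genotyping_error > 0:
        flip = rng.random(geno.shape) < genotyping_error
        noise = rng.integers(0, 3, size=geno.shape).astype(np.int8)
        geno = np.where(flip, noise, geno).astype(np.int8)

    genotypes = pd.DataFrame(geno, index=pd.Index(marker_ids, name="marker"), columns=sample_ids)
    markers = pd.DataFrame(
        {"chrom": marker_chrom, "pos": marker_pos}, index=genotypes.index
    )
    truth = TruthLabels(
        marker_chromosome=pd.Series(marker_chrom, index=genotypes.index, name="chrom"),
        true_genotypes=pd.DataFrame(true_geno, index=genotypes.index, columns=sample_ids),
        sample_sex=pd.Series(
            {i.id: i.sex for i in pedigree.individuals}, name="sex"
        ),
    )
    return GenotypeMatrix(genotypes=genotypes, markers=markers), truth


def simulate_intensities(
    genotypes: GenotypeMatrix | pd.DataFrame,
    geometry: ClusterGeometry | None = None,
    msv_fraction: float = 0.0,
    otv_fraction: float = 0.0,
    otv_sample_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthLabels]:
    """Emit two-channel probe intensities for each marker (probeset) x sample.

    Each sample's latent (contrast, size) point is drawn from the Gaussian
    cluster of its genotype; two probe replicates are jittered around that
    point and back-transformed to linear A/B signals (log2 convention).
    MSV probesets have all contrast means shifted toward the fixed
    paralogue's allele; OTV probesets relocate a random subset of samples
    to a zero-contrast, low-size cluster.
    """
    import warnings

    geometry = geometry or ClusterGeometry()
    geno = genotypes.genotypes if isinstance(genotypes, GenotypeMatrix) else genotypes
    rng = np.random.default_rng(seed)

    means = np.asarray(geometry.contrast_means, dtype=float)
    if np.min(np.abs(np.diff(means))) < geometry.min_separation:
        warnings.warn(
            "cluster contrast means are closer than the configured separation",
            stacklevel=2,
        )

    probeset_ids = list(geno.index)
    sample_ids = list(geno.columns)
    n_ps = len(probeset_ids)
    is_msv = rng.random(n_ps) < msv_fraction
    is_otv = rng.random(n_ps) < otv_fraction
    # a probeset is labelled by its dominant anomaly; OTV wins ties
    ps_class = np.where(is_otv, "otv", np.where(is_msv, "msv", "plain"))

    rows: dict[str, list] = {
        "probeset_id": [],
        "probe_replicate": [],
        "sample_id": [],
        "signal_A": [],
        "signal_B": [],
    }
    otv_samples: dict[str, set[str]] = {}
    for pi, ps in enumerate(probeset_ids):
        shift = geometry.msv_contrast_shift if ps_class[pi] == "msv" else 0.0
        g_row = geno.loc[ps].to_numpy()
        affected: set[str] = set()
        if ps_class[pi] == "otv":
            mask = rng.random(len(sample_ids)) < otv_sample_fraction
            if not mask.any():
                mask[rng.integers(len(sample_ids))] = True
            affected = {sample_ids[k] for k in np.flatnonzero(mask)}
            otv_samples[ps] = affected
        for si, sid in enumerate(sample_ids):
            g = int(g_row[si])
            if sid in affected:
                c = rng.normal(0.0, geometry.contrast_sd)
                s = rng.normal(
                    geometry.size_mean - geometry.otv_size_offset, geometry.size_sd
                )
            else:
                if g == MISSING:
                    g = int(rng.integers(0, 3))
                c = rng.normal(means[g] + shift, geometry.contrast_sd)
                s = rng.normal(geometry.size_mean, geometry.size_sd)
            for rep in (1, 2):
                cj = c + rng.normal(0.0, geometry.replicate_sd)
                sj = s + rng.normal(0.0, geometry.replicate_sd)
                rows["probeset_id"].append(ps)
                rows["probe_replicate"].append(rep)
                rows["sample_id"].append(sid)
                rows["signal_A"].append(float(2.0 ** (sj + cj / 2)))
                rows["signal_B"].append(float(2.0 ** (sj - cj / 2)))
    table = pd.DataFrame(rows)
    truth = TruthLabels(
        probeset_class=pd.Series(ps_class, index=pd.Index(probeset_ids, name="probeset_id")),
        otv_samples=otv_samples,
        true_genotypes=geno.copy(),
    )
    return table, truth


def simulate_y_probe_intensities(
    panel: PopulationPanel,
    n_probes: int = 87,
    male_level: float = 10.0,
    female_level: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthLabels]:
    """Single-channel intensities for Y-specific probes, bimodal by sex.

    Males carry the male-specific sdY fragment so their probes hybridise at
    ``male_level``; females only produce background at ``female_level``.
    Returns a long table (probe_id, sample_id, signal) plus truth sexes.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if not male_level > female_level >= 0:
        raise ValueError("male_level must exceed female_level >= 0")
    rng = np.random.default_rng(seed)
    probe_effect = rng.normal(0.0, noise_sd * 0.2, size=n_probes) if noise_sd > 0 else np.zeros(n_probes)
    rows = {"probe_id": [], "sample_id": [], "signal": []}
    sexes = {}
    for s in panel.samples:
        sex = s.sex if s.sex in ("male", "female") else "female"
        sexes[s.id] = sex
        level = male_level if sex == "male" else female_level
        noise = rng.normal(0.0, noise_sd, size=n_probes) if noise_sd > 0 else np.zeros(n_probes)
        signals = level + probe_effect + noise
        for p in range(n_probes):
            rows["probe_id"].append(f"Yprobe{p + 1}")
            rows["sample_id"].append(s.id)
            rows["signal"].append(float(signals[p]))
    table = pd.DataFrame(rows)
    truth = TruthLabels(sample_sex=pd.Series(sexes, name="sex"))
    return table, truth
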