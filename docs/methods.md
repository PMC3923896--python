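# Methods

This note documents the models, parameter choices and numerical decisions
behind `dupsnp`, and what the synthetic-data experiments do and do not
demonstrate about real array data.

## The problem

In a genome that retains an ancient whole-genome duplication, three
artefacts dominate SNP-array design and analysis. First, reads from two
paralogous loci co-align, so a fixed difference between paralogues looks
like a heterozygous SNP (a PSV); in a haploid individual, where true
heterozygosity is impossible, such apparent heterozygosity is diagnostic.
Second, an array probe may hybridise to both paralogues: if one paralogue
segregates (A/B) while the other is fixed (A/A), the bi-locus genotypes
AAAA/AAAB/AABB produce three clusters shifted toward the fixed allele (an
MSV). Third, a variant under the probe's flanking sequence can abolish
hybridisation on one haplotype, collapsing affected samples into a
low-intensity, zero-contrast cluster easily miscalled heterozygous (an
OTV). The package implements the discovery filters, the intensity-based
caller and the downstream analyses that confront each artefact.

## Synthetic data: what it emulates

Generators are pure functions of their arguments including the seed, and
every generator returns the truth labels needed to score downstream
operators.

- **Genome.** Contig lengths are gamma-distributed (shape 4) around a
  configurable mean; each contig contributes one pair of equal duplicated
  regions totalling `duplicated_fraction` of its length. Only region
  bookkeeping is simulated — no nucleotide sequence, since no consumer
  needs it.
- **Populations.** Present-day allele frequencies drift from a shared
  ancestral frequency under the Balding–Nichols model,
  `p_pop ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`. Default drift parameters
  (0.05–0.12) are in the F_ST range typical of recently separated farmed
  and wild salmon strains; the study populations' true divergences are
  not published, so these are free scenario parameters.
- **Candidate variants.** Pooled read depth is Poisson around
  `depth_mean` (default 30). PSV sites draw reads 50/50 from the two
  collapsed paralogues, for diploids and — crucially — for the haploid
  sample; true SNP sites give the haploid a single allele. The haploid
  genotype is called by likelihood (hom: minor reads are errors at rate
  `max(error_rate, 1e-4)`; het: Binomial(½)), with a Phred-scale quality
  capped at 99. Conversion scores (the externally supplied probability
  that a SNP converts to a working assay) are Beta(2,2) stand-ins: the
  real scorer is proprietary and only the *selection logic* that consumes
  the score is in scope.
- **Families.** Offspring receive one intact sire haplotype per
  chromosome (male recombination rate 0 by default, a single uniform
  crossover with probability `male_recomb` otherwise) and a dam gamete
  recombined as a Poisson process (default 1 crossover/Mb). Male
  recombination is modelled as a per-chromosome rate rather than a
  centromere-proximal block because the grouping procedure exploits only
  its total absence, not its position.
- **Intensities.** Noise is Gaussian in contrast/size space — the space
  the caller clusters in — not in raw channel space; generator and caller
  share the log2 convention, and signals are back-transformed via
  `A = 2^(size + contrast/2)`, `B = 2^(size − contrast/2)`. Each probeset
  emits two replicate probe values per sample (replicate jitter SD 0.05).
  Default geometry: contrast means (+1.5, 0, −1.5), size mean 10, cluster
  SD 0.12, MSV shift +0.75, OTV cluster 2 units below the size mean.
- **Y probes.** 87 probes (the array's sdY probe count); male level 10,
  female background 2, per-probe and per-sample Gaussian noise (SD 0.5
  default, i.e. a 16-SD separation; the sexing guard needs ≥ 3 SD).

What passing tests on these data do **not** show: robustness to spatial
array artefacts, batch effects, DNA quality variation, allele-specific
amplification bias, or mis-specified pedigrees — none of which the
generators model.

## Genotype calling

The caller follows the Axiom staging: per-channel quantile normalization
across samples (rank-average ties, reference = mean of sorted vectors),
Tukey median polish of the log2 replicate × sample matrix (tolerance
1e-6, 10 sweeps; per-sample summary = overall + column effect), then
clustering in contrast/size space.

Initial labels come from an exhaustive scan of the O(n²) placements of
two vertical boundaries on the contrast axis (degenerate placements give
one- and two-cluster labelings). Each candidate labeling is scored by the
sum of per-segment Gaussian log-likelihoods around the segment mean using
the prior cluster SD, plus the log prior density of the segment mean
under that cluster's prior — so sparse or empty clusters are penalised
toward the prior geometry. Sorted segments map left-to-right onto
BB/AB/AA (A-positive convention).

The prior mixture is then updated cluster-by-cluster with a conjugate
pseudo-count blend: posterior mean `(ν·m0 + n·x̄)/(ν + n)`, covariance
blended with the same weights (plus a 1e-6 variance floor), weights
∝ ν + n. The published description of the production algorithm says only
that the update is "Bayesian" and that posteriors are reusable as priors;
the blend is the simplest update satisfying that reuse property, and the
model JSON flags it as such. Default prior: means (±1.5, 0) contrast,
common size mean 10, diagonal covariance 0.05, ν = 1 per cluster. Calls
are argmax responsibilities; confidence is the winning responsibility,
with no-call below 0.95 (configurable — the production confidence scale
is proprietary).

MSV probesets get no special caller: the shifted three-cluster geometry
is absorbed by the adaptive prior update, which is exactly the
adaptability argument for Bayesian re-positioning of pre-set clusters.

OTV detection augments the fitted mixture with a fourth component and
runs plain EM (tolerance 1e-8, ≤ 200 iterations, variance floor 1e-4).
The component is seeded from the data: points whose size falls more than
half the configured offset below the median cluster size initialise its
mean and weight; absent such points it starts at contrast 0, size =
lowest cluster mean − offset, weight 1/(n+1). Seeding from the actual
low-size points matters because those points inflate the heterozygote
cluster's covariance during the initial fit, and a poorly seeded OTV
component then loses the likelihood competition against that inflated
cluster. Samples with maximal responsibility for the component are
relabelled OTV; an empty component leaves calls unchanged.

## QC categories and the ledger

Decision order: OTV flag → call rate < 0.97 → cluster-separation below
floor (default 3 pooled-SD units; the published category list names no
numeric cluster-quality cutoffs) → minor allele in < 2 samples →
no-minor-homozygote (zero samples in the minor-homozygote cluster while
MAF > 0) → polymorphic high resolution. Only the polymorphic
high-resolution and no-minor-homozygote categories are retained
downstream. The accounting ledger maps the six categories onto the three
exclusion rows of the published accounting (low-quality = call-rate +
OTV + other; monomorphic = monomorphic high resolution; Mendelian =
retained categories failing the pedigree filter) and enforces
`final = total − lowquality − monomorphic − mendelian` per source column.
The pedigree filter is zero-tolerance (any trio-incompatible genotype
fails the SNP); missing genotypes never count as errors.

## Linkage grouping

Sire-informative markers (sire AB × dam homozygous in ≥ 1 family) yield
per-offspring transmitted sire alleles by subtracting the dam's obligate
contribution. For a marker pair, each family contributes recombinant /
informative counts (R, N); the phase-unknown likelihood
`L(θ) = ½[θ^R(1−θ)^(N−R)] + ½[(1−θ)^R θ^(N−R)]` is summed in log over
families and maximised over θ ∈ [0, 0.5] by bounded scalar minimisation
(tolerance 1e-6) with a closed-form shortcut (θ̂ = 0,
Z = Σ(Nᵢ−1)·log10 2) when every family is recombinant-free or fully
complementary. All-pairs matrices are computed by expressing (R, N) as
0/1 matrix products and memoising the LOD over the unique per-family
count combinations, which makes thousand-marker problems interactive.

Autogrouping seeds one group per anchor chromosome and runs four layers
with the published parameter tuples (5, 2.0, 4, 0.9) … (2.5, 0.5, 4,
0.3), mapped to (LOD threshold, max θ̂, min meioses, min link fraction).
The tuples' original semantics inside the modified CriMap autogroup are
not published; this mapping preserves the printed values and the
stringency ordering and is configurable. Within a layer, a marker joins
the group holding ≥ `min_link_fraction` of its significant links to
already-grouped markers; evaluation is batched per sweep (order
independence) and sweeps repeat to a fixed point. The final 2.5 layer
admits single-sire markers, whose ceiling with 10 meioses is
9·log10 2 ≈ 2.71. Anchor conflicts (two chromosomes sharing a sire
pattern in one family) are resolved by regrouping the affected members
with the family whose between-anchor LOD is below threshold; when no
family discriminates, the pair is reported merged rather than silently
assigned. Note the multiple-testing caveat: at LOD 2.5 with thousands of
markers, occasional chance same-pattern pairs across chromosomes are
expected; the link-fraction rule, not the LOD alone, is what keeps
cross-chromosome assignments at zero in the tested scenarios (≤ ~600
informative markers per run).

Within-group ordering and genetic distances are out of scope: ten
offspring per family cannot resolve marker order.

## Population structure and sexing

IBS similarity is mean shared alleles / 2 over pairwise-complete SNPs
(Plink DST-compatible; missing genotypes excluded pairwise, per-pair
overlap recorded); distance is its complement. Classical MDS
double-centres the squared distances, embeds on the top-k eigenvectors
scaled by √λ, truncates negative eigenvalues, and fixes signs by making
each dimension's largest-magnitude loading positive. MAF analyses default
to unrelated samples only.

Sex calls use the largest gap in sorted per-sample mean Y-probe
intensity, male above; a 2-means split would be equivalent on separated
data but the gap rule is deterministic and parameter-free. Calls are
refused (all "unknown") when the gap is < 3 pooled within-cluster SDs —
a relative criterion, so calls are scale-invariant. Per-probe
single-channel signals are assumed; how the production array combined
channels for non-polymorphic probes is unpublished.

## Problem sizes and determinism

The default demo scenario runs 96 samples (three populations plus two
families of 10 offspring), 2,000 markers on five 20-Mb chromosomes, and
2,000 candidate sites — sizes chosen so the full pipeline completes in
about a minute on one core while keeping ≥ 150 samples per genotype
cluster statistic and several hundred informative markers per linkage
run. All stage seeds derive from the single scenario seed via named
substreams (CRC-keyed `SeedSequence` children), so reruns are
byte-identical.

## Known limitations

- The conjugate blend is a documented stand-in for the proprietary
  production posterior update; cluster-specific covariance priors and
  heteroscedastic channel noise are not modelled.
- The boundary scan is one-dimensional in contrast; probesets whose
  clusters separate only in size (beyond the OTV case) would need the
  full 2-D scan the production software applies.
- `select_array_content` treats direction recommendations as given; it
  does not re-derive them from probe sequence.
- The distortion χ² uses asymptotic p-values without continuity
  correction; with 10 offspring the test is conservative only in
  aggregate, which matches its use as a coarse exclusion filter.
- IBS/MDS offers no admixture modelling or significance testing of
  cluster separation.
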