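"""Chromosome assignment by sire-based two-point linkage.

Male salmonids recombine at close to zero rate over large chromosomal
regions, so a sire transmits each chromosome to his offspring as one of
two intact haplotypes.  Markers with the segregation pattern AB (sire) x
AA-or-BB (dam) therefore share identical (or complementary) sire
transmission patterns whenever they sit on the same chromosome, and a
two-point LOD score cleanly separates same-chromosome from
different-chromosome pairs even with only ~10 offspring per family.

Grouping proceeds in stringency layers seeded by anchor markers of known
chromosome; a final layer at LOD 2.5 admits markers informative in a
single sire (whose ceiling with 10 meioses and zero recombinants is
LOD ~ 2.7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .synthetic_data import GenotypeMatrix, Pedigree

__all__ = [
    "AutogroupLayer",
    "DEFAULT_LAYERS",
    "SireTransmissions",
    "select_sire_informative",
    "twopoint_lod",
    "pairwise_lod_matrix",
    "autogroup_layers",
    "resolve_anchor_conflicts",
    "assign_chromosomes",
]

LOG10_2 = np.log10(2.0)


@dataclass(frozen=True)
class AutogroupLayer:
    lod_threshold: float
    max_theta: float
    min_meioses: int
    min_link_fraction: float


# stringent -> relaxed; the final layer sits at LOD 2.5 to admit markers
# informative in one sire only
DEFAULT_LAYERS = (
    AutogroupLayer(5.0, 2.0, 4, 0.9),
    AutogroupLayer(4.0, 1.5, 4, 0.7),
    AutogroupLayer(3.0, 1.0, 4, 0.6),
    AutogroupLayer(2.5, 0.5, 4, 0.3),
)


@dataclass
class SireTransmissions:
    """Per-family sire-transmission codes for informative markers.

    ``transmissions[fam]`` is a markers x offspring frame with values
    0 / 1 (which sire allele was transmitted: A=0, B=1) or -1 (unknown —
    offspring missing or incompatible).  A marker appears in a family's
    frame only when it is sire-informative (sire AB, dam homozygous)
    there.
    """

    transmissions: dict[str, pd.DataFrame]

    @property
    def marker_ids(self) -> pd.Index:
        idx: pd.Index | None = None
        for frame in self.transmissions.values():
            idx = frame.index if idx is None else idx.union(frame.index)
        return idx if idx is not None else pd.Index([])


def select_sire_informative(
    genotypes: GenotypeMatrix, pedigree: Pedigree
) -> SireTransmissions:
    """Find markers with sire AB x dam homozygous in >= 1 family and deduce
    each offspring's transmitted sire allele.

    With the dam homozygous her obligate contribution is known, so the
    sire allele is the offspring genotype minus the dam allele; offspring
    genotypes incompatible with the cross are coded unknown (-1).
    """
    geno = genotypes.genotypes
    out: dict[str, pd.DataFrame] = {}
    for fam, members in pedigree.families().items():
        sires = [m for m in members if m.sire is None and m.sex == "male"]
        dams = [m for m in members if m.dam is None and m.sex == "female"]
        offspring = [m for m in members if m.sire is not None and m.dam is not None]
        if not (sires and dams and offspring):
            continue
        sire_id, dam_id = sires[0].id, dams[0].id
        if sire_id not in geno.columns or dam_id not in geno.columns:
            continue
        s = geno[sire_id].to_numpy()
        d = geno[dam_id].to_numpy()
        informative = (s == 1) & ((d == 0) | (d == 2))
        if not informative.any():
            continue
        markers = geno.index[informative]
        dam_allele = (d[informative] // 2).astype(np.int8)  # 0 for AA, 1 for BB
        cols = {}
        for off in offspring:
            if off.id not in geno.columns:
                continue
            o = geno[off.id].to_numpy()[informative]
            trans = o - dam_allele  # offspring minus the dam's obligate allele
            trans = np.where((o < 0) | (trans < 0) | (trans > 1), -1, trans)
            cols[off.id] = trans.astype(np.int8)
        out[fam] = pd.DataFrame(cols, index=markers)
    return SireTransmissions(transmissions=out)


def _pair_counts(
    t1: np.ndarray, t2: np.ndarray
) -> tuple[int, int]:
    """(R, N) for one family: informative meioses and discordant
    transmissions between two markers (phase-unknown, so R and N - R are
    interchangeable in the likelihood)."""
    ok = (t1 >= 0) & (t2 >= 0)
    n = int(ok.sum())
    r = int((t1[ok] != t2[ok]).sum())
    return r, n


def twopoint_lod(
    counts: list[tuple[int, int]], tol: float = 1e-6
) -> tuple[float, float]:
    """Maximum two-point LOD over theta in [0, 0.5] for phase-unknown sires.

    Per sire, L(theta) = 1/2[theta^R (1-theta)^(N-R)] +
    1/2[(1-theta)^R theta^(N-R)]; log-likelihoods sum over sires.
    Z = log10 L(theta_hat) / L(0.5).  Returns (theta_hat, Z).

    Closed form when every sire has R = 0 (or R = N): theta_hat = 0 and
    Z = sum_i (N_i - 1) log10 2.
    """
    counts = [(r, n) for r, n in counts if n > 0]
    if not counts:
        raise ValueError("no informative meioses for this pair")
    for r, n in counts:
        if not 0 <= r <= n:
            raise ValueError(f"invalid counts R={r}, N={n}")

    if all(r == 0 or r == n for r, n in counts):
        z = sum((n - 1) * LOG10_2 for _, n in counts)
        return 0.0, float(z)

    def neg_ll(theta: float) -> float:
        theta = min(max(theta, 1e-12), 0.5)
        total = 0.0
        for r, n in counts:
            with np.errstate(divide="ignore"):
                a = r * np.log(theta) + (n - r) * np.log1p(-theta)
                b = r * np.log1p(-theta) + (n - r) * np.log(theta)
            m = max(a, b)
            total += m + np.log(0.5 * np.exp(a - m) + 0.5 * np.exp(b - m))
        return -total

    res = minimize_scalar(neg_ll, bounds=(0.0, 0.5), method="bounded", options={"xatol": tol})
    theta_hat = float(res.x)
    ll_null = -neg_ll(0.5)
    ll_hat = -float(res.fun)
    # golden-section can miss the boundary optimum; check theta = 0 explicitly
    ll_zero = -neg_ll(0.0)
    if ll_zero > ll_hat:
        theta_hat, ll_hat = 0.0, ll_zero
    z = max((ll_hat - ll_null) / np.log(10), 0.0)
    return theta_hat, float(z)


def pairwise_lod_matrix(
    trans: SireTransmissions,
    markers: list[str] | None = None,
    families: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All-pairs (Z, theta_hat, meioses) over the requested markers.

    Families may be restricted (used when resolving anchor conflicts).
    Pairs with zero shared informative meioses get Z = 0, theta = 0.5.
    """
    fams = families if families is not None else list(trans.transmissions)
    idx = pd.Index(markers) if markers is not None else trans.marker_ids
    m = len(idx)

    # per-family (R, N) matrices via 0/1 matrix products:
    #   N = pairs of offspring informative at both markers
    #   R = discordant transmissions among those
    r_mats, n_mats = [], []
    for fam in fams:
        frame = trans.transmissions.get(fam)
        if frame is None:
            continue
        t = frame.reindex(idx).fillna(-1).to_numpy(dtype=np.int16)
        valid = (t >= 0).astype(np.int16)
        ones = np.where(t == 1, 1, 0).astype(np.int16)
        zeros = valid - ones
        n_mat = valid @ valid.T
        r_mat = ones @ zeros.T + zeros @ ones.T
        r_mats.append(r_mat)
        n_mats.append(n_mat)

    z = np.zeros((m, m))
    theta = np.full((m, m), 0.5)
    meioses = np.zeros((m, m))
    if r_mats:
        counts_stack = np.stack(
            [a for pair in zip(r_mats, n_mats) for a in pair], axis=-1
        ).reshape(m * m, -1)
        meioses = np.sum(n_mats, axis=0).astype(float)
        # memoize over the (few) unique per-family count combinations
        combos, inverse = np.unique(counts_stack, axis=0, return_inverse=True)
        z_flat = np.zeros(len(combos))
        t_flat = np.full(len(combos), 0.5)
        for ci, combo in enumerate(combos):
            counts = [
                (int(combo[2 * f]), int(combo[2 * f + 1]))
                for f in range(len(r_mats))
                if combo[2 * f + 1] > 0
            ]
            if not counts:
                continue
            th, zz = twopoint_lod(counts)
            z_flat[ci], t_flat[ci] = zz, th
        z = z_flat[inverse].reshape(m, m)
        theta = t_flat[inverse].reshape(m, m)
        np.fill_diagonal(z, 0.0)
        np.fill_diagonal(theta, 0.0)
    zf = pd.DataFrame(z, index=idx, columns=idx)
    tf = pd.DataFrame(theta, index=idx, columns=idx)
    nf = pd.DataFrame(meioses, index=idx, columns=idx)
    return zf, tf, nf


def autogroup_layers(
    lod: pd.DataFrame,
    theta: pd.DataFrame,
    meioses: pd.DataFrame,
    anchors: dict[str, str],
    layers: tuple[AutogroupLayer, ...] = DEFAULT_LAYERS,
) -> pd.DataFrame:
    """Layered assignment of markers to anchor-seeded linkage groups.

    Groups are seeded by the anchor markers (one group per chromosome
    label).  Within each layer, every unassigned marker's significant
    links (Z >= lod_threshold, theta_hat <= max_theta, meioses >=
    min_meioses) to already-grouped markers are tallied per group; the
    marker joins the group holding the largest share when that share is >=
    min_link_fraction of its significant grouped links.  Evaluation is
    batched per sweep so results do not depend on marker order; sweeps
    repeat until a layer reaches a fixed point.  Markers never joined
    remain unassigned.

    Returns a frame indexed by marker with columns chromosome, layer,
    best_lod (NaN chromosome = unassigned).
    """
    markers = list(lod.index)
    for a in anchors:
        if a not in lod.index:
            raise ValueError(f"anchor marker {a!r} absent from the LOD matrix")
    assignment: dict[str, str] = dict(anchors)
    joined_layer: dict[str, int] = {a: 0 for a in anchors}
    best_lod: dict[str, float] = {a: np.nan for a in anchors}

    z = lod.to_numpy()
    th = theta.to_numpy()
    nn = meioses.to_numpy()
    pos = {mk: k for k, mk in enumerate(markers)}

    group_names = sorted(set(anchors.values()))
    group_id = {g: gi for gi, g in enumerate(group_names)}
    grp_of = np.full(len(markers), -1, dtype=int)
    for mk, g in assignment.items():
        grp_of[pos[mk]] = group_id[g]

    for li, layer in enumerate(layers, start=1):
        sig = (z >= layer.lod_threshold) & (th <= layer.max_theta) & (
            nn >= layer.min_meioses
        )
        np.fill_diagonal(sig, False)
        changed = True
        while changed:
            changed = False
            batch: dict[str, tuple[str, float]] = {}
            for mk in markers:
                if mk in assignment:
                    continue
                i = pos[mk]
                links = np.flatnonzero(sig[i])
                if len(links) == 0:
                    continue
                link_groups = grp_of[links]
                grouped = link_groups >= 0
                if not grouped.any():
                    continue
                tallies = np.bincount(link_groups[grouped], minlength=len(group_names))
                gi = int(tallies.argmax())
                # fraction of this marker's significant links *to grouped
                # markers* that point into the winning group
                frac = tallies[gi] / tallies.sum()
                if frac >= layer.min_link_fraction:
                    in_grp = links[link_groups == gi]
                    batch[mk] = (group_names[gi], float(z[i, in_grp].max()))
            for mk, (grp, zz) in batch.items():
                assignment[mk] = grp
                grp_of[pos[mk]] = group_id[grp]
                joined_layer[mk] = li
                best_lod[mk] = zz
                changed = True
    rows = []
    for mk in markers:
        rows.append(
            {
                "marker": mk,
                "chromosome": assignment.get(mk, None),
                "layer": joined_layer.get(mk, None),
                "best_lod": best_lod.get(mk, np.nan),
            }
        )
    return pd.DataFrame(rows).set_index("marker")


def resolve_anchor_conflicts(
    groups: pd.DataFrame,
    trans: SireTransmissions,
    anchors: dict[str, str],
    lod_threshold: float = 2.5,
) -> tuple[pd.DataFrame, list[dict]]:
    """Re-split groups whose members link two anchor chromosomes.

    When two chromosomes happen to share a near-identical sire pattern in
    one family, markers from both collapse into one group.  For each such
    chromosome pair, the family whose sire pattern *discriminates* the
    pair (lowest between-anchor LOD) is identified and members are
    regrouped using that family's transmissions only.  If no family
    discriminates, the pair is reported as merged and left alone.

    A conflict is detected when a marker's assigned chromosome differs
    from a well-supported single-family assignment; operationally we
    re-examine every chromosome pair whose anchors show a cross-LOD above
    ``lod_threshold`` in any family.

    Returns (updated groups, conflict reports).
    """
    reports: list[dict] = []
    chrom_anchor = {}
    for mk, chrom in anchors.items():
        chrom_anchor.setdefault(chrom, mk)
    chroms = sorted(chrom_anchor)
    updated = groups.copy()
    for i in range(len(chroms)):
        for j in range(i + 1, len(chroms)):
            c1, c2 = chroms[i], chroms[j]
            a1, a2 = chrom_anchor[c1], chrom_anchor[c2]
            per_family: dict[str, float] = {}
            for fam, frame in trans.transmissions.items():
                if a1 not in frame.index or a2 not in frame.index:
                    continue
                r, n = _pair_counts(
                    frame.loc[a1].to_numpy(), frame.loc[a2].to_numpy()
                )
                if n > 0:
                    _, zz = twopoint_lod([(r, n)])
                    per_family[fam] = zz
            confounded = [f for f, zz in per_family.items() if zz >= lod_threshold]
            if not confounded:
                continue
            discriminating = [
                f for f, zz in per_family.items() if zz < lod_threshold
            ]
            if not discriminating:
                reports.append(
                    {
                        "chromosomes": (c1, c2),
                        "status": "merged",
                        "family": None,
                    }
                )
                continue
            fam = min(discriminating, key=lambda f: per_family[f])
            members = list(
                updated.index[updated["chromosome"].isin([c1, c2])]
            )
            zf, tf, nf = pairwise_lod_matrix(trans, markers=members, families=[fam])
            for mk in members:
                if mk in (a1, a2):
                    continue
                z1 = float(zf.at[mk, a1]) if a1 in zf.columns else 0.0
                z2 = float(zf.at[mk, a2]) if a2 in zf.columns else 0.0
                if max(z1, z2) < lod_threshold:
                    updated.at[mk, "chromosome"] = None
                else:
                    updated.at[mk, "chromosome"] = c1 if z1 >= z2 else c2
                    updated.at[mk, "best_lod"] = max(z1, z2)
            reports.append(
                {
                    "chromosomes": (c1, c2),
                    "status": "resolved",
                    "family": fam,
                }
            )
    return updated, reports


def assign_chromosomes(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    anchors: dict[str, str],
    layers: tuple[AutogroupLayer, ...] = DEFAULT_LAYERS,
    resolve_conflicts: bool = True,
) -> pd.DataFrame:
    """End-to-end: informative selection -> LOD matrix -> autogroup ->
    conflict resolution.  Returns the groups frame."""
    trans = select_sire_informative(genotypes, pedigree)
    if not len(trans.marker_ids):
        return pd.DataFrame(columns=["chromosome", "layer", "best_lod"])
    zf, tf, nf = pairwise_lod_matrix(trans)
    present_anchors = {a: c for a, c in anchors.items() if a in zf.index}
    groups = autogroup_layers(zf, tf, nf, present_anchors, layers)
    if resolve_conflicts:
        groups, _ = resolve_anchor_conflicts(groups, trans, present_anchors)
    return groups
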