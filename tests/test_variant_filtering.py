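"""Filter semantics: threshold inclusivity, Mendelian logic, masking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dupsnp import synthetic_data as sd
from dupsnp import variant_filtering as vf


def _cand(**overrides):
    base = {
        "id": "x1",
        "contig": "c1",
        "pos": 100,
        "ref": "A",
        "alt": "C",
        "source": "RR",
        "pooled_af": 0.3,
        "depth": 40,
        "haploid_call": "hom",
        "haploid_gq": 50.0,
        "conversion_score": 0.5,
    }
    base.update(overrides)
    return pd.DataFrame([base]).set_index("id", drop=False)


class TestHaploidFilter:
    @pytest.mark.parametrize(
        "call,gq,removed",
        [("het", 30.0, True), ("het", 10.0, False), ("hom", 99.0, False), ("missing", 0.0, False)],
    )
    def test_gq_threshold_cases(self, call, gq, removed):
        res = vf.filter_haploid_heterozygotes(_cand(haploid_call=call, haploid_gq=gq))
        assert (res.n_removed == 1) is removed

    def test_exact_psv_recovery_on_clean_data(self, genome, panel):
        table, truth = sd.simulate_candidate_variants(
            genome, panel, 600, psv_fraction=0.2, depth_mean=30, error_rate=0.0, seed=21
        )
        res = vf.filter_haploid_heterozygotes(table)
        removed = set(res.removed["id"])
        truth_psv = set(truth.candidate_class[truth.candidate_class == "psv"].index)
        assert removed == truth_psv


class TestRRFilters:
    @pytest.mark.parametrize(
        "af,dp,removed",
        [
            (0.10, 50, True),  # frequency threshold is inclusive
            (0.25, 11, False),
            (0.25, 10, True),  # depth threshold is inclusive
            (0.11, 11, False),
        ],
    )
    def test_inclusive_thresholds(self, af, dp, removed):
        res = vf.apply_rr_filters(_cand(pooled_af=af, depth=dp))
        assert (res.n_removed == 1) is removed

    def test_missing_values_are_unscorable(self):
        res = vf.apply_rr_filters(_cand(pooled_af=np.nan))
        assert res.n_removed == 1
        assert res.removed["reason"].iloc[0] == "unscorable"


class TestTransversion:
    def test_transitions_and_transversions(self):
        assert not vf.is_transversion("A", "G")
        assert not vf.is_transversion("C", "T")
        assert vf.is_transversion("A", "C")
        assert vf.is_transversion("A", "T")

    def test_complement_invariance_all_pairs(self):
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for ref, alt in itertools.permutations("ACGT", 2):
            assert vf.is_transversion(ref, alt) == vf.is_transversion(comp[ref], comp[alt])

    def test_rejects_non_nucleotide(self):
        with pytest.raises(ValueError):
            vf.is_transversion("A", "N")


class TestRNAFilters:
    @pytest.mark.parametrize(
        "ref,alt,af,kept",
        [
            ("C", "T", 0.4, False),  # transition always removed
            ("A", "T", 0.1, True),  # MAF threshold inclusive
            ("A", "T", 0.09, False),
            ("A", "T", 0.95, False),  # MAF folds: 1 - 0.95 < 0.1
        ],
    )
    def test_transversion_and_maf(self, ref, alt, af, kept):
        res = vf.apply_rna_filters(_cand(ref=ref, alt=alt, pooled_af=af))
        assert (res.n_kept == 1) is kept


def _family_table(sire, dam, offspring, marker="m1"):
    cols = {"sire": [sire], "dam": [dam]}
    for i, o in enumerate(offspring):
        cols[f"off{i}"] = [o]
    geno = pd.DataFrame(cols, index=[marker], dtype=np.int8)
    return vf.FamilyGenotypeTable(genotypes={"f1": geno}, parents={"f1": ("sire", "dam")})


def _mendel_oracle(sire, dam, off):
    """Independent allele-string enumeration of feasible offspring."""
    alleles = {0: "AA", 1: "AB", 2: "BB", -1: None}
    s, d, o = alleles[sire], alleles[dam], alleles[off]
    if s is None or d is None or o is None:
        return False  # missing never counts as an error
    feasible = {"".join(sorted(a + b)) for a in s for b in d}
    return "".join(sorted(o)) not in feasible


class TestMendelianErrors:
    def test_known_impossible_transmissions(self):
        assert vf.count_mendelian_errors(_family_table(0, 0, [1]), "f1", "m1") == 1
        assert vf.count_mendelian_errors(_family_table(1, 0, [2]), "f1", "m1") == 1
        assert vf.count_mendelian_errors(_family_table(1, 1, [0]), "f1", "m1") == 0

    def test_exhaustive_27_case_gamete_oracle(self):
        for s, d, o in itertools.product((0, 1, 2), repeat=3):
            got = vf.count_mendelian_errors(_family_table(s, d, [o]), "f1", "m1")
            assert got == int(_mendel_oracle(s, d, o)), (s, d, o)

    def test_missing_genotypes_never_count(self):
        assert vf.count_mendelian_errors(_family_table(0, 0, [-1]), "f1", "m1") == 0
        assert vf.count_mendelian_errors(_family_table(-1, 0, [2]), "f1", "m1") == 0

    def test_family_without_parents_rejected(self):
        table = _family_table(0, 0, [0])
        with pytest.raises(ValueError):
            vf.count_mendelian_errors(table, "nope")


class TestSegregationDistortion:
    def test_perfect_backcross_fit(self):
        table = _family_table(1, 0, [0, 0, 0, 1, 1, 1])
        p, flag = vf.segregation_distortion_test(table, "f1", "m1")
        assert flag == "ok"
        assert p == pytest.approx(1.0)

    def test_extreme_distortion_p_value(self):
        # 10:0 in a backcross: chi2 = 10, df = 1 -> p ~ 0.00157
        table = _family_table(1, 0, [0] * 10)
        p, flag = vf.segregation_distortion_test(table, "f1", "m1")
        assert p == pytest.approx(float(stats.chi2.sf(10, 1)), rel=1e-6)
        assert p == pytest.approx(0.00157, rel=5e-3)

    def test_perfect_intercross_fit(self):
        table = _family_table(1, 1, [0] * 5 + [1] * 10 + [2] * 5)
        p, _ = vf.segregation_distortion_test(table, "f1", "m1")
        assert p == pytest.approx(1.0)

    def test_uninformative_cross_flagged(self):
        p, flag = vf.segregation_distortion_test(_family_table(0, 2, [1, 1]), "f1", "m1")
        assert p == 1.0 and flag == "uninformative"


class TestRADFilters:
    def _two_family_table(self, fam1_geno, fam2_geno):
        return vf.FamilyGenotypeTable(
            genotypes={
                "f1": pd.DataFrame(fam1_geno, index=["m1"], dtype=np.int8),
                "f2": pd.DataFrame(fam2_geno, index=["m1"], dtype=np.int8),
            },
            parents={"f1": ("sire", "dam"), "f2": ("sire", "dam")},
        )

    def test_single_errors_across_families_kept(self):
        # one error per family stays below the per-family threshold of two
        fams = self._two_family_table(
            {"sire": [1], "dam": [0], "off0": [2], "off1": [0], "off2": [1], "off3": [0], "off4": [1]},
            {"sire": [1], "dam": [0], "off0": [2], "off1": [1], "off2": [0], "off3": [1], "off4": [0]},
        )
        cands = _cand(id="m1")
        res = vf.apply_rad_filters(cands, fams)
        assert res.n_kept == 1

    def test_two_errors_in_one_family_removed(self):
        fams = self._two_family_table(
            {"sire": [0], "dam": [0], "off0": [1], "off1": [1], "off2": [0], "off3": [0]},
            {"sire": [0], "dam": [0], "off0": [0], "off1": [0]},
        )
        res = vf.apply_rad_filters(_cand(id="m1"), fams)
        assert res.n_removed == 1
        assert res.removed["reason"].iloc[0] == "mendelian_errors"

    def test_clean_simulated_families_pass_error_clause(self, family_data, pedigree):
        gm, _ = family_data
        genotypes, parents = {}, {}
        for fam, members in pedigree.families().items():
            ids = [m.id for m in members]
            genotypes[fam] = gm.genotypes[ids]
            parents[fam] = (f"{fam}_sire", f"{fam}_dam")
        fams = vf.FamilyGenotypeTable(genotypes=genotypes, parents=parents)
        markers = list(gm.marker_ids[:40])
        cands = pd.DataFrame({"id": markers}).assign(
            contig="c", pos=1, ref="A", alt="C", pooled_af=0.5, depth=30
        ).set_index("id", drop=False)
        res = vf.apply_rad_filters(cands, fams)
        assert not (res.removed["reason"] == "mendelian_errors").any()


class TestRepeatMask:
    def _mask(self):
        bed = pd.DataFrame({"contig": ["c1"], "start": [100], "end": [200]})
        return vf.RepeatMask.from_frame(bed)

    def test_boundary_convention(self):
        mask = self._mask()
        inside = _cand(pos=101)  # 0-based 100: inside [100, 200)
        edge = _cand(pos=100)  # 0-based 99: outside
        assert vf.mask_repeats(inside, mask).n_removed == 1
        assert vf.mask_repeats(edge, mask).n_removed == 0

    def test_unknown_contig_kept_with_warning(self):
        with pytest.warns(UserWarning):
            res = vf.mask_repeats(_cand(contig="unknown"), self._mask())
        assert res.n_kept == 1

    def test_agrees_with_quadratic_oracle(self):
        rng = np.random.default_rng(31)
        bed = pd.DataFrame(
            {
                "contig": rng.choice(["c1", "c2"], 40),
                "start": (s := rng.integers(0, 5_000, 40)),
                "end": s + rng.integers(1, 400, 40),
            }
        )
        mask = vf.RepeatMask.from_frame(bed)
        cands = pd.DataFrame(
            {
                "id": [f"v{i}" for i in range(300)],
                "contig": rng.choice(["c1", "c2"], 300),
                "pos": rng.integers(1, 6_000, 300),
            }
        ).set_index("id", drop=False)
        res = vf.mask_repeats(cands, mask)
        for _, r in cands.iterrows():
            hit = any(
                row["contig"] == r["contig"] and row["start"] <= r["pos"] - 1 < row["end"]
                for _, row in bed.iterrows()
            )
            assert (r["id"] in set(res.removed["id"])) == hit


class TestArrayContent:
    def _pool(self):
        rows = [
            # base set members
            ("b1", "recommended", "recommended", 0.9, False, False, False),
            ("b2", "recommended", "neutral", 0.8, False, False, False),
            ("b3", "neutral", "neutral", 0.7, False, False, False),
            ("b4", "recommended", "not recommended", 0.6, False, False, False),
            # excluded from base
            ("n1", "neutral", "not recommended", 0.95, False, False, False),
            # fill candidates
            ("f1", "not recommended", "not recommended", 0.2, True, False, False),
            ("f2", "not recommended", "not recommended", 0.7, False, True, False),
            ("f3", "not recommended", "not recommended", 0.6, False, True, False),
            ("f4", "not recommended", "not recommended", 0.3, False, False, True),
            ("f5", "not recommended", "not recommended", 0.0, False, False, True),
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "id", "direction_fwd", "direction_rev", "conversion_score",
                "multi_source", "dual_mapping", "previously_verified",
            ],
        )

    def test_base_set_pairing_rules(self):
        out = vf.select_array_content(self._pool(), capacity=4)
        assert set(out["id"]) == {"b1", "b2", "b3", "b4"}

    def test_neutral_with_not_recommended_excluded(self):
        out = vf.select_array_content(self._pool(), capacity=10)
        assert "n1" not in set(out["id"])

    def test_fill_order_and_strict_dual_mapping_threshold(self):
        out = vf.select_array_content(self._pool(), capacity=7)
        ids = set(out["id"])
        # stage (i) first, then stage (ii): f2 (0.7 > 0.6) but not f3 (= 0.6)
        assert {"f1", "f2"} <= ids
        assert "f3" not in ids
        # stage (iii) fills the last slot; zero-score candidates ineligible
        assert "f4" in ids and "f5" not in ids

    def test_capacity_below_base_raises(self):
        with pytest.raises(ValueError):
            vf.select_array_content(self._pool(), capacity=3)


class TestPartitionInvariant:
    def test_partitions_are_exhaustive_and_exclusive(self, genome, panel):
        table, _ = sd.simulate_candidate_variants(genome, panel, 200, seed=41)
        for res in (
            vf.filter_haploid_heterozygotes(table),
            vf.apply_rr_filters(table),
            vf.apply_rna_filters(table),
        ):
            assert res.n_kept + res.n_removed == len(table)
            assert set(res.kept["id"]).isdisjoint(set(res.removed["id"]))
            if res.n_removed:
                assert res.removed["reason"].notna().all()

    def test_rr_pipeline_ledger_reconciles(self, genome, panel):
        table, _ = sd.simulate_candidate_variants(genome, panel, 300, seed=42)
        kept, ledger = vf.run_rr_pipeline(table)
        assert ledger["output"].iloc[-1] == len(kept)
        assert (ledger["input"].iloc[1:].to_numpy() == ledger["output"].iloc[:-1].to_numpy()).all()
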