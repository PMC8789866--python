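import numpy as np
import pandas as pd
import pytest

from haplotrace import (
    AMBIGUOUS,
    HET,
    HOM_A,
    HOM_B,
    NDJ_EMBRYO,
    NDJ_PPB,
    NO_AMP,
    PROPER,
    STRAIN_A,
    STRAIN_B,
    DonorZygosityMap,
    SimConfig,
    call_sex,
    classify_contribution,
    classify_pair,
    simulate_haploidization,
    summarize,
)
from haplotrace.segregation import (
    COMPLETE_SH,
    FEMALE,
    MALE,
    NO_SOMATIC,
    PARTIAL_SH,
    PairClassification,
    ChromClassification,
    UNDETERMINED,
    X_BOTH,
    X_SOMATIC,
)
from haplotrace.io import DEFAULT_CHROMOSOMES
from haplotrace.model import clopper_pearson


def donor_map(chroms=("1",), hom_sites=()):
    """All-HET donor except explicit (chrom, strain) homozygous sites."""
    rows = []
    for c in chroms:
        for i in range(10):
            rows.append((c, 1000 + i, HET))
    for c, strain in hom_sites:
        rows.append((c, 5000, HOM_A if strain == STRAIN_A else HOM_B))
    return DonorZygosityMap(pd.DataFrame(rows, columns=["chrom", "pos", "donor_call"]))


def one_chrom(embryo, ppb, donor=None, sperm=STRAIN_B, male=False):
    pc = classify_pair(
        {"1": embryo},
        {"1": ppb},
        donor or donor_map(),
        sperm,
        embryo_is_male=male,
        chromosomes=["1"],
    )
    return pc.chromosomes["1"]


class TestClassifyPair:
    def test_canonical_reciprocal_pattern(self):
        # embryo HET (somatic A + sperm B), PPB carries the B homolog
        c = one_chrom(HET, HOM_B)
        assert (c.class_, c.retained_origin) == (PROPER, STRAIN_A)

    def test_ppb_heterozygous_is_nondisjunction_to_ppb(self):
        c = one_chrom(HOM_B, HET)
        assert c.class_ == NDJ_PPB
        assert c.retained_origin is None

    def test_both_no_amp_is_ambiguous(self):
        c = one_chrom(NO_AMP, NO_AMP)
        assert c.class_ == AMBIGUOUS

    def test_sperm_masked_complement_is_proper(self):
        # PPB extruded the A homolog; embryo somatic B is hidden behind B sperm
        c = one_chrom(HOM_B, HOM_A)
        assert (c.class_, c.retained_origin) == (PROPER, STRAIN_B)

    def test_same_strain_both_sides_requires_donor_loh(self):
        strict = one_chrom(HET, HOM_A)  # somatic A in embryo AND A in PPB
        assert strict.class_ == AMBIGUOUS
        relaxed = one_chrom(HET, HOM_A, donor=donor_map(hom_sites=[("1", STRAIN_A)]))
        assert (relaxed.class_, relaxed.retained_origin) == (PROPER, STRAIN_A)

    def test_sperm_strain_on_both_sides_requires_donor_loh(self):
        strict = one_chrom(HOM_B, HOM_B)
        assert strict.class_ == AMBIGUOUS
        relaxed = one_chrom(HOM_B, HOM_B, donor=donor_map(hom_sites=[("1", STRAIN_B)]))
        assert (relaxed.class_, relaxed.retained_origin) == (PROPER, STRAIN_B)

    def test_empty_ppb_with_somatic_signal_is_ndj_embryo(self):
        c = one_chrom(HET, NO_AMP)
        assert c.class_ == NDJ_EMBRYO

    def test_empty_ppb_without_somatic_signal_abstains(self):
        c = one_chrom(HOM_B, NO_AMP)  # only the sperm strain visible
        assert c.class_ == AMBIGUOUS

    def test_embryo_no_amp_with_ppb_hom_abstains(self):
        c = one_chrom(NO_AMP, HOM_A)
        assert c.class_ == AMBIGUOUS

    def test_missing_chromosome_is_ambiguous_not_dropped(self):
        pc = classify_pair({"1": HET}, {}, donor_map(), STRAIN_B, chromosomes=["1"])
        assert pc.chromosomes["1"].class_ == AMBIGUOUS
        assert pc.chromosomes["1"].rationale == "missing_chromosome"

    def test_uninformative_donor_abstains(self):
        rows = [("1", 1000 + i, HOM_A) for i in range(10)]
        dm = DonorZygosityMap(pd.DataFrame(rows, columns=["chrom", "pos", "donor_call"]))
        pc = classify_pair({"1": HOM_A}, {"1": HOM_A}, dm, STRAIN_B, chromosomes=["1"])
        assert pc.chromosomes["1"].class_ == AMBIGUOUS
        assert pc.chromosomes["1"].rationale == "donor_uninformative"

    def test_male_x_classified_without_sperm_subtraction(self):
        dm = donor_map(chroms=("X",))
        pc = classify_pair(
            {"X": HOM_B}, {"X": HOM_A}, dm, STRAIN_B, embryo_is_male=True, chromosomes=["X"]
        )
        assert (pc.chromosomes["X"].class_, pc.chromosomes["X"].retained_origin) == (
            PROPER,
            STRAIN_B,
        )
        # a female X behaves like an autosome: HOM_B embryo + HOM_A PPB is the
        # sperm-masked complement, also PROPER
        pc_f = classify_pair(
            {"X": HET}, {"X": HOM_B}, dm, STRAIN_B, embryo_is_male=False, chromosomes=["X"]
        )
        assert pc_f.chromosomes["X"].retained_origin == STRAIN_A

    def test_strain_relabeling_equivariance(self):
        swap_call = {HET: HET, NO_AMP: NO_AMP, HOM_A: HOM_B, HOM_B: HOM_A}
        swap_strain = {STRAIN_A: STRAIN_B, STRAIN_B: STRAIN_A, None: None}
        cases = [(HET, HOM_B), (HOM_B, HET), (HOM_B, HOM_A), (HET, NO_AMP), (HOM_A, HOM_A)]
        for e, p in cases:
            fwd = one_chrom(e, p, sperm=STRAIN_B)
            rev = one_chrom(swap_call[e], swap_call[p], sperm=STRAIN_A)
            assert rev.class_ == fwd.class_
            assert rev.retained_origin == swap_strain[fwd.retained_origin]


def hand_built_classifications():
    """Three pairs: 20/20, 15/20 (4 NDJ_PPB + 1 NDJ_EMBRYO), 10/20 (10 AMBIGUOUS)."""
    chroms = list(DEFAULT_CHROMOSOMES)

    def build(pair_id, classes, origins=None):
        pc = PairClassification(pair_id=pair_id, sperm_strain=STRAIN_B)
        for i, c in enumerate(chroms):
            cls = classes[i]
            origin = (origins or {}).get(c, STRAIN_A if cls == PROPER else None)
            ppb = HOM_B if cls == PROPER else (HET if cls == NDJ_PPB else NO_AMP)
            pc.chromosomes[c] = ChromClassification(
                chrom=c,
                class_=cls,
                retained_origin=origin if cls == PROPER else None,
                rationale="test",
                embryo_call=HET,
                ppb_call=ppb,
            )
        return pc

    p1 = build("p1", [PROPER] * 20)
    p2 = build("p2", [PROPER] * 15 + [NDJ_PPB] * 4 + [NDJ_EMBRYO])
    p3 = build("p3", [PROPER] * 10 + [AMBIGUOUS] * 10)
    return [p1, p2, p3]


class TestSummarize:
    def test_hand_enumerated_cohort(self):
        summary = summarize(hand_built_classifications(), n_chromosomes_assayed=20)
        assert summary.n_proper_per_pair == {"p1": 20, "p2": 15, "p3": 10}
        assert summary.n_ndj_ppb == 4 and summary.n_ndj_embryo == 1
        assert summary.ndj_in_ppb_fraction == pytest.approx(4 / 5)
        assert summary.percent_proper_mean == pytest.approx((100 + 75 + 50) / 3)
        assert summary.total_classified == 50
        # chromosome "1" was PROPER in all three pairs
        assert summary.proper_count_per_chromosome["1"] == 3

    def test_all_proper_reports_absent_ndj_fraction(self):
        pcs = [hand_built_classifications()[0]]
        summary = summarize(pcs)
        assert summary.ndj_in_ppb_fraction is None
        assert summary.retained_origin_a_fraction == pytest.approx(1.0)

    def test_single_pair_all_ndj_ppb(self):
        pc = PairClassification(pair_id="p", sperm_strain=STRAIN_B)
        for c in DEFAULT_CHROMOSOMES:
            pc.chromosomes[c] = ChromClassification(c, NDJ_PPB, None, "t", HOM_B, HET)
        summary = summarize([pc])
        assert summary.ndj_in_ppb_fraction == 1.0
        assert summary.retained_origin_a_fraction is None

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestCallSex:
    def test_y_marker_forces_male_with_somatic_x(self):
        assert call_sex(None, True, STRAIN_B) == (MALE, X_SOMATIC)

    def test_female_het_x_carries_both_origins(self):
        assert call_sex(HET, False, STRAIN_B) == (FEMALE, X_BOTH)

    def test_no_evidence_is_undetermined(self):
        assert call_sex(None, None, STRAIN_B) == (UNDETERMINED, UNDETERMINED)
        assert call_sex(NO_AMP, None, STRAIN_B) == (UNDETERMINED, UNDETERMINED)

    def test_simulated_cohort_sex_ratio_is_binomial_around_half(self):
        cfg = SimConfig(n_pairs=2000, seed=7)
        truth = simulate_haploidization(cfg)
        frac_male = (truth.pairs["embryo_sex"] == MALE).mean()
        lo, hi = clopper_pearson(int((truth.pairs["embryo_sex"] == MALE).sum()), 2000)
        assert lo <= 0.5 <= hi
        assert abs(frac_male - 0.5) < 3 * np.sqrt(0.25 / 2000)


class TestClassifyContribution:
    def test_all_het_is_complete_sh(self):
        calls = {c: HET for c in DEFAULT_CHROMOSOMES}
        res = classify_contribution(calls, STRAIN_B)
        assert res.category == COMPLETE_SH
        assert res.n_somatic_positive == 20

    def test_one_sperm_only_chromosome_is_partial(self):
        calls = {c: HET for c in DEFAULT_CHROMOSOMES}
        calls["6"] = HOM_B
        res = classify_contribution(calls, STRAIN_B)
        assert res.category == PARTIAL_SH
        assert res.n_somatic_positive == 19
        assert res.somatic_positive["6"] is False

    def test_sperm_strain_everywhere_is_no_somatic(self):
        calls = {c: HOM_B for c in DEFAULT_CHROMOSOMES}
        assert classify_contribution(calls, STRAIN_B).category == NO_SOMATIC

    def test_male_somatic_x_still_counts_as_complete(self):
        calls = {c: HET for c in DEFAULT_CHROMOSOMES}
        calls["X"] = HOM_A  # male: sperm gave Y, X is purely somatic
        assert classify_contribution(calls, STRAIN_B, embryo_is_male=True).category == COMPLETE_SH
        assert classify_contribution(calls, STRAIN_B, embryo_is_male=False).category == PARTIAL_SH
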