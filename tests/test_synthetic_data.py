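import numpy as np
import pandas as pd
import pytest

from haplotrace import (
    HET,
    STRAIN_A,
    STRAIN_B,
    SimConfig,
    SimTruth,
    default_reference_profile,
    simulate_allele_counts,
    simulate_catalog_and_donor,
    simulate_chrom_read_counts,
    simulate_experiment,
    simulate_haploidization,
)
from haplotrace.synthetic_data import NDJ_EMBRYO, NDJ_PPB, PROPER, _place_loh_tracts


class TestConfig:
    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            SimConfig(p_nondisjunction=1.5)
        with pytest.raises(ValueError):
            SimConfig(donor_loh_fraction=-0.1)

    def test_chromosome_universe(self):
        assert len(SimConfig().chromosomes) == 20
        assert SimConfig(include_X=False).chromosomes == [str(i) for i in range(1, 20)]


class TestCatalogAndDonor:
    def test_no_loh_limit_donor_fully_heterozygous(self):
        cfg = SimConfig(donor_loh_fraction=0.0, seed=5)
        _, donor, tracts = simulate_catalog_and_donor(cfg)
        assert (donor.zygosity["donor_call"] == HET).all()
        assert all(len(t) == 0 for t in tracts.values())

    def test_full_loh_limit_donor_fully_homozygous(self):
        cfg = SimConfig(donor_loh_fraction=1.0, sites_per_chromosome=15, seed=5)
        _, donor, _ = simulate_catalog_and_donor(cfg)
        assert not (donor.zygosity["donor_call"] == HET).any()
        assert not donor.donor_informative("1")

    def test_homozygous_site_count_matches_emitted_tracts(self):
        cfg = SimConfig(donor_loh_fraction=0.2, sites_per_chromosome=50, seed=9)
        _, donor, tracts = simulate_catalog_and_donor(cfg)
        for chrom, chrom_tracts in tracts.items():
            expected = sum(stop - start for start, stop, _ in chrom_tracts)
            sub = donor.zygosity[donor.zygosity["chrom"] == chrom]
            assert (sub["donor_call"] != HET).sum() == expected
            # target is 10 of 50 sites, reached within tract granularity
            assert abs(expected - 10) <= max(1, 50 // 8)

    def test_tracts_are_disjoint_and_in_range(self):
        rng = np.random.default_rng(0)
        for frac in (0.1, 0.5, 0.9, 1.0):
            tracts = _place_loh_tracts(rng, 40, frac)
            covered = np.zeros(40, dtype=int)
            for start, stop, strain in tracts:
                assert 0 <= start < stop <= 40
                assert strain in (STRAIN_A, STRAIN_B)
                covered[start:stop] += 1
            assert covered.max() <= 1
            assert covered.sum() == round(frac * 40)

    def test_catalog_sites_unique_sorted_distinct_alleles(self):
        cat, _, _ = simulate_catalog_and_donor(SimConfig(seed=2))
        df = cat.to_frame()
        assert not df.duplicated(["chrom", "pos"]).any()
        assert (df["allele_A"] != df["allele_B"]).all()
        for chrom in cat.chromosomes:
            pos = cat.positions(chrom)
            assert pos == sorted(pos)
            assert len(pos) == SimConfig().sites_per_chromosome


class TestHaploidization:
    def test_no_ndj_limit_all_proper(self):
        truth = simulate_haploidization(SimConfig(p_nondisjunction=0.0, seed=1))
        assert (truth.events["event"] == PROPER).all()

    def test_full_ndj_to_ppb_limit(self):
        truth = simulate_haploidization(
            SimConfig(p_nondisjunction=1.0, p_ndj_to_ppb=1.0, seed=1)
        )
        assert (truth.events["event"] == NDJ_PPB).all()
        assert (truth.events["ppb_copies"] == 2).all()
        assert (truth.events["embryo_somatic_copies"] == 0).all()

    def test_conservation_of_somatic_copies(self):
        truth = simulate_haploidization(SimConfig(n_pairs=50, seed=4))
        total = truth.events["embryo_somatic_copies"] + truth.events["ppb_copies"]
        assert (total == 2).all()
        proper = truth.events[truth.events["event"] == PROPER]
        assert (proper["embryo_somatic_copies"] == 1).all()
        assert proper["retained_homolog"].isin([STRAIN_A, STRAIN_B]).all()

    def test_event_frequencies_recover_configured_rates(self):
        cfg = SimConfig(n_pairs=2000, p_nondisjunction=0.24, p_ndj_to_ppb=0.74, seed=13)
        truth = simulate_haploidization(cfg)
        ev = truth.events["event"]
        n = len(ev)
        p_ndj = (ev != PROPER).mean()
        se = np.sqrt(0.24 * 0.76 / n)
        assert abs(p_ndj - 0.24) < 3 * se
        ndj = ev[ev != PROPER]
        p_ppb = (ndj == NDJ_PPB).mean()
        se_ppb = np.sqrt(0.74 * 0.26 / len(ndj))
        assert abs(p_ppb - 0.74) < 3 * se_ppb
        # retained homolog is uniform over strains
        retained = truth.events.loc[truth.events["event"] == PROPER, "retained_homolog"]
        assert abs((retained == STRAIN_A).mean() - 0.5) < 3 * np.sqrt(0.25 / len(retained))

    def test_truth_json_round_trip(self, tmp_path):
        cfg = SimConfig(n_pairs=4, seed=8)
        cat, donor, tracts = simulate_catalog_and_donor(cfg)
        truth = simulate_haploidization(cfg, cat, donor, donor_tracts=tracts)
        truth.to_json(tmp_path / "truth.json")
        back = SimTruth.from_json(tmp_path / "truth.json")
        assert back.config == cfg
        pd.testing.assert_frame_equal(back.events, truth.events)
        assert back.donor_tracts == tracts


class TestAlleleCounts:
    def test_seed_determinism_byte_identical(self):
        cfg = SimConfig(n_pairs=3, sites_per_chromosome=8, seed=21)
        t1 = simulate_experiment(cfg)
        t2 = simulate_experiment(cfg)
        assert t1["allele_counts"].to_csv() == t2["allele_counts"].to_csv()
        assert t1["chrom_counts"].to_csv() == t2["chrom_counts"].to_csv()
        pd.testing.assert_frame_equal(t1["truth"].events, t2["truth"].events)

    def test_noiseless_proper_embryo_fraction_half(self):
        cfg = SimConfig(
            n_pairs=6,
            p_nondisjunction=0.0,
            p_site_dropout=0.0,
            p_chrom_amp_failure=0.0,
            donor_loh_fraction=0.0,
            mean_depth=5000.0,
            seed=17,
        )
        bundle = simulate_experiment(cfg)
        truth, counts = bundle["truth"], bundle["allele_counts"]
        # pick a PROPER autosome with retained homolog A in a male embryo or any pair
        ev = truth.events
        row = ev[(ev["retained_homolog"] == STRAIN_A) & (ev["chrom"] == "2")].iloc[0]
        sub = counts[
            (counts["sample_id"] == f"embryo_{row['pair_id']}") & (counts["chrom"] == "2")
        ]
        frac = sub["reads_A"] / (sub["reads_A"] + sub["reads_B"])
        assert np.allclose(frac, 0.5, atol=0.05)  # somatic A : sperm B mixture

    def test_ndj_ppb_content_forced(self):
        cfg = SimConfig(
            n_pairs=4,
            p_nondisjunction=1.0,
            p_ndj_to_ppb=1.0,
            p_site_dropout=0.0,
            p_chrom_amp_failure=0.0,
            donor_loh_fraction=0.0,
            mean_depth=500.0,
            seed=23,
        )
        bundle = simulate_experiment(cfg)
        counts = bundle["allele_counts"]
        ppb = counts[counts["sample_id"].str.startswith("ppb_")]
        emb = counts[(counts["sample_id"].str.startswith("embryo_")) & (counts["chrom"] != "X")]
        # PPB holds both somatic homologs: both alleles present at every site
        assert (ppb["reads_A"] > 0).all() and (ppb["reads_B"] > 0).all()
        # embryo autosomes carry only the sperm (B) allele
        assert (emb["reads_A"] == 0).all() and (emb["reads_B"] > 0).all()

    def test_zero_copy_chromosome_yields_no_reads(self):
        cfg = SimConfig(
            n_pairs=4,
            p_nondisjunction=1.0,
            p_ndj_to_ppb=0.0,  # everything retained in the embryo
            p_site_dropout=0.0,
            p_chrom_amp_failure=0.0,
            seed=29,
        )
        bundle = simulate_experiment(cfg)
        counts = bundle["allele_counts"]
        ppb = counts[counts["sample_id"].str.startswith("ppb_")]
        assert (ppb["reads_A"] == 0).all() and (ppb["reads_B"] == 0).all()


class TestChromReadCounts:
    def test_all_proper_embryo_normalizes_to_one(self):
        cfg = SimConfig(n_pairs=5, p_nondisjunction=0.0, seed=31)
        truth = simulate_haploidization(cfg)
        ref = default_reference_profile(cfg)
        counts = simulate_chrom_read_counts(truth, cfg, ref)
        emb = counts[counts["sample_id"].str.startswith("embryo_")]
        auto = emb[emb["chrom"] != "X"]
        # copy 2 against a diploid reference of lambda=10000: ratio about 1
        assert np.allclose(auto["count"] / 10_000.0, 1.0, atol=0.05)

    def test_ndj_embryo_copy_three_and_empty_ppb(self):
        cfg = SimConfig(n_pairs=3, p_nondisjunction=1.0, p_ndj_to_ppb=0.0, seed=37)
        truth = simulate_haploidization(cfg)
        counts = simulate_chrom_read_counts(truth, cfg)
        ppb = counts[counts["sample_id"].str.startswith("ppb_")]
        assert (ppb["count"] == 0).all()
        emb = counts[(counts["sample_id"].str.startswith("embryo_")) & (counts["chrom"] == "5")]
        assert np.allclose(emb["count"] / 10_000.0, 1.5, atol=0.1)  # copy 3 vs diploid

    def test_poisson_concentration_copy_three(self):
        # 100 replicate draws at lambda=10000 per chromosome, copy 3:
        # normalized value within 5% of 1.5
        rng = np.random.default_rng(41)
        lam = 10_000.0
        draws = rng.poisson(3 * lam / 2, size=100)
        normalized = draws / (2 * lam / 2)
        assert np.all(np.abs(normalized - 1.5) < 0.075)
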