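"""Synthetic cohort generator: haplotype math, Hardy-Weinberg sampling,
recall filtering, phenotype calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rbgdesign import (
    LDPair,
    SNPSpec,
    TRPA1_LD_PAIRS,
    TRPA1_SNPS,
    cohens_d,
    generate_qst,
    haplotype_freqs,
    recall_sample,
    sample_genotypes,
    screen_exclusions,
    synthesize_cohort,
)
from rbgdesign.cohort import QstNoiseConfig, write_vcf
from rbgdesign.errors import (
    InfeasibleLDError,
    InsufficientPoolError,
    InvalidParameterError,
)


class TestHaplotypeFreqs:
    def test_perfect_ld_equal_mafs_two_haplotype_system(self):
        freqs = haplotype_freqs(0.15, 0.15, 1.0, 1)
        assert freqs[0] == pytest.approx(0.15)
        assert freqs[1] == pytest.approx(0.0)
        assert freqs[2] == pytest.approx(0.0)
        assert freqs[3] == pytest.approx(0.85)

    def test_zero_ld_gives_product_frequencies(self):
        freqs = haplotype_freqs(0.1, 0.3, 0.0)
        assert freqs == pytest.approx([0.03, 0.07, 0.27, 0.63])

    def test_infeasible_r2_names_frechet_bound(self):
        with pytest.raises(InfeasibleLDError, match="Frechet"):
            haplotype_freqs(0.05, 0.45, 1.0, 1)

    @given(
        pa=st.floats(0.01, 0.5),
        pb=st.floats(0.01, 0.5),
        r2=st.floats(0.0, 1.0),
    )
    def test_frequencies_sum_to_one_when_feasible(self, pa, pb, r2):
        try:
            freqs = haplotype_freqs(pa, pb, r2)
        except InfeasibleLDError:
            return
        assert freqs.sum() == pytest.approx(1.0)
        assert (freqs >= 0).all()

    def test_moderate_ld_pair_recovers_r2(self):
        """Sampling a million haplotypes from the moderately linked pair
        (MAFs 0.10 and 0.16) reproduces r-squared = 0.51."""
        freqs = haplotype_freqs(0.10, 0.16, 0.51, 1)
        rng = np.random.default_rng(17)
        n = 1_000_000
        haps = rng.choice(4, size=n, p=freqs)
        a = np.isin(haps, (0, 1)).astype(float)
        b = np.isin(haps, (0, 2)).astype(float)
        r2_emp = np.corrcoef(a, b)[0, 1] ** 2
        # delta method SE of r^2 from 1e6 draws is about 1.1e-3
        assert r2_emp == pytest.approx(0.51, abs=3 * 1.2e-3)


@pytest.fixture(scope="module")
def big_table():
    return sample_genotypes(300_000, seed=21)


@pytest.fixture(scope="module")
def pool():
    return sample_genotypes(150_000, seed=23)


class TestSampleGenotypes:
    def test_minor_homozygote_frequency_matches_hwe(self, big_table):
        # common SNP, MAF 0.40 -> p^2 = 0.16
        dos = big_table["dosage_rs7819749"]
        frac = (dos == 2).mean()
        se = np.sqrt(0.16 * 0.84 / len(dos))
        assert frac == pytest.approx(0.16, abs=3 * se)

    def test_empirical_mafs_match_spec(self, big_table):
        n = len(big_table)
        for spec in TRPA1_SNPS:
            maf_emp = big_table[f"dosage_{spec.rsid}"].mean() / 2
            se = np.sqrt(spec.maf * (1 - spec.maf) / (2 * n))
            assert maf_emp == pytest.approx(spec.maf, abs=3 * se), spec.rsid

    def test_complete_ld_pair_identical_dosages(self, big_table):
        assert (
            big_table["dosage_rs16937976"] == big_table["dosage_rs13268757"]
        ).all()

    def test_moderate_ld_pair_genotypic_r2(self, big_table):
        r2 = (
            np.corrcoef(
                big_table["dosage_rs920829"], big_table["dosage_rs959976"]
            )[0, 1]
            ** 2
        )
        assert r2 == pytest.approx(0.51, abs=0.01)

    def test_fixed_seed_reproducible(self):
        a = sample_genotypes(500, seed=3)
        b = sample_genotypes(500, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_certainty_mostly_above_eligibility_bar(self, big_table):
        cols = [f"imputation_prob_{s.rsid}" for s in TRPA1_SNPS]
        all_high = (big_table[cols] > 0.99).all(axis=1).mean()
        assert 0.9 < all_high < 1.0


class TestRecallSample:
    def test_control_pool_frequency_closed_form(self, pool):
        """Controls (major-homozygous everywhere, all loci certain) occur at
        about the independent-loci product, boosted slightly by coupling LD."""
        cohort = recall_sample(pool, {"control": 10}, seed=1)
        dosage_cols = [f"dosage_{s.rsid}" for s in TRPA1_SNPS]
        assert (cohort[dosage_cols] == 0).all().all()
        frac = (
            (pool[dosage_cols] == 0).all(axis=1)
        ).mean()

        # closed form: independent common SNP times, per linked pair, the
        # squared major-major haplotype frequency
        def mm_sq(pa, pb, r2):
            d_coef = np.sqrt(r2 * pa * (1 - pa) * pb * (1 - pb))
            return ((1 - pa) * (1 - pb) + d_coef) ** 2

        expected = 0.6**2 * mm_sq(0.10, 0.16, 0.51) * mm_sq(0.15, 0.15, 1.0)
        se = np.sqrt(expected * (1 - expected) / len(pool))
        assert frac == pytest.approx(expected, abs=3 * se)
        # coupling LD boosts the control pool above the independence product
        assert frac > np.prod([(1 - s.maf) ** 2 for s in TRPA1_SNPS])

    def test_rare_group_pool_near_p_squared(self, pool):
        # the rare-variant homozygotes (MAF 0.10) are about 1% of the sample
        frac = (pool["dosage_rs920829"] == 2).mean()
        assert frac == pytest.approx(0.01, abs=0.002)

    def test_group_membership_constraints_hold(self, pool):
        cohort = recall_sample(
            pool,
            {"control": 30, "group1": 10, "group2": 10, "group3": 10},
            seed=2,
        )
        for g, snps in (
            (1, ["rs7819749"]),
            (2, ["rs920829", "rs959976"]),
            (3, ["rs16937976", "rs13268757"]),
        ):
            sub = cohort[cohort["recall_group"] == f"group{g}"]
            for rsid in snps:
                assert (sub[f"dosage_{rsid}"] == 2).all()
        probs = cohort[[f"imputation_prob_{s.rsid}" for s in TRPA1_SNPS]]
        assert (probs > 0.99).all().all()

    def test_oversized_request_reports_shortfall(self, pool):
        with pytest.raises(InsufficientPoolError, match="expected yield"):
            recall_sample(pool, {"group2": 100_000}, seed=0)

    def test_no_participant_reused_across_groups(self, pool):
        cohort = recall_sample(pool, {"control": 50, "group1": 20}, seed=5)
        assert cohort["participant_id"].is_unique


class TestGenerateQst:
    def _cohort(self, n_per_group=200, seed=0):
        return pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(2 * n_per_group)],
                "recall_group": ["control"] * n_per_group
                + ["group1"] * n_per_group,
            }
        )

    def test_baseline_distribution(self):
        df = generate_qst(self._cohort(5000), seed=31)
        assert df["hpt_baseline"].mean() == pytest.approx(42.0, abs=0.15)
        assert df["hpt_baseline"].std() == pytest.approx(2.5, abs=0.1)

    def test_null_effect_calibration(self):
        """With no group effect the post-sensitization comparison rejects at
        about the nominal rate over replicates."""
        from scipy import stats

        cohort = self._cohort(15)
        rejections = 0
        reps = 2000
        for s in range(reps):
            df = generate_qst(cohort, effect_map={}, seed=s)
            t = df[df.recall_group == "group1"]["hpt_post"]
            c = df[df.recall_group == "control"]["hpt_post"]
            rejections += stats.ttest_ind(t, c).pvalue <= 0.05
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rate == pytest.approx(0.05, abs=3 * se)

    def test_injected_effect_recovered_within_ci(self):
        """The injected shift lands inside the 95% CI of the mean difference
        in at least 93% of replicates."""
        from scipy import stats

        cohort = self._cohort(30)
        delta = -4.0
        hits = 0
        reps = 500
        for s in range(reps):
            df = generate_qst(cohort, effect_map={"group1": delta}, seed=s)
            t = df[df.recall_group == "group1"]["hpt_post"]
            c = df[df.recall_group == "control"]["hpt_post"]
            diff = t.mean() - c.mean()
            se = np.sqrt(t.var(ddof=1) / len(t) + c.var(ddof=1) / len(c))
            crit = stats.t.ppf(0.975, len(t) + len(c) - 2)
            hits += abs(diff - delta) <= crit * se
        assert hits / reps >= 0.93

    def test_post_sd_stays_at_configured_value(self):
        df = generate_qst(self._cohort(5000), seed=33)
        assert df["hpt_post"].std() == pytest.approx(2.5, abs=0.1)

    def test_censoring_flag_caps_thresholds(self):
        noise = QstNoiseConfig(censor_at_50c=True, hpt_mean=49.0)
        df = generate_qst(self._cohort(500), noise=noise, seed=34)
        assert df["hpt_baseline"].max() <= 50.0

    def test_pain_rating_integer_scale(self):
        df = generate_qst(self._cohort(500), seed=35)
        assert df["cinnamaldehyde_pain"].between(0, 10).all()
        assert df["cinnamaldehyde_pain"].dtype.kind == "i"


class TestScreenExclusions:
    def _records(self, n):
        return pd.DataFrame({"participant_id": [f"P{i}" for i in range(n)]})

    def test_zero_prevalence_is_identity(self):
        records = self._records(100)
        kept, counts = screen_exclusions(records, {"pregnancy": 0.0}, seed=0)
        assert len(kept) == 100
        assert counts["pregnancy"] == 0

    def test_certain_criterion_empties_cohort(self):
        kept, _ = screen_exclusions(
            self._records(50), {"pain_condition": 1.0}, seed=0
        )
        assert kept.empty

    def test_independent_criteria_retention_closed_form(self):
        p, k, n = 0.1, 4, 100_000
        prev = {f"crit{i}": p for i in range(k)}
        kept, _ = screen_exclusions(self._records(n), prev, seed=1)
        expected = (1 - p) ** k
        se = np.sqrt(expected * (1 - expected) / n)
        assert len(kept) / n == pytest.approx(expected, abs=3 * se)

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(InvalidParameterError):
            screen_exclusions(self._records(5), {"x": 1.5}, seed=0)


class TestEndToEnd:
    def test_synthesize_cohort_invariants(self):
        cohort = synthesize_cohort(
            pool_size=60_000, effect_map={"group1": -4.0}, seed=41
        )
        assert set(cohort["recall_group"].unique()) == {
            "control",
            "group1",
            "group2",
            "group3",
        }
        assert cohort["eligible"].all()
        ctrl = cohort[cohort.recall_group == "control"]
        assert (
            ctrl[[f"dosage_{s.rsid}" for s in TRPA1_SNPS]] == 0
        ).all().all()
        t = cohort.loc[cohort.recall_group == "group1", "hpt_post"]
        c = cohort.loc[cohort.recall_group == "control", "hpt_post"]
        d, _ = cohens_d(t, c)
        assert d < 0  # hypersensitive group: lower pain threshold

    def test_vcf_round_trip(self, tmp_path):
        import cyvcf2

        pool = sample_genotypes(50, seed=43)
        path = tmp_path / "panel.vcf"
        write_vcf(pool, path)
        seen = {}
        vcf = cyvcf2.VCF(str(path))
        assert list(vcf.samples) == pool["participant_id"].tolist()
        for variant in vcf:
            seen[variant.ID] = np.array(variant.gt_types)
        for spec in TRPA1_SNPS:
            # cyvcf2 gt_types: 0 hom-ref, 1 het, 3 hom-alt
            dosages = pool[f"dosage_{spec.rsid}"].to_numpy()
            expected = np.where(dosages == 2, 3, dosages)
            assert (seen[spec.rsid] == expected).all()
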