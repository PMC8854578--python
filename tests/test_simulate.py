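"""Generator determinism, planted-truth propagation and stop-model oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from mitomethyl import (
    CleavageSimParams,
    Dntp,
    FootprintSimParams,
    Genotype,
    MethylSite,
    RtStopSimParams,
    SimulationTruth,
    cleavage_counts,
    correct_mixing,
    occupancy,
    rt_stop_fold_change,
    rt_stop_ratio,
    score_a,
    simulate_cleavage_profiles,
    simulate_footprint_library,
    simulate_rtstop_profiles,
    simulate_silac_table,
)
from mitomethyl.occupancy import (
    count_footprints,
    expression_table,
    filter_footprints,
    human_mt_mrna_annotation,
)
from mitomethyl.simulate import _uniform_fragments
from mitomethyl.profiles import EndCountProfile, ReferenceIndex, Strand


def oracle_rtstop_expectation(L, frag_len, dropoff, site_q):
    """Exact per-molecule expectations of S and C by fragment enumeration.

    Fragments are uniform over valid (start, length) pairs; reverse
    transcription survives the extension step into position x with
    probability (1 - dropoff) * (1 - q_x).
    """
    lo, hi = frag_len
    frags = [(s, s + l - 1)
             for l in range(lo, hi + 1)
             for s in range(1, L - l + 2)]
    ES = np.zeros(L)
    EC = np.zeros(L)
    p_frag = 1.0 / len(frags)
    for s, e in frags:
        cover = [0.0] * (e - s + 1)
        cover[e - s] = 1.0
        pc = 1.0
        for x in range(e - 1, s - 1, -1):
            pc *= (1.0 - dropoff) * (1.0 - site_q.get(x, 0.0))
            cover[x - s] = pc
        for x in range(s, e + 1):
            EC[x - 1] += p_frag * cover[x - s]
        ES[s - 1] += p_frag * cover[0]
        for x in range(s + 1, e + 1):
            ES[x - 1] += p_frag * (cover[x - s] - cover[x - 1 - s])
    return ES, EC


class TestCleavageSimulator:
    def test_same_seed_bit_identical(self):
        params = CleavageSimParams(length=300, n_frag=2000, seed=7)
        truth = SimulationTruth(sites=(MethylSite(150, 0.8),))
        a = simulate_cleavage_profiles(params, truth)
        b = simulate_cleavage_profiles(params, truth)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.coverage, pb.coverage)
            np.testing.assert_array_equal(pa.starts5, pb.starts5)
            np.testing.assert_array_equal(pa.ends3, pb.ends3)

    def test_full_protection_gives_zero_cleavage(self):
        params = CleavageSimParams(length=300, n_frag=5000, seed=1)
        truth = SimulationTruth(sites=(MethylSite(150, 1.0),))
        for prof in simulate_cleavage_profiles(params, truth):
            n = cleavage_counts(prof)
            assert n[149] == 0

    def test_profiles_satisfy_coverage_identity(self):
        params = CleavageSimParams(length=300, n_frag=2000, seed=3)
        for prof in simulate_cleavage_profiles(params, SimulationTruth()):
            prof.validate()

    def test_null_simulation_scores_near_zero(self):
        """Unmethylated uniform-propensity libraries score ~0 on average."""
        means = []
        for seed in range(20):
            params = CleavageSimParams(length=400, n_frag=6000,
                                       dispersion=0.0, replicates=1,
                                       seed=seed)
            prof = simulate_cleavage_profiles(params, SimulationTruth())[0]
            track = score_a(cleavage_counts(prof))
            means.append(np.nanmean(track.score))
        assert np.mean(means) <= 0.05

    def test_protected_site_scores_high(self):
        params = CleavageSimParams(length=400, n_frag=20000,
                                   dispersion=0.0, replicates=1, seed=5)
        truth = SimulationTruth(sites=(MethylSite(200, 0.95),))
        prof = simulate_cleavage_profiles(params, truth)[0]
        track = score_a(cleavage_counts(prof))
        assert track.score[199] > 0.6

    def test_impossible_length_range_raises(self):
        params = CleavageSimParams(length=300, n_frag=100,
                                   frag_len=(290, 295), seed=1)
        with pytest.raises(ValueError, match="acceptance"):
            simulate_cleavage_profiles(params, SimulationTruth())


class TestRtStopSimulator:
    def test_same_seed_bit_identical(self):
        params = RtStopSimParams(length=200, n_frag=3000, seed=9)
        truth = SimulationTruth(sites=(MethylSite(100, 0.0, 0.5, 0.05),))
        a = simulate_rtstop_profiles(params, truth, Dntp.low)
        b = simulate_rtstop_profiles(params, truth, Dntp.low)
        np.testing.assert_array_equal(a.starts5, b.starts5)
        np.testing.assert_array_equal(a.ends3, b.ends3)

    def test_low_and_high_conditions_use_distinct_streams(self):
        params = RtStopSimParams(length=200, n_frag=3000, seed=9)
        low = simulate_rtstop_profiles(params, SimulationTruth(), Dntp.low)
        high = simulate_rtstop_profiles(params, SimulationTruth(), Dntp.high)
        assert not np.array_equal(low.starts5, high.starts5)

    def test_profiles_satisfy_coverage_identity(self):
        params = RtStopSimParams(length=200, n_frag=3000, seed=2)
        truth = SimulationTruth(sites=(MethylSite(100, 0.0, 0.5, 0.05),))
        for cond in (Dntp.low, Dntp.high):
            simulate_rtstop_profiles(params, truth, cond).validate()

    def test_no_stall_limit_reproduces_pure_fragments(self):
        """With zero drop-off and no sites every read is a full fragment."""
        params = RtStopSimParams(length=200, n_frag=3000, dropoff=0.0, seed=4)
        prof = simulate_rtstop_profiles(params, SimulationTruth(), Dntp.low)
        ss = np.random.SeedSequence([params.seed, 1, 0])
        s, e = _uniform_fragments(200, 3000, params.frag_len,
                                  np.random.default_rng(ss))
        ref = ReferenceIndex(name="chrM", length_nt=200)
        pure = EndCountProfile.from_intervals(
            zip(s.tolist(), e.tolist()), ref
        )
        np.testing.assert_array_equal(prof.starts5, pure.starts5)
        np.testing.assert_array_equal(prof.ends3, pure.ends3)

    def test_stop_ratio_matches_enumeration_oracle(self):
        """Observed stop ratio at a planted site sits within 3 binomial SE
        of the exact expectation computed by fragment enumeration."""
        L, site, q, d = 120, 60, 0.5, 0.001
        params = RtStopSimParams(length=L, n_frag=30000, dropoff=d,
                                 frag_len=(20, 40), seed=13)
        truth = SimulationTruth(sites=(MethylSite(site, 0.0, q, 0.05),))
        prof = simulate_rtstop_profiles(params, truth, Dntp.low)
        ES, EC = oracle_rtstop_expectation(L, (20, 40), d, {site: q})
        r_exp = ES[site] / EC[site]  # index site = position site+1
        n_cov = params.n_frag * EC[site]
        se = math.sqrt(r_exp * (1 - r_exp) / n_cov)
        r_obs = rt_stop_ratio(prof).ratio[site - 1]
        assert r_obs == pytest.approx(r_exp, abs=3 * se)

    def test_null_condition_fold_change_near_unity(self):
        """Equal stall probabilities in both dNTP pools give F ~= 1."""
        L, site = 150, 75
        fcs = []
        for seed in range(20):
            params = RtStopSimParams(length=L, n_frag=8000, seed=seed)
            truth = SimulationTruth(
                sites=(MethylSite(site, 0.0, 0.3, 0.3),)
            )
            low = simulate_rtstop_profiles(params, truth, Dntp.low)
            high = simulate_rtstop_profiles(params, truth, Dntp.high)
            fc = rt_stop_fold_change(rt_stop_ratio(low),
                                     rt_stop_ratio(high))
            fcs.append(fc.fold_change[site - 1])
        fcs = np.array(fcs)
        se = fcs.std(ddof=1) / math.sqrt(len(fcs))
        assert abs(fcs.mean() - 1.0) <= 3 * se

    def test_enriched_fold_change_at_methylated_site(self):
        params = RtStopSimParams(length=150, n_frag=10000, seed=21)
        truth = SimulationTruth(sites=(MethylSite(75, 0.0, 0.5, 0.05),))
        low = simulate_rtstop_profiles(params, truth, Dntp.low)
        high = simulate_rtstop_profiles(params, truth, Dntp.high)
        fc = rt_stop_fold_change(rt_stop_ratio(low), rt_stop_ratio(high))
        assert fc.fold_change[74] > 1.5


@pytest.fixture(scope="module")
def annotation():
    return human_mt_mrna_annotation()


class TestFootprintSimulator:
    def _occupancy_from_sims(self, annotation, ko_truth, par_truth,
                             scale=0.5, seeds=(101, 202)):
        tables = {}
        for label, truth, seed in (("ko", ko_truth, seeds[0]),
                                   ("par", par_truth, seeds[1])):
            params = FootprintSimParams(annotation=annotation, scale=scale,
                                        seed=seed)
            reads, norm = simulate_footprint_library(params, truth)
            kept, _ = filter_footprints(reads, annotation)
            tables[label] = expression_table(
                count_footprints(kept, annotation), norm
            )
        return occupancy(tables["ko"], tables["par"])

    def test_same_seed_bit_identical(self, annotation):
        params = FootprintSimParams(annotation=annotation, scale=0.1, seed=5)
        t = SimulationTruth()
        r1, n1 = simulate_footprint_library(params, t)
        r2, n2 = simulate_footprint_library(params, t)
        assert r1 == r2 and n1 == n2

    def test_null_contrast_near_100_percent(self, annotation):
        s = self._occupancy_from_sims(annotation, SimulationTruth(),
                                      SimulationTruth())
        assert s.mean == pytest.approx(100.0, abs=3 * s.sd / math.sqrt(13))

    def test_zero_scale_ko_gives_zero_occupancy(self, annotation):
        params = FootprintSimParams(annotation=annotation, scale=0.0, seed=1)
        reads, _ = simulate_footprint_library(params, SimulationTruth())
        assert reads == []
        s = self._occupancy_from_sims(
            annotation,
            ko_truth=SimulationTruth(
                occupancy_factors={g.gene: 0.0
                                   for g in annotation.mrna_genes()}
            ),
            par_truth=SimulationTruth(),
        )
        assert all(v == 0.0 for v in s.per_gene_occupancy.values())

    def test_simulated_reads_survive_filters(self, annotation):
        """Generated 5' positions avoid windows and overlap regions."""
        params = FootprintSimParams(annotation=annotation, scale=0.2, seed=8)
        reads, _ = simulate_footprint_library(params, SimulationTruth())
        kept, drops = filter_footprints(reads, annotation)
        assert len(kept) == len(reads)
        assert sum(drops.values()) == 0


class TestSilacSimulator:
    def test_null_table_is_exactly_unity(self):
        table, median = simulate_silac_table(
            SimulationTruth(mixing_bias=1.0, subunit_effect_log2=0.0),
            noise_sd=0.0, seed=2,
        )
        np.testing.assert_allclose(table["ratio"], 1.0)
        assert median == pytest.approx(1.0)

    def test_mixing_correction_inverts_bias_exactly(self):
        truth_biased = SimulationTruth(mixing_bias=2.0,
                                       subunit_effect_log2=0.7)
        truth_clean = SimulationTruth(mixing_bias=1.0,
                                      subunit_effect_log2=0.7)
        biased, median = simulate_silac_table(truth_biased, noise_sd=0.0,
                                              seed=6)
        clean, _ = simulate_silac_table(truth_clean, noise_sd=0.0, seed=6)
        corrected = correct_mixing(biased, median)
        np.testing.assert_allclose(corrected["ratio"], clean["ratio"])

    def test_same_seed_bit_identical(self):
        t = SimulationTruth(mixing_bias=1.5, subunit_effect_log2=0.4)
        a, ma = simulate_silac_table(t, seed=3)
        b, mb = simulate_silac_table(t, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert ma == mb


class TestTruthConfig:
    def test_yaml_round_trip(self, tmp_path):
        truth = SimulationTruth(
            sites=(MethylSite(2815, 0.9, 0.5, 0.05),
                   MethylSite(3039, 0.8, 0.4, 0.02)),
            occupancy_factors={"CO1": 0.139},
            mixing_bias=1.2,
            subunit_effect_log2=0.8,
        )
        path = tmp_path / "truth.yaml"
        truth.to_yaml(path)
        back = SimulationTruth.from_yaml(path)
        assert back.sites == truth.sites
        assert back.occupancy_factors == truth.occupancy_factors
        assert back.mixing_bias == truth.mixing_bias
        assert back.subunit_effect_log2 == truth.subunit_effect_log2

    def test_inverted_stop_efficiencies_warn(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="mitomethyl.simulate"):
            SimulationTruth(sites=(MethylSite(10, 0.5, 0.05, 0.5),))
        assert "q_low" in caplog.text
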