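"""Fisher tests, BH correction, bootstrap significance and retention."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from rnamotifs.cluster_calling import calibrate_h_min
from rnamotifs.motif_space import Tetramer
from rnamotifs.region_enrichment import (
    BootstrapConfig,
    HypergeomTail,
    bh_correct,
    bootstrap_empirical,
    cooccurrence_test,
    enrichment_analysis,
    fisher_region_test,
    region_occurrence,
    region_occurrence_matrices,
    retain_tetramers,
)


def enumerate_tail_p(k_reg, n_reg, k_ctl, n_ctl):
    """Independent oracle: enumerate all 2x2 tables with fixed margins and
    sum the probabilities of tables at least as enriched."""
    K = k_reg + k_ctl
    M = n_reg + n_ctl

    def choose(a, b):
        return math.comb(a, b) if 0 <= b <= a else 0

    denom = choose(M, n_reg)
    total = 0.0
    for x in range(max(0, K - n_ctl), min(K, n_reg) + 1):
        if x >= k_reg:
            total += choose(K, x) * choose(M - K, n_reg - x) / denom
    return total


class TestFisher:
    def test_printed_example_table(self):
        """30/98 regulated vs 300/4200 controls: upper hypergeometric tail,
        cross-checked against scipy's fisher_exact."""
        from scipy.stats import fisher_exact

        p = fisher_region_test(30, 98, 300, 4200)
        ref = fisher_exact([[30, 300], [68, 3900]], alternative="greater")[1]
        assert p == pytest.approx(ref, rel=1e-12)

    def test_zero_count_gives_one(self):
        assert fisher_region_test(0, 98, 300, 4200) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "k_reg,n_reg,k_ctl,n_ctl",
        [(3, 5, 1, 5), (0, 4, 2, 6), (5, 5, 0, 10), (2, 8, 7, 9)],
    )
    def test_small_tables_match_enumeration_oracle(self, k_reg, n_reg, k_ctl, n_ctl):
        assert fisher_region_test(k_reg, n_reg, k_ctl, n_ctl) == pytest.approx(
            enumerate_tail_p(k_reg, n_reg, k_ctl, n_ctl), rel=1e-10
        )

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            fisher_region_test(0, 0, 1, 10)

    def test_fast_tail_table_matches_scipy(self, rng):
        from scipy.stats import hypergeom

        tail = HypergeomTail()
        k = rng.integers(0, 80, 300)
        kc = rng.integers(0, 500, 300)
        mine = tail.p_greater(k, 80, kc, 1500)
        ref = hypergeom.sf(k - 1, 1580, k + kc, 80)
        assert np.allclose(mine, ref, rtol=1e-9)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_correct([0.03]) == pytest.approx([0.03])

    def test_hand_stepup_example(self):
        assert bh_correct([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_dominates_raw_and_preserves_order(self, rng):
        p = rng.random(320)
        adj = bh_correct(p)
        assert np.all(adj >= p) and np.all(adj <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(320) ** 3
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_correct(p), ref)

    def test_last_axis_vectorization(self, rng):
        p = rng.random((2, 3, 50))
        out = bh_correct(p)
        for s in range(2):
            for r in range(3):
                assert np.allclose(out[s, r], bh_correct(p[s, r]))


def _toy_occurrence(rng, n_e=30, n_s=30, n_c=200, n_t=8, signal_t=0, rate=0.7, bg=0.05):
    """Hand-built occurrence indicators: tetramer ``signal_t`` enriched in r3
    of enhanced events, everything else at background."""
    from rnamotifs.region_enrichment import RegionOccurrence

    n = n_e + n_s + n_c
    classes = np.array([0] * n_e + [1] * n_s + [2] * n_c, dtype=np.int8)
    O = (rng.random((n, 3, n_t)) < bg).astype(np.uint8)
    O[: n_e, 2, signal_t] = rng.random(n_e) < rate
    tets = [Tetramer(p) for p in ["AAAA", "CCCC", "GGGG", "TTTT", "ACGT", "TGCA", "GATC", "CTAG"][:n_t]]
    return RegionOccurrence(
        events=[None] * n, tetramers=tets, O=O,
        valid=np.ones((n, 3), bool), classes=classes,
    )


class TestBootstrap:
    def test_empirical_bounds_and_formula(self, rng):
        occ = _toy_occurrence(rng)
        p_obs = np.full((2, 3, 8), 0.5)
        cfg = BootstrapConfig(n_samples=200, seed=5)
        p_emp = bootstrap_empirical(occ, p_obs, cfg, log_every=0)
        assert np.all(p_emp >= 1 / 201) and np.all(p_emp <= 1.0)
        # an observed p below any achievable bootstrap p -> zero exceedances
        p_emp0 = bootstrap_empirical(occ, np.zeros((2, 3, 8)), cfg, log_every=0)
        assert np.all(p_emp0 == pytest.approx(1 / 201))
        # an observed p above all -> every replicate exceeds
        p_emp1 = bootstrap_empirical(occ, np.full((2, 3, 8), 2.0), cfg, log_every=0)
        assert np.all(p_emp1 == pytest.approx(1.0))

    def test_identical_seed_reproduces_identical_values(self, rng):
        occ = _toy_occurrence(rng)
        p_obs = np.full((2, 3, 8), 0.05)
        a = bootstrap_empirical(occ, p_obs, BootstrapConfig(n_samples=300, seed=9), log_every=0)
        b = bootstrap_empirical(occ, p_obs, BootstrapConfig(n_samples=300, seed=9), log_every=0)
        assert np.array_equal(a, b)
        c = bootstrap_empirical(occ, p_obs, BootstrapConfig(n_samples=300, seed=10), log_every=0)
        assert not np.array_equal(a, c)

    def test_pooled_null_detects_planted_signal(self, rng):
        occ = _toy_occurrence(rng)
        df = enrichment_analysis(occ, BootstrapConfig(n_samples=400, seed=2))
        row = df[(df.exon_set == "enhanced") & (df.region == "r3") & (df.tetramer == "AAAA")]
        assert float(row.p.iloc[0]) < 1e-10
        assert float(row.p_empirical.iloc[0]) == pytest.approx(1 / 401)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            BootstrapConfig(n_samples=0)
        with pytest.raises(ValueError):
            BootstrapConfig(scheme="sideways")


class TestRetention:
    def _frame(self, p_fdr, p_emp, region="r1"):
        return pd.DataFrame(
            {
                "exon_set": ["enhanced"] * 3,
                "region": ["r1", "r2", "r3"],
                "tetramer": ["TCAT"] * 3,
                "p": [p_fdr] * 3,
                "p_fdr": [p_fdr if r == region else 1.0 for r in ("r1", "r2", "r3")],
                "p_empirical": [p_emp if r == region else 1.0 for r in ("r1", "r2", "r3")],
            }
        )

    def test_both_thresholds_pass(self):
        df = retain_tetramers(self._frame(0.09, 0.0004))
        assert df.retained.all()

    def test_empirical_fails(self):
        df = retain_tetramers(self._frame(0.09, 0.002))
        assert not df.retained.any()

    def test_fdr_fails(self):
        df = retain_tetramers(self._frame(0.11, 0.0001))
        assert not df.retained.any()

    def test_thresholds_must_pass_in_same_region(self):
        df = self._frame(0.09, 0.0004)
        # move the passing p_empirical to a different region than the p_fdr
        df.loc[df.region == "r1", "p_empirical"] = 1.0
        df.loc[df.region == "r3", "p_empirical"] = 0.0004
        out = retain_tetramers(df)
        assert not out.retained.any()


class TestLabelSwap:
    def test_swapping_regulated_and_control_inverts_enrichment(self, rng):
        occ = _toy_occurrence(rng, rate=0.8, bg=0.02)
        tail = HypergeomTail()
        n_e = (occ.classes == 0).sum()
        k_e = occ.O[occ.classes == 0, 2, 0].sum()
        n_c = (occ.classes == 2).sum()
        k_c = occ.O[occ.classes == 2, 2, 0].sum()
        p_fwd = fisher_region_test(k_e, n_e, k_c, n_c)
        p_rev = fisher_region_test(k_c, n_c, k_e, n_e)
        assert p_fwd < 1e-12 and p_rev > 0.999


class TestOccurrenceScanning:
    def test_planted_cluster_sets_only_its_region(self, small_planted):
        cfg, genome, events, _, _ = small_planted
        hmin = calibrate_h_min(events, genome)
        occ = region_occurrence_matrices(events, genome, hmin)
        yi = [t.pattern for t in hmin.tetramers].index("YCAY")
        enh = occ.classes == 0
        ctl = occ.classes == 2
        r3_rate = occ.O[enh, 2, yi].mean()
        bg = occ.O[ctl, 2, yi].mean()
        # ~plant_rate of enhanced events carry the r3 cluster, plus background
        assert r3_rate > 0.55
        assert abs(r3_rate - cfg.plant_rate) < 0.25
        assert bg < 0.2
        # other regions stay near background
        assert occ.O[enh, 0, yi].mean() < bg + 0.2

    def test_matchless_genome_gives_all_zero_indicators(self, tmp_path):
        from rnamotifs.genome_io import ExonEvent, load_genome
        from rnamotifs.synthetic_fixtures import write_fasta

        # poly-A genome: GGGG can never match anywhere
        p = tmp_path / "g.fa"
        write_fasta({"c": "A" * 2000}, p)
        g = load_genome(p)
        e = ExonEvent(
            event_id="e", chrom="c", strand="+", ce_start=600, ce_end=700,
            up_exon_start=100, up_exon_end=200, down_exon_start=1100,
            down_exon_end=1200, reg_class="control",
        )
        res = region_occurrence(e, g, Tetramer("GGGG"), h_min=4)
        assert res == {"r1": 0, "r2": 0, "r3": 0}

    def test_single_event_wrapper(self, small_planted):
        cfg, genome, events, _, _ = small_planted
        e = next(ev for ev in events if ev.reg_class == "enhanced")
        res = region_occurrence(e, genome, Tetramer("YCAY"), h_min=9)
        assert set(res) == {"r1", "r2", "r3"}
        assert all(v in (0, 1) for v in res.values())


class TestCooccurrence:
    def test_reduces_to_region_test(self, rng):
        occ = _toy_occurrence(rng, rate=0.6, bg=0.05)
        res = cooccurrence_test(occ, "AAAA", "r3", "CCCC", "r1", "enhanced")
        both = (occ.O[:, 2, 0] > 0) & (occ.O[:, 0, 1] > 0)
        k_reg = both[occ.classes == 0].sum()
        k_ctl = both[occ.classes == 2].sum()
        expect = fisher_region_test(int(k_reg), 30, int(k_ctl), 200)
        assert res["p"] == pytest.approx(expect)
        assert res["k_reg"] == k_reg and res["k_ctl"] == k_ctl

    def test_zero_double_positives_give_p_one(self, rng):
        occ = _toy_occurrence(rng, bg=0.0, rate=0.0)
        res = cooccurrence_test(occ, "AAAA", "r3", "CCCC", "r1", "enhanced")
        assert res["p"] == pytest.approx(1.0)

    def test_perfect_separation_hits_hypergeometric_minimum(self, rng):
        occ = _toy_occurrence(rng, bg=0.0, rate=0.0)
        occ.O[occ.classes == 0, 2, 0] = 1
        occ.O[occ.classes == 0, 0, 1] = 1
        res = cooccurrence_test(occ, "AAAA", "r3", "CCCC", "r1", "enhanced")
        assert res["p"] == pytest.approx(enumerate_tail_p(30, 30, 0, 200), rel=1e-9)
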