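"""Fisher/KS/hypergeometric statistics, down-sampling and group analyses."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest

from pitmatch.enrichment_stats import (
    donor_level_fractions,
    downsample,
    fisher_or,
    group_match_fractions,
    ks_compare,
    overlap_hypergeom,
    threshold_curve_regression,
    vgene_enrichment,
)
from pitmatch.errors import ContractError
from pitmatch.repertoire_io import Repertoire
from conftest import make_record, make_repertoire


class TestFisherOr:
    def test_published_counts_log2_or(self):
        # 47 of 1,606 matched vs 22 of 1,606 in the unselected repertoire
        res = fisher_or([[47, 1559], [22, 1584]])
        closed_form = math.log2((47 * 1584) / (1559 * 22))
        assert res.log2_odds_ratio == pytest.approx(closed_form)
        assert res.log2_odds_ratio == pytest.approx(1.118, abs=5e-4)
        assert res.ci95[0] < res.log2_odds_ratio < res.ci95[1]
        assert res.p_value < 0.05

    def test_symmetric_table_is_null(self):
        res = fisher_or([[5, 50], [5, 50]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.log2_odds_ratio == pytest.approx(0.0)

    def test_balanced_exact_p_by_enumeration(self):
        res = fisher_or([[5, 5], [5, 5]])
        # hypergeometric enumeration over all tables with the same margins
        N, K, n = 20, 10, 10
        probs = {k: comb(K, k) * comb(N - K, n - k) / comb(N, n)
                 for k in range(max(0, n - (N - K)), min(K, n) + 1)}
        p0 = probs[5]
        expected = sum(p for p in probs.values() if p <= p0 + 1e-12)
        assert res.p_value == pytest.approx(expected)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        res = fisher_or([[10, 90], [0, 100]])
        assert res.corrected
        assert math.isfinite(res.log2_odds_ratio)
        res_inf = fisher_or([[10, 90], [0, 100]], zero_correction=False)
        assert math.isinf(res_inf.log2_odds_ratio)

    def test_row_and_column_swap_invariance(self):
        a = fisher_or([[12, 7], [3, 9]])
        both = fisher_or([[9, 3], [7, 12]])  # swap rows then columns
        assert a.log2_odds_ratio == pytest.approx(both.log2_odds_ratio)
        rows = fisher_or([[3, 9], [12, 7]])  # single row swap
        assert rows.log2_odds_ratio == pytest.approx(-a.log2_odds_ratio)

    def test_all_zero_row_flagged_undefined(self):
        assert fisher_or([[0, 0], [3, 4]]).undefined


class TestDownsample:
    def _rep(self, n):
        rng = np.random.default_rng(1)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        return make_repertoire(
            ["C" + "".join(rng.choice(aas, size=10)) + f"{'F'}"
             for _ in range(n)])

    def test_identity_and_determinism(self):
        rep = self._rep(50)
        assert (downsample(rep, 50, seed=1).junction_set()
                == rep.junction_set())
        a = downsample(rep, 20, seed=7)
        b = downsample(rep, 20, seed=7)
        assert a.junction_set() == b.junction_set()
        assert len(a.unique_junctions) == 20

    def test_too_large_n_errors(self):
        with pytest.raises(ContractError):
            downsample(self._rep(10), 11, seed=0)

    def test_inclusion_frequency_uniform(self):
        rep = self._rep(400)
        n, n_seeds = 100, 400
        counts = {j: 0 for j in rep.junction_set()}
        for s in range(n_seeds):
            for j in downsample(rep, n, seed=s).junction_set():
                counts[j] += 1
        p = n / 400
        se = math.sqrt(p * (1 - p) / n_seeds)
        freqs = np.array(list(counts.values())) / n_seeds
        assert abs(freqs.mean() - p) < 1e-9  # exactly n drawn each time
        assert (np.abs(freqs - p) < 5 * se).mean() > 0.99


class TestThresholdCurve:
    def test_identity_line(self):
        res = threshold_curve_regression([10, 50, 200, 800],
                                         [10, 50, 200, 800])
        assert res.slope == pytest.approx(1.0)
        assert res.p_vs_1 > 0.99

    def test_exact_linear_scaling(self):
        x = np.array([10, 50, 200, 800], dtype=float)
        res = threshold_curve_regression(x, 0.8 * x)
        assert res.slope == pytest.approx(0.8)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(2)
        slopes = []
        for _ in range(300):
            x = np.array([20, 80, 250, 600, 1100], dtype=float)
            y = 0.87 * x + rng.normal(scale=15, size=x.size)
            slopes.append(threshold_curve_regression(x, y).slope)
        mean = np.mean(slopes)
        se = np.std(slopes, ddof=1) / math.sqrt(len(slopes))
        assert abs(mean - 0.87) < 2 * se + 1e-3

    def test_too_few_points(self):
        with pytest.raises(ContractError):
            threshold_curve_regression([1, 2], [1, 2])


class TestOverlapHypergeom:
    def test_disjoint_and_degenerate(self):
        assert overlap_hypergeom({"a"}, {"b"}, 10) == pytest.approx(1.0)
        u = {f"j{i}" for i in range(8)}
        assert overlap_hypergeom(u, u, 8) == pytest.approx(1.0)

    def test_matches_bruteforce_pmf_sum(self):
        universe = [f"j{i}" for i in range(1000)]
        A = set(universe[:50])
        B = set(universe[40:80])  # overlap 10
        p = overlap_hypergeom(A, B, 1000)
        brute = sum(
            comb(50, k) * comb(950, 40 - k) / comb(1000, 40)
            for k in range(10, 41))
        assert p == pytest.approx(brute, rel=1e-10)

    def test_inconsistent_sizes_error(self):
        with pytest.raises(ContractError):
            overlap_hypergeom({"a", "b"}, {"a"}, 1)


class TestKsCompare:
    def test_identical_samples(self):
        d, p = ks_compare([1, 2, 3, 4], [1, 2, 3, 4])
        assert d == 0

    def test_disjoint_supports(self):
        d, _ = ks_compare([1, 2, 3], [10, 11, 12])
        assert d == 1

    def test_alternative_honored(self):
        x = [1, 2, 3, 4, 5]
        y = [3, 4, 5, 6, 7]
        _, p_less = ks_compare(x, y, alternative="less")
        _, p_greater = ks_compare(x, y, alternative="greater")
        assert p_less != p_greater

    def test_small_sample_error(self):
        with pytest.raises(ContractError):
            ks_compare([1], [1, 2])


def _usage_repertoire(rng, n, weights: dict[str, float], prefix):
    genes = sorted(weights)
    p = np.array([weights[g] for g in genes])
    p = p / p.sum()
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    records = []
    for i in range(n):
        g = genes[rng.choice(len(genes), p=p)]
        jx = "C" + "".join(rng.choice(aas, size=11)) + "F"
        records.append(make_record(jx, record_id=f"{prefix}{i}",
                                   cell_id=f"{prefix}c{i}", v_gene=g))
    return Repertoire(records)


class TestVgeneEnrichment:
    def test_identical_profiles_null(self):
        rng = np.random.default_rng(3)
        w = {f"TRAV{i}": 1.0 for i in range(1, 9)}
        m = _usage_repertoire(rng, 400, w, "m")
        n = _usage_repertoire(rng, 400, w, "n")
        out = vgene_enrichment(m, n)
        assert all(e.p_adj > 0.05 for e in out)

    def test_gene_only_in_matched_flagged(self):
        m = make_repertoire(["CAVRMNTGFQKLVF"])
        n = Repertoire([make_record("CAASNTGNQFYF", v_gene="TRAV41")])
        out = {e.gene: e for e in vgene_enrichment(m, n)}
        assert out["TRAV1-2"].result.corrected
        assert out["TRAV1-2"].direction == "over"

    def test_planted_threefold_usage_recovered(self):
        rng = np.random.default_rng(5)
        null = {f"TRAV{i}": 1.0 for i in range(1, 21)}
        base = dict(null, TRAVP1=1.0, TRAVP2=1.0)
        boosted = dict(null, TRAVP1=3.0, TRAVP2=3.0)
        m = _usage_repertoire(rng, 800, boosted, "m")
        n = _usage_repertoire(rng, 800, base, "n")
        out = {e.gene: e for e in vgene_enrichment(m, n)}
        assert out["TRAVP1"].p_adj < 0.05
        assert out["TRAVP2"].p_adj < 0.05
        assert out["TRAVP1"].direction == "over"

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(6)
        w = {f"TRAV{i}": rng.uniform(0.5, 2.0) for i in range(1, 15)}
        m = _usage_repertoire(rng, 300, w, "m")
        n = _usage_repertoire(
            rng, 300, {g: v * rng.uniform(0.8, 1.2) for g, v in w.items()},
            "n")
        out = vgene_enrichment(m, n)
        by_raw = sorted(out, key=lambda e: e.result.p_value)
        padj = [e.p_adj for e in by_raw]
        assert padj == sorted(padj)


def _flagged_repertoire(rng, groups, n_per_group, matched_fraction):
    records, flags = [], {}
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    i = 0
    for g in groups:
        for k in range(n_per_group):
            jx = "C" + "".join(rng.choice(aas, size=11)) + "F"
            records.append(make_record(
                jx, record_id=f"r{i}", cell_id=f"c{i}",
                donor_id=f"{g}_d{k % 6}", disease_group=g))
            flags[jx] = bool(rng.random() < matched_fraction[g])
            i += 1
    return Repertoire(records), flags


class TestGroupFractions:
    def test_null_composition_no_signal(self):
        rng = np.random.default_rng(8)
        rep, flags = _flagged_repertoire(
            rng, ["HC", "newT1D", "T1D"], 150,
            {"HC": 0.1, "newT1D": 0.1, "T1D": 0.1})
        res = group_match_fractions(rep, flags)
        assert (res.pairwise.p_adj > 0.05).all()

    def test_planted_difference_detected(self):
        rng = np.random.default_rng(9)
        rep, flags = _flagged_repertoire(
            rng, ["HC", "newT1D", "T1D"], 150,
            {"HC": 0.1, "newT1D": 0.3, "T1D": 0.1})
        res = group_match_fractions(rep, flags)
        hit = res.pairwise[(res.pairwise.group_a == "HC")
                           & (res.pairwise.group_b == "newT1D")]
        assert (hit.p_adj < 0.05).all()

    def test_equalize_is_seeded_and_reproducible(self):
        rng = np.random.default_rng(10)
        rep, flags = _flagged_repertoire(
            rng, ["HC", "T1D"], 120, {"HC": 0.15, "T1D": 0.15})
        a = group_match_fractions(rep, flags, equalize=True, seed=4)
        b = group_match_fractions(rep, flags, equalize=True, seed=4)
        pd.testing.assert_frame_equal(a.fractions, b.fractions)
        with pytest.raises(ContractError):
            group_match_fractions(rep, flags, equalize=True)


class TestDonorLevel:
    def test_identical_fractions_null(self):
        rng = np.random.default_rng(11)
        rep, flags = _flagged_repertoire(
            rng, ["HC", "T1D"], 120, {"HC": 0.2, "T1D": 0.2})
        res = donor_level_fractions(rep, flags)
        assert (res.pairwise.p > 0.05).all()

    def test_planted_shift_sign_recovered(self):
        rng = np.random.default_rng(12)
        rep, flags = _flagged_repertoire(
            rng, ["HC", "newT1D"], 200, {"HC": 0.1, "newT1D": 0.25})
        res = donor_level_fractions(rep, flags)
        row = res.pairwise.iloc[0]
        assert row.delta < 0  # HC minus newT1D

    def test_single_donor_group_skipped(self):
        rep = Repertoire([
            make_record("CAVRMNTGFQKLVF", record_id="r1", cell_id="c1",
                        donor_id="solo", disease_group="HC"),
            make_record("CAASNTGNQFYF", record_id="r2", cell_id="c2",
                        donor_id="a", disease_group="T1D"),
            make_record("CVVNDQAGTALIF", record_id="r3", cell_id="c3",
                        donor_id="b", disease_group="T1D"),
        ])
        res = donor_level_fractions(rep, {})
        assert ("HC", "T1D") in res.skipped
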