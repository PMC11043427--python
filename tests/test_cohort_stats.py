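import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from katascan.cohort_stats import (
    bh_adjust,
    chi_square_test,
    classify_binary,
    compute_tmb,
    driver_association,
    event_counts,
    frequency_by_cutoff,
    kruskal_wallis,
    metagene_rank_score,
    wilcoxon_rank_sum,
)
from katascan.detection import DetectionParams, detect_kataegis

from conftest import build_catalog
from _oracles import bh_stepup, exact_wilcoxon_pvalue

RUN6 = [100, 600, 1100, 1600, 2100, 2600]


def _loci(chroms):
    cat = build_catalog(
        {c: [p + i * 10_000 for p in RUN6] for i, c in enumerate(chroms)}
    )
    return detect_kataegis(cat, DetectionParams())


class TestBinaryStatus:
    def test_zero_events_always_negative(self):
        for cutoff in (1, 2, 5):
            assert classify_binary({"S": []}, cutoff)["S"] is False

    def test_x_chromosome_event_counts(self):
        loci = {"S": _loci(["X"])}
        assert classify_binary(loci, 1)["S"] is True

    def test_y_chromosome_event_excluded(self):
        loci = {"S": _loci(["Y"])}
        assert classify_binary(loci, 1)["S"] is False

    def test_cutoff_above_count_is_negative(self):
        loci = {"S": _loci(["1", "2"])}
        assert classify_binary(loci, 3)["S"] is False
        assert classify_binary(loci, 2)["S"] is True

    def test_positive_sets_nested_across_cutoffs(self):
        rng = np.random.default_rng(2)
        loci = {
            f"S{i}": _loci([str(c) for c in range(1, 1 + rng.integers(0, 6))])
            for i in range(20)
        }
        pos = {
            k: {s for s in loci if classify_binary(loci, k)[s]} for k in (1, 2, 3)
        }
        assert pos[3] <= pos[2] <= pos[1]


class TestFrequencyCurve:
    def test_all_samples_above_three_events(self):
        counts = {f"S{i}": 3 + i for i in range(5)}
        curve = frequency_by_cutoff(counts, list(counts), cutoffs=(1, 2, 3))
        assert (curve["frequency"] == 1.0).all()

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(6)
        counts = {f"S{i}": int(rng.poisson(2)) for i in range(50)}
        curve = frequency_by_cutoff(counts, list(counts), cutoffs=range(1, 8))
        assert (np.diff(curve["frequency"]) <= 0).all()

    def test_matches_direct_counting(self):
        counts = {"A": 0, "B": 1, "C": 2, "D": 5}
        curve = frequency_by_cutoff(counts, list(counts), cutoffs=(1, 2, 3))
        assert curve["frequency"].tolist() == [0.75, 0.5, 0.25]

    def test_empty_subgroup_rejected(self):
        with pytest.raises(ValueError):
            frequency_by_cutoff({}, [])


class TestTmb:
    def test_basic(self):
        assert compute_tmb(3000, 0, 3_000_000_000) == pytest.approx(1.0)
        assert compute_tmb(0, 0, 1_000_000) == 0.0
        assert compute_tmb(50, 50, 50_000_000) == pytest.approx(2.0)

    def test_positive_genome_size_required(self):
        with pytest.raises(ValueError):
            compute_tmb(1, 1, 0)


class TestMetageneScore:
    def test_top_two_of_five(self):
        expr = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        assert metagene_rank_score(expr, ["d", "e"]) == pytest.approx(0.9)

    def test_all_genes_score(self):
        g = 7
        expr = pd.Series(np.arange(g, dtype=float), index=[f"g{i}" for i in range(g)])
        assert metagene_rank_score(expr, expr.index) == pytest.approx((g + 1) / (2 * g))

    def test_single_sample_independence(self):
        rng = np.random.default_rng(1)
        expr = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        before = metagene_rank_score(expr, ["g3", "g7", "g11"])
        # scores never depend on other samples; recomputing after reordering
        # the gene index must not change the score either
        shuffled = expr.sample(frac=1.0, random_state=0)
        assert metagene_rank_score(shuffled, ["g3", "g7", "g11"]) == pytest.approx(before)

    def test_missing_set_flagged(self):
        expr = pd.Series([1.0], index=["a"])
        assert metagene_rank_score(expr, ["zzz"]) is None

    def test_ties_get_average_ranks(self):
        expr = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
        # b and c share ranks 2,3 -> 2.5 each
        assert metagene_rank_score(expr, ["b", "c"]) == pytest.approx(2.5 / 4)


class TestWilcoxon:
    def test_identical_groups_null_center(self):
        res = wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.pvalue > 0.9

    def test_exact_small_sample(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.pvalue == pytest.approx(2 / 6)
        assert res.pvalue == pytest.approx(exact_wilcoxon_pvalue([1, 2], [3, 4]))

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            n, m = rng.integers(2, 6, 2)
            pool = rng.choice(np.arange(100), size=n + m, replace=False).astype(float)
            x, y = pool[:n].tolist(), pool[n:].tolist()
            res = wilcoxon_rank_sum(x, y)
            assert res.pvalue == pytest.approx(exact_wilcoxon_pvalue(x, y))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=25).tolist()
        y = (rng.normal(size=30) + 0.5).tolist()
        p1 = wilcoxon_rank_sum(x, y).pvalue
        p2 = wilcoxon_rank_sum(np.exp(x).tolist(), np.exp(y).tolist()).pvalue
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestKruskalWallis:
    def test_two_groups_agree_with_rank_sum_normal_approx(self):
        """For k=2 the H statistic is the square of the tie-corrected
        rank-sum z score, so the chi2(1) p equals the two-sided normal p."""
        rng = np.random.default_rng(15)
        x = rng.normal(size=20)
        y = rng.normal(0.8, 1, size=25)
        res = kruskal_wallis([x, y])
        # independent z from the rank-sum statistic, no continuity correction
        n, m = len(x), len(y)
        ranks = sps.rankdata(np.concatenate([x, y]))
        rank_sum = ranks[:n].sum()
        z = (rank_sum - n * (n + m + 1) / 2) / np.sqrt(n * m * (n + m + 1) / 12)
        assert res.statistic == pytest.approx(z**2)
        assert res.pvalue == pytest.approx(2 * sps.norm.sf(abs(z)))

    def test_all_equal_degenerate(self):
        res = kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert res.statistic == 0.0 and res.degenerate

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(16)
        groups = [rng.normal(loc, 1, size=15) for loc in (0, 0.5, 1.0)]
        p1 = kruskal_wallis(groups).pvalue
        p2 = kruskal_wallis([np.tanh(g) for g in groups]).pvalue
        assert p1 == pytest.approx(p2)


class TestChiSquare:
    def test_balanced_table_statistic_zero(self):
        res = chi_square_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.pvalue == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # all expected counts are 15: chi2 = 4 * 25/15 = 20/3
        res = chi_square_test([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(20 / 3)

    def test_yates_flag_changes_2x2(self):
        plain = chi_square_test([[20, 10], [10, 20]])
        yates = chi_square_test([[20, 10], [10, 20]], continuity=True)
        assert yates.statistic < plain.statistic

    def test_zero_marginal_degenerate(self):
        res = chi_square_test([[0, 0], [5, 10]])
        assert res.degenerate and np.isnan(res.pvalue)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[1, -1], [2, 3]])


class TestBhAdjust:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.03]).tolist() == [0.03]

    def test_uniformly_spaced_all_collapse(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_stepup_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 30)))
            assert bh_adjust(p).tolist() == pytest.approx(bh_stepup(p.tolist()))

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(18)
        p = rng.random(25)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDriverAssociation:
    def _simulated(self, seed, shuffle=False):
        rng = np.random.default_rng(seed)
        n = 400
        samples = [f"S{i}" for i in range(n)]
        status = {s: bool(rng.random() < 0.5) for s in samples}
        flags = {}
        for g in range(20):
            gene = "EFFECT" if g == 0 else f"NULL{g:02d}"
            p_pos = 0.4 if gene == "EFFECT" else 0.15  # OR ~ 3.8 vs 1
            flags[gene] = [
                int(rng.random() < (p_pos if status[s] else 0.15)) for s in samples
            ]
        df = pd.DataFrame(flags, index=pd.Index(samples, name="sample"))
        if shuffle:
            values = list(status.values())
            rng.shuffle(values)
            status = dict(zip(samples, values))
        return df, status, samples

    def test_effect_gene_has_smallest_adjusted_p(self):
        df, status, samples = self._simulated(seed=19)
        out = driver_association(df, status, samples)
        best = out.loc[out["adjusted_pvalue"].idxmin(), "gene"]
        assert best == "EFFECT"
        assert out.loc[out["gene"] == "EFFECT", "adjusted_pvalue"].iloc[0] < 0.01

    def test_permuted_status_destroys_significance(self):
        df, status, samples = self._simulated(seed=19, shuffle=True)
        out = driver_association(df, status, samples)
        assert out.loc[out["gene"] == "EFFECT", "adjusted_pvalue"].iloc[0] > 0.05

    def test_gene_altered_everywhere_degenerate_and_excluded(self):
        samples = [f"S{i}" for i in range(10)]
        status = {s: i % 2 == 0 for i, s in enumerate(samples)}
        df = pd.DataFrame(
            {"ALL": [1] * 10, "SOME": [1, 0] * 5},
            index=pd.Index(samples, name="sample"),
        )
        out = driver_association(df, status, samples)
        row = out[out["gene"] == "ALL"].iloc[0]
        assert row["degenerate"] and np.isnan(row["adjusted_pvalue"])
        assert not out[out["gene"] == "SOME"]["degenerate"].iloc[0]
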