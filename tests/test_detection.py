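import numpy as np
import pytest

from katascan.detection import (
    DetectionParams,
    confidence_score,
    detect_kataegis,
    filter_loci,
)

from conftest import build_catalog
from _oracles import brute_loci_max, brute_loci_mean

MAX = DetectionParams(imd_rule="max")
MEAN = DetectionParams(imd_rule="mean")


def _intervals(loci, positions):
    pos = list(positions)
    return [(pos.index(lc.start), pos.index(lc.end)) for lc in loci]


class TestExamples:
    def test_uniform_run_is_one_locus(self):
        cat = build_catalog({"1": [100, 600, 1100, 1600, 2100, 2600]})
        loci = detect_kataegis(cat, MAX)
        assert len(loci) == 1
        lc = loci[0]
        assert (lc.start, lc.end, lc.n_sbs) == (100, 2600, 6)
        assert lc.max_imd == 500 and lc.mean_imd == 500
        assert lc.span_bp == 2501

    def test_below_min_sbs_is_no_locus(self):
        cat = build_catalog({"1": [100, 200, 300, 400, 500]})
        assert detect_kataegis(cat, MAX) == []
        assert detect_kataegis(cat, MEAN) == []

    def test_rule_discrimination(self):
        """Two tight quartets joined by a 5 kb gap: the max rule sees two
        sub-threshold runs, the mean rule one 7-SBS locus (916.7 <= 1000)."""
        positions = [1, 101, 201, 301, 5301, 5401, 5501]
        cat = build_catalog({"1": positions})
        assert detect_kataegis(cat, MAX) == []
        loci = detect_kataegis(cat, MEAN)
        assert len(loci) == 1
        assert loci[0].n_sbs == 7
        assert loci[0].mean_imd == pytest.approx(5500 / 6)

    def test_same_position_multiallelic_gives_zero_imd(self):
        cat = build_catalog(
            {"1": [100, 100, 600, 1100, 1600, 2100]},
            alleles={"1": (["C"] * 6, ["T", "G", "T", "T", "T", "T"])},
        )
        loci = detect_kataegis(cat, MAX)
        assert len(loci) == 1 and loci[0].n_sbs == 6

    def test_no_cross_chromosome_runs(self):
        cat = build_catalog({"1": [100, 200, 300], "2": [400, 500, 600]})
        assert detect_kataegis(cat, DetectionParams(min_sbs=6)) == []

    def test_empty_catalog(self):
        assert detect_kataegis(build_catalog({}), MAX) == []


class TestOracleEquivalence:
    @pytest.mark.parametrize("rule,oracle", [("max", brute_loci_max), ("mean", brute_loci_mean)])
    def test_random_catalogs(self, rule, oracle):
        rng = np.random.default_rng(42)
        params = DetectionParams(imd_rule=rule)
        for _ in range(150):
            n = int(rng.integers(0, 60))
            positions = np.sort(
                rng.choice(np.arange(1, 200_001), size=n, replace=False)
            )
            cat = build_catalog({"1": positions.tolist()})
            got = _intervals(detect_kataegis(cat, params), positions.tolist())
            assert got == oracle(positions.tolist(), 6, 1000)

    @pytest.mark.parametrize("rule,oracle", [("max", brute_loci_max), ("mean", brute_loci_mean)])
    def test_dense_catalogs_small_threshold(self, rule, oracle):
        """Densely packed positions with a tiny threshold exercise window
        merging much harder than uniform catalogs do."""
        rng = np.random.default_rng(5)
        params = DetectionParams(min_sbs=3, imd_threshold=7, imd_rule=rule)
        for _ in range(100):
            n = int(rng.integers(2, 25))
            positions = np.sort(rng.choice(np.arange(1, 120), size=n, replace=False))
            cat = build_catalog({"1": positions.tolist()})
            got = _intervals(detect_kataegis(cat, params), positions.tolist())
            assert got == oracle(positions.tolist(), 3, 7)


class TestInvariants:
    def _random_catalog(self, rng, n=80, span=300_000):
        positions = np.sort(rng.choice(np.arange(1, span), size=n, replace=False))
        return build_catalog({"1": positions.tolist()}), positions

    def test_members_pairwise_disjoint(self):
        rng = np.random.default_rng(9)
        for params in (MAX, MEAN):
            for _ in range(20):
                cat, _ = self._random_catalog(rng)
                seen = set()
                for lc in detect_kataegis(cat, params):
                    members = set(lc.positions.tolist())
                    assert not members & seen
                    seen |= members

    def test_monotone_in_threshold_and_min_sbs(self):
        rng = np.random.default_rng(10)
        cat, _ = self._random_catalog(rng, n=120, span=100_000)
        base_members = {
            p for lc in detect_kataegis(cat, DetectionParams(imd_rule="max"))
            for p in lc.positions.tolist()
        }
        looser = [
            DetectionParams(imd_rule="max", imd_threshold=2500),
            DetectionParams(imd_rule="max", min_sbs=4),
        ]
        for params in looser:
            members = {
                p for lc in detect_kataegis(cat, params)
                for p in lc.positions.tolist()
            }
            assert base_members <= members

    def test_deleting_non_member_leaves_loci_unchanged(self):
        rng = np.random.default_rng(12)
        cat, positions = self._random_catalog(rng, n=60, span=80_000)
        loci = detect_kataegis(cat, MAX)
        members = {p for lc in loci for p in lc.positions.tolist()}
        non_members = [p for p in positions.tolist() if p not in members]
        assert non_members, "catalog should contain background"
        drop = non_members[len(non_members) // 2]
        cat2 = build_catalog({"1": [p for p in positions.tolist() if p != drop]})
        loci2 = detect_kataegis(cat2, MAX)
        assert [(l.start, l.end) for l in loci] == [(l.start, l.end) for l in loci2]


class TestConfidence:
    def _locus(self, classes):
        spacing = list(range(100, 100 * (len(classes) + 1), 100))
        by_class = {"C>T": ("C", "T"), "C>G": ("C", "G"), "T>A": ("T", "A")}
        refs = [by_class[c][0] for c in classes]
        alts = [by_class[c][1] for c in classes]
        cat = build_catalog({"1": spacing}, alleles={"1": (refs, alts)})
        loci = detect_kataegis(cat, DetectionParams(min_sbs=min(6, len(classes))))
        assert len(loci) == 1
        return loci[0]

    def test_small_apobec_locus_is_tier_two(self):
        assert self._locus(["C>T"] * 6).confidence == 2

    def test_large_apobec_locus_is_tier_three(self):
        lc = self._locus(["C>G"] * 11 + ["T>A"])
        assert lc.n_sbs == 12 and lc.confidence == 3

    def test_mixed_locus_is_tier_one(self):
        assert self._locus(["C>T"] * 3 + ["T>A"] * 3).confidence == 1

    def test_purine_strand_counts_as_apobec_after_normalization(self):
        cat = build_catalog({"1": [100, 200, 300, 400, 500, 600]}, ref="G", alt="A")
        lc = detect_kataegis(cat, MAX)[0]
        assert lc.class_counts["C>T"] == 6
        assert confidence_score(lc) == 2


class TestFilter:
    def _three_loci(self):
        return [
            TestConfidence()._locus(["C>T"] * 6),
            TestConfidence()._locus(["C>G"] * 11 + ["T>A"]),
            TestConfidence()._locus(["C>T"] * 3 + ["T>A"] * 3),
        ]

    def test_default_filter_keeps_everything_on_1_23(self):
        loci = self._three_loci()
        assert filter_loci(loci, DetectionParams(min_confidence=1)) == loci

    def test_high_confidence_filter(self):
        loci = self._three_loci()
        kept = filter_loci(loci, DetectionParams(min_confidence=3))
        assert kept == [loci[1]]

    def test_chromosome_y_always_removed(self):
        cat = build_catalog({"Y": [100, 200, 300, 400, 500, 600]})
        loci = detect_kataegis(cat, MAX)
        assert len(loci) == 1
        assert filter_loci(loci, MAX) == []

    def test_chromosome_x_retained(self):
        cat = build_catalog({"X": [100, 200, 300, 400, 500, 600]})
        assert len(filter_loci(detect_kataegis(cat, MAX), MAX)) == 1


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            DetectionParams(min_sbs=1)
        with pytest.raises(ValueError):
            DetectionParams(imd_threshold=0)
        with pytest.raises(ValueError):
            DetectionParams(imd_rule="median")
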