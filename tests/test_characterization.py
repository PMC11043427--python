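import numpy as np
import pytest

from katascan.characterization import (
    bin_recurrence,
    events_per_chromosome,
    locus_midpoint_bin,
    locus_size_summary,
    merged_spectrum,
)
from katascan.detection import DetectionParams, detect_kataegis
from katascan.genome import GenomeBuild, make_bins
from katascan.simulate import SimulationConfig, SubgroupSpec, simulate_cohort

from conftest import build_catalog


def _locus(positions, ref="C", alt="T", chrom="1", sample="S1"):
    cat = build_catalog({chrom: positions}, sample_id=sample, ref=ref, alt=alt)
    loci = detect_kataegis(cat, DetectionParams())
    assert len(loci) == 1
    return loci[0]


RUN6 = [100, 600, 1100, 1600, 2100, 2600]


class TestSpectrum:
    def test_purine_members_are_strand_normalized(self):
        profile = merged_spectrum([_locus(RUN6, ref="G", alt="A")])
        assert profile.proportions["C>T"] == 1.0

    def test_even_split(self):
        loci = [_locus(RUN6, ref="C", alt="T"), _locus(RUN6, ref="C", alt="G")]
        props = merged_spectrum(loci).proportions
        assert props["C>T"] == 0.5 and props["C>G"] == 0.5

    def test_empty_pool_flagged(self):
        profile = merged_spectrum([])
        assert profile.total == 0 and profile.proportions is None

    def test_proportions_sum_to_one(self):
        loci = [
            _locus(RUN6, ref="C", alt="T"),
            _locus(RUN6, ref="T", alt="A"),
            _locus(RUN6, ref="G", alt="C"),
        ]
        assert sum(merged_spectrum(loci).proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_merged_equals_sum_of_per_tumor_spectra(self):
        l1 = _locus(RUN6, ref="C", alt="T", sample="A")
        l2 = _locus(RUN6, ref="T", alt="C", sample="B")
        merged = merged_spectrum([l1, l2]).counts
        per_tumor = [merged_spectrum([l1]).counts, merged_spectrum([l2]).counts]
        for cls in merged:
            assert merged[cls] == sum(c[cls] for c in per_tumor)


class TestSizeSummary:
    def test_single_locus(self):
        out = locus_size_summary([_locus(RUN6)])
        assert out["span_bp"].tolist() == [2501]
        assert out["n_sbs"].tolist() == [6]

    def test_empty_subgroup(self):
        out = locus_size_summary([])
        assert len(out["span_bp"]) == 0 and out["quantiles"]["span_bp"] == {}

    def test_quantiles_match_sort_oracle(self):
        rng = np.random.default_rng(4)
        loci = [
            _locus((start + np.arange(6) * int(step)).tolist())
            for start, step in zip(
                rng.integers(1, 10**7, 30), rng.integers(50, 900, 30)
            )
        ]
        out = locus_size_summary(loci)
        spans = sorted(lc.span_bp for lc in loci)
        assert out["quantiles"]["span_bp"]["q50"] == pytest.approx(
            np.quantile(spans, 0.5)
        )
        assert out["quantiles"]["n_sbs"]["mean"] == 6.0


class TestChromosomeCounts:
    def test_counts_by_chromosome(self):
        loci = [
            _locus(RUN6, chrom="17"),
            _locus([p + 10_000 for p in RUN6], chrom="17"),
            _locus([p + 20_000 for p in RUN6], chrom="17"),
            _locus(RUN6, chrom="8"),
        ]
        counts = events_per_chromosome(loci)
        assert counts["17"] == 3 and counts["8"] == 1
        assert sum(counts.values()) == 4

    def test_x_excluded_by_default(self):
        counts = events_per_chromosome([_locus(RUN6, chrom="X")])
        assert sum(counts.values()) == 0
        with_x = events_per_chromosome(
            [_locus(RUN6, chrom="X")], chromosomes=[str(i) for i in range(1, 23)] + ["X"]
        )
        assert with_x["X"] == 1


class TestBinRecurrence:
    def _genome(self):
        return GenomeBuild("t", (("1", 5_000_000), ("2", 3_000_000)))

    def test_midpoint_assignment(self):
        scheme = make_bins(self._genome(), 2_000_000)
        lc = _locus([1_999_000 + i * 500 for i in range(6)])
        # midpoint (1998999 + 2001500) // 2 = 2000249 -> bin 1
        assert locus_midpoint_bin(lc, scheme) == 1

    def test_events_not_tumors_counted(self):
        scheme = make_bins(self._genome(), 2_000_000)
        one_tumor_two_loci = [
            _locus(RUN6, sample="A"),
            _locus([p + 10_000 for p in RUN6], sample="A"),
        ]
        table = bin_recurrence({"g": one_tumor_two_loci}, scheme, {"g": 4})
        assert table["count_g"].iloc[0] == 2
        assert table["frequency_g"].iloc[0] == pytest.approx(0.5)

    def test_two_tumors_same_bin(self):
        scheme = make_bins(self._genome(), 2_000_000)
        loci = [_locus(RUN6, sample="A"), _locus([p + 5000 for p in RUN6], sample="B")]
        table = bin_recurrence({"g": loci}, scheme, {"g": 4})
        assert table["count_g"].iloc[0] == 2 and table["frequency_g"].iloc[0] == 0.5

    def test_conservation_and_chromosome_agreement(self):
        rng = np.random.default_rng(8)
        genome = GenomeBuild("t", tuple((str(i), 4_000_000) for i in range(1, 6)))
        scheme = make_bins(genome, 2_000_000)
        loci = [
            _locus((int(start) + np.arange(6) * 200).tolist(), chrom=str(chrom))
            for chrom, start in zip(
                rng.integers(1, 6, 40), rng.integers(1, 3_900_000, 40)
            )
        ]
        table = bin_recurrence({"g": loci}, scheme, {"g": 10})
        chrom_counts = events_per_chromosome(loci)
        assert table["count_g"].sum() == len(loci) == sum(chrom_counts.values())
        for chrom in genome.names:
            assert (
                table.loc[table["chromosome"] == chrom, "count_g"].sum()
                == chrom_counts[chrom]
            )

    def test_group_size_validated(self):
        scheme = make_bins(self._genome(), 2_000_000)
        with pytest.raises(ValueError):
            bin_recurrence({"g": []}, scheme, {"g": 0})

    def test_injected_hotspot_attains_maximum_frequency(self):
        """Concentrating clusters at one genomic location across tumors must
        surface that bin as the group's recurrence maximum."""
        config = SimulationConfig(
            subgroups={"g": SubgroupSpec(20, 1.0)},
            background_rate_per_mb=0.5,
            hotspot_regions=(("5", 10_000_000, 12_000_000),),
            hotspot_probability=0.9,
            tracks={},
            placement_track=None,
        )
        cohort = simulate_cohort(config, seed=5)
        loci = [
            lc
            for sid, cat in cohort.catalogs.items()
            for lc in detect_kataegis(cat, DetectionParams())
        ]
        scheme = make_bins(config.genome, 2_000_000)
        table = bin_recurrence({"g": loci}, scheme, {"g": 20})
        top = table.loc[table["count_g"].idxmax()]
        assert top["chromosome"] == "5"
        assert 10_000_000 <= top["start"] < 12_000_000
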