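"""Ground-truth cohort simulator.

Generates everything the pipeline consumes — per-sample SBS catalogs,
annotation tracks, clinical metadata, driver-alteration flags, an
expression matrix with metagene structure — together with the ground truth
used to score detection.

The generative model, briefly:

* **Background SBSs** are placed uniformly per chromosome at a configurable
  per-Mb rate (Poisson counts), with a configurable six-class substitution
  distribution.  Kataegis-positive samples may carry a higher background
  rate (``tmb_positive_multiplier``), emulating the observed association of
  kataegis with tumor mutational burden.
* **Kataegis clusters**: each sample is kataegis-positive with its
  subgroup's positivity probability; a positive sample receives a geometric
  number of clusters.  A cluster has a uniform size (default 6-25 SBSs) and
  uniform adjacent spacing (default 10-300 bp), is optionally placed into a
  hotspot region or into one designated annotation track with an elevated
  probability, and draws its substitutions from an APOBEC-like class
  distribution (default C>T 0.45, C>G 0.40, remainder split evenly).  Each
  cluster sits on one strand (all C>N or all G>N before pyrimidine
  normalization) to mimic strand-coordinated kataegis.
* **Annotation tracks** are regular interval tilings with configured genome
  coverage fractions; the designated placement track receives clusters with
  probability ``enrichment x coverage`` (in-track placement uniform over
  track intervals, out-of-track uniform over the complement), so the
  expected kataegis-SBS mapped proportion is ``enrichment x coverage``.
* **Metadata / drivers / expression** are drawn from simple conditional
  models given the true kataegis status (driver log-odds shifts, metagene
  mean shifts on log-scale Gaussian expression).

Everything is driven by one ``numpy`` Generator, so a fixed seed makes every
output bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import (
    GenomeBuild,
    SUBSTITUTION_CLASSES,
    canonical_chromosome,
    synthetic_genome,
)
from .variant_io import AnnotationTrack, SampleCatalog, merge_intervals, write_bed, write_catalog
from .detection import KataegisLocus

logger = logging.getLogger(__name__)

__all__ = [
    "SubgroupSpec",
    "TrackSpec",
    "SimulationConfig",
    "TruthLocus",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "truth_match",
    "MatchResult",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Receptor status implied by each clinical subgroup label.
_SUBGROUP_RECEPTORS = {
    "TNBC": ("neg", "neg", "neg"),
    "ERpHER2n": ("pos", "pos", "neg"),
    "ERpHER2p": ("pos", "pos", "pos"),
    "ERnHER2p": ("neg", "neg", "pos"),
}

_PAM50 = {
    "TNBC": (("Basal", 0.8), ("HER2E", 0.1), ("Normal", 0.1)),
    "ERpHER2n": (("LumA", 0.5), ("LumB", 0.4), ("Normal", 0.1)),
    "ERpHER2p": (("LumB", 0.5), ("HER2E", 0.4), ("LumA", 0.1)),
    "ERnHER2p": (("HER2E", 0.8), ("Basal", 0.2)),
}


@dataclass(frozen=True)
class SubgroupSpec:
    n_samples: int
    positivity: float  # P(>= 1 true kataegis cluster)


@dataclass(frozen=True)
class TrackSpec:
    coverage: float  # fraction of the genome covered
    tile_width: int = 100_000  # width of each regular interval


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort (defaults are the headline
    conditions: subgroup positivities mirroring observed breast cancer
    kataegis frequencies, APOBEC-like cluster spectra, desk-scale genome)."""

    genome: GenomeBuild = field(default_factory=synthetic_genome)
    subgroups: dict = field(
        default_factory=lambda: {
            "TNBC": SubgroupSpec(50, 0.38),
            "ERpHER2n": SubgroupSpec(50, 0.48),
            "ERpHER2p": SubgroupSpec(50, 0.94),
            "ERnHER2p": SubgroupSpec(50, 0.89),
        }
    )
    background_rate_per_mb: float = 2.0
    background_class_probs: dict = field(
        default_factory=lambda: {
            "C>A": 0.10, "C>G": 0.08, "C>T": 0.40,
            "T>A": 0.08, "T>C": 0.26, "T>G": 0.08,
        }
    )
    tmb_positive_multiplier: float = 1.0
    # clusters
    locus_count_geometric_p: float = 0.25  # mean ~4 clusters per positive sample
    max_loci_per_sample: int = 50
    cluster_size_range: tuple = (6, 25)
    cluster_spacing_range: tuple = (10, 300)
    cluster_class_probs: dict = field(
        default_factory=lambda: {
            "C>T": 0.45, "C>G": 0.40,
            "C>A": 0.0375, "T>A": 0.0375, "T>C": 0.0375, "T>G": 0.0375,
        }
    )
    strand_coordinated: bool = True
    # hotspots
    hotspot_regions: tuple = ()  # ((chrom, start0, end0), ...)
    hotspot_probability: float = 0.0
    # annotation tracks
    tracks: dict = field(
        default_factory=lambda: {"ATAC": TrackSpec(0.10), "DHS": TrackSpec(0.15)}
    )
    placement_track: Optional[str] = "ATAC"
    placement_enrichment: float = 2.0
    # indels / drivers / expression
    indel_rate_per_mb: float = 0.3
    driver_genes: int = 20
    driver_base_rate: float = 0.15
    driver_effect_gene: str = "TP53"
    driver_effect_or: float = 4.0
    expression_genes: int = 400
    metagene_size: int = 25
    metagene_effects: dict = field(
        default_factory=lambda: {
            "mitotic_progression": 0.8,
            "immune_response": 0.0,
        }
    )
    cluster_retry_cap: int = 100

    def subgroup_names(self) -> list[str]:
        return list(self.subgroups)


@dataclass
class TruthLocus:
    chromosome: str
    positions: np.ndarray  # sorted 1-based member positions
    in_placement_track: bool = False
    in_hotspot: bool = False

    @property
    def start(self) -> int:
        return int(self.positions[0])

    @property
    def end(self) -> int:
        return int(self.positions[-1])


@dataclass
class GroundTruth:
    genome_name: str
    status: dict  # sample -> bool
    loci: dict  # sample -> list[TruthLocus]
    subgroup: dict  # sample -> subgroup name
    track_enrichment: dict  # track -> factor
    driver_or: dict  # gene -> odds ratio
    metagene_effect: dict  # metagene -> mean shift

    def event_count(self, sample: str) -> int:
        return len(self.loci.get(sample, []))

    def n_clustered_sbs(self) -> int:
        return int(sum(len(t.positions) for ll in self.loci.values() for t in ll))


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    catalogs: dict  # sample -> SampleCatalog
    tracks: dict  # name -> AnnotationTrack
    metadata: pd.DataFrame
    driver_flags: pd.DataFrame
    expression: pd.DataFrame  # genes x samples
    metagenes: dict  # name -> list of genes
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> None:
        """Emit the formats the pipeline reads, plus ``truth.json``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.genome.to_tsv(out / "genome.tsv")
        write_catalog(
            [self.catalogs[s] for s in sorted(self.catalogs)], out / "catalog.tsv"
        )
        tracks_dir = out / "tracks"
        tracks_dir.mkdir(exist_ok=True)
        for name, track in self.tracks.items():
            write_bed(track, tracks_dir / f"{name}.bed")
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        self.driver_flags.to_csv(out / "drivers.tsv", sep="\t", index_label="sample")
        self.expression.round(6).to_csv(
            out / "expression.tsv", sep="\t", index_label="gene"
        )
        with open(out / "metagenes.tsv", "w") as fh:
            for name, genes in self.metagenes.items():
                for g in genes:
                    fh.write(f"{name}\t{g}\n")
        truth = {
            "genome": self.truth.genome_name,
            "status": {s: bool(v) for s, v in self.truth.status.items()},
            "subgroup": self.truth.subgroup,
            "loci": {
                s: [
                    {
                        "chromosome": t.chromosome,
                        "positions": [int(p) for p in t.positions],
                        "in_placement_track": t.in_placement_track,
                        "in_hotspot": t.in_hotspot,
                    }
                    for t in ll
                ]
                for s, ll in self.truth.loci.items()
            },
            "track_enrichment": self.truth.track_enrichment,
            "driver_or": self.truth.driver_or,
            "metagene_effect": self.truth.metagene_effect,
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# track construction


def make_tiled_track(
    genome: GenomeBuild, name: str, coverage: float, tile_width: int = 100_000
) -> AnnotationTrack:
    """Regular interval tiling with the requested genome coverage fraction.

    One ``tile_width`` interval is placed at the start of every period of
    ``tile_width / coverage`` bp on each chromosome, so coverage is exact up
    to chromosome-end truncation.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    period = int(round(tile_width / coverage))
    intervals = {}
    for chrom, length in genome.chromosomes:
        starts = np.arange(0, length, period, dtype=np.int64)
        # each period contributes a tile proportional to the part of the
        # period actually on the chromosome, so coverage is exact even on
        # short chromosomes with a truncated final period
        period_ends = np.minimum(starts + period, length)
        widths = np.round(coverage * (period_ends - starts)).astype(np.int64)
        keep = widths > 0
        intervals[chrom] = merge_intervals(starts[keep], starts[keep] + widths[keep])
    return AnnotationTrack(name=name, intervals=intervals)


def _complement_intervals(
    track: AnnotationTrack, genome: GenomeBuild
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, length in genome.chromosomes:
        if chrom not in track.intervals:
            out[chrom] = (np.array([0]), np.array([length]))
            continue
        starts, ends = track.intervals[chrom]
        comp_s, comp_e = [], []
        prev = 0
        for s, e in zip(starts, ends):
            if s > prev:
                comp_s.append(prev)
                comp_e.append(s)
            prev = e
        if prev < length:
            comp_s.append(prev)
            comp_e.append(length)
        out[chrom] = (np.asarray(comp_s, dtype=np.int64), np.asarray(comp_e, dtype=np.int64))
    return out


# ---------------------------------------------------------------------------
# drawing helpers


def _draw_class(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> np.ndarray:
    classes = list(SUBSTITUTION_CLASSES)
    p = np.array([probs.get(c, 0.0) for c in classes], dtype=float)
    p = p / p.sum()
    return rng.choice(classes, size=n, p=p)


def _alleles_for_class(cls: str, pyrimidine_strand: bool) -> tuple[str, str]:
    ref, alt = cls.split(">")
    if pyrimidine_strand:
        return ref, alt
    return _COMPLEMENT[ref], _COMPLEMENT[alt]


def _uniform_in_intervals(
    rng: np.random.Generator,
    intervals: tuple[np.ndarray, np.ndarray],
    margin: int,
) -> Optional[int]:
    """Length-weighted uniform 0-based start inside intervals, leaving
    ``margin`` bp of room to the interval end; None if nothing fits."""
    starts, ends = intervals
    room = ends - starts - margin
    ok = room > 0
    if not ok.any():
        return None
    weights = room[ok].astype(float)
    idx = rng.choice(np.nonzero(ok)[0], p=weights / weights.sum())
    return int(starts[idx] + rng.integers(0, room[idx]))


# ---------------------------------------------------------------------------
# main generator


def simulate_cohort(config: SimulationConfig, seed: int) -> SimulatedCohort:
    """Draw one synthetic cohort; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    genome = config.genome
    chrom_names = [c for c, _ in genome.chromosomes]
    chrom_lengths = np.array([l for _, l in genome.chromosomes], dtype=np.int64)
    chrom_weights = chrom_lengths / chrom_lengths.sum()

    tracks = {
        name: make_tiled_track(genome, name, spec.coverage, spec.tile_width)
        for name, spec in config.tracks.items()
    }
    placement = tracks.get(config.placement_track) if config.placement_track else None
    placement_complement = (
        _complement_intervals(placement, genome) if placement is not None else None
    )
    p_in_track = (
        min(1.0, config.placement_enrichment * config.tracks[config.placement_track].coverage)
        if placement is not None
        else 0.0
    )
    max_span = config.cluster_size_range[1] * config.cluster_spacing_range[1] + 1

    samples: list[str] = []
    subgroup_of: dict[str, str] = {}
    for group, spec in config.subgroups.items():
        for i in range(spec.n_samples):
            sid = f"{group}_{i+1:03d}"
            samples.append(sid)
            subgroup_of[sid] = group

    status: dict[str, bool] = {}
    truth_loci: dict[str, list[TruthLocus]] = {}
    catalogs: dict[str, SampleCatalog] = {}
    indel_counts: dict[str, int] = {}
    genome_mb = genome.total_length / 1e6

    for sid in samples:
        group = subgroup_of[sid]
        positive = bool(rng.random() < config.subgroups[group].positivity)
        status[sid] = positive

        rows_chrom: list[str] = []
        rows_pos: list[int] = []
        rows_ref: list[str] = []
        rows_alt: list[str] = []

        # background
        rate = config.background_rate_per_mb * (
            config.tmb_positive_multiplier if positive else 1.0
        )
        for chrom, length in genome.chromosomes:
            n_bg = rng.poisson(rate * length / 1e6)
            if n_bg == 0:
                continue
            positions = np.sort(rng.integers(1, length + 1, size=n_bg))
            classes = _draw_class(rng, config.background_class_probs, n_bg)
            strands = rng.random(n_bg) < 0.5
            for p, cls, pyr in zip(positions, classes, strands):
                ref, alt = _alleles_for_class(cls, bool(pyr))
                rows_chrom.append(chrom)
                rows_pos.append(int(p))
                rows_ref.append(ref)
                rows_alt.append(alt)

        # clusters
        loci: list[TruthLocus] = []
        if positive:
            n_loci = min(
                int(rng.geometric(config.locus_count_geometric_p)),
                config.max_loci_per_sample,
            )
            for _ in range(n_loci):
                locus = _draw_cluster(
                    rng,
                    config,
                    genome,
                    chrom_names,
                    chrom_weights,
                    placement,
                    placement_complement,
                    p_in_track,
                    max_span,
                )
                loci.append(locus)
                size = len(locus.positions)
                classes = _draw_class(rng, config.cluster_class_probs, size)
                if config.strand_coordinated:
                    pyr = bool(rng.random() < 0.5)
                    strands = [pyr] * size
                else:
                    strands = (rng.random(size) < 0.5).tolist()
                for p, cls, pyr in zip(locus.positions, classes, strands):
                    ref, alt = _alleles_for_class(cls, bool(pyr))
                    rows_chrom.append(locus.chromosome)
                    rows_pos.append(int(p))
                    rows_ref.append(ref)
                    rows_alt.append(alt)
        truth_loci[sid] = loci

        indel_counts[sid] = int(rng.poisson(config.indel_rate_per_mb * genome_mb))
        df = pd.DataFrame(
            {
                "chromosome": rows_chrom,
                "position": rows_pos,
                "ref": rows_ref,
                "alt": rows_alt,
            }
        )
        catalogs[sid] = SampleCatalog.from_dataframe(
            sid, df, indel_count=indel_counts[sid]
        )

    metadata = _draw_metadata(rng, config, samples, subgroup_of, status, truth_loci,
                              catalogs, indel_counts)
    driver_flags, driver_or = _draw_drivers(rng, config, samples, status)
    expression, metagenes = _draw_expression(rng, config, samples, status)

    truth = GroundTruth(
        genome_name=genome.name,
        status=status,
        loci=truth_loci,
        subgroup=subgroup_of,
        track_enrichment={
            name: (config.placement_enrichment if name == config.placement_track else 1.0)
            for name in tracks
        },
        driver_or=driver_or,
        metagene_effect=dict(config.metagene_effects),
    )
    return SimulatedCohort(
        config=config,
        catalogs=catalogs,
        tracks=tracks,
        metadata=metadata,
        driver_flags=driver_flags,
        expression=expression,
        metagenes=metagenes,
        truth=truth,
    )


def _draw_cluster(
    rng, config, genome, chrom_names, chrom_weights, placement,
    placement_complement, p_in_track, max_span,
) -> TruthLocus:
    size = int(rng.integers(config.cluster_size_range[0], config.cluster_size_range[1] + 1))
    lo, hi = config.cluster_spacing_range
    for _ in range(config.cluster_retry_cap):
        spacings = rng.integers(lo, hi + 1, size=size - 1)
        span = int(spacings.sum())
        in_hotspot = in_track = False
        if config.hotspot_regions and rng.random() < config.hotspot_probability:
            region = config.hotspot_regions[
                int(rng.integers(0, len(config.hotspot_regions)))
            ]
            chrom, r_start, r_end = region[0], int(region[1]), int(region[2])
            if r_end - r_start <= span + 1:
                continue
            start0 = int(r_start + rng.integers(0, r_end - r_start - span - 1))
            in_hotspot = True
        else:
            chrom = str(rng.choice(chrom_names, p=chrom_weights))
            length = genome.length(chrom)
            if placement is not None and rng.random() < p_in_track:
                ivs = placement.intervals.get(chrom)
                start0 = (
                    _uniform_in_intervals(rng, ivs, span + 1) if ivs is not None else None
                )
                in_track = start0 is not None
            else:
                start0 = _uniform_in_intervals(
                    rng, placement_complement[chrom], span + 1
                ) if placement_complement is not None else None
            if start0 is None:
                if length <= span + 1:
                    continue
                start0 = int(rng.integers(0, length - span - 1))
        positions = start0 + 1 + np.concatenate([[0], np.cumsum(spacings)])
        if positions[-1] > genome.length(chrom):
            continue
        return TruthLocus(
            chromosome=chrom,
            positions=positions.astype(np.int64),
            in_placement_track=in_track,
            in_hotspot=in_hotspot,
        )
    raise RuntimeError("cluster placement failed after retry cap")


def _draw_metadata(rng, config, samples, subgroup_of, status, truth_loci, catalogs,
                   indel_counts) -> pd.DataFrame:
    rows = []
    for sid in samples:
        group = subgroup_of[sid]
        er, pr, her2 = _SUBGROUP_RECEPTORS.get(group, ("na", "na", "na"))
        pam_choices = _PAM50.get(group, (("Unknown", 1.0),))
        labels = [l for l, _ in pam_choices]
        probs = np.array([p for _, p in pam_choices])
        pam50 = str(rng.choice(labels, p=probs / probs.sum()))
        hrd_rate = 0.6 if group == "TNBC" else 0.2
        rows.append(
            {
                "sample": sid,
                "subgroup": group,
                "cohort": "synthetic",
                "ER": er,
                "PR": pr,
                "HER2": her2,
                "PAM50": pam50,
                "TNBCtype": str(rng.choice(["BL1", "BL2", "M", "LAR"]))
                if group == "TNBC"
                else "NA",
                "grade": int(rng.integers(1, 4)),
                "node_positive": int(rng.random() < 0.4),
                "age": int(np.clip(round(rng.normal(62, 11)), 25, 95)),
                "HRD": int(rng.random() < hrd_rate),
                "ploidy": round(float(rng.normal(2.8, 0.5)), 2),
                "cn_fga": round(float(np.clip(rng.beta(2, 3), 0, 1)), 4),
                "loh_fraction": round(float(np.clip(rng.beta(2, 5), 0, 1)), 4),
                "indel_count": indel_counts[sid],
                "n_sbs": len(catalogs[sid]),
                "true_status": int(status[sid]),
                "true_event_count": len(truth_loci[sid]),
            }
        )
    return pd.DataFrame(rows)


def _draw_drivers(rng, config, samples, status):
    genes = [config.driver_effect_gene] + [
        f"GENE{i:02d}" for i in range(1, config.driver_genes)
    ]
    base = config.driver_base_rate
    logit0 = np.log(base / (1 - base))
    flags = {}
    for gene in genes:
        shift = np.log(config.driver_effect_or) if gene == config.driver_effect_gene else 0.0
        p_pos = 1 / (1 + np.exp(-(logit0 + shift)))
        col = [
            int(rng.random() < (p_pos if status[s] else base)) for s in samples
        ]
        flags[gene] = col
    driver_or = {
        g: (config.driver_effect_or if g == config.driver_effect_gene else 1.0)
        for g in genes
    }
    return pd.DataFrame(flags, index=pd.Index(samples, name="sample")), driver_or


def _draw_expression(rng, config, samples, status):
    n_genes = config.expression_genes
    genes = [f"g{i:04d}" for i in range(n_genes)]
    metagenes = {}
    cursor = 0
    for name in config.metagene_effects:
        metagenes[name] = genes[cursor : cursor + config.metagene_size]
        cursor += config.metagene_size
    baseline = rng.normal(5.0, 2.0, size=n_genes)
    data = rng.normal(0.0, 1.0, size=(n_genes, len(samples))) + baseline[:, None]
    status_vec = np.array([status[s] for s in samples], dtype=float)
    for name, effect in config.metagene_effects.items():
        idx = [genes.index(g) for g in metagenes[name]]
        data[np.ix_(idx, np.arange(len(samples)))] += effect * status_vec[None, :]
    expr = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=samples)
    return expr, metagenes


# ---------------------------------------------------------------------------
# truth matching


@dataclass
class MatchResult:
    n_truth: int
    n_recovered: int
    n_detected: int
    n_false: int
    n_isolated: int
    n_boundary_exact: int

    @property
    def sensitivity(self) -> float:
        return self.n_recovered / self.n_truth if self.n_truth else float("nan")

    @property
    def false_call_rate_per_sample(self) -> float:
        # set externally by truth_match via n_samples
        return self._false_rate

    _false_rate: float = float("nan")


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def truth_match(
    detected_by_sample: Mapping[str, Sequence[KataegisLocus]],
    truth: GroundTruth,
    catalogs: Optional[Mapping[str, SampleCatalog]] = None,
    isolation_bp: int = 1000,
    imd_rule: str = "max",
    imd_threshold: int = 1000,
) -> MatchResult:
    """Score detected loci against the simulated truth.

    A truth locus is *recovered* iff some detected locus of the same sample
    and chromosome either contains all its member positions or overlaps it
    reciprocally by >= 50%.  A detected locus sharing no member position
    with any truth locus is a *false call*.  When catalogs are supplied,
    truth loci isolated from all background SBSs on both flanks are
    additionally checked for exact boundary recovery (detected start/end
    equal to the min/max injected positions).

    The isolation margin that forbids a background SBS from joining a
    cluster depends on the detection rule.  Under ``max`` any flanking gap
    above the IMD threshold breaks the run, so ``isolation_bp`` (default
    1000) suffices.  Under ``mean`` the gap average telescopes: an n-member
    cluster of span S can absorb a point up to ``threshold*n - S`` bp away
    (the window mean stays below threshold because the tight interior
    subsidizes the long flanking gap), so the margin is the maximum of
    ``isolation_bp`` and that per-locus bound.
    """
    n_truth = n_recovered = n_detected = n_false = 0
    n_isolated = n_boundary = 0
    for sid, t_loci in truth.loci.items():
        d_loci = list(detected_by_sample.get(sid, ()))
        n_detected += len(d_loci)
        truth_positions = {
            (t.chromosome, int(p)) for t in t_loci for p in t.positions
        }
        for d in d_loci:
            if not any((d.chromosome, int(p)) in truth_positions for p in d.positions):
                n_false += 1
        for t in t_loci:
            n_truth += 1
            matched = best = None
            for d in d_loci:
                if d.chromosome != t.chromosome:
                    continue
                contains_all = set(t.positions.tolist()) <= set(d.positions.tolist())
                ov = _overlap(d.start, d.end, t.start, t.end)
                reciprocal = (
                    ov >= 0.5 * (d.end - d.start + 1) and ov >= 0.5 * (t.end - t.start + 1)
                )
                if contains_all or reciprocal:
                    matched = d
                    break
            if matched is not None:
                n_recovered += 1
            if catalogs is not None:
                cat = catalogs[sid]
                positions = cat.positions(t.chromosome)
                member = np.isin(positions, t.positions)
                background = positions[~member]
                margin = isolation_bp
                if imd_rule == "mean":
                    span = t.end - t.start
                    margin = max(margin, imd_threshold * len(t.positions) - span)
                isolated = not np.any(
                    (background >= t.start - margin)
                    & (background <= t.end + margin)
                )
                if isolated:
                    n_isolated += 1
                    if (
                        matched is not None
                        and matched.start == t.start
                        and matched.end == t.end
                    ):
                        n_boundary += 1
    result = MatchResult(
        n_truth=n_truth,
        n_recovered=n_recovered,
        n_detected=n_detected,
        n_false=n_false,
        n_isolated=n_isolated,
        n_boundary_exact=n_boundary,
    )
    result._false_rate = n_false / max(1, len(truth.status))
    return result
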