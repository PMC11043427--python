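"""Kataegis locus detection by the intermutation-distance (IMD) rule.

A kataegis locus is a cluster of closely spaced single-base substitutions in
one sample on one chromosome.  Two rule variants are implemented:

``max`` (default)
    Loci are the maximal runs of consecutive SBSs in which *every* adjacent
    intermutation distance is <= the threshold and the run holds at least
    ``min_sbs`` substitutions.  This matches a detector run with a
    "six consecutive SBSs with a maximum intermutation distance of 1000 bp"
    requirement.

``mean``
    The textbook definition: any window of >= ``min_sbs`` consecutive SBSs
    whose *average* adjacent IMD is <= the threshold qualifies; overlapping
    qualifying windows are merged by union into maximal disjoint loci.  The
    average of adjacent gaps telescopes, so a window [i, j] qualifies iff
    ``(pos_j - pos_i) / (j - i) <= threshold``.

IMDs are never computed across chromosome boundaries or across samples.
Same-position records (multi-allelic sites) contribute an IMD of zero.

The confidence tier attached to each locus is a documented APOBEC-context
surrogate, not a reimplementation of any particular tool's unpublished
score: tier 1 = passes detection; tier 2 = additionally >= 70% of member
substitutions are pyrimidine C>N after strand normalization
(APOBEC-consistent); tier 3 = tier 2 with >= 10 members.  With the default
``min_confidence = 1`` the tier acts only as an annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome import (
    DEFAULT_CHROMOSOMES_1_23,
    SUBSTITUTION_CLASSES,
    canonical_chromosome,
    class_of,
)
from .variant_io import SampleCatalog

__all__ = [
    "DetectionParams",
    "KataegisLocus",
    "detect_kataegis",
    "confidence_score",
    "filter_loci",
]

APOBEC_FRACTION_THRESHOLD = 0.70
HIGH_CONFIDENCE_MIN_SBS = 10


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the IMD detector (defaults = headline settings)."""

    min_sbs: int = 6
    imd_threshold: int = 1000
    imd_rule: str = "max"
    min_confidence: int = 1
    chromosomes: frozenset[str] = DEFAULT_CHROMOSOMES_1_23

    def __post_init__(self):
        if self.min_sbs < 2:
            raise ValueError("min_sbs must be >= 2")
        if self.imd_threshold <= 0:
            raise ValueError("imd_threshold must be positive")
        if self.imd_rule not in ("max", "mean"):
            raise ValueError(f"imd_rule must be 'max' or 'mean', got {self.imd_rule!r}")
        object.__setattr__(
            self,
            "chromosomes",
            frozenset(canonical_chromosome(c) for c in self.chromosomes),
        )


@dataclass
class KataegisLocus:
    """One detected cluster of SBSs.

    ``start``/``end`` are the 1-based positions of the first and last member;
    ``mean_imd`` is ``(end - start) / (n_sbs - 1)`` (the telescoped mean of
    adjacent gaps); ``class_counts`` are member counts over the six
    pyrimidine-normalized substitution classes.
    """

    sample_id: str
    chromosome: str
    start: int
    end: int
    positions: np.ndarray
    refs: tuple[str, ...]
    alts: tuple[str, ...]
    confidence: int = 0
    class_counts: dict = field(default_factory=dict)

    @property
    def n_sbs(self) -> int:
        return len(self.positions)

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def mean_imd(self) -> float:
        return (self.end - self.start) / (self.n_sbs - 1)

    @property
    def max_imd(self) -> int:
        return int(np.diff(self.positions).max())


def _qualifying_index_intervals_max(
    positions: np.ndarray, min_sbs: int, threshold: int
) -> list[tuple[int, int]]:
    """Closed index intervals [i, j] of maximal runs with all gaps <= threshold."""
    n = len(positions)
    if n < min_sbs:
        return []
    gaps_ok = np.diff(positions) <= threshold
    intervals = []
    i = 0
    while i < n - 1:
        if gaps_ok[i]:
            j = i
            while j < n - 1 and gaps_ok[j]:
                j += 1
            if j - i + 1 >= min_sbs:
                intervals.append((i, j))
            i = j + 1
        else:
            i += 1
    return intervals


def _qualifying_index_intervals_mean(
    positions: np.ndarray, min_sbs: int, threshold: int
) -> list[tuple[int, int]]:
    """Union of all windows [i, j] with j-i+1 >= min_sbs and telescoped mean
    gap <= threshold, merged into maximal closed index intervals."""
    n = len(positions)
    if n < min_sbs:
        return []
    covered_s: list[int] = []
    covered_e: list[int] = []
    pos = positions.astype(np.int64)
    # For each window size k, vectorize over start index.
    for k in range(min_sbs, n + 1):
        span = pos[k - 1 :] - pos[: n - k + 1]
        ok = np.nonzero(span <= threshold * (k - 1))[0]
        for i in ok:
            covered_s.append(int(i))
            covered_e.append(int(i) + k - 1)
    if not covered_s:
        return []
    # Merge closed integer index intervals (adjacent windows sharing an SBS
    # or abutting indices form one connected union only if they overlap).
    order = np.argsort(covered_s, kind="mergesort")
    merged: list[tuple[int, int]] = []
    for idx in order:
        s, e = covered_s[idx], covered_e[idx]
        if merged and s <= merged[-1][1]:  # overlapping windows share members
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def detect_kataegis(
    catalog: SampleCatalog, params: Optional[DetectionParams] = None
) -> list[KataegisLocus]:
    """Find kataegis loci in a sorted SBS catalog.

    Returns loci sorted by (chromosome order, start), each scored with the
    surrogate confidence tier but *not* yet filtered (see
    :func:`filter_loci`).  Member SBS sets of the returned loci are pairwise
    disjoint under both rules.
    """
    params = params or DetectionParams()
    loci: list[KataegisLocus] = []
    df = catalog.df
    for chrom in catalog.chromosomes:
        sub = df[df["chromosome"] == chrom]
        positions = sub["position"].to_numpy()
        if np.any(np.diff(positions) < 0):
            raise RuntimeError(f"catalog {catalog.sample_id} not sorted on {chrom}")
        if params.imd_rule == "max":
            intervals = _qualifying_index_intervals_max(
                positions, params.min_sbs, params.imd_threshold
            )
        else:
            intervals = _qualifying_index_intervals_mean(
                positions, params.min_sbs, params.imd_threshold
            )
        refs = sub["ref"].to_numpy()
        alts = sub["alt"].to_numpy()
        for i, j in intervals:
            locus = KataegisLocus(
                sample_id=catalog.sample_id,
                chromosome=chrom,
                start=int(positions[i]),
                end=int(positions[j]),
                positions=positions[i : j + 1].copy(),
                refs=tuple(refs[i : j + 1]),
                alts=tuple(alts[i : j + 1]),
            )
            locus.class_counts = _count_classes(locus)
            locus.confidence = confidence_score(locus)
            loci.append(locus)
    return loci


def _count_classes(locus: KataegisLocus) -> dict[str, int]:
    counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    for r, a in zip(locus.refs, locus.alts):
        counts[class_of(r, a)] += 1
    return counts


def confidence_score(locus: KataegisLocus) -> int:
    """Surrogate confidence tier 1-3 (see module docstring)."""
    counts = locus.class_counts or _count_classes(locus)
    total = sum(counts.values())
    c_n = counts["C>A"] + counts["C>G"] + counts["C>T"]
    if total and c_n / total >= APOBEC_FRACTION_THRESHOLD:
        return 3 if locus.n_sbs >= HIGH_CONFIDENCE_MIN_SBS else 2
    return 1


def filter_loci(
    loci: Iterable[KataegisLocus], params: Optional[DetectionParams] = None
) -> list[KataegisLocus]:
    """Keep loci meeting the confidence floor on the configured chromosome set.

    With the default ``min_confidence = 1`` this reduces to a chromosome
    filter (every detected locus has tier >= 1).
    """
    params = params or DetectionParams()
    return [
        lc
        for lc in loci
        if lc.confidence >= params.min_confidence
        and canonical_chromosome(lc.chromosome) in params.chromosomes
    ]


def detect_and_filter(
    catalog: SampleCatalog, params: Optional[DetectionParams] = None
) -> list[KataegisLocus]:
    """Convenience: detection followed by the confidence/chromosome filter."""
    params = params or DetectionParams()
    return filter_loci(detect_kataegis(catalog, params), params)
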