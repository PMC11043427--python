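"""Subgroup-level descriptions of detected kataegis loci.

Covers the merged substitution spectrum of all member SBSs of a subgroup,
locus size / SBS-count distributions, per-chromosome event counts, and
recurrence of events in consecutive fixed-width genome bins (default 2 Mbp).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .detection import KataegisLocus
from .genome import (
    AUTOSOMES,
    SUBSTITUTION_CLASSES,
    BinScheme,
    canonical_chromosome,
    chromosome_sort_key,
)

__all__ = [
    "SpectrumProfile",
    "merged_spectrum",
    "locus_size_summary",
    "events_per_chromosome",
    "bin_recurrence",
]


@dataclass
class SpectrumProfile:
    """Six-class substitution spectrum of a pooled set of SBSs."""

    label: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> Optional[dict[str, float]]:
        """Class proportions, or ``None`` when the pool is empty (flagged)."""
        t = self.total
        if t == 0:
            return None
        return {c: n / t for c, n in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        props = self.proportions
        return pd.DataFrame(
            {
                "label": self.label,
                "substitution_class": list(SUBSTITUTION_CLASSES),
                "count": [self.counts[c] for c in SUBSTITUTION_CLASSES],
                "proportion": [
                    props[c] if props else np.nan for c in SUBSTITUTION_CLASSES
                ],
            }
        )


def merged_spectrum(loci: Iterable[KataegisLocus], label: str = "all") -> SpectrumProfile:
    """Pool every member SBS of every locus into one spectrum.

    All tumors of a subgroup are merged and analyzed as a single set, so the
    merged spectrum equals the sum of per-tumor spectra (additivity).
    APOBEC-like input is expected to be dominated by C>T and C>G.
    """
    counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    for lc in loci:
        for c, n in lc.class_counts.items():
            counts[c] += n
    return SpectrumProfile(label=label, counts=counts)


def locus_size_summary(loci: Sequence[KataegisLocus]) -> dict:
    """Raw span/SBS-count vectors plus quantiles (no smoothing).

    Kernel-smoothed density displays are a plotting device and deliberately
    not part of the computation; the raw vectors are returned so callers can
    plot them however they like.
    """
    spans = np.array([lc.span_bp for lc in loci], dtype=float)
    n_sbs = np.array([lc.n_sbs for lc in loci], dtype=float)
    qs = (0.05, 0.25, 0.5, 0.75, 0.95)
    summary = {}
    for name, vec in (("span_bp", spans), ("n_sbs", n_sbs)):
        if len(vec):
            summary[name] = {f"q{int(q*100)}": float(np.quantile(vec, q)) for q in qs}
            summary[name]["mean"] = float(vec.mean())
        else:
            summary[name] = {}
    return {"span_bp": spans, "n_sbs": n_sbs, "quantiles": summary}


def events_per_chromosome(
    loci: Iterable[KataegisLocus],
    chromosomes: Sequence[str] = AUTOSOMES,
) -> dict[str, int]:
    """Event counts by chromosome; X is excluded by default for this view."""
    keys = [canonical_chromosome(c) for c in chromosomes]
    counts = {c: 0 for c in keys}
    for lc in loci:
        c = canonical_chromosome(lc.chromosome)
        if c in counts:
            counts[c] += 1
    return counts


def locus_midpoint_bin(locus: KataegisLocus, scheme: BinScheme) -> int:
    """Global bin holding the locus midpoint ``floor((start-1 + end) / 2)``
    in 0-based coordinates; a locus is never split across bins."""
    mid0 = (locus.start - 1 + locus.end) // 2
    return scheme.locate(locus.chromosome, mid0 + 1)


def bin_recurrence(
    loci_by_group: Mapping[str, Sequence[KataegisLocus]],
    scheme: BinScheme,
    group_sizes: Mapping[str, int],
) -> pd.DataFrame:
    """Per-bin kataegis event counts and frequencies per tumor subgroup.

    Each locus maps to exactly one bin by its midpoint; counts accumulate
    over all tumors of the group (several events of one tumor in one bin all
    count), and frequency = count / number of tumors in the group, with
    kataegis-negative tumors included in the denominator.

    Returns one row per bin with columns ``bin, chromosome, start, end`` and
    per-group ``count_<g>`` / ``frequency_<g>``.
    """
    n_bins = scheme.n_bins
    rows = {
        "bin": np.arange(n_bins),
    }
    coords = [scheme.bin_coordinates(i) for i in range(n_bins)]
    rows["chromosome"] = [c for c, _, _ in coords]
    rows["start"] = [s for _, s, _ in coords]
    rows["end"] = [e for _, _, e in coords]
    out = pd.DataFrame(rows)
    for group in sorted(loci_by_group):
        size = group_sizes[group]
        if size <= 0:
            raise ValueError(f"group {group!r} has non-positive size")
        counts = np.zeros(n_bins, dtype=int)
        for lc in loci_by_group[group]:
            counts[locus_midpoint_bin(lc, scheme)] += 1
        out[f"count_{group}"] = counts
        out[f"frequency_{group}"] = counts / size
    return out
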