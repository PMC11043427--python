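"""Genomic-context enrichment of kataegis-associated SBSs.

For a given annotation track (ATAC, DHS, repeat classes, chromatin states,
...) and tumor subgroup, three SBS pools are compared:

1. *kataegis SBSs* — every member SBS of every locus of every
   kataegis-positive tumor in the subgroup;
2. *all SBSs, kataegis-positive tumors* — the complete catalogs of the same
   tumors;
3. *all SBSs, kataegis-negative tumors* — the complete catalogs of the
   remaining tumors.

The enrichment ratio is proportion(1) / proportion(2).  Tracks are treated
independently (an SBS may belong to many tracks); no hierarchy or
exclusivity is imposed, and no statistical test is attached to ratios —
binomial confidence intervals can be emitted as an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .detection import KataegisLocus
from .variant_io import AnnotationTrack, SampleCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "ContextProportion",
    "EnrichmentResult",
    "annotate_sbs",
    "context_proportions",
    "enrichment_ratio",
]

POOL_KATAEGIS = "kataegis_sbs"
POOL_ALL_POSITIVE = "all_sbs_kataegis_positive"
POOL_ALL_NEGATIVE = "all_sbs_kataegis_negative"


@dataclass(frozen=True)
class ContextProportion:
    subgroup: str
    track: str
    pool: str
    n_mapped: int
    n_total: int

    @property
    def proportion(self) -> Optional[float]:
        """Mapped fraction, or ``None`` when the pool is empty (flagged)."""
        if self.n_total == 0:
            return None
        return self.n_mapped / self.n_total

    def binomial_ci(self, alpha: float = 0.05) -> Optional[tuple[float, float]]:
        """Normal-approximation CI on the proportion (optional output)."""
        p = self.proportion
        if p is None:
            return None
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        se = math.sqrt(p * (1 - p) / self.n_total)
        return (max(0.0, p - z * se), min(1.0, p + z * se))


@dataclass(frozen=True)
class EnrichmentResult:
    subgroup: str
    track: str
    ratio: Optional[float]  # None when the denominator proportion is zero/empty


def annotate_sbs(catalog: SampleCatalog, track: AnnotationTrack) -> np.ndarray:
    """Per-SBS membership flags for a track (order = catalog row order)."""
    flags = np.zeros(len(catalog.df), dtype=bool)
    for chrom in catalog.chromosomes:
        mask = (catalog.df["chromosome"] == chrom).to_numpy()
        positions = catalog.df.loc[mask, "position"].to_numpy()
        if chrom not in track.intervals:
            logger.debug(
                "track %s has no intervals on chromosome %s", track.name, chrom
            )
        flags[mask] = track.contains(chrom, positions)
    return flags


def _count_pool(
    positions_by_chrom: Mapping[str, np.ndarray], track: AnnotationTrack
) -> tuple[int, int]:
    mapped = total = 0
    for chrom, positions in positions_by_chrom.items():
        total += len(positions)
        mapped += int(track.contains(chrom, positions).sum())
    return mapped, total


def context_proportions(
    catalogs: Mapping[str, SampleCatalog],
    loci_by_sample: Mapping[str, Sequence[KataegisLocus]],
    positive_samples: Iterable[str],
    track: AnnotationTrack,
    subgroup_samples: Iterable[str],
    subgroup: str = "all",
) -> dict[str, ContextProportion]:
    """The three pooled mapped-proportions for one track and subgroup.

    ``positive_samples`` holds the kataegis-positive sample ids (binary
    status); pooling is at SBS level, summarized across all tumors of the
    subgroup (every SBS counts once, tumors are not re-weighted).
    """
    subgroup_set = list(subgroup_samples)
    positive = set(positive_samples)

    kat_positions: dict[str, list[np.ndarray]] = {}
    pos_positions: dict[str, list[np.ndarray]] = {}
    neg_positions: dict[str, list[np.ndarray]] = {}
    for sid in subgroup_set:
        cat = catalogs[sid]
        target = pos_positions if sid in positive else neg_positions
        for chrom in cat.chromosomes:
            target.setdefault(chrom, []).append(cat.positions(chrom))
        if sid in positive:
            for lc in loci_by_sample.get(sid, ()):
                kat_positions.setdefault(lc.chromosome, []).append(lc.positions)

    def _concat(d):
        return {c: np.concatenate(v) for c, v in d.items()}

    results = {}
    for pool, positions in (
        (POOL_KATAEGIS, _concat(kat_positions)),
        (POOL_ALL_POSITIVE, _concat(pos_positions)),
        (POOL_ALL_NEGATIVE, _concat(neg_positions)),
    ):
        mapped, total = _count_pool(positions, track)
        results[pool] = ContextProportion(
            subgroup=subgroup, track=track.name, pool=pool, n_mapped=mapped, n_total=total
        )
    return results


def enrichment_ratio(
    p_kataegis: ContextProportion, p_all_positive: ContextProportion
) -> EnrichmentResult:
    """Kataegis-SBS proportion divided by the all-SBS proportion of
    kataegis-positive tumors (same subgroup and track)."""
    if (p_kataegis.subgroup, p_kataegis.track) != (
        p_all_positive.subgroup,
        p_all_positive.track,
    ):
        raise ValueError("proportions are from different subgroups or tracks")
    num = p_kataegis.proportion
    den = p_all_positive.proportion
    if num is None or den is None or den == 0:
        return EnrichmentResult(p_kataegis.subgroup, p_kataegis.track, None)
    return EnrichmentResult(p_kataegis.subgroup, p_kataegis.track, num / den)


def proportions_table(records: Iterable[ContextProportion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subgroup": r.subgroup,
                "track": r.track,
                "pool": r.pool,
                "n_mapped": r.n_mapped,
                "n_total": r.n_total,
                "proportion": np.nan if r.proportion is None else r.proportion,
            }
            for r in records
        ]
    )
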