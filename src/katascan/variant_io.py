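"""Readers and writers for SBS catalogs, BED annotation tracks, and result tables.

Supported catalog formats:

``tsv``
    Plain table with columns ``sample``, ``chromosome``, ``position``,
    ``ref``, ``alt`` (header required; extra columns ignored).
``maf``
    MAF-like table using ``Tumor_Sample_Barcode``, ``Chromosome``,
    ``Start_Position``, ``Reference_Allele``, ``Tumor_Seq_Allele2``.
``vcf``
    VCF 4.x via pysam; multi-allelic rows are split into one record per ALT.

All reads are gzip-transparent.  Non-SBS rows (indels, MNVs, symbolic
alleles) are skipped and counted; exact duplicate records (same sample,
position, ref, alt) are dropped and counted; same-position different-alt
records are kept and later contribute an intermutation distance of zero.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import canonical_chromosome, chromosome_sort_key, class_of

logger = logging.getLogger(__name__)

__all__ = [
    "SbsRecord",
    "SampleCatalog",
    "AnnotationTrack",
    "read_sbs_catalogs",
    "read_bed",
    "write_catalog",
    "write_loci_table",
    "read_loci_table",
    "rainfall_table",
]

_BASES = frozenset("ACGT")

CATALOG_COLUMNS = ["sample", "chromosome", "position", "ref", "alt"]

LOCI_COLUMNS = [
    "sample",
    "chromosome",
    "start",
    "end",
    "n_sbs",
    "span_bp",
    "mean_imd",
    "max_imd",
    "confidence",
]


@dataclass(frozen=True)
class SbsRecord:
    """One somatic single-base substitution (1-based position)."""

    sample_id: str
    chromosome: str
    position: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt are identical")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("SbsRecord requires single-base alleles")
        if self.position < 1:
            raise ValueError("position must be >= 1")


@dataclass
class SampleCatalog:
    """Position-sorted SBS catalog of one sample.

    The catalog is a DataFrame with columns ``chromosome, position, ref, alt``
    sorted by (chromosome order, position); duplicates have been removed.
    """

    sample_id: str
    df: pd.DataFrame
    indel_count: int = 0
    n_duplicates_dropped: int = 0
    n_non_sbs_skipped: int = 0

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chromosome"]))

    def positions(self, chromosome: str) -> np.ndarray:
        key = canonical_chromosome(chromosome)
        return self.df.loc[self.df["chromosome"] == key, "position"].to_numpy()

    def subset(self, chromosomes: Iterable[str]) -> "SampleCatalog":
        keys = {canonical_chromosome(c) for c in chromosomes}
        return SampleCatalog(
            sample_id=self.sample_id,
            df=self.df[self.df["chromosome"].isin(keys)].reset_index(drop=True),
            indel_count=self.indel_count,
        )

    @classmethod
    def from_dataframe(
        cls, sample_id: str, df: pd.DataFrame, indel_count: int = 0
    ) -> "SampleCatalog":
        """Build a catalog from raw rows: canonicalize, sort, deduplicate."""
        df = df.copy()
        df["chromosome"] = df["chromosome"].astype(str).map(canonical_chromosome)
        df["position"] = df["position"].astype(np.int64)
        df["ref"] = df["ref"].astype(str).str.upper()
        df["alt"] = df["alt"].astype(str).str.upper()
        key = df["chromosome"].map(chromosome_sort_key)
        df = df.assign(_key=key).sort_values(
            ["_key", "position", "ref", "alt"], kind="mergesort"
        )
        before = len(df)
        df = df.drop_duplicates(subset=["chromosome", "position", "ref", "alt"])
        dropped = before - len(df)
        if dropped:
            logger.info("%s: dropped %d exact duplicate SBS records", sample_id, dropped)
        df = df.drop(columns="_key").reset_index(drop=True)
        return cls(
            sample_id=sample_id,
            df=df[["chromosome", "position", "ref", "alt"]],
            indel_count=indel_count,
            n_duplicates_dropped=dropped,
        )


def _is_sbs(ref: str, alt: str) -> bool:
    return (
        len(ref) == 1 and len(alt) == 1 and ref in _BASES and alt in _BASES and ref != alt
    )


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _catalogs_from_rows(rows: pd.DataFrame, n_skipped_by_sample=None) -> dict[str, SampleCatalog]:
    catalogs: dict[str, SampleCatalog] = {}
    for sample_id, sub in rows.groupby("sample", sort=True):
        cat = SampleCatalog.from_dataframe(str(sample_id), sub.rename(columns={}))
        if n_skipped_by_sample:
            cat.n_non_sbs_skipped = n_skipped_by_sample.get(sample_id, 0)
        catalogs[str(sample_id)] = cat
    return catalogs


def _read_tabular(path, colmap: dict[str, str]) -> dict[str, SampleCatalog]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    out = pd.DataFrame(
        {
            "sample": df[colmap["sample"]].astype(str),
            "chromosome": df[colmap["chromosome"]].astype(str),
            "ref": df[colmap["ref"]].astype(str).str.upper(),
            "alt": df[colmap["alt"]].astype(str).str.upper(),
        }
    )
    try:
        out["position"] = df[colmap["position"]].astype(np.int64)
    except (ValueError, TypeError) as exc:
        bad = df[colmap["position"]][
            pd.to_numeric(df[colmap["position"]], errors="coerce").isna()
        ]
        line = bad.index[0] + 2 if len(bad) else "?"
        raise ValueError(f"{path}: malformed position near line {line}") from exc
    sbs_mask = np.asarray(
        [_is_sbs(r, a) for r, a in zip(out["ref"], out["alt"])], dtype=bool
    )
    skipped = out.loc[~sbs_mask]
    n_skipped = skipped.groupby("sample").size().to_dict()
    if (~sbs_mask).sum():
        logger.info("%s: skipped %d non-SBS rows", path, int((~sbs_mask).sum()))
    if len(out) == 0:
        logger.warning("%s: empty catalog file", path)
    return _catalogs_from_rows(out.loc[sbs_mask], n_skipped)


def _read_vcf(path, sample_field: Optional[str]) -> dict[str, SampleCatalog]:
    import pysam

    rows = []
    n_skipped: dict[str, int] = {}
    with pysam.VariantFile(str(path)) as vf:
        header_samples = list(vf.header.samples)
        default_sample = (
            header_samples[0] if len(header_samples) == 1 else Path(path).stem
        )
        for rec in vf:
            if sample_field and sample_field in rec.info:
                sample = str(rec.info[sample_field])
            else:
                sample = default_sample
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = (alt or "").upper()
                if _is_sbs(ref, alt):
                    rows.append((sample, rec.chrom, rec.pos, ref, alt))
                else:
                    n_skipped[sample] = n_skipped.get(sample, 0) + 1
    if n_skipped:
        logger.info("%s: skipped %d non-SBS alleles", path, sum(n_skipped.values()))
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    if df.empty:
        logger.warning("%s: no SBS records parsed", path)
        return {}
    return _catalogs_from_rows(df, n_skipped)


def read_sbs_catalogs(
    path: str | Path,
    format: str = "tsv",
    sample_field: Optional[str] = None,
) -> dict[str, SampleCatalog]:
    """Read an SBS catalog file into one :class:`SampleCatalog` per sample.

    Parameters
    ----------
    path
        Input file (``.gz`` transparent for tsv/maf).
    format
        ``"tsv"``, ``"maf"``, or ``"vcf"``.
    sample_field
        Column holding the sample id (tsv/maf; defaults to ``sample`` /
        ``Tumor_Sample_Barcode``) or an INFO tag (vcf).
    """
    format = format.lower()
    if format == "tsv":
        colmap = {
            "sample": sample_field or "sample",
            "chromosome": "chromosome",
            "position": "position",
            "ref": "ref",
            "alt": "alt",
        }
        return _read_tabular(path, colmap)
    if format == "maf":
        colmap = {
            "sample": sample_field or "Tumor_Sample_Barcode",
            "chromosome": "Chromosome",
            "position": "Start_Position",
            "ref": "Reference_Allele",
            "alt": "Tumor_Seq_Allele2",
        }
        return _read_tabular(path, colmap)
    if format == "vcf":
        return _read_vcf(path, sample_field)
    raise ValueError(f"unknown catalog format {format!r}")


def write_catalog(catalogs: Iterable[SampleCatalog], path: str | Path) -> None:
    """Write catalogs as a combined plain TSV (columns per ``CATALOG_COLUMNS``)."""
    frames = []
    for cat in catalogs:
        df = cat.df.copy()
        df.insert(0, "sample", cat.sample_id)
        frames.append(df)
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=CATALOG_COLUMNS)
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotation tracks


@dataclass
class AnnotationTrack:
    """Named set of merged, sorted, half-open genomic intervals.

    ``intervals`` maps chromosome -> (starts, ends) as parallel int arrays,
    merged so that membership can be answered with a single searchsorted.
    """

    name: str
    intervals: dict[str, tuple[np.ndarray, np.ndarray]]

    def total_span(self) -> int:
        return int(
            sum((e - s).sum() for s, e in self.intervals.values())
        )

    def contains(self, chromosome: str, positions: np.ndarray) -> np.ndarray:
        """Membership flags for 1-based positions (vectorized).

        A position ``p`` is inside iff the 0-based coordinate ``p-1`` falls
        in some ``[start, end)`` interval of this chromosome.
        """
        key = canonical_chromosome(chromosome)
        positions = np.asarray(positions, dtype=np.int64)
        if key not in self.intervals:
            return np.zeros(len(positions), dtype=bool)
        starts, ends = self.intervals[key]
        coords = positions - 1
        idx = np.searchsorted(starts, coords, side="right") - 1
        valid = idx >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[valid] = coords[valid] < ends[idx[valid]]
        return out


def merge_intervals(
    starts: Sequence[int], ends: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping *and adjacent* half-open intervals; returns sorted arrays."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:  # overlap or exact adjacency under half-open semantics
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def read_bed(path: str | Path, name: Optional[str] = None) -> AnnotationTrack:
    """Read a BED3+ file into a merged :class:`AnnotationTrack`."""
    name = name or Path(str(path)).stem.replace(".bed", "")
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            chrom = canonical_chromosome(parts[0])
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            per_chrom.setdefault(chrom, []).append((start, end))
    intervals = {
        c: merge_intervals([s for s, _ in ivs], [e for _, e in ivs])
        for c, ivs in per_chrom.items()
    }
    return AnnotationTrack(name=name, intervals=intervals)


def write_bed(track: AnnotationTrack, path: str | Path) -> None:
    keys = sorted(track.intervals, key=chromosome_sort_key)
    with open(path, "w") as fh:
        for c in keys:
            starts, ends = track.intervals[c]
            for s, e in zip(starts, ends):
                fh.write(f"{c}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Result tables


def write_loci_table(loci, path: str | Path) -> None:
    """Write detected kataegis loci as a TSV with a deterministic row order."""
    rows = [
        {
            "sample": lc.sample_id,
            "chromosome": lc.chromosome,
            "start": lc.start,
            "end": lc.end,
            "n_sbs": lc.n_sbs,
            "span_bp": lc.span_bp,
            "mean_imd": round(lc.mean_imd, 6),
            "max_imd": lc.max_imd,
            "confidence": lc.confidence,
        }
        for lc in loci
    ]
    df = pd.DataFrame(rows, columns=LOCI_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["sample", "chromosome", "start"],
            key=lambda col: col.map(chromosome_sort_key)
            if col.name == "chromosome"
            else col,
            kind="mergesort",
        )
    df.to_csv(path, sep="\t", index=False)


def read_loci_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str})


def rainfall_table(catalog: SampleCatalog) -> pd.DataFrame:
    """Per-SBS companion table for rainfall plots.

    Columns: chromosome, position, ``imd`` (distance to the previous SBS on
    the same chromosome; NaN for the first), ``substitution_class``.
    """
    df = catalog.df.copy()
    imd = df.groupby("chromosome", sort=False)["position"].diff()
    df["imd"] = imd
    df["substitution_class"] = [
        class_of(r, a) for r, a in zip(df["ref"], df["alt"])
    ]
    return df[["chromosome", "position", "imd", "substitution_class"]]
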