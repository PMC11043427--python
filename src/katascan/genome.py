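"""Genome coordinate system, fixed-width binning, and substitution normalization.

Conventions used throughout the package:

* variant positions are 1-based inclusive (VCF convention);
* bins and annotation intervals are 0-based half-open (BED convention);
* conversion between the two happens exactly once, at comparison time
  (``locate_bin`` and interval membership subtract 1 from the variant position).

Substitutions are pyrimidine-normalized: a purine-reference change is
reverse-complemented (together with its trinucleotide context, when present)
so that the reference base is always C or T, giving the standard six classes
C>A, C>G, C>T, T>A, T>C, T>G.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "GenomeBuild",
    "BinScheme",
    "SUBSTITUTION_CLASSES",
    "canonical_chromosome",
    "chromosome_sort_key",
    "make_bins",
    "normalize_substitution",
]

SUBSTITUTION_CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Autosomes 1-22 plus X, which takes index 23 for binary-status counting.
AUTOSOMES = tuple(str(i) for i in range(1, 23))
DEFAULT_CHROMOSOMES_1_23 = frozenset(AUTOSOMES) | {"X"}


def canonical_chromosome(name: str) -> str:
    """Normalize a chromosome name: strip a ``chr`` prefix, map 23->X, 24->Y."""
    s = str(name).strip()
    s = re.sub(r"^chr", "", s, flags=re.IGNORECASE)
    if s == "23":
        return "X"
    if s == "24":
        return "Y"
    return s.upper() if s.lower() in ("x", "y", "mt", "m") else s


def chromosome_sort_key(name: str) -> tuple[int, str]:
    """Sort key giving the natural order 1..22, X, Y, then others lexically."""
    s = canonical_chromosome(name)
    if s.isdigit():
        return (int(s), "")
    if s == "X":
        return (23, "")
    if s == "Y":
        return (24, "")
    return (100, s)


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of chromosomes with lengths, optionally FASTA-backed.

    Parameters
    ----------
    name
        Build label, e.g. ``"hg19"`` or ``"synthetic"``.
    chromosomes
        Ordered ``(name, length)`` pairs; names are stored canonically
        (no ``chr`` prefix).
    fasta
        Optional path to a FASTA file used for trinucleotide-context lookup.
        When absent, spectra are reported at 6-class resolution only.
    """

    name: str
    chromosomes: tuple[tuple[str, int], ...]
    fasta: Optional[str] = None
    _lengths: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        canon = tuple(
            (canonical_chromosome(c), int(length)) for c, length in self.chromosomes
        )
        names = [c for c, _ in canon]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome build")
        if any(length <= 0 for _, length in canon):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "chromosomes", canon)
        object.__setattr__(self, "_lengths", dict(canon))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def length(self, chromosome: str) -> int:
        key = canonical_chromosome(chromosome)
        if key not in self._lengths:
            raise KeyError(f"unknown chromosome {chromosome!r}")
        return self._lengths[key]

    def __contains__(self, chromosome: str) -> bool:
        return canonical_chromosome(chromosome) in self._lengths

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def context_at(self, chromosome: str, position: int) -> Optional[str]:
        """Trinucleotide context centred on a 1-based position, or ``None``
        when no sequence source is attached or the site touches a contig end."""
        if self.fasta is None:
            return None
        from pyfaidx import Fasta

        fa = Fasta(self.fasta, as_raw=True, sequence_always_upper=True)
        key = chromosome if chromosome in fa else f"chr{chromosome}"
        if key not in fa or position < 2 or position > len(fa[key]) - 1:
            return None
        return str(fa[key][position - 2 : position + 1])

    @classmethod
    def from_tsv(cls, path: str | Path, name: str = "custom") -> "GenomeBuild":
        """Read a two-column (chromosome, length) TSV, header optional."""
        chroms: list[tuple[str, int]] = []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2 or not parts[1].strip():
                    continue
                try:
                    length = int(parts[1])
                except ValueError:
                    continue  # header row
                chroms.append((parts[0], length))
        if not chroms:
            raise ValueError(f"no chromosomes parsed from {path}")
        return cls(name=name, chromosomes=tuple(chroms))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chromosome\tlength\n")
            for c, length in self.chromosomes:
                fh.write(f"{c}\t{length}\n")


@dataclass(frozen=True)
class BinScheme:
    """Consecutive fixed-width half-open bins tiling a genome.

    Each chromosome is tiled by ``[k*w, (k+1)*w)`` windows with the last bin
    truncated at the chromosome length (never dropped), so that every base
    belongs to exactly one bin.  Global bin indices are contiguous in
    chromosome order.
    """

    genome: GenomeBuild
    width: int
    counts: tuple[int, ...]  # bins per chromosome, genome order
    offsets: tuple[int, ...]  # cumulative global index of each chromosome's bin 0

    @property
    def n_bins(self) -> int:
        return self.offsets[-1] + self.counts[-1] if self.counts else 0

    def chromosome_offset(self, chromosome: str) -> int:
        key = canonical_chromosome(chromosome)
        for (c, _), off in zip(self.genome.chromosomes, self.offsets):
            if c == key:
                return off
        raise KeyError(f"unknown chromosome {chromosome!r}")

    def bin_coordinates(self, global_index: int) -> tuple[str, int, int]:
        """Map a global bin index back to ``(chromosome, start, end)`` (half-open)."""
        if not 0 <= global_index < self.n_bins:
            raise IndexError(f"bin index {global_index} out of range")
        for (chrom, length), off, cnt in zip(
            self.genome.chromosomes, self.offsets, self.counts
        ):
            if global_index < off + cnt:
                local = global_index - off
                start = local * self.width
                return chrom, start, min(start + self.width, length)
        raise AssertionError("unreachable")

    def locate(self, chromosome: str, position: int) -> int:
        """Global index of the bin containing a 1-based position."""
        key = canonical_chromosome(chromosome)
        if key not in self.genome:
            raise KeyError(f"unknown chromosome {chromosome!r}")
        length = self.genome.length(key)
        if not 1 <= position <= length:
            raise ValueError(
                f"position {position} outside chromosome {key} (length {length})"
            )
        return self.chromosome_offset(key) + (position - 1) // self.width


def make_bins(genome: GenomeBuild, width: int = 2_000_000) -> BinScheme:
    """Tile ``genome`` with half-open bins of ``width`` bp (default 2 Mbp)."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    counts = tuple(-(-length // width) for _, length in genome.chromosomes)
    offsets = tuple(np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(int).tolist())
    return BinScheme(genome=genome, width=int(width), counts=counts, offsets=offsets)


def locate_bin(scheme: BinScheme, chromosome: str, position: int) -> int:
    """Functional alias for :meth:`BinScheme.locate`."""
    return scheme.locate(chromosome, position)


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in {seq!r}") from exc


def normalize_substitution(
    ref: str, alt: str, context: Optional[str] = None
) -> tuple[str, Optional[str]]:
    """Pyrimidine-normalize a substitution (and its context, jointly).

    Returns ``(substitution_class, context)`` where the class is one of the
    six ``C>A`` ... ``T>G`` strings and the context, when given, is the 3-mer
    on the strand carrying the pyrimidine reference.

    >>> normalize_substitution("G", "A")
    ('C>T', None)
    >>> normalize_substitution("G", "A", "TGA")
    ('C>T', 'TCA')
    """
    ref = ref.upper()
    alt = alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"bases must be A/C/G/T, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref!r}")
    if context is not None:
        context = context.upper()
        if len(context) != 3 or any(b not in _COMPLEMENT for b in context):
            raise ValueError(f"context must be an ACGT 3-mer, got {context!r}")
        if context[1] != ref:
            raise ValueError(
                f"context middle base {context[1]!r} does not match ref {ref!r}"
            )
    if ref in ("A", "G"):  # purine reference: flip strand
        ref2, alt2 = _COMPLEMENT[ref], _COMPLEMENT[alt]
        ctx2 = reverse_complement(context) if context is not None else None
        return f"{ref2}>{alt2}", ctx2
    return f"{ref}>{alt}", context


def class_of(ref: str, alt: str) -> str:
    """Six-class label of a substitution, ignoring context."""
    return normalize_substitution(ref, alt)[0]


def synthetic_genome(scale: float = 0.1, name: str = "synthetic") -> GenomeBuild:
    """Desk-scale surrogate genome: 23 chromosomes (1-22 and X) whose lengths
    are the human hg19 lengths scaled down (default 10%, ~310 Mb total).

    All rates in the package are per-Mb, so analyses transfer directly
    between this genome and a full-size build.
    """
    hg19_mb = {
        "1": 249.25, "2": 243.20, "3": 198.02, "4": 191.15, "5": 180.92,
        "6": 171.12, "7": 159.14, "8": 146.36, "9": 141.21, "10": 135.53,
        "11": 135.01, "12": 133.85, "13": 115.17, "14": 107.35, "15": 102.53,
        "16": 90.35, "17": 81.20, "18": 78.08, "19": 59.13, "20": 63.03,
        "21": 48.13, "22": 51.30, "X": 155.27,
    }
    chroms = tuple(
        (c, max(1, int(round(mb * 1e6 * scale)))) for c, mb in hg19_mb.items()
    )
    return GenomeBuild(name=name, chromosomes=chroms)
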