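"""Cohort-level kataegis statistics.

Binary kataegis status at event cut-offs, subgroup frequency curves, tumor
mutational burden, single-sample metagene rank scores, and the association
tests used across the analysis (Wilcoxon rank-sum for 2 groups,
Kruskal-Wallis for >2, chi-square for contingency tables, Benjamini-
Hochberg adjustment).  All p-values are two-sided.

The rank-based and chi-square machinery is delegated to scipy/statsmodels;
this module owns the method-selection policy (exact Wilcoxon only for small
tie-free samples, continuity correction defaults) and the degenerate-input
flagging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .detection import KataegisLocus
from .genome import canonical_chromosome

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "classify_binary",
    "event_counts",
    "frequency_by_cutoff",
    "compute_tmb",
    "metagene_rank_score",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "chi_square_test",
    "bh_adjust",
    "driver_association",
]

DEFAULT_STATUS_CHROMOSOMES = frozenset(
    {str(i) for i in range(1, 23)} | {"X"}
)  # "chromosomes 1-23", X aliased to 23

EXACT_WILCOXON_MAX_N = 8


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    pvalue: float
    group_sizes: tuple[int, ...]
    adjusted_pvalue: Optional[float] = None
    degenerate: bool = False


def event_counts(
    loci_by_sample: Mapping[str, Sequence[KataegisLocus]],
    chromosomes: Iterable[str] = DEFAULT_STATUS_CHROMOSOMES,
) -> dict[str, int]:
    """Kataegis event count per sample on the given chromosome set."""
    keys = {canonical_chromosome(c) for c in chromosomes}
    return {
        sid: sum(1 for lc in loci if canonical_chromosome(lc.chromosome) in keys)
        for sid, loci in loci_by_sample.items()
    }


def classify_binary(
    loci_by_sample: Mapping[str, Sequence[KataegisLocus]],
    cutoff: int = 1,
    chromosomes: Iterable[str] = DEFAULT_STATUS_CHROMOSOMES,
) -> dict[str, bool]:
    """Binary kataegis status: positive iff the event count on the chromosome
    set (default 1-22 plus X) reaches the cut-off (default >= 1 event)."""
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    counts = event_counts(loci_by_sample, chromosomes)
    return {sid: n >= cutoff for sid, n in counts.items()}


def frequency_by_cutoff(
    counts_by_sample: Mapping[str, int],
    samples: Sequence[str],
    cutoffs: Sequence[int] = (1, 2, 3, 4, 5),
) -> pd.DataFrame:
    """Positive fraction of a subgroup at each event cut-off.

    The curve is monotone non-increasing in the cut-off by construction
    (higher cut-offs select subsets).
    """
    if len(samples) == 0:
        raise ValueError("empty subgroup")
    rows = []
    for k in cutoffs:
        n_pos = sum(counts_by_sample.get(s, 0) >= k for s in samples)
        rows.append({"cutoff": k, "n_positive": n_pos, "n": len(samples),
                     "frequency": n_pos / len(samples)})
    return pd.DataFrame(rows)


def compute_tmb(n_sbs: int, n_indel: int, genome_size_bp: int) -> float:
    """Tumor mutational burden: (SBS + indel count) per Mbp of genome."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    return (n_sbs + n_indel) / (genome_size_bp / 1e6)


def metagene_rank_score(
    expression: pd.Series, gene_set: Iterable[str]
) -> Optional[float]:
    """Single-sample metagene rank score in (0, 1].

    All measured genes of the sample are ranked ascending by expression
    (average ranks for ties, so higher expression means a higher rank) and
    the score is the mean rank of the set members divided by the total gene
    count.  No cross-sample normalization or centering is applied, so the
    score of a sample never depends on which other samples are present.

    Returns ``None`` (flagged missing) when no set member was measured.
    """
    members = [g for g in gene_set if g in expression.index]
    if not members:
        return None
    ranks = sps.rankdata(expression.to_numpy())
    idx = expression.index.get_indexer(members)
    return float(ranks[idx].mean() / len(expression))


# ---------------------------------------------------------------------------
# Association tests


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact: Optional[bool] = None
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration is used when both samples have <= 8 observations and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.  ``exact`` overrides the automatic choice.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if exact is None:
        exact = (
            len(x) <= EXACT_WILCOXON_MAX_N
            and len(y) <= EXACT_WILCOXON_MAX_N
            and not has_ties
        )
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic",
        use_continuity=not exact,
    )
    return TestResult(
        test="wilcoxon_rank_sum",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        group_sizes=(len(x), len(y)),
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected) against chi-square with k-1 df."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # All observations identical: H = 0 and the tie correction divides
        # by zero; flag instead of erroring.
        return TestResult(
            test="kruskal_wallis",
            statistic=0.0,
            pvalue=1.0,
            group_sizes=tuple(len(g) for g in arrays),
            degenerate=True,
        )
    stat, p = sps.kruskal(*arrays)
    return TestResult(
        test="kruskal_wallis",
        statistic=float(stat),
        pvalue=float(p),
        group_sizes=tuple(len(g) for g in arrays),
    )


def chi_square_test(
    table: Sequence[Sequence[float]], continuity: bool = False
) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    Continuity (Yates) correction is OFF by default for all table sizes —
    one consistent rule — and can be enabled for 2x2 tables via the flag.
    A zero row or column marginal is flagged degenerate (p undefined).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    sizes = tuple(int(n) for n in arr.sum(axis=1))
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return TestResult(
            test="chi_square",
            statistic=float("nan"),
            pvalue=float("nan"),
            group_sizes=sizes,
            degenerate=True,
        )
    res = sps.chi2_contingency(arr, correction=continuity)
    return TestResult(
        test="chi_square",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        group_sizes=sizes,
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def driver_association(
    driver_flags: pd.DataFrame,
    status: Mapping[str, bool],
    samples: Sequence[str],
    subgroup: str = "all",
    continuity: bool = False,
) -> pd.DataFrame:
    """Per-gene 2x2 chi-square of driver alteration vs binary kataegis status
    within one subgroup, with BH adjustment across the subgroup's gene panel.

    ``driver_flags`` is a samples x genes 0/1 matrix.  Genes with a zero
    marginal (altered in all or in no samples, or a one-sided status) are
    flagged degenerate, logged, and excluded from the BH family.
    """
    samples = [s for s in samples if s in driver_flags.index]
    status_vec = np.array([bool(status[s]) for s in samples])
    rows = []
    for gene in driver_flags.columns:
        flags = driver_flags.loc[samples, gene].to_numpy().astype(bool)
        table = [
            [int((flags & status_vec).sum()), int((flags & ~status_vec).sum())],
            [int((~flags & status_vec).sum()), int((~flags & ~status_vec).sum())],
        ]
        res = chi_square_test(table, continuity=continuity)
        rows.append(
            {
                "subgroup": subgroup,
                "gene": gene,
                "n_altered": int(flags.sum()),
                "n_altered_positive": table[0][0],
                "statistic": res.statistic,
                "pvalue": res.pvalue,
                "degenerate": res.degenerate,
            }
        )
    out = pd.DataFrame(rows)
    out["adjusted_pvalue"] = np.nan
    ok = ~out["degenerate"]
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info(
            "%s: %d degenerate gene(s) excluded from the BH family", subgroup, n_excluded
        )
    if ok.any():
        out.loc[ok, "adjusted_pvalue"] = bh_adjust(out.loc[ok, "pvalue"].to_numpy())
    return out
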