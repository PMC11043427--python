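"""Cohort-level association statistics.

Binary kataegis status (>= 1 event on chromosomes 1-23) and event-count
frequency curves over cut-offs 1-5 per subgroup; Wilcoxon tests of TMB and
age vs binary status; per-gene driver-alteration chi-square with BH
adjustment (the simulator planted one gene at odds ratio 4); and
single-sample metagene rank scores compared between status groups.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SIM_DIR, require_simulation

import numpy as np
import pandas as pd

from katascan.cohort_stats import (
    classify_binary,
    compute_tmb,
    driver_association,
    event_counts,
    frequency_by_cutoff,
    metagene_rank_score,
    wilcoxon_rank_sum,
)
from katascan.detection import detect_and_filter
from katascan.genome import GenomeBuild
from katascan.variant_io import read_sbs_catalogs


def main():
    require_simulation()
    genome = GenomeBuild.from_tsv(SIM_DIR / "genome.tsv", name="synthetic")
    catalogs = read_sbs_catalogs(SIM_DIR / "catalog.tsv")
    metadata = pd.read_csv(SIM_DIR / "metadata.tsv", sep="\t").set_index("sample")

    loci = {s: detect_and_filter(c) for s, c in catalogs.items()}
    counts = event_counts(loci)
    status = classify_binary(loci)

    # frequency curves
    frames = []
    for group, sub in metadata.groupby("subgroup"):
        curve = frequency_by_cutoff(counts, list(sub.index), cutoffs=(1, 2, 3, 4, 5))
        curve.insert(0, "subgroup", group)
        frames.append(curve)
        at1 = curve.loc[curve["cutoff"] == 1, "frequency"].iloc[0]
        at3 = curve.loc[curve["cutoff"] == 3, "frequency"].iloc[0]
        print(f"{group}: binary frequency {at1:.3f} at cutoff 1, {at3:.3f} at cutoff 3")
    pd.concat(frames, ignore_index=True).to_csv(
        RESULTS / "frequency_curves.tsv", sep="\t", index=False
    )

    # TMB and age vs binary status
    tmb = {
        s: compute_tmb(len(catalogs[s]), int(metadata.loc[s, "indel_count"]),
                       genome.total_length)
        for s in catalogs
    }
    assoc = []
    for var, values in (("tmb", tmb), ("age", metadata["age"].to_dict())):
        for group, sub in metadata.groupby("subgroup"):
            pos = [values[s] for s in sub.index if status[s]]
            neg = [values[s] for s in sub.index if not status[s]]
            if not pos or not neg:
                continue
            res = wilcoxon_rank_sum(pos, neg)
            assoc.append(
                {"variable": var, "subgroup": group, "pvalue": res.pvalue,
                 "n_positive": len(pos), "n_negative": len(neg)}
            )
    assoc_df = pd.DataFrame(assoc)
    assoc_df.to_csv(RESULTS / "association_tests.tsv", sep="\t", index=False,
                    float_format="%.4g")

    # driver association (BH within each subgroup's gene panel)
    drivers = pd.read_csv(SIM_DIR / "drivers.tsv", sep="\t", index_col=0)
    frames = []
    for group, sub in metadata.groupby("subgroup"):
        frames.append(driver_association(drivers, status, list(sub.index),
                                         subgroup=group))
    ddf = pd.concat(frames, ignore_index=True)
    ddf.to_csv(RESULTS / "driver_association.tsv", sep="\t", index=False,
               float_format="%.6g")
    ok = ddf.dropna(subset=["adjusted_pvalue"])
    for group, sub in ok.groupby("subgroup"):
        top = sub.loc[sub["adjusted_pvalue"].idxmin()]
        print(
            f"top driver association in {group}: {top['gene']} "
            f"(adjusted p = {top['adjusted_pvalue']:.3g})"
        )

    # metagene rank scores by status
    expr = pd.read_csv(SIM_DIR / "expression.tsv", sep="\t", index_col=0)
    sets = {}
    for line in (SIM_DIR / "metagenes.tsv").read_text().splitlines():
        name, gene = line.split("\t")
        sets.setdefault(name, []).append(gene)
    rows = []
    for sample in expr.columns:
        for name, genes in sets.items():
            rows.append(
                {"sample": sample, "metagene": name,
                 "score": metagene_rank_score(expr[sample], genes),
                 "kataegis_positive": int(status[sample])}
            )
    scores = pd.DataFrame(rows)
    scores.to_csv(RESULTS / "metagene_scores.tsv", sep="\t", index=False,
                  float_format="%.6g")
    for name in sets:
        sub = scores[scores["metagene"] == name]
        pos = sub.loc[sub["kataegis_positive"] == 1, "score"]
        neg = sub.loc[sub["kataegis_positive"] == 0, "score"]
        res = wilcoxon_rank_sum(pos, neg)
        print(
            f"metagene {name}: median score {pos.median():.3f} (positive) vs "
            f"{neg.median():.3f} (negative), Wilcoxon p = {res.pvalue:.3g}"
        )
    print(f"tables -> {RESULTS}")


if __name__ == "__main__":
    main()
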