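"""Map SBS pools to annotation tracks and compute enrichment ratios.

For every track (ATAC, DHS) and subgroup: the proportion of
kataegis-associated SBSs mapped to the track, the all-SBS proportions of
kataegis-positive and -negative tumors, and the kataegis/all enrichment
ratio.  The simulator placed clusters into ATAC-like regions at twice the
background propensity, so the ATAC ratio should recover ~2.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SIM_DIR, require_simulation

import numpy as np
import pandas as pd

from katascan.cohort_stats import classify_binary
from katascan.detection import detect_and_filter
from katascan.enrichment import (
    POOL_ALL_POSITIVE,
    POOL_KATAEGIS,
    context_proportions,
    enrichment_ratio,
    proportions_table,
)
from katascan.variant_io import read_bed, read_sbs_catalogs


def main():
    require_simulation()
    catalogs = read_sbs_catalogs(SIM_DIR / "catalog.tsv")
    metadata = pd.read_csv(SIM_DIR / "metadata.tsv", sep="\t")
    subgroups = metadata.groupby("subgroup")["sample"].apply(list).to_dict()

    loci = {s: detect_and_filter(c) for s, c in catalogs.items()}
    status = classify_binary(loci)
    positives = {s for s, v in status.items() if v}

    records, ratio_rows = [], []
    for bed in sorted((SIM_DIR / "tracks").glob("*.bed")):
        track = read_bed(bed)
        for group, members in sorted(subgroups.items()):
            props = context_proportions(
                catalogs, loci, positives, track, members, subgroup=group
            )
            records.extend(props.values())
            ratio = enrichment_ratio(props[POOL_KATAEGIS], props[POOL_ALL_POSITIVE])
            ratio_rows.append(
                {
                    "subgroup": group,
                    "track": track.name,
                    "ratio": np.nan if ratio.ratio is None else round(ratio.ratio, 4),
                }
            )
    proportions_table(records).to_csv(
        RESULTS / "context_proportions.tsv", sep="\t", index=False, float_format="%.6g"
    )
    ratios = pd.DataFrame(ratio_rows)
    ratios.to_csv(RESULTS / "enrichment_ratios.tsv", sep="\t", index=False)
    for _, row in ratios.iterrows():
        print(f"{row['subgroup']:>9} {row['track']}: kataegis/all ratio {row['ratio']}")
    print(f"tables -> {RESULTS}")


if __name__ == "__main__":
    main()
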