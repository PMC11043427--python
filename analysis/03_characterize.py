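"""Characterize detected loci per clinical subgroup.

Merged six-class substitution spectra (all member SBSs of a subgroup pooled
into one set), locus span / SBS-count distributions, events per chromosome
(1-22), and kataegis recurrence in consecutive 2-Mbp bins with per-group
event frequencies.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SIM_DIR, require_simulation

import pandas as pd

from katascan.characterization import (
    bin_recurrence,
    events_per_chromosome,
    locus_size_summary,
    merged_spectrum,
)
from katascan.detection import detect_and_filter
from katascan.genome import GenomeBuild, make_bins
from katascan.variant_io import read_sbs_catalogs


def main():
    require_simulation()
    genome = GenomeBuild.from_tsv(SIM_DIR / "genome.tsv", name="synthetic")
    catalogs = read_sbs_catalogs(SIM_DIR / "catalog.tsv")
    metadata = pd.read_csv(SIM_DIR / "metadata.tsv", sep="\t")
    subgroup_of = dict(zip(metadata["sample"], metadata["subgroup"]))

    loci_by_group = {}
    for sid, cat in catalogs.items():
        loci_by_group.setdefault(subgroup_of[sid], []).extend(detect_and_filter(cat))

    spectra, sizes = [], []
    for group, loci in sorted(loci_by_group.items()):
        profile = merged_spectrum(loci, label=group)
        spectra.append(profile.to_frame())
        summary = locus_size_summary(loci)["quantiles"]
        sizes.append(
            {
                "subgroup": group,
                "n_loci": len(loci),
                "median_span_bp": summary["span_bp"].get("q50"),
                "median_n_sbs": summary["n_sbs"].get("q50"),
            }
        )
        top = max(profile.proportions, key=profile.proportions.get)
        apobec = profile.proportions["C>T"] + profile.proportions["C>G"]
        print(
            f"{group}: {len(loci)} loci, dominant class {top} "
            f"({profile.proportions[top]:.2f}), C>T+C>G = {apobec:.2f}"
        )
    pd.concat(spectra, ignore_index=True).to_csv(
        RESULTS / "spectra.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pd.DataFrame(sizes).to_csv(
        RESULTS / "loci_size_summary.tsv", sep="\t", index=False
    )

    chrom_rows = [
        {"subgroup": g, "chromosome": c, "count": n}
        for g, loci in sorted(loci_by_group.items())
        for c, n in events_per_chromosome(loci).items()
    ]
    pd.DataFrame(chrom_rows).to_csv(RESULTS / "chrom_counts.tsv", sep="\t", index=False)

    scheme = make_bins(genome, 2_000_000)
    group_sizes = metadata.groupby("subgroup").size().to_dict()
    table = bin_recurrence(loci_by_group, scheme, group_sizes)
    table.to_csv(RESULTS / "bin_recurrence.tsv", sep="\t", index=False,
                 float_format="%.6g")
    for group in sorted(loci_by_group):
        top = table.loc[table[f"count_{group}"].idxmax()]
        print(
            f"most recurrent 2-Mbp bin in {group}: chr{top['chromosome']}:"
            f"{int(top['start'])}-{int(top['end'])} "
            f"({int(top[f'count_{group}'])} events, "
            f"frequency {top[f'frequency_{group}']:.3f})"
        )
    print(f"tables -> {RESULTS}")


if __name__ == "__main__":
    main()
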