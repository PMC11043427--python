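"""Simulate the synthetic breast cancer cohort with ground truth.

Draws 200 tumors in four clinical subgroups (TNBC, ERpHER2n, ERpHER2p,
ERnHER2p) on a ~304 Mb desk-scale genome: uniform background SBSs at
2/Mb, APOBEC-like kataegis clusters in positive tumors, ATAC/DHS-like
annotation tracks (clusters enriched 2x into ATAC), driver flags, and an
expression matrix.  Writes the pipeline input formats plus truth.json to
scratch/sim/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import SEED, SIM_DIR, cohort_config

from katascan.simulate import simulate_cohort


def main():
    config = cohort_config()
    cohort = simulate_cohort(config, seed=SEED)
    cohort.write(SIM_DIR)
    n_sbs = sum(len(c) for c in cohort.catalogs.values())
    n_pos = sum(cohort.truth.status.values())
    print(f"cohort: {len(cohort.catalogs)} tumors, {n_sbs} SBSs")
    print(
        f"truth: {n_pos} kataegis-positive tumors, "
        f"{sum(len(v) for v in cohort.truth.loci.values())} injected loci, "
        f"{cohort.truth.n_clustered_sbs()} clustered SBSs"
    )
    for group in config.subgroups:
        members = [s for s, g in cohort.truth.subgroup.items() if g == group]
        pos = sum(cohort.truth.status[s] for s in members)
        print(f"  {group}: {pos}/{len(members)} positive "
              f"(input positivity {config.subgroups[group].positivity})")
    print(f"written to {SIM_DIR}")


if __name__ == "__main__":
    main()
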