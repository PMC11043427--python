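import numpy as np
import pandas as pd
import pytest

from katascan.genome import GenomeBuild
from katascan.variant_io import SampleCatalog


@pytest.fixture
def small_genome():
    return GenomeBuild(
        name="toy", chromosomes=(("1", 10_000_000), ("2", 3_000_000), ("X", 1_000_000))
    )


def build_catalog(positions_by_chrom, sample_id="S1", ref="C", alt="T", alleles=None):
    """Catalog from {chrom: positions}; alleles may override per-chromosome
    (ref_list, alt_list) pairs."""
    rows = []
    for chrom, positions in positions_by_chrom.items():
        if alleles and chrom in alleles:
            refs, alts = alleles[chrom]
        else:
            refs = [ref] * len(positions)
            alts = [alt] * len(positions)
        for p, r, a in zip(positions, refs, alts):
            rows.append({"chromosome": chrom, "position": int(p), "ref": r, "alt": a})
    df = pd.DataFrame(rows, columns=["chromosome", "position", "ref", "alt"])
    df["position"] = df["position"].astype(np.int64) if len(df) else df["position"]
    return SampleCatalog.from_dataframe(sample_id, df)


@pytest.fixture
def make_catalog():
    return build_catalog
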