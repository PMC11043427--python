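"""End-to-end orchestration: detect -> characterize -> enrich -> associate.

`run_pipeline` drives every stage from one :class:`RunConfig`, writing each
stage's TSV outputs plus a JSON manifest (tool version, config hash,
per-stage row counts, seed).  Stages with missing optional inputs
(expression, drivers) are skipped with a logged notice.  Re-running with
identical inputs and configuration reproduces byte-identical outputs: no
timestamps or machine identifiers are written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .genome import GenomeBuild, make_bins, chromosome_sort_key, AUTOSOMES
from .variant_io import (
    read_sbs_catalogs,
    read_bed,
    write_loci_table,
)
from .detection import DetectionParams, detect_kataegis, filter_loci
from .characterization import (
    merged_spectrum,
    locus_size_summary,
    events_per_chromosome,
    bin_recurrence,
)
from .enrichment import (
    context_proportions,
    enrichment_ratio,
    proportions_table,
    POOL_KATAEGIS,
    POOL_ALL_POSITIVE,
)
from .cohort_stats import (
    classify_binary,
    event_counts,
    frequency_by_cutoff,
    compute_tmb,
    metagene_rank_score,
    wilcoxon_rank_sum,
    kruskal_wallis,
    driver_association,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    catalog: str
    genome: str
    out_dir: str
    catalog_format: str = "tsv"
    tracks_dir: Optional[str] = None
    metadata: Optional[str] = None
    expression: Optional[str] = None
    metagenes: Optional[str] = None
    drivers: Optional[str] = None
    subgroup_column: str = "subgroup"
    min_sbs: int = 6
    imd_threshold: int = 1000
    imd_rule: str = "max"
    min_confidence: int = 1
    bin_width: int = 2_000_000
    cutoffs: Sequence[int] = (1, 2, 3, 4, 5)
    seed: int = 0
    log_level: str = "INFO"

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            min_sbs=self.min_sbs,
            imd_threshold=self.imd_threshold,
            imd_rule=self.imd_rule,
            min_confidence=self.min_confidence,
        )

    def config_hash(self) -> str:
        # out_dir is excluded: the hash identifies the analysis, not where
        # its results land, so re-runs into different directories compare equal
        payload = json.dumps(
            {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self).items()
                if k != "out_dir"
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _read_metagene_sets(path: str) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0]:
                sets.setdefault(parts[0], []).append(parts[1])
    return sets


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {
        "tool": "katascan",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    genome = GenomeBuild.from_tsv(config.genome)
    params = config.detection_params()
    catalogs = read_sbs_catalogs(
        config.catalog, format=config.catalog_format
    )
    manifest["stages"]["read"] = {
        "n_samples": len(catalogs),
        "n_sbs": int(sum(len(c) for c in catalogs.values())),
    }

    # --- detection -------------------------------------------------------
    loci_by_sample = {
        sid: filter_loci(detect_kataegis(cat, params), params)
        for sid, cat in sorted(catalogs.items())
    }
    all_loci = [lc for ll in loci_by_sample.values() for lc in ll]
    write_loci_table(all_loci, out / "loci.tsv")
    manifest["stages"]["detect"] = {"n_loci": len(all_loci)}

    # --- metadata / subgroups -------------------------------------------
    if config.metadata:
        metadata = pd.read_csv(config.metadata, sep="\t", dtype={"sample": str})
        metadata = metadata.set_index("sample")
    else:
        metadata = pd.DataFrame(index=pd.Index(sorted(catalogs), name="sample"))
    if config.subgroup_column not in metadata.columns:
        metadata[config.subgroup_column] = "all"
    subgroups = {
        g: list(sub.index)
        for g, sub in metadata.groupby(config.subgroup_column, sort=True)
    }

    # --- binary status and frequency curves -----------------------------
    counts = event_counts(loci_by_sample)
    status = classify_binary(loci_by_sample, cutoff=1)
    status_df = pd.DataFrame(
        {
            "sample": sorted(catalogs),
            "event_count": [counts.get(s, 0) for s in sorted(catalogs)],
            "kataegis_positive": [int(status.get(s, False)) for s in sorted(catalogs)],
        }
    )
    genome_size = sum(
        genome.length(c) for c in genome.names if c != "Y"
    )
    tmb = []
    for s in sorted(catalogs):
        indels = 0
        if "indel_count" in metadata.columns and s in metadata.index:
            indels = int(metadata.loc[s, "indel_count"])
        tmb.append(compute_tmb(len(catalogs[s]), indels, genome_size))
    status_df["tmb"] = np.round(tmb, 6)
    status_df.to_csv(out / "binary_status.tsv", sep="\t", index=False)
    manifest["stages"]["binary_status"] = {"n_rows": len(status_df)}

    freq_frames = []
    for g, members in subgroups.items():
        members_present = [s for s in members if s in catalogs]
        if not members_present:
            continue
        fdf = frequency_by_cutoff(counts, members_present, config.cutoffs)
        fdf.insert(0, "subgroup", g)
        freq_frames.append(fdf)
    freq = pd.concat(freq_frames, ignore_index=True) if freq_frames else pd.DataFrame()
    freq.to_csv(out / "frequency_curves.tsv", sep="\t", index=False)
    manifest["stages"]["frequency_curves"] = {"n_rows": len(freq)}

    # --- characterization ------------------------------------------------
    spectra = []
    sizes = []
    chrom_rows = []
    loci_by_group = {}
    for g, members in subgroups.items():
        g_loci = [lc for s in members for lc in loci_by_sample.get(s, [])]
        loci_by_group[g] = g_loci
        spectra.append(merged_spectrum(g_loci, label=g).to_frame())
        summ = locus_size_summary(g_loci)
        for span, n in zip(summ["span_bp"], summ["n_sbs"]):
            sizes.append({"subgroup": g, "span_bp": int(span), "n_sbs": int(n)})
        for chrom, n in events_per_chromosome(g_loci).items():
            chrom_rows.append({"subgroup": g, "chromosome": chrom, "count": n})
    pd.concat(spectra, ignore_index=True).to_csv(
        out / "spectra.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pd.DataFrame(sizes, columns=["subgroup", "span_bp", "n_sbs"]).to_csv(
        out / "loci_sizes.tsv", sep="\t", index=False
    )
    pd.DataFrame(chrom_rows, columns=["subgroup", "chromosome", "count"]).to_csv(
        out / "chrom_counts.tsv", sep="\t", index=False
    )
    scheme = make_bins(genome, config.bin_width)
    group_sizes = {g: len(m) for g, m in subgroups.items() if len(m)}
    recurrence = bin_recurrence(
        {g: loci_by_group[g] for g in group_sizes}, scheme, group_sizes
    )
    recurrence.to_csv(out / "bin_recurrence.tsv", sep="\t", index=False,
                      float_format="%.6g")
    manifest["stages"]["characterize"] = {
        "n_bins": len(recurrence),
        "n_spectra": len(spectra),
    }

    # --- context enrichment ---------------------------------------------
    if config.tracks_dir and Path(config.tracks_dir).is_dir():
        prop_records = []
        ratio_rows = []
        positives = {s for s, v in status.items() if v}
        bed_files = sorted(Path(config.tracks_dir).glob("*.bed"))
        for bed in bed_files:
            track = read_bed(bed)
            for g, members in subgroups.items():
                members_present = [s for s in members if s in catalogs]
                props = context_proportions(
                    catalogs, loci_by_sample, positives, track,
                    members_present, subgroup=g,
                )
                prop_records.extend(props.values())
                ratio = enrichment_ratio(
                    props[POOL_KATAEGIS], props[POOL_ALL_POSITIVE]
                )
                ratio_rows.append(
                    {
                        "subgroup": g,
                        "track": track.name,
                        "ratio": np.nan if ratio.ratio is None else round(ratio.ratio, 6),
                    }
                )
        proportions_table(prop_records).to_csv(
            out / "context_proportions.tsv", sep="\t", index=False, float_format="%.6g"
        )
        pd.DataFrame(ratio_rows).to_csv(
            out / "enrichment_ratios.tsv", sep="\t", index=False
        )
        manifest["stages"]["enrich"] = {
            "n_tracks": len(bed_files),
            "n_rows": len(ratio_rows),
        }
    else:
        logger.info("no annotation tracks supplied; enrichment stage skipped")
        manifest["stages"]["enrich"] = "skipped"

    # --- association tests ----------------------------------------------
    assoc_rows = []
    for var in ("age", "tmb", "cn_fga", "loh_fraction"):
        if var == "tmb":
            values = dict(zip(status_df["sample"], status_df["tmb"]))
        elif var in metadata.columns:
            values = metadata[var].to_dict()
        else:
            continue
        for g, members in subgroups.items():
            pos = [values[s] for s in members if s in values and status.get(s)]
            neg = [values[s] for s in members if s in values and not status.get(s)]
            if not pos or not neg:
                continue
            res = wilcoxon_rank_sum(pos, neg)
            assoc_rows.append(
                {
                    "variable": var,
                    "subgroup": g,
                    "test": res.test,
                    "statistic": round(res.statistic, 6),
                    "pvalue": float(f"{res.pvalue:.6g}"),
                    "n_positive": len(pos),
                    "n_negative": len(neg),
                }
            )
    # event count across subgroups (Kruskal-Wallis)
    groups = [
        [counts.get(s, 0) for s in members if s in catalogs]
        for g, members in subgroups.items()
    ]
    groups = [g for g in groups if g]
    if len(groups) >= 2:
        res = kruskal_wallis(groups)
        assoc_rows.append(
            {
                "variable": "event_count",
                "subgroup": "across_subgroups",
                "test": res.test,
                "statistic": round(res.statistic, 6),
                "pvalue": float(f"{res.pvalue:.6g}"),
                "n_positive": sum(len(g) for g in groups),
                "n_negative": 0,
            }
        )
    pd.DataFrame(assoc_rows).to_csv(out / "association_tests.tsv", sep="\t", index=False)
    manifest["stages"]["associate"] = {"n_tests": len(assoc_rows)}

    # --- driver association ----------------------------------------------
    if config.drivers and Path(config.drivers).is_file():
        drivers = pd.read_csv(config.drivers, sep="\t", index_col=0)
        drivers.index = drivers.index.astype(str)
        frames = []
        for g, members in subgroups.items():
            members_present = [s for s in members if s in drivers.index and s in status]
            if len(members_present) < 2:
                continue
            frames.append(
                driver_association(drivers, status, members_present, subgroup=g)
            )
        ddf = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        ddf.to_csv(out / "driver_association.tsv", sep="\t", index=False,
                   float_format="%.6g")
        manifest["stages"]["drivers"] = {"n_rows": len(ddf)}
    else:
        logger.info("no driver matrix supplied; driver stage skipped")
        manifest["stages"]["drivers"] = "skipped"

    # --- metagene scores --------------------------------------------------
    if (
        config.expression
        and Path(config.expression).is_file()
        and config.metagenes
        and Path(config.metagenes).is_file()
    ):
        expr = pd.read_csv(config.expression, sep="\t", index_col=0)
        sets = _read_metagene_sets(config.metagenes)
        rows = []
        for sample in expr.columns:
            for name, genes in sets.items():
                score = metagene_rank_score(expr[sample], genes)
                rows.append(
                    {
                        "sample": sample,
                        "metagene": name,
                        "score": np.nan if score is None else round(score, 6),
                    }
                )
        pd.DataFrame(rows).to_csv(out / "metagene_scores.tsv", sep="\t", index=False)
        manifest["stages"]["metagenes"] = {"n_rows": len(rows)}
    else:
        logger.info("expression or metagene sets missing; metagene stage skipped")
        manifest["stages"]["metagenes"] = "skipped"

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
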