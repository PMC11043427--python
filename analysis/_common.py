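"""Shared paths and the cohort configuration used by the numbered drivers.

The drivers simulate one desk-scale cohort (seed 17) into ``scratch/sim``
(bulky per-SBS inputs, not part of the deliverable) and write their summary
tables under ``results/``.
"""

from pathlib import Path

from katascan.simulate import SimulationConfig

REPO = Path(__file__).resolve().parent.parent
SIM_DIR = REPO / "scratch" / "sim"
RESULTS = REPO / "results"
SEED = 17

DETECTION_DEFAULTS = dict(min_sbs=6, imd_threshold=1000, imd_rule="max")


def cohort_config() -> SimulationConfig:
    """Default study conditions: four clinical subgroups of 50 tumors with
    the observed kataegis positivities, APOBEC-like clusters, ATAC/DHS-like
    tracks, a TP53-like driver effect, and a metagene-structured
    expression matrix."""
    return SimulationConfig()


def require_simulation():
    if not (SIM_DIR / "catalog.tsv").is_file():
        raise SystemExit(
            f"no simulated cohort under {SIM_DIR}; run analysis/01_simulate.py first"
        )
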