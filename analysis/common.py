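"""Shared paths and settings for the numbered analysis scripts.

The scripts form one narrative run over a synthetic cohort shaped like
the motivating study (18 tumor vs 6 control samples, 453 detected
miRNAs) and write their tables under results/study/.
"""

from pathlib import Path

from mirvalid.simdata import SimConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "study"
SEED = 20260926

SIM = SimConfig(seed=SEED)  # study-shaped defaults: 453 miRNAs, 18 vs 6


def results_dir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
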