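"""RT-qPCR validation stage on the synthetic cohort.

Builds a 40-target custom panel from the top DE candidates, simulates CT
values against the selected normalizer trio, quantifies each target by
ddCT and classifies the volcano (|fold regulation| >= 2, p < 0.05).
Writes results/study/ct.tsv and qpcr.tsv.
"""

import json
import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import SIM, results_dir

from mirvalid import io
from mirvalid.concordance import summarize_validation
from mirvalid.diffexpr import rank_candidates
from mirvalid.qpcrquant import PanelConfig, classify_volcano, ddct_quantify, delta_ct
from mirvalid.simdata import simulate_ct

out = results_dir()
truth = io.read_truth_table(out / "truth.tsv")
de = io.read_de_table(out / "de.tsv")
normalizers = json.loads((out / "normalizers.json").read_text())["candidates"]

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    targets = rank_candidates(de, 40)
panel = PanelConfig(target_assays=targets, reference_assays=normalizers)

ct = simulate_ct(truth, SIM, panel)
io.write_ct_table(ct, out / "ct.tsv")

qpcr = classify_volcano(ddct_quantify(delta_ct(ct, panel)))
qpcr.rename_axis("mirna_id").to_csv(out / "qpcr.tsv", sep="\t")

n_val, n_up, n_down = summarize_validation(qpcr)
print(f"panel: {len(panel.target_assays)} targets, "
      f"references {', '.join(normalizers)}")
print(f"validated {n_val}/{len(panel.target_assays)} targets "
      f"({n_up} up, {n_down} down) at |FR|>=2, p<0.05")
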