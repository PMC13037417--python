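"""Cross-platform and cross-tissue agreement.

First compares the synthetic sequencing DE calls against the synthetic
qPCR volcano classes (direction concordance among jointly significant
miRNAs). Then reproduces the published cross-tissue comparison: volcano
classification of the splenic and cardiac validated tables, their
signed overlap, and the single consistently downregulated miRNA.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import results_dir

from mirvalid import io
from mirvalid.concordance import direction_concordance, overlap_sets, summarize_validation
from mirvalid.datasets import load_cardiac_validation, load_splenic_validation
from mirvalid.qpcrquant import classify_volcano

out = results_dir()
de = io.read_de_table(out / "de.tsv")
qpcr = pd.read_csv(out / "qpcr.tsv", sep="\t", index_col="mirna_id")

frac, table = direction_concordance(de, qpcr)
table.rename_axis("mirna_id").to_csv(out / "concordance.tsv", sep="\t")
n_joint = int(table["jointly_significant"].sum())
print(f"synthetic cohort: {n_joint} jointly significant miRNAs, "
      f"direction concordance {frac:.3f}")

splenic = classify_volcano(load_splenic_validation())
cardiac = classify_volcano(load_cardiac_validation())
print("published splenic table: %d validated (%d up, %d down)"
      % summarize_validation(splenic))
print("published cardiac table: %d validated (%d up, %d down)"
      % summarize_validation(cardiac))

report = overlap_sets(splenic["class"], cardiac["class"])
(out / "venn.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
print(f"shared between tissues: {report.n_shared} "
      f"({len(report.discordant)} discordant: {', '.join(report.discordant)})")
print(f"concordant in both tissues: {', '.join(report.concordant)} "
      f"({splenic.loc[report.concordant[0], 'class']} in both)")
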