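"""Multi-step endogenous-normalizer selection on the synthetic cohort.

Filters non-DE miRNAs (FDR > 0.05), ranks by fold-change proximity to 1,
keeps the lowest-CV half of CPM values and applies the exclusion list,
then picks a trio of candidate reference miRNAs. Writes the stability
table and a JSON report, and checks the trio against the planted truth.
"""

import json
import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import results_dir

from mirvalid import io
from mirvalid.refselect import select_normalizers

out = results_dir()
counts = io.read_count_matrix(out / "counts.tsv", out / "groups.tsv")
truth = io.read_truth_table(out / "truth.tsv")
de = io.read_de_table(out / "de.tsv")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = select_normalizers(counts, de, n=3)

(out / "normalizers.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
report.stability.rename_axis("mirna_id").to_csv(out / "stability.tsv", sep="\t")

print("stage survivors:", report.stage_counts)
print("selected normalizer trio:", ", ".join(report.candidates))
planted = [bool(truth.loc[m, "is_stable"]) for m in report.candidates]
print("all selected are planted-stable:", all(planted))
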