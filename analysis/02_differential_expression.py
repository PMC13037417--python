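"""Differential expression on the synthetic cohort.

Runs the NB Wald test with the study thresholds (|log2FC| >= 1,
BH-FDR < 0.01), writes results/study/de.tsv and reports how well the
calls recover the planted truth.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import results_dir

from mirvalid import io
from mirvalid.diffexpr import test_de

out = results_dir()
counts = io.read_count_matrix(out / "counts.tsv", out / "groups.tsv")
truth = io.read_truth_table(out / "truth.tsv")

de = test_de(counts, "wald")
io.write_de_table(de, out / "de.tsv")

called = de[de["call"] != "ns"]
truth_de = set(truth.index[truth["is_de"]])
tp = len(set(called.index) & truth_de)
print(f"{len(called)} of {len(de)} miRNAs called DE "
      f"({(de['call'] == 'up').sum()} up, {(de['call'] == 'down').sum()} down) "
      "at |log2FC|>=1, FDR<0.01")
print(f"recovery: {tp}/{len(truth_de)} planted DE miRNAs found, "
      f"{len(set(called.index) - truth_de)} false calls")
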