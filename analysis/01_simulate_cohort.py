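"""Simulate the synthetic FFPE cohort that drives the downstream analyses.

Generates a study-shaped small-RNA count matrix (453 miRNAs, 18 tumor vs
6 control samples, libraries of 17-49 M reads) with a planted
differentially expressed subset and a planted stable (normalizer-like)
subset, and writes the counts, group map and truth table under
results/study/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import SIM, results_dir

from mirvalid import io
from mirvalid.simdata import simulate_counts

out = results_dir()
counts, truth = simulate_counts(SIM)
io.write_count_matrix(counts, out / "counts.tsv", out / "groups.tsv")
io.write_truth_table(truth, out / "truth.tsv")

n_de = int(truth["is_de"].sum())
n_stable = int(truth["is_stable"].sum())
print(f"simulated {counts.counts.shape[0]} miRNAs x {counts.counts.shape[1]} samples")
print(f"planted {n_de} DE miRNAs (|log2FC| in {SIM.lfc_range}) "
      f"and {n_stable} stable normalizer-like miRNAs")
print(f"library sizes {counts.counts.sum(axis=0).min():.2e}"
      f"-{counts.counts.sum(axis=0).max():.2e} reads")
print(f"tables written to {out}")
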