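"""GeNorm stability check of the selected normalizer trio.

Converts the simulated reference-assay CT values to linear quantities
(2^-CT), computes per-assay M values and the pairwise-variation curve,
and reports how many references suffice (V < 0.15).
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import results_dir

from mirvalid import io
from mirvalid.genorm import evaluate, quantities_from_ct

out = results_dir()
normalizers = json.loads((out / "normalizers.json").read_text())["candidates"]
ct = io.read_ct_table(out / "ct.tsv")

wide = (
    ct.records[ct.records["assay_id"].isin(normalizers)]
    .pivot(index="assay_id", columns="sample_id", values="ct")
)
result = evaluate(quantities_from_ct(wide))

payload = {
    "m_values": {k: float(v) for k, v in result.m_values.items()},
    "ranking": result.ranking,
    "v_curve": {str(k): float(v) for k, v in result.v_curve.items()},
    "recommended_n": result.recommended_n,
}
(out / "genorm.json").write_text(json.dumps(payload, indent=2) + "\n")

for gene, m in result.m_values.sort_values().items():
    print(f"M({gene}) = {m:.4f}")
for n, v in result.v_curve.items():
    print(f"V({n},{n + 1}) = {v:.4f}")
print(f"recommended number of references: {result.recommended_n}")
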