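"""Apply the two QC tiers: call-rate filters (QC1) and the extra MAF filter (QC2).

QC1 feeds run and island detection; QC2 feeds Tajima's D and FST. When a
breed exceeds 20 samples, a kinship-ranked greedy pruning selects 20.
"""

import runpy
from pathlib import Path

common = runpy.run_path(Path(__file__).parent / "00_common.py")

out = common["run_stage"]("qc")
for tier in ("qc1", "qc2"):
    n = sum(1 for _ in open(out / f"{tier}.map"))
    print(f"{tier}: {n} markers retained")
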