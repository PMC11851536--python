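"""Call HRR islands and ROH islands per breed from run-sharing frequencies.

Threshold: top 0.1% of per-SNP sharing frequencies genome-wide per breed,
islands require >= 2 consecutive member SNPs.
"""

import runpy
from pathlib import Path

import pandas as pd

common = runpy.run_path(Path(__file__).parent / "00_common.py")

out = common["run_stage"]("islands")
isl = pd.read_csv(out / "islands.tsv", sep="\t")
print(isl.groupby(["island_type", "breed"]).size().to_string())
print(f"{len(isl)} islands total; thresholds "
      f"{isl.threshold.min():.2f}-{isl.threshold.max():.2f}")
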