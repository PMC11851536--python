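"""Cross-breed accounting: hot spots, HRRI x signal overlaps, ANOVA, FST.

Hot spots are sweep-line regions whose breed-sharing count is a one-sided
Z-score outlier (z >= 1.645); overlaps are same-breed island/signal pairs;
ANOVA relates region sharing to breed factors; FST is Weir-Cockerham.
"""

import runpy
from pathlib import Path

import pandas as pd

common = runpy.run_path(Path(__file__).parent / "00_common.py")

out = common["run_stage"]("overlap", "fst", "anova")
hs = pd.read_csv(out / "hotspots.tsv", sep="\t")
ov = pd.read_csv(out / "overlaps.tsv", sep="\t")
fst = pd.read_csv(out / "fst.tsv", sep="\t", index_col=0)
print(f"{int(hs.significant.sum())} significant hot spots of {len(hs)} regions")
print(f"{len(ov)} HRRI x signal overlaps")
print("mean pairwise FST: "
      f"{fst.to_numpy()[[i for i in range(len(fst)) for j in range(len(fst)) if i < j], [j for i in range(len(fst)) for j in range(len(fst)) if i < j]].mean():.3f}")
anova = pd.read_csv(out / "anova.tsv", sep="\t")
print(anova.to_string(index=False))
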