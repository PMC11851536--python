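"""Call runs of homozygosity with the multi-class HBD hidden Markov model.

Rate classes R = 2..64 plus a non-HBD class at R = 128; mixing proportions
fitted per individual by EM; segments called at posterior >= 0.5.
"""

import runpy
from pathlib import Path

import pandas as pd

common = runpy.run_path(Path(__file__).parent / "00_common.py")

out = common["run_stage"]("hbd")
segs = pd.read_csv(out / "hbd_segments.tsv", sep="\t")
print(f"{len(segs)} HBD segments; mean length "
      f"{(segs.end_bp - segs.start_bp).mean() / 1e3:.0f} kb" if len(segs) else "no segments")
print(segs.groupby("breed").size().to_string())
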