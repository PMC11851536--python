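"""Windowed Tajima's D per breed and top-0.1% balancing-selection signals.

Non-overlapping 250 kb windows over QC2 genotypes; positive-D windows at
each breed's genome-wide 99.9th percentile become selection signals.
"""

import runpy
from pathlib import Path

import pandas as pd

common = runpy.run_path(Path(__file__).parent / "00_common.py")

out = common["run_stage"]("tajima")
win = pd.read_csv(out / "windows.tsv", sep="\t")
sig = pd.read_csv(out / "signals.tsv", sep="\t")
print(f"{len(win)} breed-windows, mean D = {win.D.mean():.3f}")
print(f"{len(sig)} signals, mean signal D = {sig.D.mean():.3f}")
print(sig.to_string(index=False))
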