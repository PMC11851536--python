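"""Detect heterozygosity-rich regions per individual and summarize them.

Consecutive-runs scan with the study settings (>= 20 SNPs, >= 50 kb span,
<= 50 kb gaps, <= 3 homozygous and <= 1 missing SNP inside). Reports run
counts, genome coverage, observed heterozygosity and their correlations.
"""

import runpy
from pathlib import Path

import pandas as pd

common = runpy.run_path(Path(__file__).parent / "00_common.py")
from hrrscan.runs import pearson_correlation  # noqa: E402

out = common["run_stage"]("runs")
runs = pd.read_csv(out / "runs.tsv", sep="\t")
summ = pd.read_csv(out / "summaries.tsv", sep="\t")
print(f"{len(runs)} HRRs, mean length {(runs.end_bp - runs.start_bp).mean() / 1e3:.0f} kb")
print(f"Ho range {summ.Ho.min():.3f}-{summ.Ho.max():.3f}, mean {summ.Ho.mean():.3f}")
for var in ("n_runs", "coverage_fraction"):
    r = pearson_correlation(summ["Ho"], summ[var], names=("Ho", var))
    print(f"corr(Ho, {var}): r^2 = {r.r_squared:.3f} (p = {r.p_value:.2g})")
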