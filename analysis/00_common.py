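"""Shared plumbing for the numbered analysis drivers.

Each driver runs one pipeline stage over the bundled demo configuration
(5 simulated breeds x 20 individuals, ~4,000 SNPs, planted heterozygous
tracts, autozygous tracts and balancing windows) and reports what it found.
Outputs accumulate under results/demo/.
"""

import logging
import sys
from pathlib import Path

REPO = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(REPO / "src"))

from hrrscan.pipeline import PipelineConfig, run_pipeline  # noqa: E402

CONFIG = REPO / "configs" / "demo.yaml"
OUTDIR = REPO / "results" / "demo"


def run_stage(*stages: str):
    logging.basicConfig(level=logging.INFO, stream=sys.stderr,
                        format="%(levelname)s %(message)s")
    cfg = PipelineConfig.from_yaml(CONFIG, output_dir=str(OUTDIR))
    return run_pipeline(cfg, stages=list(stages))
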