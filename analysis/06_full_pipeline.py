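"""Run the whole synthetic study in one pass and print its run report.

Equivalent to `coregscan pipeline --seed 1 --outdir results/pipeline`; all
stage outputs and the machine-readable run report land under
results/pipeline/.
"""

import json
from pathlib import Path

from coregscan.pipeline import run_synthetic_pipeline

SEED = 1
OUTDIR = Path(__file__).resolve().parents[1] / "results" / "pipeline"


def main() -> None:
    report = run_synthetic_pipeline(seed=SEED, outdir=OUTDIR, B=5000)
    print(json.dumps(report, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
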