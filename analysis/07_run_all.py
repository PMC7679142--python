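"""Run the packaged end-to-end pipeline twice on the demo config and verify
the manifests agree (full determinism from the master seed).

Outputs under scratch/pipeline_run; the manifest summary is printed.
"""

import json
from pathlib import Path

from common import SCRATCH
from pavnet.report import run_pipeline

DEMO = Path(__file__).resolve().parent.parent / "configs" / "demo.cfg"


def main():
    m1 = run_pipeline(DEMO, out_dir=SCRATCH / "pipeline_run")
    m2 = run_pipeline(DEMO, out_dir=SCRATCH / "pipeline_run_check")
    print(f"artifacts: {len(m1.artifacts)}")
    print(f"manifests identical: {m1.artifacts == m2.artifacts}")
    print(json.dumps(m1.artifacts, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
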