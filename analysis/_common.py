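"""Shared plumbing for the numbered analysis drivers.

Every driver reads/writes the same run directory (``results/run`` by
default, override with ``--run-dir``) and uses the bundled demo
configuration unless ``--config`` points elsewhere.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from emtcre.data import DEMO_CONFIG
from emtcre.pipeline import PipelineConfig

REPO_ROOT = Path(__file__).resolve().parents[1]


def parse_args(description: str) -> tuple[PipelineConfig, Path]:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--config", type=Path, default=DEMO_CONFIG)
    parser.add_argument("--run-dir", type=Path,
                        default=REPO_ROOT / "results" / "run")
    args = parser.parse_args()
    cfg = PipelineConfig.from_yaml(args.config)
    args.run_dir.mkdir(parents=True, exist_ok=True)
    return cfg, args.run_dir
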