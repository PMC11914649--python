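"""Shared plumbing for the analysis drivers."""

import argparse
import logging
from pathlib import Path

from osmohet.syndata import SENTINELS

INDUCED = list(SENTINELS) + [f"IND{i:04d}" for i in range(len(SENTINELS), 200)]
REPRESSED = ["EFT2"] + [f"REP{i:04d}" for i in range(1, 200)]


def driver_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--log-level", default="INFO")
    args = parser.parse_args()
    logging.basicConfig(level=args.log_level,
                        format="%(levelname)s %(name)s: %(message)s")
    (args.out / "tables").mkdir(parents=True, exist_ok=True)
    return args
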