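"""Shared argument handling for the numbered analysis drivers."""

import argparse
import dataclasses
import logging
from pathlib import Path

from alphanet.pipeline import RunConfig

DEFAULT_CONFIG = Path(__file__).parent / "config.yaml"


def load_config(description: str) -> RunConfig:
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--config", type=Path, default=DEFAULT_CONFIG)
    ap.add_argument("--seed", type=int, default=None)
    ap.add_argument("--out", type=Path, default=None)
    args = ap.parse_args()
    cfg = RunConfig.from_yaml(args.config)
    if args.seed is not None:
        cfg = dataclasses.replace(cfg, seed=args.seed)
    if args.out is not None:
        cfg = dataclasses.replace(cfg, out_dir=str(args.out))
    return cfg
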