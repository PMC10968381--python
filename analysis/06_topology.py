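#!/usr/bin/env python
"""Graph topology of the alpha-band networks across the ten-sparsity grid:
clustering coefficient, local efficiency, betweenness hubs, and normalized
rich-club lateralization, with per-sparsity group tests.

Writes the metric/comparison/hub/laterality tables under <out_dir>/topology.
"""

import json

import numpy as np
import pandas as pd

from _common import load_config
from alphanet import pipeline

cfg = load_config(__doc__)
out = pipeline.stage_topology(cfg)

comp = pd.read_csv(out / "group_comparison.tsv", sep="\t")
at = comp[np.isclose(comp["sparsity"], 0.2)]
for r in at.itertuples():
    print(f"sparsity 0.20, {r.metric}: t={r.t:.2f}, p={r.p:.4g} "
          f"(athlete - control)")
summary = json.loads((out / "topology_summary.json").read_text())
for group, hubs in summary.get("hubs", {}).items():
    print(f"hubs ({group}): {', '.join(hubs) or 'none'}")
lat = summary.get("richclub_laterality_mean", {})
for group, diff in lat.items():
    print(f"rich-club left-minus-right ({group}): {diff:+.4f}")
test = summary.get("richclub_laterality_test")
if test:
    print(f"laterality group test: t={test['t']:.2f}, p={test['p']:.4g}")
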