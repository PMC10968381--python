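#!/usr/bin/env python
"""Group inference on the wPLI matrices: per-edge permutation tests and NBS
family-wise correction per band.

Writes edge tables and nbs_summary.json under <out_dir>/nbs and lists the
suprathreshold components with their corrected p-values.
"""

import json

from _common import load_config
from alphanet import pipeline

cfg = load_config(__doc__)
out = pipeline.stage_nbs(cfg)

summary = json.loads((out / "nbs_summary.json").read_text())
for band, info in summary.items():
    print(f"{band}: primary |t| threshold {info['primary_threshold']:.2f}, "
          f"{info['n_permutations']} permutations, "
          f"{info['n_significant']} significant component(s)")
    for c in info["components"][:3]:
        edges = ", ".join("-".join(e) for e in c["edges"][:5])
        more = "..." if len(c["edges"]) > 5 else ""
        print(f"  {c['direction']} component, {c['size']} edges, "
              f"p={c['p_corrected']:.4g}: {edges}{more}")
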