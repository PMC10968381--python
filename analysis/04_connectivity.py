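#!/usr/bin/env python
"""Weighted phase-lag index connectivity: one symmetric 60 x 60 matrix per
subject per band (alpha, alpha1, alpha2) from the epoch-wise cross-spectra.

Writes labeled tab-delimited matrices under <out_dir>/connectivity/<band>/.
"""

import json

import numpy as np

from _common import load_config
from alphanet import pipeline
from alphanet.io import read_matrix

cfg = load_config(__doc__)
out = pipeline.stage_connectivity(cfg)

groups = json.loads((out / "groups.json").read_text())
means = {}
for sid, group in groups.items():
    m, _ = read_matrix(out / "alpha" / f"{sid}.tsv")
    iu = np.triu_indices(m.shape[0], 1)
    means.setdefault(group, []).append(m[iu].mean())
for group in sorted(means):
    print(f"mean alpha wPLI, {group}: {np.mean(means[group]):.4f} "
          f"(n={len(means[group])})")
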