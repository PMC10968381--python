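#!/usr/bin/env python
"""Epoch-averaged Hanning/FFT power spectra, alpha band powers, and the
between-group t-tests (per frequency bin on the grand-average PSD, per
electrode on band power).

Writes the PSD and comparison tables under <out_dir>/psd and reports where
the groups separate.
"""

import pandas as pd

from _common import load_config
from alphanet import pipeline

cfg = load_config(__doc__)
out = pipeline.stage_psd(cfg)

comp = pd.read_csv(out / "psd_group_comparison.tsv", sep="\t")
alpha = comp[(comp.frequency_hz >= 8) & (comp.frequency_hz < 13)]
sig = alpha[alpha.p < 0.05]
print(f"grand-average PSD: {len(sig)}/{len(alpha)} alpha bins differ at p<0.05 "
      f"(orientation athlete - control; mean alpha t = {alpha.t.mean():.2f})")
for band in cfg.band_names:
    ecomp = pd.read_csv(out / f"band_power_{band}_comparison.tsv", sep="\t")
    top = ecomp.nsmallest(3, "p")
    rows = ", ".join(f"{r.electrode} (t={r.t:.2f}, p={r.p:.3g})"
                     for r in top.itertuples())
    print(f"{band}: strongest electrodes {rows}")
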