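#!/usr/bin/env python
"""Preprocess every recording: drop EOG/mastoid channels, average-reference,
band-pass 0.1-50 Hz, notch 48/52 Hz, cut 2-s epochs, reject epochs whose
absolute amplitude exceeds 75 uV.

Writes per-subject epoch stores and epochs_summary.tsv under <out_dir>/epochs.
"""

import pandas as pd

from _common import load_config
from alphanet import pipeline

cfg = load_config(__doc__)
out = pipeline.stage_preprocess(cfg)
summary = pd.read_csv(out / "epochs_summary.tsv", sep="\t")
print(f"preprocessed {len(summary)} subjects; "
      f"epochs kept {summary['n_epochs'].sum()}, "
      f"rejected {summary['rejected'].sum()}")
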