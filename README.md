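# alphanet

Resting-state EEG alpha-band network analysis: power spectra, weighted
phase-lag index (wPLI) functional connectivity, permutation/NBS group
inference, and graph topology — validated end to end on synthetic two-group
recordings with known ground truth.

## The problem

Eyes-closed resting EEG is dominated by the alpha rhythm (8–13 Hz, split
into a slow α1 band 8–10.5 Hz and a fast α2 band 10.5–13 Hz).  Comparing
two groups of participants — e.g. trained athletes against controls — at
the level of whole-brain functional networks requires a chain of steps,
each easy to get subtly wrong:

1. **Preprocessing**: average re-referencing, removal of non-scalp channels
   (EOG, mastoids), zero-phase FIR band-pass 0.1–50 Hz with 48/52 Hz
   notches, segmentation into 2-s epochs, and rejection of epochs whose
   absolute amplitude exceeds 75 μV.
2. **Spectra**: Hanning-windowed, epoch-averaged FFT power spectral
   densities; per-electrode band powers; two-sample t-tests per frequency
   bin and per electrode.
3. **Connectivity**: the weighted phase-lag index per channel pair

   wPLI = |⟨|Im S| · sign(Im S)⟩| / ⟨|Im S|⟩,

   where S is the cross-spectrum of two channels and ⟨·⟩ averages over
   observations.  Because volume conduction is instantaneous it contributes
   no imaginary cross-spectrum, so wPLI is robust to the spurious zero-lag
   coupling that contaminates coherence-type measures.  One symmetric
   60 × 60 matrix per subject per band.
4. **Group inference**: per-edge two-sample t statistics, a permutation
   null from subject-label exchanges (1000 permutations by default), and
   network-based statistics (NBS): family-wise error control via the
   permutation distribution of the largest connected suprathreshold
   component.
5. **Topology**: proportional thresholding at ten sparsities (0.05–0.50),
   Onnela weighted clustering coefficient, weighted local efficiency,
   betweenness-centrality hubs (mean + 1 SD criterion), and binary
   rich-club curves normalized by degree-preserving rewired null graphs,
   including a left/right-hemisphere comparison.

No public recordings accompany the protocol, so the package ships a
first-class synthetic-data module: narrowband alpha oscillators with
random-walk phase, pairwise and module-level nonzero-lag phase coupling
through shared sources, 1/f background noise, zero-lag volume-conduction
mixing, and EOG/mastoid-like channels, over a 64-channel 10-10 montage.
Every stage is tested against this ground truth — closed forms, brute-force
oracles, error-control simulations, and planted-effect recovery.

## Worked example

The numbered scripts under `analysis/` run a scaled study (12 + 12
subjects, 90 s at 250 Hz) in which the athlete-like group has a 50%
alpha-amplitude boost and a phase-locked posterior module:

```bash
python analysis/01_simulate_study.py
python analysis/02_preprocess.py
python analysis/03_spectral_analysis.py
python analysis/04_connectivity.py
python analysis/05_network_stats.py
python analysis/06_topology.py
```

Output of the chain (seed 1):

```
simulated 24 subjects (12 athlete-like, 12 control) into results/study/sim
preprocessed 24 subjects; epochs kept 1080, rejected 0
grand-average PSD: 10/10 alpha bins differ at p<0.05 (orientation athlete - control; mean alpha t = 48.44)
alpha: strongest electrodes Oz (t=40.45, p=3.8e-22), PO3 (t=39.70, p=5.69e-22), PO4 (t=38.55, p=1.08e-21)
mean alpha wPLI, athlete: 0.3719 (n=12)
mean alpha wPLI, control: 0.1210 (n=12)
alpha: primary |t| threshold 3.79, 500 permutations, 1 significant component(s)
  A>B component, 1002 edges, p=0.001996: Fp1-C2, Fp1-C4, Fp1-C6, Fp1-T8, Fp1-TP7...
sparsity 0.20, clustering: t=10.14, p=9.414e-10 (athlete - control)
sparsity 0.20, local_efficiency: t=8.02, p=5.665e-08 (athlete - control)
hubs (athlete): C4, O1, O2, Oz, P3, PO3, PO4, POz
```

Reading this: the planted amplitude effect appears as higher alpha power at
every alpha bin, strongest over parieto-occipital electrodes; the planted
phase coupling triples the mean alpha wPLI and is recovered by NBS as a
single significant athlete > control component at the smallest attainable
corrected p (1/501 ≈ 0.002); and the synchronized posterior module makes
the athlete networks significantly more clustered and locally efficient at
sparsity 0.2, with hubs concentrating over the planted posterior region.

The same pipeline is scriptable through the `alphanet` CLI
(`alphanet full --config run.yaml`, or per-stage subcommands
`simulate | preprocess | psd | connectivity | nbs | topology`), and each
stage reruns standalone from the previous stage's on-disk outputs.

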