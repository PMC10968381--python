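"""Config-driven orchestration of the full analysis.

Stages communicate through files under the run's output directory, so each
stage can be re-run standalone from the previous stage's outputs and a full
run is exactly the chain of standalone stages.  Defaults reproduce the
study's processing choices: 0.1–50 Hz band-pass, 48/52 Hz notches, 2-s
epochs, 75 uV rejection, alpha/alpha1/alpha2 bands, 1000 permutations and
the 0.05–0.50 sparsity grid at a 0.05 significance level.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity, network_stats, preprocess, spectral, synth, topology
from .io import (Montage, Recording, read_matrix, read_montage, read_recording,
                 select_scalp_channels, write_matrix)
from .spectral import ALPHA, ALPHA1, ALPHA2, BandDefinition

log = logging.getLogger("alphanet")

BANDS = {"alpha": ALPHA, "alpha1": ALPHA1, "alpha2": ALPHA2}


@dataclass
class RunConfig:
    out_dir: str = "alphanet_run"
    seed: int = 0
    input_dir: str | None = None  # existing study; None = simulate
    synthetic: dict = field(default_factory=dict)  # GroupDesign overrides
    sim_format: str = "delimited"  # or "edf"
    drop_labels: tuple = ("HEOG", "VEOG", "M1", "M2")
    restore_reference: str | None = None  # e.g. "FCz": add as flat channel first
    highpass: float = 0.1
    lowpass: float = 50.0
    notch_freqs: tuple = (48.0, 52.0)
    epoch_length: float = 2.0
    reject_threshold: float = 75.0
    band_names: tuple = ("alpha", "alpha1", "alpha2")
    topology_band: str = "alpha"
    wpli_granularity: str = "pooled"  # or "epochs" / "per_epoch"
    n_perm: int = 1000
    nbs_threshold: float | None = None  # raw |t|; overrides nbs_primary_p
    nbs_primary_p: float = 0.001
    alpha_level: float = 0.05
    sparsities: tuple = topology.DEFAULT_SPARSITIES
    hub_sd_multiplier: float = 1.0
    hub_sparsity: float = 0.2
    richclub_nulls: int = 50
    laterality_sparsity: float = 0.2

    def __post_init__(self):
        if not 0 < self.highpass < self.lowpass:
            raise ValueError("need 0 < highpass < lowpass")
        if self.epoch_length <= 0 or self.reject_threshold <= 0:
            raise ValueError("epoch_length and reject_threshold must be positive")
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must lie in (0, 1)")
        for b in self.band_names:
            if b not in BANDS:
                raise ValueError(f"unknown band {b!r} (choose from {list(BANDS)})")
        if self.topology_band not in self.band_names:
            raise ValueError("topology_band must be among band_names")
        if self.wpli_granularity not in ("pooled", "epochs", "per_epoch"):
            raise ValueError("wpli_granularity must be pooled, epochs or per_epoch")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def bands(self) -> dict[str, BandDefinition]:
        return {name: BANDS[name] for name in self.band_names}

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def _design_from_config(cfg: RunConfig) -> synth.GroupDesign:
    """Build a GroupDesign from the config's ``synthetic`` section."""
    opts = dict(cfg.synthetic)
    osc = synth.OscillatorSpec(**opts.pop("oscillator", {}))
    group_osc = {}
    for group, factor in opts.pop("group_amplitude_scale", {}).items():
        group_osc[group] = dataclasses.replace(osc, amplitude=osc.amplitude * factor)
    for group, spec in opts.pop("group_oscillator", {}).items():
        group_osc[group] = synth.OscillatorSpec(**spec)
    group_couplings = {
        group: [synth.CouplingSpec(channel_pair=tuple(c["pair"]),
                                   phase_lag=c.get("phase_lag", np.pi / 4),
                                   coupling_strength=c.get("coupling_strength", 1.0))
                for c in specs]
        for group, specs in opts.pop("group_couplings", {}).items()
    }
    group_modules = {
        group: [synth.ModuleSpec(channels=tuple(m["channels"]),
                                 coupling_strength=m.get("coupling_strength", 0.6),
                                 lag_spacing=m.get("lag_spacing", 0.25))
                for m in specs]
        for group, specs in opts.pop("group_modules", {}).items()
    }
    montage = synth.make_montage_fixture()
    mixing = None
    spread = opts.pop("mixing_spread", None)
    if spread:
        mixing = synth.MixingModel.from_montage(montage, spread=spread)
    if "group_labels" in opts:
        opts["group_labels"] = tuple(opts["group_labels"])
    return synth.GroupDesign(montage=montage, oscillator=osc,
                             group_oscillator=group_osc,
                             group_couplings=group_couplings,
                             group_modules=group_modules,
                             mixing=mixing, seed=opts.pop("seed", cfg.seed),
                             **opts)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir) / "sim"
    design = _design_from_config(cfg)
    log.info("simulating %d+%d subjects (%g s at %g Hz)", design.n_per_group,
             design.n_per_group, design.duration, design.fs)
    study = synth.generate_group_study(design)
    synth.write_study(study, out, format=cfg.sim_format)
    return out


def _load_manifest(input_dir) -> tuple[list[dict], Montage]:
    input_dir = Path(input_dir)
    manifest = json.loads((input_dir / "manifest.json").read_text())
    montage = read_montage(input_dir / manifest["montage"])
    return manifest["subjects"], montage


def stage_preprocess(cfg: RunConfig, input_dir=None) -> Path:
    """Channel selection, average reference, filtering, epoching, rejection."""
    input_dir = Path(input_dir or cfg.input_dir or Path(cfg.out_dir) / "sim")
    subjects, montage = _load_manifest(input_dir)
    out = Path(cfg.out_dir) / "epochs"
    out.mkdir(parents=True, exist_ok=True)
    summary = []
    for sub in subjects:
        rec = read_recording(input_dir / sub["file"], montage=montage)
        if cfg.restore_reference and cfg.restore_reference not in rec.channel_labels:
            zero = np.zeros((1, rec.n_samples))
            rec = Recording(data=np.vstack([rec.data, zero]), fs=rec.fs,
                            channel_labels=rec.channel_labels + [cfg.restore_reference],
                            montage=rec.montage)
        rec = select_scalp_channels(rec, list(cfg.drop_labels), ignore_missing=True)
        rec = preprocess.rereference_average(rec)
        rec = preprocess.bandpass_fir(rec, cfg.highpass, cfg.lowpass)
        if cfg.notch_freqs:
            rec = preprocess.notch(rec, list(cfg.notch_freqs))
        ep = preprocess.segment_epochs(rec, cfg.epoch_length)
        ep = preprocess.reject_amplitude(ep, cfg.reject_threshold)
        np.savez(out / f"{sub['subject_id']}.npz", blocks=ep.blocks, fs=ep.fs,
                 channel_labels=np.array(ep.channel_labels),
                 rejected_count=ep.rejected_count, group=sub["group"])
        summary.append({"subject_id": sub["subject_id"], "group": sub["group"],
                        "n_epochs": ep.n_epochs, "rejected": ep.rejected_count})
        log.info("preprocessed %s: %d epochs kept, %d rejected",
                 sub["subject_id"], ep.n_epochs, ep.rejected_count)
    pd.DataFrame(summary).to_csv(out / "epochs_summary.tsv", sep="\t", index=False)
    return out


def _load_epochs(path) -> tuple[preprocess.Epochs, str]:
    z = np.load(path, allow_pickle=False)
    ep = preprocess.Epochs(blocks=z["blocks"], fs=float(z["fs"]),
                           channel_labels=[str(l) for l in z["channel_labels"]],
                           rejected_count=int(z["rejected_count"]))
    return ep, str(z["group"])


def _epoch_files(cfg: RunConfig):
    out = Path(cfg.out_dir) / "epochs"
    files = sorted(out.glob("*.npz"))
    if not files:
        raise FileNotFoundError(
            f"no epoch files under {out}; run the preprocess stage first")
    return files


def stage_psd(cfg: RunConfig) -> Path:
    """Per-subject PSD and band powers plus group comparisons."""
    out = Path(cfg.out_dir) / "psd"
    out.mkdir(parents=True, exist_ok=True)
    ga, bp, groups, sids = [], [], [], []
    freqs = labels = None
    for f in _epoch_files(cfg):
        ep, group = _load_epochs(f)
        res = spectral.psd_epochs(ep)
        freqs, labels = res.freqs, res.channel_labels
        ga.append(spectral.grand_average_psd(res))
        bp.append({name: spectral.band_power(res, band)
                   for name, band in cfg.bands().items()})
        groups.append(group)
        sids.append(f.stem)
    ga = np.array(ga)
    pd.DataFrame(ga.T, index=pd.Index(freqs, name="frequency_hz"),
                 columns=sids).to_csv(out / "grand_average_psd.tsv", sep="\t")
    g_names = sorted(set(groups))
    masks = {g: np.array([x == g for x in groups]) for g in g_names}
    tables = {}
    if len(g_names) == 2:
        a, b = g_names
        t, p = spectral.compare_psd_groups(ga[masks[a]], ga[masks[b]])
        pd.DataFrame({"frequency_hz": freqs, "t": t, "p": p}).to_csv(
            out / "psd_group_comparison.tsv", sep="\t", index=False)
        tables["psd_bins"] = {"group_order": f"{a} - {b}"}
        for name in cfg.band_names:
            mat = np.array([row[name] for row in bp])
            df = pd.DataFrame(mat, index=sids, columns=labels)
            df.insert(0, "group", groups)
            df.to_csv(out / f"band_power_{name}.tsv", sep="\t")
            t, p = spectral.compare_psd_groups(mat[masks[a]], mat[masks[b]])
            pd.DataFrame({"electrode": labels, "t": t, "p": p}).to_csv(
                out / f"band_power_{name}_comparison.tsv", sep="\t", index=False)
    (out / "psd_summary.json").write_text(json.dumps(tables, indent=2))
    return out


def stage_connectivity(cfg: RunConfig) -> Path:
    """One labeled wPLI matrix per subject per band."""
    out = Path(cfg.out_dir) / "connectivity"
    groups = {}
    for f in _epoch_files(cfg):
        ep, group = _load_epochs(f)
        groups[f.stem] = group
        for name, band in cfg.bands().items():
            cm = connectivity.subject_wpli(ep, band,
                                           granularity=cfg.wpli_granularity)
            band_dir = out / name
            band_dir.mkdir(parents=True, exist_ok=True)
            write_matrix(cm.values, band_dir / f"{f.stem}.tsv", cm.channel_labels)
        log.info("connectivity matrices written for %s", f.stem)
    (out / "groups.json").write_text(json.dumps(groups, indent=2))
    return out


def _load_band_matrices(cfg: RunConfig, band_name: str):
    base = Path(cfg.out_dir) / "connectivity"
    if not (base / "groups.json").exists():
        raise FileNotFoundError(
            f"no connectivity outputs under {base}; run the connectivity stage first")
    groups = json.loads((base / "groups.json").read_text())
    by_group: dict[str, list[np.ndarray]] = {}
    labels = None
    for sid in sorted(groups):
        m, labels = read_matrix(base / band_name / f"{sid}.tsv")
        by_group.setdefault(groups[sid], []).append(m)
    return {g: np.stack(v) for g, v in by_group.items()}, labels


def stage_nbs(cfg: RunConfig) -> Path:
    """Per-edge permutation tests and NBS per band."""
    out = Path(cfg.out_dir) / "nbs"
    out.mkdir(parents=True, exist_ok=True)
    summary = {}
    for bi, name in enumerate(cfg.band_names):
        by_group, labels = _load_band_matrices(cfg, name)
        g_names = sorted(by_group)
        if len(g_names) != 2:
            raise ValueError("NBS needs exactly two groups")
        a, b = g_names
        thr = cfg.nbs_threshold
        if thr is None:
            thr = network_stats.default_primary_threshold(
                len(by_group[a]), len(by_group[b]), cfg.nbs_primary_p)
        edge, result = network_stats.nbs_compare(
            by_group[a], by_group[b], n_perm=cfg.n_perm,
            seed=cfg.seed + 1000 + bi, primary_threshold=thr)
        comp_of_edge = {}
        for ci, comp in enumerate(result.components):
            for e in comp.edges:
                comp_of_edge[e] = (ci, comp.p_corrected)
        pairs = [(labels[i], labels[j]) for i, j in zip(*edge.iu)]
        df = pd.DataFrame({
            "node_a": [x for x, _ in pairs],
            "node_b": [y for _, y in pairs],
            "t": edge.t,
            "p_uncorrected": edge.p,
            "component_id": [comp_of_edge.get(e, (None, None))[0]
                             for e in range(len(pairs))],
            "p_component": [comp_of_edge.get(e, (None, None))[1]
                            for e in range(len(pairs))],
        })
        df.to_csv(out / f"edges_{name}.tsv", sep="\t", index=False)
        summary[name] = {
            "group_order": f"{a} - {b}",
            "primary_threshold": result.primary_threshold,
            "n_permutations": result.n_permutations,
            "components": [
                {"direction": c.direction, "size": c.size,
                 "p_corrected": c.p_corrected,
                 "edges": [list(pairs[e]) for e in c.edges]}
                for c in result.components
            ],
            "n_significant": len(result.significant(cfg.alpha_level)),
        }
        log.info("NBS %s: %d components, %d significant at alpha=%g", name,
                 len(result.components), summary[name]["n_significant"],
                 cfg.alpha_level)
    (out / "nbs_summary.json").write_text(json.dumps(summary, indent=2))
    return out


def stage_topology(cfg: RunConfig, montage: Montage | None = None) -> Path:
    """Per-subject topology metrics, group tests, hubs and rich-club laterality."""
    out = Path(cfg.out_dir) / "topology"
    out.mkdir(parents=True, exist_ok=True)
    if montage is None:
        for cand in (Path(cfg.input_dir or "") / "montage.tsv",
                     Path(cfg.out_dir) / "sim" / "montage.tsv"):
            if cand.exists():
                montage = read_montage(cand)
                break
    by_group, labels = _load_band_matrices(cfg, cfg.topology_band)
    band = BANDS[cfg.topology_band]
    g_names = sorted(by_group)
    per_subject_rows = []
    metric_arrays: dict[str, dict[str, list]] = {g: {"clustering": [], "local_efficiency": []}
                                                 for g in g_names}
    bc_group: dict[str, list[dict]] = {g: [] for g in g_names}
    laterality_rows = []
    for g in g_names:
        for si, m in enumerate(by_group[g]):
            cm = connectivity.ConnectivityMatrix(values=m, band=band,
                                                 n_epochs=0, channel_labels=labels)
            df = topology.subject_topology(cm, cfg.sparsities,
                                           hub_sd_multiplier=cfg.hub_sd_multiplier)
            metric_arrays[g]["clustering"].append(df["clustering"].to_numpy())
            metric_arrays[g]["local_efficiency"].append(df["local_efficiency"].to_numpy())
            hub_row = df[np.isclose(df["sparsity"], cfg.hub_sparsity)]
            if len(hub_row):
                bc_group[g].append(hub_row.iloc[0]["betweenness"])
            for _, r in df.iterrows():
                per_subject_rows.append({"group": g, "subject": si,
                                         "sparsity": r["sparsity"],
                                         "clustering": r["clustering"],
                                         "local_efficiency": r["local_efficiency"],
                                         "hubs": r["hubs"]})
            if montage is not None:
                lat = topology.rich_club_laterality(
                    cm, montage, sparsity=cfg.laterality_sparsity,
                    n_nulls=cfg.richclub_nulls,
                    seed=cfg.seed + 2000 + 100 * g_names.index(g) + si)
                laterality_rows.append({"group": g, "subject": si, **lat})
    pd.DataFrame(per_subject_rows).to_csv(out / "per_subject_metrics.tsv",
                                          sep="\t", index=False)
    summary: dict = {"band": cfg.topology_band}
    if len(g_names) == 2:
        a, b = g_names
        comp = topology.compare_topology_groups(
            {k: np.array(v) for k, v in metric_arrays[a].items()},
            {k: np.array(v) for k, v in metric_arrays[b].items()},
            cfg.sparsities)
        comp.to_csv(out / "group_comparison.tsv", sep="\t", index=False)
        summary["group_order"] = f"{a} - {b}"
    hubs = {}
    for g in g_names:
        if bc_group[g]:
            mean_bc = {lab: float(np.mean([d[lab] for d in bc_group[g]]))
                       for lab in labels}
            hs = topology.identify_hubs(mean_bc, cfg.hub_sd_multiplier)
            hubs[g] = hs.hubs
            pd.DataFrame({"node": list(mean_bc), "betweenness": list(mean_bc.values()),
                          "is_hub": [l in hs.hubs for l in mean_bc]}).to_csv(
                out / f"hubs_{g}.tsv", sep="\t", index=False)
    summary["hubs"] = hubs
    if laterality_rows:
        lat_df = pd.DataFrame(laterality_rows)
        lat_df.to_csv(out / "richclub_laterality.tsv", sep="\t", index=False)
        summary["richclub_laterality_mean"] = {
            g: float(lat_df[lat_df["group"] == g]["left_minus_right"].mean())
            for g in g_names}
        if len(g_names) == 2:
            a_vals = lat_df[lat_df["group"] == g_names[0]]["left_minus_right"].to_numpy()
            b_vals = lat_df[lat_df["group"] == g_names[1]]["left_minus_right"].to_numpy()
            if len(a_vals) >= 2 and len(b_vals) >= 2:
                t, p = spectral.two_sample_t(a_vals[:, None], b_vals[:, None])
                summary["richclub_laterality_test"] = {"t": float(t), "p": float(p)}
    (out / "topology_summary.json").write_text(json.dumps(summary, indent=2))
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order and assemble the run report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        import alphanet

        log.info("alphanet %s, numpy %s, seed %d", alphanet.__version__,
                 np.__version__, cfg.seed)
        if cfg.input_dir is None:
            stage_simulate(cfg)
        stage_preprocess(cfg)
        stage_psd(cfg)
        stage_connectivity(cfg)
        stage_nbs(cfg)
        stage_topology(cfg)
        report = {
            "config": cfg.echo(),
            "nbs": json.loads((out / "nbs" / "nbs_summary.json").read_text()),
            "topology": json.loads(
                (out / "topology" / "topology_summary.json").read_text()),
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
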