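"""End-to-end orchestration: simulate -> fit maps -> DCE analysis ->
histology indexing -> register/sample -> statistics -> report, driven by a
single config with per-stage seeds, writing plain-file artifacts and a
provenance manifest so any stage can be rerun standalone."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import dce, histo, io, mrfit, register, stats, synth
from .datatypes import DCE_PARAM_NAMES, HISTO_INDEX_NAMES, MR_PARAM_NAMES

log = logging.getLogger("mpmr")

N_MR_PARAMETERS = len(MR_PARAM_NAMES)  # 19: D, f, D*, ADC, T1, T2* + 13 dynamic


@dataclass
class RunConfig:
    """Pipeline configuration; every threshold default is the protocol value
    used throughout the analysis."""

    out_dir: str = "run"
    n_tumours: int = 4
    map_shape: tuple[int, int] = (32, 32)
    mr_pixel_um: float = 320.0
    b_values: list[float] = field(default_factory=lambda: list(synth.DEFAULT_B_VALUES))
    te_values: list[float] = field(default_factory=lambda: list(synth.DEFAULT_TE_VALUES))
    tr_values: list[float] = field(default_factory=lambda: list(synth.DEFAULT_TR_VALUES))
    n_dynamics: int = synth.DEFAULT_N_DYNAMICS
    dt_s: float = synth.DEFAULT_DT
    injection_index: int = synth.DEFAULT_INJECTION_INDEX
    snr: float = synth.DEFAULT_SNR
    slide_px: tuple[int, int] = (1500, 1500)
    um_per_px: float = 2.0
    tile_size_um: float = 250.0
    r2_cutoff: float = mrfit.R2_EXCLUSION
    enhancement_multiplier: float = dce.ENHANCEMENT_MULTIPLIER
    inclusion_multiplier: float = dce.INCLUSION_MULTIPLIER
    significance_threshold: float = stats.SIGNIFICANCE_THRESHOLD
    smoothing_parameter: float = dce.DEFAULT_SMOOTHING
    cv_folds: int = stats.CV_FOLDS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**payload)
        cfg.map_shape = tuple(cfg.map_shape)
        cfg.slide_px = tuple(cfg.slide_px)
        return cfg

    def to_yaml(self, path: Path) -> None:
        d = asdict(self)
        d["map_shape"] = [int(v) for v in self.map_shape]
        d["slide_px"] = [int(v) for v in self.slide_px]
        for k in ("b_values", "te_values", "tr_values"):
            d[k] = [float(v) for v in d[k]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def stage_seed(self, stage: str, tumour: int = 0) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}:{tumour}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def simulate_stage(cfg: RunConfig, out: Path) -> None:
    """Generate ground truth and all four acquisition series per tumour."""
    for t in range(1, cfg.n_tumours + 1):
        tdir = out / f"tumour{t}" / "acq"
        tdir.mkdir(parents=True, exist_ok=True)
        gt_seed = cfg.stage_seed("gt", t)
        gt = synth.generate_ground_truth(cfg.map_shape, cfg.mr_pixel_um, seed=gt_seed)
        io.write_series(synth.simulate_dwi(gt, cfg.b_values, cfg.snr,
                                           cfg.stage_seed("dwi", t)), tdir / "dwi.nii")
        io.write_series(synth.simulate_relaxometry(gt, "T2star", cfg.te_values,
                                                   cfg.snr, cfg.stage_seed("t2s", t)),
                        tdir / "t2star.nii")
        io.write_series(synth.simulate_relaxometry(gt, "T1", cfg.tr_values,
                                                   cfg.snr, cfg.stage_seed("t1", t)),
                        tdir / "t1.nii")
        io.write_series(synth.simulate_dce(gt, cfg.n_dynamics, cfg.dt_s,
                                           cfg.injection_index, cfg.snr,
                                           cfg.stage_seed("dce", t)), tdir / "dce.nii")
        np.savez(tdir / "ground_truth.npz", D=gt.D_map, f=gt.f_map,
                 Dstar=gt.Dstar_map, T1=gt.T1_map, T2star=gt.T2star_map,
                 S0=gt.S0_map, **{f"dce_{k}": v for k, v in gt.dce_kinetics.items()})
        log.info("simulated tumour %d", t)


def fit_maps_stage(cfg: RunConfig, out: Path) -> None:
    """Fit the 19 parameter maps for every tumour."""
    for t in range(1, cfg.n_tumours + 1):
        tdir = out / f"tumour{t}"
        maps_dir = tdir / "maps"
        dwi = io.read_series(tdir / "acq" / "dwi.nii")
        maps = mrfit.fit_ivim_maps(dwi, seed=cfg.stage_seed("ivim", t))
        maps["ADC"] = mrfit.fit_adc_map(dwi)
        maps["T2star"] = mrfit.fit_t2star_map(io.read_series(tdir / "acq" / "t2star.nii"))
        maps["T1"] = mrfit.fit_t1_map(io.read_series(tdir / "acq" / "t1.nii"))
        dce_maps, flags = dce.analyze_dce_series(
            io.read_series(tdir / "acq" / "dce.nii"),
            smoothing_parameter=cfg.smoothing_parameter)
        maps.update(dce_maps)
        for pmap in maps.values():
            io.write_map(pmap, maps_dir)
        flags.to_csv(maps_dir / "dce_flags.csv", index=False)
        log.info("fitted %d maps for tumour %d", len(maps), t)


def histology_stage(cfg: RunConfig, out: Path) -> None:
    """Render and index the four stained sections per tumour."""
    for t in range(1, cfg.n_tumours + 1):
        hdir = out / f"tumour{t}" / "histology"
        hdir.mkdir(parents=True, exist_ok=True)
        for stain in ("HE", "Ki67", "CD31", "MT"):
            slide = synth.generate_slide(stain, cfg.slide_px, cfg.um_per_px,
                                         seed=cfg.stage_seed(f"slide_{stain}", t))
            io.write_slide(slide.image, slide.um_per_px, hdir / f"{stain}.tiff")
            slide.truth.to_csv(hdir / f"{stain}_truth.csv", index=False)
            table = histo.index_slide(slide.image, stain, slide.um_per_px,
                                      tile_size_um=cfg.tile_size_um)
            table.to_csv(hdir / f"{stain}_tiles.csv", index=False)
        log.info("indexed histology for tumour %d", t)


def sample_stage(cfg: RunConfig, out: Path) -> pd.DataFrame:
    """Register histology tile grids to the MR frame and emit the paired
    sample table."""
    index_for_stain = {"HE": "HEcount", "Ki67": "Ki67count",
                       "CD31": "MVD", "MT": "FD"}
    all_samples = []
    for t in range(1, cfg.n_tumours + 1):
        tdir = out / f"tumour{t}"
        maps = {}
        for name in MR_PARAM_NAMES:
            p = tdir / "maps" / f"{name}.nii"
            if p.exists():
                maps[name] = io.read_map(p)
        tables = {}
        for stain, index_name in index_for_stain.items():
            tbl = pd.read_csv(tdir / "histology" / f"{stain}_tiles.csv")
            tables[index_name] = tbl
        # known acquisition geometry: histology frame is offset/rotated
        # slightly within the MR field of view
        true_tf = synth.similarity_matrix(rotation_deg=3.0, scale=1.0,
                                          translation=(800.0, 800.0))
        src, dst = synth.make_landmark_pairs(true_tf, n_points=6, jitter_um=0.0,
                                             seed=cfg.stage_seed("landmarks", t))
        io.write_landmarks(src, dst, tdir / "landmarks.csv")
        tf = register.fit_transform(src, dst, family="affine")
        samples = register.sample_subregion(maps, tables, tf,
                                            tile_size_um=cfg.tile_size_um,
                                            tumour_id=t)
        all_samples.append(samples)
        log.info("sampled %d tiles for tumour %d", len(samples), t)
    table = pd.concat(all_samples, ignore_index=True)
    table.to_csv(out / "samples.csv", index=False)
    return table


def stats_stage(cfg: RunConfig, out: Path,
                sample_table: Optional[pd.DataFrame] = None) -> dict:
    """Pairwise mixed-effects screen, per-tumour predictive power for the
    significant pairs, and parameter clustering."""
    if sample_table is None:
        sample_table = pd.read_csv(out / "samples.csv")
    mr_names = [n for n in MR_PARAM_NAMES if n in sample_table.columns]
    hi_names = [n for n in HISTO_INDEX_NAMES if n in sample_table.columns]
    pairwise = stats.pairwise_all(sample_table, mr_names, hi_names,
                                  threshold=cfg.significance_threshold)
    pairwise.to_csv(out / "pairwise.csv", index=False)

    power_rows = []
    for _, row in pairwise[pairwise["significant"]].iterrows():
        for t, sub in sample_table.groupby("tumour_id"):
            pp = stats.predictive_power_cv(sub, row.mr_parameter,
                                           row.histology_index,
                                           k=cfg.cv_folds,
                                           seed=cfg.stage_seed("cv", int(t)),
                                           tumour_id=int(t))
            if pp is not None:
                power_rows.append({"tumour_id": pp.tumour_id,
                                   "mr_parameter": pp.mr_parameter,
                                   "histology_index": pp.histology_index,
                                   "npmse": pp.npmse})
    power = pd.DataFrame(power_rows,
                         columns=["tumour_id", "mr_parameter",
                                  "histology_index", "npmse"])
    power.to_csv(out / "predictive_power.csv", index=False)

    cluster_cols = [c for c in mr_names + hi_names
                    if sample_table[c].notna().sum() >= 3]
    complete = sample_table[cluster_cols].dropna()
    tree = None
    if len(cluster_cols) >= 3 and len(complete) >= 3:
        tree = stats.cluster_parameters(sample_table, cluster_cols)
        pd.DataFrame(tree.merges,
                     columns=["node_a", "node_b", "height", "size"]
                     ).to_csv(out / "linkage.csv", index=False)
        (out / "linkage_leaves.json").write_text(json.dumps(tree.leaf_names))
    summary = {
        "n_samples": int(len(sample_table)),
        "n_pairs_tested": int(len(pairwise)),
        "n_significant": int(pairwise["significant"].sum()),
        "clustered_parameters": cluster_cols if tree is not None else [],
    }
    (out / "stats_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_pipeline(cfg: RunConfig, stages: Optional[list[str]] = None) -> Path:
    """Run the enabled stages in order, writing a provenance manifest.

    Stage outputs are plain files, so any stage can run standalone given the
    artifacts of the previous one. Reruns with identical config and seeds
    reproduce the outputs.
    """
    all_stages = ["simulate", "fit_maps", "histology", "sample", "stats", "report"]
    enabled = stages or all_stages
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    required_artifact = {
        "fit_maps": "tumour1/acq/dwi.nii", "sample": "tumour1/maps/D.nii",
        "stats": "samples.csv", "report": "pairwise.csv",
    }
    for stage in enabled:
        req = required_artifact.get(stage)
        if req and not (out / req).exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs missing upstream artifact {req}")
        if stage == "simulate":
            simulate_stage(cfg, out)
        elif stage == "fit_maps":
            fit_maps_stage(cfg, out)
        elif stage == "histology":
            histology_stage(cfg, out)
        elif stage == "sample":
            sample_stage(cfg, out)
        elif stage == "stats":
            stats_stage(cfg, out)
        elif stage == "report":
            write_report(out)
        else:
            raise ValueError(f"unknown stage {stage!r}")

    manifest = {
        "seed": cfg.seed,
        "stages": enabled,
        "files": {str(p.relative_to(out)): _hash_file(p)
                  for p in sorted(out.rglob("*"))
                  if p.is_file() and p.suffix in (".csv", ".json", ".yaml")},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def write_report(run_dir: Path) -> Path:
    """Summary figures and a machine-readable JSON of every plotted number:
    per-tumour histology-index boxplots (median, quartiles, 2.5/97.5
    percentiles), the npmse matrix of significant pairs, the r/p chart of
    the pairwise screen, and the parameter dendrogram."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    run_dir = Path(run_dir)
    report_dir = run_dir / "report"
    report_dir.mkdir(exist_ok=True)
    numbers: dict = {}

    samples = pd.read_csv(run_dir / "samples.csv")
    hist_cols = [c for c in HISTO_INDEX_NAMES if c in samples.columns]
    box_stats = {}
    fig, axes = plt.subplots(1, len(hist_cols), figsize=(4 * len(hist_cols), 4))
    axes = np.atleast_1d(axes)
    for ax, col in zip(axes, hist_cols):
        groups, labels = [], []
        for t, sub in samples.groupby("tumour_id"):
            v = sub[col].dropna().to_numpy()
            if len(v):
                groups.append(v)
                labels.append(str(t))
                box_stats[f"{col}_tumour{t}"] = {
                    "median": float(np.median(v)),
                    "q25": float(np.percentile(v, 25)),
                    "q75": float(np.percentile(v, 75)),
                    "p2.5": float(np.percentile(v, 2.5)),
                    "p97.5": float(np.percentile(v, 97.5)),
                }
        if groups:
            ax.boxplot(groups, tick_labels=labels, whis=(2.5, 97.5))
        ax.set_title(col)
        ax.set_xlabel("tumour")
    fig.tight_layout()
    fig.savefig(report_dir / "histology_boxplots.png", dpi=100)
    plt.close(fig)
    numbers["boxplots"] = box_stats

    pairwise = pd.read_csv(run_dir / "pairwise.csv")
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    labels = pairwise["mr_parameter"] + "/" + pairwise["histology_index"]
    ax1.bar(labels, pairwise["r"])
    ax1.set_ylabel("r (fixed slope)")
    with np.errstate(divide="ignore"):
        ax2.bar(labels, -np.log10(pairwise["p"]))
    ax2.axhline(-np.log10(stats.SIGNIFICANCE_THRESHOLD), ls="--", c="k")
    ax2.set_ylabel("-log10 p")
    ax2.tick_params(axis="x", rotation=90, labelsize=5)
    fig.tight_layout()
    fig.savefig(report_dir / "pairwise.png", dpi=100)
    plt.close(fig)
    numbers["pairwise"] = pairwise.to_dict(orient="records")

    power_path = run_dir / "predictive_power.csv"
    if power_path.exists():
        power = pd.read_csv(power_path)
        if len(power):
            pivot = power.pivot_table(index=["mr_parameter", "histology_index"],
                                      columns="tumour_id", values="npmse")
            fig, ax = plt.subplots(figsize=(6, max(2, 0.4 * len(pivot))))
            im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis")
            ax.set_yticks(range(len(pivot)),
                          ["/".join(map(str, i)) for i in pivot.index])
            ax.set_xticks(range(pivot.shape[1]), pivot.columns.astype(str))
            fig.colorbar(im, label="npmse")
            fig.tight_layout()
            fig.savefig(report_dir / "npmse_matrix.png", dpi=100)
            plt.close(fig)
            numbers["npmse"] = power.to_dict(orient="records")
        else:
            numbers["npmse"] = []
            numbers["npmse_note"] = "no significant pairs: npmse matrix empty"

    linkage_path = run_dir / "linkage.csv"
    if linkage_path.exists():
        merges = pd.read_csv(linkage_path).to_numpy(float)
        leaves = json.loads((run_dir / "linkage_leaves.json").read_text())
        fig, ax = plt.subplots(figsize=(8, 4))
        dendrogram(merges, labels=leaves, ax=ax, leaf_rotation=90)
        fig.tight_layout()
        fig.savefig(report_dir / "dendrogram.png", dpi=100)
        plt.close(fig)
        numbers["linkage"] = {"merges": merges.tolist(), "leaves": leaves}

    (report_dir / "report.json").write_text(json.dumps(numbers, indent=2))
    return report_dir
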