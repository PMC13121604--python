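"""Pipeline orchestration: config, staged execution, synthetic demo.

Stages: profile (bin E/L counts, log2 ratio, optional quantile normalization)
-> call (per-window test, BH, stitching) -> integrate (region RPKM, noise
threshold, transcription change) -> classify. Scaled/smoothed profiles are
produced only for display-track export; every statistic consumes unscaled
values. A manifest records seeds, thresholds and per-stage counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genomic_core as gc
from . import rt_change, rt_profile, synthetic_data, transcription
from .rt_profile import FractionCoverage, RTProfile, SampleKey
from .transcription import NascentTrack

__all__ = ["PipelineConfig", "load_dataset", "run_pipeline", "make_demo"]

log = logging.getLogger("rtswitch")


@dataclass
class PipelineConfig:
    data_dir: str
    out_dir: str
    bin_size: int = 50_000
    display_bin_size: int = 5_000
    epsilon: float = rt_profile.DEFAULT_EPSILON
    coverage_floor: float = rt_profile.DEFAULT_FLOOR
    scale_lo_q: float = 0.005
    scale_hi_q: float = 0.995
    scale_bound: float = 3.0
    smoothing_window: int = 300_000
    # Quantile normalization harmonizes samples from different library preps
    # on real data; the synthetic generator emits already-calibrated samples,
    # so the default leaves profiles on their native scale.
    quantile_normalize: bool = False
    # median-center the per-window deltas to remove compositional offsets
    center_deltas: bool = True
    # The MC empirical null pools replicate differences genome-wide, so its
    # per-window test does not pay the small-sample variance-estimation
    # penalty a 4v4 t-test does; n_mc is sized so the add-one p floor
    # (1/(n_mc+1)) clears the BH-adjusted alpha at q_cut.
    test_mode: str = "mc"                 # "mc" | "ttest"
    paired: bool = False
    n_mc: int = 50_000
    q_cut: float = rt_change.DEFAULT_Q_CUT
    p_cut: float = transcription.DEFAULT_TX_P_CUT
    gap_bp: int = rt_change.DEFAULT_GAP_BP
    noise_quantile: float = transcription.DEFAULT_NOISE_QUANTILE
    n_shuffles: int = 100
    fc_pseudocount: float = transcription.DEFAULT_FC_PSEUDOCOUNT
    excluded_chromosomes: list[str] = field(default_factory=list)
    export_display_tracks: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q_cut", "p_cut", "noise_quantile"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.test_mode not in ("ttest", "mc"):
            raise ValueError("test_mode must be 'ttest' or 'mc'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Dataset loading (manifest-driven, as written by synthetic_data.write_dataset)
# ---------------------------------------------------------------------------

def load_dataset(
    data_dir, config: PipelineConfig
) -> tuple[FractionCoverage, NascentTrack, pd.DataFrame, pd.DataFrame, dict]:
    """Load a dataset directory: coverage, nascent track, genes, truth regions,
    and per-replicate nascent library sizes (total sequenced reads)."""
    data_dir = Path(data_dir)
    with open(data_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    layout = gc.read_chrom_sizes(data_dir / "chrom.sizes")
    if config.excluded_chromosomes:
        layout = layout.drop(config.excluded_chromosomes)
        log.info("excluded chromosomes: %s", config.excluded_chromosomes)
    grid = gc.BinGrid(layout, manifest["bin_size"])
    fine = gc.BinGrid(layout, manifest["transcription_bin"])

    cov = FractionCoverage(grid)
    track = NascentTrack(fine)
    for name in manifest["files"]:
        if name.startswith("repliseq_") and name.endswith("_early.bedGraph"):
            stem = name[len("repliseq_"):-len("_early.bedGraph")]
            cond, rep, allele = stem.rsplit("_", 2)
            rep = int(rep.removeprefix("rep"))
            early = _load_track(data_dir / name, grid, config)
            late = _load_track(data_dir / f"repliseq_{stem}_late.bedGraph", grid, config)
            cov.add(SampleKey(cond, rep, allele), early, late)
        elif name.startswith("bru_") and name.endswith(".bedGraph"):
            cond, rep = name[len("bru_"):-len(".bedGraph")].rsplit("_rep", 1)
            track.add(cond, int(rep), _load_track(data_dir / name, fine, config))
    genes = gc.read_bed(data_dir / "genes.bed")
    truth_regions = (
        pd.read_csv(data_dir / "truth_regions.tsv", sep="\t")
        if (data_dir / "truth_regions.tsv").exists()
        else pd.DataFrame(columns=["chrom", "start", "end", "rt_class", "tx_class"])
    )
    if config.excluded_chromosomes:
        genes = genes[~genes["chrom"].isin(config.excluded_chromosomes)].reset_index(drop=True)
        truth_regions = truth_regions[
            ~truth_regions["chrom"].isin(config.excluded_chromosomes)
        ].reset_index(drop=True)
    # library size = total sequenced reads; falls back to track totals for
    # datasets whose manifest does not declare it
    nominal = manifest.get("library_size")
    library_sizes = {
        key: float(nominal) if nominal else track.library_size(*key)
        for key in track.counts
    }
    return cov, track, genes, truth_regions, library_sizes


def _load_track(path, grid: gc.BinGrid, config: PipelineConfig) -> np.ndarray:
    df = gc.read_bedgraph(path)
    if config.excluded_chromosomes:
        df = df[~df["chrom"].isin(config.excluded_chromosomes)]
    return grid.bin_coverage(df)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _profiles_by_condition(
    cov: FractionCoverage, config: PipelineConfig
) -> dict[str, list[RTProfile]]:
    """log2(E/L) per sample, optionally quantile-normalized to a reference.

    All samples of a condition — every replicate of every allele — enter the
    condition's replicate pool. The normalization reference is the first
    sample of the first condition.
    """
    keys = cov.keys()
    profiles = {
        key: rt_profile.compute_log2_ratio(
            cov, key, floor=config.coverage_floor, epsilon=config.epsilon
        )
        for key in keys
    }
    if config.quantile_normalize:
        ref = profiles[keys[0]]
        profiles = {
            key: rt_profile.quantile_normalize(p, ref) for key, p in profiles.items()
        }
    by_cond: dict[str, list[RTProfile]] = {}
    for key, p in profiles.items():
        by_cond.setdefault(key.condition, []).append(p)
    for cond, plist in by_cond.items():
        n_masked = int(np.sum(~plist[0].mask))
        log.info("condition %s: %d samples, %d masked bins (first sample)",
                 cond, len(plist), n_masked)
    return by_cond


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute profile -> call -> integrate -> classify; write all outputs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "parameters": asdict(config)}

    def stage(name: str):
        log.info("stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    try:
        cov, track, genes, truth_regions, library_sizes = load_dataset(
            config.data_dir, config
        )
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise RuntimeError(f"stage load: {exc}") from exc

    # -- profile ----------------------------------------------------------
    info = stage("profile")
    by_cond = _profiles_by_condition(cov, config)
    conds = sorted(by_cond)
    if len(conds) != 2:
        raise RuntimeError(f"stage profile: need exactly 2 conditions, got {conds}")
    info["conditions"] = conds
    info["samples"] = {c: len(v) for c, v in by_cond.items()}
    info["masked_bins"] = {
        c: int(np.sum(~np.stack([p.mask for p in v]).all(axis=0)))
        for c, v in by_cond.items()
    }
    if config.export_display_tracks:
        bins = cov.grid.bins_frame()
        for cond, plist in by_cond.items():
            disp = rt_profile.smooth_profile(
                rt_profile.scale_profile(
                    plist[0], config.scale_lo_q, config.scale_hi_q, config.scale_bound
                ),
                config.smoothing_window,
            )
            df = bins[disp.mask].copy()
            df["value"] = disp.values[disp.mask]
            gc.write_bedgraph(df, out_dir / f"rt_display_{cond}.bedGraph")

    # -- call -------------------------------------------------------------
    info = stage("call")
    a, b = by_cond[conds[0]], by_cond[conds[1]]
    for p in a + b:
        assert "scaled" not in p.steps and "smoothed" not in p.steps, (
            "statistics must consume unscaled, unsmoothed profiles"
        )
    if config.test_mode == "mc":
        windows = rt_change.monte_carlo_window_test(
            a, b, n_mc=config.n_mc, seed=config.seed, center=config.center_deltas
        )
    else:
        windows = rt_change.ttest_window_test(
            a, b, paired=config.paired, center=config.center_deltas
        )
    regions = rt_change.call_switch_regions(windows, config.q_cut, config.gap_bp)
    windows.to_csv(out_dir / "windows.tsv", sep="\t", index=False)
    regions.to_csv(out_dir / "switch_regions.tsv", sep="\t", index=False)
    if not regions.empty:
        bed = regions[["chrom", "start", "end", "direction", "mean_delta_rt"]].copy()
        bed.columns = ["chrom", "start", "end", "name", "score"]
        gc.write_bed(bed, out_dir / "switch_regions.bed")
    sig = windows[windows["q"] <= config.q_cut]
    if not sig.empty:
        gc.write_bed(sig[["chrom", "start", "end"]], out_dir / "significant_windows.bed")
    info["tested_windows"] = int(len(windows))
    info["significant_windows"] = int(len(sig))
    info["regions"] = int(len(regions))
    log.info("called %d switching regions from %d significant windows",
             len(regions), len(sig))

    # -- integrate --------------------------------------------------------
    info = stage("integrate")
    eval_regions = truth_regions if not truth_regions.empty else regions
    if eval_regions.empty:
        raise RuntimeError("stage integrate: no regions to quantify")
    advance = regions[regions["direction"] == "advance"] if not regions.empty else regions
    if advance.empty:
        noise = transcription.NoiseThreshold(0.0, 0, config.noise_quantile, np.empty(0))
        log.warning("no RT-advancing regions; noise threshold defaults to 0")
    else:
        noise = transcription.noise_threshold(
            track,
            advance[["chrom", "start", "end"]],
            genes,
            cov.grid.layout,
            n_shuffles=config.n_shuffles,
            quantile=config.noise_quantile,
            seed=config.seed,
            library_sizes=library_sizes,
        )
    quant = transcription.region_rpkm(
        track, eval_regions[["chrom", "start", "end"]], library_sizes=library_sizes
    )
    tx_stats = transcription.transcription_change_test(
        quant, pseudocount=config.fc_pseudocount
    )
    tx_stats.to_csv(out_dir / "region_transcription.tsv", sep="\t", index=False)
    with open(out_dir / "noise_threshold.json", "w") as fh:
        json.dump(
            {
                "threshold_rpkm": noise.threshold,
                "quantile": noise.quantile,
                "n_shuffles": noise.n_shuffles,
                "n_shuffled_regions": int(noise.shuffled_rpkm.size),
            },
            fh,
            indent=2,
        )
    np.savetxt(out_dir / "noise_shuffled_rpkm.tsv", noise.shuffled_rpkm, fmt="%.6g")
    info["noise_threshold_rpkm"] = noise.threshold
    log.info("noise threshold: %.4g RPKM (q=%.3g, %d shuffles)",
             noise.threshold, noise.quantile, noise.n_shuffles)

    # -- classify ---------------------------------------------------------
    info = stage("classify")
    labelled = eval_regions[["chrom", "start", "end"]].copy()
    labelled["rt_class"] = transcription.label_regions_by_rt(labelled, regions).to_numpy()
    result = transcription.classify_regions(labelled, tx_stats, noise, p_cut=config.p_cut)
    result.table.to_csv(out_dir / "classification_table.tsv", sep="\t")
    result.labels.to_csv(out_dir / "region_classes.tsv", sep="\t", index=False)
    info["table"] = {
        rt: {tx: int(result.table.loc[rt, tx]) for tx in result.table.columns}
        for rt in result.table.index
    }

    manifest["seed"] = config.seed
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "windows": windows,
        "switch_regions": regions,
        "noise": noise,
        "tx_stats": tx_stats,
        "classification": result,
        "manifest": manifest,
    }


def make_demo(outdir, seed: int = 0) -> synthetic_data.SimConfig:
    """Generate the standard synthetic study into ``outdir``; returns its config."""
    config = synthetic_data.demo_config(seed=seed)
    truth, cov, track = synthetic_data.simulate_dataset(config)
    synthetic_data.write_dataset(truth, cov, track, outdir, config)
    return config
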