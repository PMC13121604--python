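"""Synthetic allele-resolved Repli-seq and nascent-transcription data.

The generator plants a known replication-timing (RT) program — piecewise-
constant replication domains joined by linear timing-transition ramps, plus
planted RT switches and allele-specific offsets — and samples early/late
fraction read counts whose expected log2(E/L) equals the planted RT. Nascent
transcription is simulated as Poisson coverage from gene models with
condition-specific RPKM targets over a low uniform intergenic background.
All ground truth (per-bin RT, switch intervals, expression, region classes)
is retained for parameter-recovery tests.

The count model: for a bin with true RT ``s`` the early-fraction probability
is the base-2 logistic pE = 2^s / (1 + 2^s), and E ~ Poisson(2*lambda*pE),
L ~ Poisson(2*lambda*(1-pE)) independently per replicate and allele, so that
E[E]/E[L] = 2^s and the measured log2 ratio recovers ``s``. An optional
gamma-multiplier overdispersion turns the counts negative-binomial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_core import (
    BinGrid,
    GenomeLayout,
    validate_intervals,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
)
from .rt_profile import FractionCoverage, SampleKey
from .transcription import NascentTrack

__all__ = [
    "SwitchSpec",
    "AllelicSpec",
    "GeneSpec",
    "SimConfig",
    "SimTruth",
    "simulate_rt_field",
    "simulate_fraction_counts",
    "simulate_transcription",
    "simulate_dataset",
    "write_dataset",
    "demo_config",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwitchSpec:
    """Planted RT change applied to the second condition (both alleles)."""

    chrom: str
    start: int
    end: int
    delta: float  # signed log2 shift; >0 advance, <0 delay

    @property
    def direction(self) -> str:
        return "advance" if self.delta > 0 else "delay"


@dataclass(frozen=True)
class AllelicSpec:
    """Planted allele-specific RT offset.

    ``when`` selects the conditions it applies to: "second" models an
    allele-specific perturbation in the perturbed state; "both" models a
    baseline allelic asynchrony present in all samples.
    """

    chrom: str
    start: int
    end: int
    allele: str
    offset: float
    when: str = "second"  # "second" | "both"


@dataclass(frozen=True)
class GeneSpec:
    """Gene body with condition-specific target expression (RPKM)."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    rpkm: dict[str, float]  # condition -> RPKM


@dataclass
class SimConfig:
    chrom_lengths: dict[str, int]
    bin_size: int = 50_000
    replicates: int = 4
    reads_per_bin: float = 100.0            # lambda per fraction
    conditions: tuple[str, str] = ("ESC", "NPC")
    alleles: tuple[str, ...] = ("both",)
    switches: list[SwitchSpec] = field(default_factory=list)
    allelic_regions: list[AllelicSpec] = field(default_factory=list)
    domains_per_chrom: int = 10
    domain_levels: tuple[float, ...] = (2.0, -2.0)
    ttr_slope: float = 4.0                  # log2 units per Mb
    genes: list[GeneSpec] = field(default_factory=list)
    background_rpkm: float = 0.01
    library_size: int = 20_000_000          # nascent reads per replicate
    transcription_bin: int = 5_000
    overdispersion: float = 0.0             # gamma CV^2; 0 = pure Poisson
    class_regions: list[tuple[str, int, int, str, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_bin <= 0:
            raise ValueError("reads_per_bin (lambda) must be > 0")
        if self.background_rpkm < 0 or any(
            v < 0 for g in self.genes for v in g.rpkm.values()
        ):
            raise ValueError("RPKM values must be >= 0")
        layout = self.layout()
        for sw in self.switches:
            if sw.start % self.bin_size or sw.end % self.bin_size:
                raise ValueError(f"switch {sw} is not bin-aligned")
        sw_df = pd.DataFrame(
            [(s.chrom, s.start, s.end) for s in self.switches],
            columns=["chrom", "start", "end"],
        )
        if not sw_df.empty:
            validate_intervals(sw_df, layout)
            sw_df = sw_df.sort_values(["chrom", "start"])
            same = sw_df["chrom"].to_numpy()[1:] == sw_df["chrom"].to_numpy()[:-1]
            if np.any(same & (sw_df["start"].to_numpy()[1:] < sw_df["end"].to_numpy()[:-1])):
                raise ValueError("planted switch regions overlap")
        for g in self.genes:
            if g.end > layout.length_of(g.chrom) or g.start < 0:
                raise ValueError(f"gene {g.name} extends beyond chromosome {g.chrom}")

    def layout(self) -> GenomeLayout:
        return GenomeLayout.from_dict(self.chrom_lengths)

    def grid(self) -> BinGrid:
        return BinGrid(self.layout(), self.bin_size)


@dataclass
class SimTruth:
    """Ground truth of one simulated study."""

    grid: BinGrid
    s: dict[tuple[str, str], np.ndarray]      # (condition, allele) -> per-bin RT
    switches: list[SwitchSpec]
    gene_expression: pd.DataFrame             # gene, condition columns
    region_classes: pd.DataFrame              # chrom,start,end,rt_class,tx_class

    def __post_init__(self) -> None:
        for arr in self.s.values():
            if not np.all(np.isfinite(arr)):
                raise ValueError("true RT must be finite everywhere")
        for sw in self.switches:
            if sw.delta == 0:
                raise ValueError("planted switch must have |delta| > 0")


# ---------------------------------------------------------------------------
# RT field
# ---------------------------------------------------------------------------

def _baseline_field(config: SimConfig) -> np.ndarray:
    """Piecewise-constant domain RT joined by linear TTR ramps, per bin."""
    grid = config.grid()
    out = np.empty(grid.n_bins)
    levels = config.domain_levels
    for chrom, length in config.chrom_lengths.items():
        n_dom = max(1, config.domains_per_chrom)
        bounds = np.linspace(0, length, n_dom + 1)
        dom_levels = [levels[i % len(levels)] for i in range(n_dom)]
        # control points for linear interpolation over bin midpoints
        xs: list[float] = [0.0]
        ys: list[float] = [dom_levels[0]]
        for i in range(1, n_dom):
            l1, l2 = dom_levels[i - 1], dom_levels[i]
            if l1 == l2:
                continue
            half = abs(l2 - l1) / config.ttr_slope * 1e6 / 2.0
            xs.extend([bounds[i] - half, bounds[i] + half])
            ys.extend([l1, l2])
        xs.append(float(length))
        ys.append(dom_levels[-1])
        sl = grid.chrom_slice(chrom)
        n = sl.stop - sl.start
        mids = (np.arange(n) + 0.5) * config.bin_size
        mids = np.minimum(mids, length - 0.5)
        out[sl] = np.interp(mids, xs, ys)
    return out


def simulate_rt_field(config: SimConfig) -> SimTruth:
    """True per-bin RT per condition and allele, with planted changes."""
    grid = config.grid()
    base = _baseline_field(config)
    c1, c2 = config.conditions
    s: dict[tuple[str, str], np.ndarray] = {}
    for allele in config.alleles:
        s[(c1, allele)] = base.copy()
        s[(c2, allele)] = base.copy()
    for sw in config.switches:
        i0, i1 = grid.bin_range(sw.chrom, sw.start, sw.end)
        for allele in config.alleles:
            s[(c2, allele)][i0:i1] += sw.delta
    for ar in config.allelic_regions:
        if ar.allele not in config.alleles:
            raise ValueError(f"allelic region names unknown allele {ar.allele!r}")
        i0, i1 = grid.bin_range(ar.chrom, ar.start, ar.end)
        targets = (c2,) if ar.when == "second" else (c1, c2)
        for cond in targets:
            s[(cond, ar.allele)][i0:i1] += ar.offset

    expr = pd.DataFrame(
        [
            {"gene": g.name, "chrom": g.chrom, "start": g.start, "end": g.end,
             **{cond: g.rpkm.get(cond, 0.0) for cond in config.conditions}}
            for g in config.genes
        ]
    )
    classes = pd.DataFrame(
        config.class_regions, columns=["chrom", "start", "end", "rt_class", "tx_class"]
    )
    return SimTruth(grid, s, list(config.switches), expr, classes)


# ---------------------------------------------------------------------------
# Read counts
# ---------------------------------------------------------------------------

def _poisson(rng: np.random.Generator, lam: np.ndarray, overdispersion: float) -> np.ndarray:
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
    return rng.poisson(lam)


def simulate_fraction_counts(truth: SimTruth, config: SimConfig) -> FractionCoverage:
    """Sample early/late counts so that E[log2(E/L)] tracks the true RT."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    cov = FractionCoverage(truth.grid)
    lam = config.reads_per_bin
    for cond in config.conditions:
        for rep in range(1, config.replicates + 1):
            for allele in config.alleles:
                s = truth.s[(cond, allele)]
                p_early = np.exp2(s) / (1.0 + np.exp2(s))
                early = _poisson(rng, 2.0 * lam * p_early, config.overdispersion)
                late = _poisson(rng, 2.0 * lam * (1.0 - p_early), config.overdispersion)
                cov.add(SampleKey(cond, rep, allele), early, late)
    return cov


def simulate_transcription(truth: SimTruth, config: SimConfig) -> NascentTrack:
    """Poisson nascent-RNA coverage from gene models plus uniform background.

    Expected reads per gene = RPKM * gene_kb * library_millions, placed
    uniformly over the gene body (at track-bin resolution); the intergenic
    background contributes its configured RPKM genome-wide.
    """
    layout = config.layout()
    fine = BinGrid(layout, config.transcription_bin)
    lib_millions = config.library_size / 1e6
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    bin_lens = fine.bin_lengths().astype(float)
    track = NascentTrack(fine)
    for cond in config.conditions:
        # reads per bp of background: RPKM * lib_millions / 1000
        rate = np.full(fine.n_bins, config.background_rpkm * lib_millions / 1000.0)
        rate = rate * bin_lens
        for g in config.genes:
            gene_rate = g.rpkm.get(cond, 0.0) * lib_millions / 1000.0
            if gene_rate == 0.0:
                continue
            i0, i1 = fine.bin_range(g.chrom, g.start, g.end)
            off = fine.offsets[g.chrom]
            starts = (np.arange(i0, i1) - off) * fine.bin_size
            ends = np.minimum(starts + fine.bin_size, layout.length_of(g.chrom))
            overlap = np.minimum(ends, g.end) - np.maximum(starts, g.start)
            rate[i0:i1] += gene_rate * overlap
        for rep in range(1, config.replicates + 1):
            track.add(cond, rep, _poisson(rng, rate, config.overdispersion))
    return track


def simulate_dataset(config: SimConfig) -> tuple[SimTruth, FractionCoverage, NascentTrack]:
    truth = simulate_rt_field(config)
    return truth, simulate_fraction_counts(truth, config), simulate_transcription(truth, config)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_dataset(
    truth: SimTruth,
    cov: FractionCoverage,
    track: NascentTrack,
    outdir,
    config: SimConfig,
) -> dict:
    """Emit the dataset in standard text formats plus truth tables.

    bedGraph per fraction/replicate/allele and per nascent replicate, BED of
    genes and planted switch regions, chrom.sizes, truth TSVs and a manifest
    (JSON). Counts round-trip losslessly through the io layer.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "bin_size": config.bin_size,
        "transcription_bin": config.transcription_bin,
        "conditions": list(config.conditions),
        "alleles": list(config.alleles),
        "replicates": config.replicates,
        "library_size": config.library_size,
        "seed": config.seed,
        "files": {},
    }

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        manifest["files"][name] = name
        return path

    layout = config.layout()
    emit("chrom.sizes", lambda p: write_chrom_sizes(layout, p))

    bins = truth.grid.bins_frame()
    for key in cov.keys():
        stem = f"repliseq_{key.condition}_rep{key.replicate}_{key.allele}"
        for frac, arr in (("early", cov.early[key]), ("late", cov.late[key])):
            df = bins.copy()
            df["value"] = arr
            emit(f"{stem}_{frac}.bedGraph", lambda p, d=df: write_bedgraph(d, p))

    fine_bins = track.grid.bins_frame()
    for (cond, rep), arr in sorted(track.counts.items()):
        df = fine_bins.copy()
        df["value"] = arr
        emit(f"bru_{cond}_rep{rep}.bedGraph", lambda p, d=df: write_bedgraph(d, p))

    genes = pd.DataFrame(
        [(g.chrom, g.start, g.end, g.name, 0, g.strand) for g in config.genes],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    emit("genes.bed", lambda p: write_bed(genes, p))

    switches = pd.DataFrame(
        [
            (s.chrom, s.start, s.end, s.direction, s.delta, ".")
            for s in truth.switches
        ],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    emit("planted_switches.bed", lambda p: write_bed(switches, p))

    rt_truth = bins.copy()
    for (cond, allele), arr in sorted(truth.s.items()):
        rt_truth[f"s_{cond}_{allele}"] = arr
    emit("truth_rt.tsv", lambda p: rt_truth.to_csv(p, sep="\t", index=False))
    emit(
        "truth_genes.tsv",
        lambda p: truth.gene_expression.to_csv(p, sep="\t", index=False),
    )
    emit(
        "truth_regions.tsv",
        lambda p: truth.region_classes.to_csv(p, sep="\t", index=False),
    )

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["files"]["manifest.json"] = "manifest.json"
    return manifest


# ---------------------------------------------------------------------------
# Study-scale demo configuration
# ---------------------------------------------------------------------------

def demo_config(seed: int = 0) -> SimConfig:
    """The standard synthetic study: 100 Mb, 4v4 replicates, planted classes.

    Five 20 Mb chromosomes on a 50 kb grid; 30 planted evaluation regions —
    14 RT advances and 6 delays at |delta RT| = 2 log2 spanning 200-600 kb,
    plus 10 no-change regions — crossed with transcription states (induced
    0 -> 10 RPKM, silent over a 0.01 RPKM background, or steadily expressed).
    Silent evaluation regions are kept gene-free; additional constitutive
    genes (>= 1 RPKM) populate the rest of the genome so intergenic space is
    realistic for the shuffle-based noise threshold.
    """
    chrom_lengths = {f"chr{i}": 20_000_000 for i in range(1, 6)}
    dom_size = 2_000_000
    # (rt_class, tx_class) plan: 8 advance+up, 6 advance+silent, 6 delay+up,
    # 5 no_change+up, 5 no_change+silent
    plan = (
        [("advance", "up")] * 8
        + [("advance", "nc_below_noise")] * 6
        + [("delay", "up")] * 6
        + [("no_change", "up")] * 5
        + [("no_change", "nc_below_noise")] * 5
    )
    spans = [200_000, 300_000, 400_000, 500_000, 600_000]
    switches: list[SwitchSpec] = []
    genes: list[GeneSpec] = []
    class_regions: list[tuple[str, int, int, str, str]] = []
    chroms = list(chrom_lengths)
    # Advances are planted in late (-1) domains and delays in early (+1)
    # domains — the biologically typical late->early / early->late switch —
    # so the perturbed RT stays within the measurable dynamic range.
    next_dom = {c: 0 for c in chroms}
    for k, (rt_class, tx_class) in enumerate(plan):
        chrom = chroms[k % len(chroms)]
        d = next_dom[chrom]
        if rt_class == "advance":
            d += d % 2           # even domains carry level -1
        elif rt_class == "delay":
            d += (d + 1) % 2     # odd domains carry level +1
        next_dom[chrom] = d + 1
        # silent regions sit at the top of the span range so their RPKM
        # spread is tighter than the pooled shuffle distribution
        span = 600_000 if tx_class == "nc_below_noise" else spans[(k // len(chroms) + k) % len(spans)]
        start = d * dom_size + 600_000  # inside the plateau, clear of TTRs
        end = start + span
        class_regions.append((chrom, start, end, rt_class, tx_class))
        if rt_class == "advance":
            switches.append(SwitchSpec(chrom, start, end, +2.0))
        elif rt_class == "delay":
            switches.append(SwitchSpec(chrom, start, end, -2.0))
        if tx_class == "up":
            genes.append(
                GeneSpec(
                    name=f"gene_up_{k}",
                    chrom=chrom,
                    start=start + 50_000,
                    end=end - 50_000,
                    strand="+",
                    rpkm={"ESC": 0.0, "NPC": 10.0},
                )
            )
    # constitutive genes away from planted regions, expressed in both states
    for chrom in chroms:
        for j in range(3):
            gstart = 16_200_000 + j * 1_200_000
            genes.append(
                GeneSpec(
                    name=f"gene_const_{chrom}_{j}",
                    chrom=chrom,
                    start=gstart,
                    end=gstart + 400_000,
                    strand="+" if j % 2 == 0 else "-",
                    rpkm={"ESC": 2.0 + j, "NPC": 2.0 + j},
                )
            )
    return SimConfig(
        chrom_lengths=chrom_lengths,
        domains_per_chrom=10,
        domain_levels=(-1.0, 1.0),
        switches=switches,
        genes=genes,
        class_regions=class_regions,
        seed=seed,
    )
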