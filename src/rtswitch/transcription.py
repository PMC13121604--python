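"""Nascent-transcription quantification and RT x transcription classification.

Region transcription is the total nascent-RNA (Bru-seq) coverage in the
region, normalized to reads per kilobase per million mapped reads (RPKM),
computed per replicate in each condition. A noise threshold separating real
regional transcription from background is derived empirically by shuffling
the RT-advancing regions into intergenic space and taking an upper quantile
of the resulting RPKM distribution. Regions (or replication domains) are then
classified jointly by RT direction and transcription behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_core import (
    BinGrid,
    GenomeLayout,
    complement,
    shuffle_into,
    validate_intervals,
)
from .rt_profile import RTProfile

__all__ = [
    "NascentTrack",
    "RegionQuant",
    "NoiseThreshold",
    "ClassificationTable",
    "region_rpkm",
    "noise_threshold",
    "transcription_change_test",
    "label_regions_by_rt",
    "classify_regions",
    "domain_integration",
    "count_barcode_reads",
]

DEFAULT_TX_P_CUT = 0.01        # region transcription-change significance
DEFAULT_NOISE_QUANTILE = 0.99  # quantile of shuffled RPKMs -> noise threshold
DEFAULT_FC_PSEUDOCOUNT = 0.01  # RPKM pseudocount for log2 fold changes

TX_CLASSES = ("up", "down", "nc_above_noise", "nc_below_noise")
RT_CLASSES = ("advance", "delay", "no_change")


@dataclass
class NascentTrack:
    """Binned nascent-RNA read counts per (condition, replicate)."""

    grid: BinGrid
    counts: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def add(self, condition: str, replicate: int, counts: np.ndarray) -> None:
        if counts.shape != (self.grid.n_bins,):
            raise ValueError("count array does not match the bin grid")
        self.counts[(condition, replicate)] = counts

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for cond, _ in sorted(self.counts):
            if cond not in seen:
                seen.append(cond)
        return seen

    def replicates(self, condition: str) -> list[int]:
        return sorted(r for c, r in self.counts if c == condition)

    def library_size(self, condition: str, replicate: int) -> float:
        return float(self.counts[(condition, replicate)].sum())


@dataclass
class RegionQuant:
    """Per-region RPKM matrices (regions x replicates) for each condition."""

    regions: pd.DataFrame
    rpkm: dict[str, np.ndarray]
    conditions: tuple[str, ...]

    def mean_rpkm(self, condition: str) -> np.ndarray:
        return self.rpkm[condition].mean(axis=1)


@dataclass(frozen=True)
class NoiseThreshold:
    """Empirical background-transcription cutoff in RPKM."""

    threshold: float
    n_shuffles: int
    quantile: float
    shuffled_rpkm: np.ndarray

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("noise threshold must be >= 0")


def region_rpkm(
    track: NascentTrack,
    regions: pd.DataFrame,
    library_sizes: dict[tuple[str, int], float] | None = None,
) -> RegionQuant:
    """RPKM = reads_in_region / (region_kb * library_millions), per replicate.

    Strand-agnostic: all coverage in the region counts. Library sizes default
    to the track totals.
    """
    validate_intervals(regions, track.grid.layout)
    if (regions["end"] - regions["start"] <= 0).any():
        raise ValueError("zero-length region")
    conditions = tuple(track.conditions())
    rpkm: dict[str, np.ndarray] = {}
    for cond in conditions:
        reps = track.replicates(cond)
        mat = np.zeros((len(regions), len(reps)))
        for j, rep in enumerate(reps):
            counts = track.counts[(cond, rep)]
            lib = (
                library_sizes[(cond, rep)]
                if library_sizes is not None
                else track.library_size(cond, rep)
            )
            if lib <= 0:
                raise ValueError(f"non-positive library size for {(cond, rep)}")
            for i, (chrom, start, end) in enumerate(
                zip(regions["chrom"], regions["start"], regions["end"])
            ):
                reads = track.grid.reads_in_interval(counts, chrom, int(start), int(end))
                kb = (end - start) / 1000.0
                mat[i, j] = reads / (kb * lib / 1e6)
        rpkm[cond] = mat
    return RegionQuant(regions.reset_index(drop=True), rpkm, conditions)


def noise_threshold(
    track: NascentTrack,
    rt_advance_regions: pd.DataFrame,
    genes: pd.DataFrame,
    layout: GenomeLayout,
    n_shuffles: int = 100,
    quantile: float = DEFAULT_NOISE_QUANTILE,
    seed: int | np.random.Generator = 0,
    condition: str | None = None,
    library_sizes: dict[tuple[str, int], float] | None = None,
) -> NoiseThreshold:
    """Background-transcription threshold from intergenic shuffles.

    The RT-advancing regions are shuffled ``n_shuffles`` times into intergenic
    space (complement of the genes); the threshold is the chosen quantile of
    the pooled RPKM values of all shuffled placements, averaged over the
    replicates of ``condition`` (default: last condition, i.e. the
    differentiated state).
    """
    intergenic = complement(genes, layout)
    shuffles = shuffle_into(rt_advance_regions, intergenic, n_shuffles, seed)
    if condition is None:
        condition = track.conditions()[-1]
    pooled: list[np.ndarray] = []
    for placed in shuffles:
        rq = region_rpkm(track, placed, library_sizes=library_sizes)
        pooled.append(rq.mean_rpkm(condition))
    sample = np.concatenate(pooled)
    thr = float(np.quantile(sample, quantile))
    return NoiseThreshold(
        threshold=thr, n_shuffles=n_shuffles, quantile=quantile, shuffled_rpkm=sample
    )


def transcription_change_test(
    quant: RegionQuant,
    pseudocount: float = DEFAULT_FC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Paired t-test of per-replicate RPKM (condition 2 vs 1) per region.

    log2 FC = log2((mean2 + c) / (mean1 + c)). Zero-variance differences with
    a nonzero mean yield NaN p (no finite paired t exists); identical vectors
    yield p = 1.
    """
    if len(quant.conditions) != 2:
        raise ValueError("transcription change test needs exactly two conditions")
    c1, c2 = quant.conditions
    x1, x2 = quant.rpkm[c1], quant.rpkm[c2]
    if x1.shape != x2.shape:
        raise ValueError("paired test needs equal replicate counts per condition")
    d = x2 - x1
    n = d.shape[1]
    md = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = md / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), n - 1)
        p = np.where((sd == 0) & (md == 0), 1.0, p)
        p = np.where((sd == 0) & (md != 0), np.nan, p)
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    out = quant.regions.copy()
    out["rpkm_1"] = m1
    out["rpkm_2"] = m2
    out["log2_fc"] = np.log2((m2 + pseudocount) / (m1 + pseudocount))
    out["p_tx"] = p
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def label_regions_by_rt(
    regions: pd.DataFrame, switch_regions: pd.DataFrame
) -> pd.Series:
    """RT class per region: direction of an overlapping switching region,
    else ``no_change``. Overlap by >= 1 bp; the largest overlap wins ties."""
    labels = []
    for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
        best, best_ov = "no_change", 0
        if not switch_regions.empty:
            sub = switch_regions[switch_regions["chrom"] == chrom]
            for _, row in sub.iterrows():
                ov = min(end, row["end"]) - max(start, row["start"])
                if ov > best_ov:
                    best, best_ov = row["direction"], ov
        labels.append(best)
    return pd.Series(labels, index=regions.index, name="rt_class")


@dataclass
class ClassificationTable:
    """RT x transcription cross-tabulation with per-region labels."""

    table: pd.DataFrame          # rows RT_CLASSES, cols TX_CLASSES, int counts
    labels: pd.DataFrame         # per-region rt_class, tx_class

    def __post_init__(self) -> None:
        if int(self.table.to_numpy().sum()) != len(self.labels):
            raise ValueError("classification counts do not sum to region count")


def classify_regions(
    regions: pd.DataFrame,
    tx_stats: pd.DataFrame,
    noise: NoiseThreshold,
    p_cut: float = DEFAULT_TX_P_CUT,
) -> ClassificationTable:
    """Cross-tabulate RT direction against transcription behavior.

    Transcription is significant iff p < p_cut, split by fold-change sign;
    non-significant regions split by whether condition-2 RPKM clears the
    noise threshold. ``regions`` must carry an ``rt_class`` column; rows are
    matched to ``tx_stats`` positionally (same region order). The partition
    is exhaustive and exclusive.
    """
    if "rt_class" not in regions.columns:
        raise ValueError("regions need an rt_class column (see label_regions_by_rt)")
    if len(regions) != len(tx_stats):
        raise ValueError("regions and transcription statistics differ in length")
    missing = tx_stats["p_tx"].isna() & (tx_stats["rpkm_1"] != tx_stats["rpkm_2"])
    if missing.any():
        i = int(np.flatnonzero(missing)[0])
        r = regions.iloc[i]
        raise ValueError(
            f"region {r['chrom']}:{r['start']}-{r['end']} lacks a usable "
            "transcription statistic"
        )
    tx_class = []
    for p, fc, rpkm2 in zip(tx_stats["p_tx"], tx_stats["log2_fc"], tx_stats["rpkm_2"]):
        if np.isfinite(p) and p < p_cut:
            tx_class.append("up" if fc > 0 else "down")
        else:
            tx_class.append(
                "nc_above_noise" if rpkm2 > noise.threshold else "nc_below_noise"
            )
    labels = pd.DataFrame(
        {
            "chrom": regions["chrom"].to_numpy(),
            "start": regions["start"].to_numpy(),
            "end": regions["end"].to_numpy(),
            "rt_class": regions["rt_class"].to_numpy(),
            "tx_class": tx_class,
        }
    )
    table = pd.DataFrame(0, index=list(RT_CLASSES), columns=list(TX_CLASSES), dtype=int)
    for rt, tx in zip(labels["rt_class"], labels["tx_class"]):
        table.loc[rt, tx] += 1
    return ClassificationTable(table=table, labels=labels)


def domain_integration(
    domains: pd.DataFrame,
    rt_profiles: dict[str, list[RTProfile]],
    track: NascentTrack,
    pseudocount: float = DEFAULT_FC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-domain paired tests of RT change and transcription change.

    For each replication domain and each replicate, the domain-mean RT and
    the domain RPKM are computed; condition-2 vs condition-1 changes are
    assessed with paired t-tests. Domains whose RT is entirely masked in some
    replicate are excluded (flagged in the ``excluded`` column of the result).
    """
    conds = sorted(rt_profiles)
    if len(conds) != 2:
        raise ValueError("domain integration needs exactly two conditions")
    grid = rt_profiles[conds[0]][0].grid
    validate_intervals(domains, grid.layout)

    # per-domain per-replicate mean RT
    means: dict[str, np.ndarray] = {}
    covered: np.ndarray | None = None
    for cond in conds:
        profs = rt_profiles[cond]
        mat = np.full((len(domains), len(profs)), np.nan)
        for j, prof in enumerate(profs):
            for i, (chrom, start, end) in enumerate(
                zip(domains["chrom"], domains["start"], domains["end"])
            ):
                i0, i1 = grid.bin_range(chrom, int(start), int(end))
                vals = prof.values[i0:i1][prof.mask[i0:i1]]
                if vals.size:
                    mat[i, j] = vals.mean()
        means[cond] = mat
        ok = np.isfinite(mat).all(axis=1)
        covered = ok if covered is None else covered & ok

    d = means[conds[1]] - means[conds[0]]
    n = d.shape[1]
    md = np.nanmean(d, axis=1)
    sd = np.nanstd(d, axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = md / (sd / np.sqrt(n))
        p_rt = 2.0 * stats.t.sf(np.abs(t), n - 1)
        p_rt = np.where((sd == 0) & (md == 0), 1.0, p_rt)

    quant = region_rpkm(track, domains)
    tx = transcription_change_test(quant, pseudocount=pseudocount)

    out = domains.reset_index(drop=True).copy()
    out["delta_rt"] = md
    out["p_rt"] = p_rt
    out["rpkm_1"] = tx["rpkm_1"].to_numpy()
    out["rpkm_2"] = tx["rpkm_2"].to_numpy()
    out["log2_fc"] = tx["log2_fc"].to_numpy()
    out["p_tx"] = tx["p_tx"].to_numpy()
    out["excluded"] = ~covered
    return out


# ---------------------------------------------------------------------------
# Barcode counting
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def count_barcode_reads(
    fastq_path,
    barcodes: list[str],
    total_reads: int | None = None,
    match_revcomp: bool = False,
) -> pd.DataFrame:
    """Per-barcode read counts and RPM from a FASTQ (plain or gzip).

    A read counts for a barcode iff the exact 16-mer occurs as a substring of
    the read sequence; a read containing the barcode twice counts once.
    RPM = count / total_reads * 1e6 (total defaults to reads in the file).
    """
    import pysam

    for bc in barcodes:
        if len(bc) != 16:
            raise ValueError(f"barcode {bc!r} is not 16 nt")
        if set(bc) - set("ACGT"):
            raise ValueError(f"barcode {bc!r} contains non-ACGT characters")
    targets = {bc: (bc, bc[::-1].translate(_COMP)) if match_revcomp else (bc,)
               for bc in barcodes}
    counts = {bc: 0 for bc in barcodes}
    n_reads = 0
    with pysam.FastxFile(str(fastq_path)) as fh:
        for entry in fh:
            n_reads += 1
            seq = entry.sequence.upper()
            for bc, pats in targets.items():
                if any(p in seq for p in pats):
                    counts[bc] += 1
    total = total_reads if total_reads is not None else n_reads
    if total <= 0:
        raise ValueError("total read count must be positive")
    return pd.DataFrame(
        {
            "barcode": list(barcodes),
            "count": [counts[bc] for bc in barcodes],
            "rpm": [counts[bc] / total * 1e6 for bc in barcodes],
        }
    )
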