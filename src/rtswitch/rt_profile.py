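"""Replication-timing profiles: log2(E/L) with normalization, scaling, smoothing.

A Repli-seq sample yields two coverage tracks — reads from the early and the
late S-phase fraction. After binning, replication timing (RT) per bin is the
log2 ratio of the library-size-normalized early to late coverage. Downstream
statistics consume these values unscaled; affine scaling and smoothing exist
only to produce display tracks with a conventional dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.stats import rankdata

from .genomic_core import BinGrid

__all__ = [
    "SampleKey",
    "FractionCoverage",
    "RTProfile",
    "compute_log2_ratio",
    "center_profile",
    "quantile_normalize",
    "scale_profile",
    "smooth_profile",
]

DEFAULT_EPSILON = 0.5      # pseudocount, RPM units, applied to both fractions
DEFAULT_FLOOR = 20         # min raw E+L per bin; below -> masked


class SampleKey(NamedTuple):
    """Identifies one Repli-seq measurement: condition x replicate x allele."""

    condition: str
    replicate: int
    allele: str = "both"


@dataclass
class FractionCoverage:
    """Per-bin early and late read counts for a set of samples."""

    grid: BinGrid
    early: dict[SampleKey, np.ndarray] = field(default_factory=dict)
    late: dict[SampleKey, np.ndarray] = field(default_factory=dict)

    def keys(self) -> list[SampleKey]:
        return sorted(self.early)

    def add(self, key: SampleKey, early: np.ndarray, late: np.ndarray) -> None:
        for arr in (early, late):
            if arr.shape != (self.grid.n_bins,):
                raise ValueError("coverage array does not match the bin grid")
            if np.any(arr < 0):
                raise ValueError("negative read counts")
        self.early[key] = early
        self.late[key] = late


@dataclass
class RTProfile:
    """Per-bin RT values (log2 E/L) with a usability mask and provenance.

    ``mask`` is True where the bin is usable; values at masked bins are
    undefined (held as NaN). ``steps`` records the processing applied, in
    order, so pipeline wiring can assert that statistics never consume
    scaled or smoothed values.
    """

    grid: BinGrid
    values: np.ndarray
    mask: np.ndarray
    key: SampleKey | None = None
    steps: tuple[str, ...] = ("raw",)

    def __post_init__(self) -> None:
        if self.values.shape != (self.grid.n_bins,) or self.mask.shape != self.values.shape:
            raise ValueError("values/mask do not match the bin grid")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite RT value at an unmasked bin")

    def with_values(self, values: np.ndarray, step: str,
                    mask: np.ndarray | None = None) -> "RTProfile":
        return replace(
            self,
            values=values,
            mask=self.mask if mask is None else mask,
            steps=self.steps + (step,),
        )

    @property
    def unmasked(self) -> np.ndarray:
        return self.values[self.mask]


def compute_log2_ratio(
    cov: FractionCoverage,
    key: SampleKey,
    floor: float = DEFAULT_FLOOR,
    epsilon: float = DEFAULT_EPSILON,
) -> RTProfile:
    """RT = log2((E_rpm + eps) / (L_rpm + eps)); low-coverage bins masked.

    Each fraction is first scaled to reads per million of its own library so
    the ratio is insensitive to sequencing depth differences between the two
    fractions. Bins whose raw E+L falls below ``floor`` are masked.
    """
    early = np.asarray(cov.early[key], dtype=float)
    late = np.asarray(cov.late[key], dtype=float)
    if np.any(early < 0) or np.any(late < 0):
        raise ValueError("negative read counts")
    e_lib, l_lib = early.sum(), late.sum()
    if e_lib == 0 or l_lib == 0:
        raise ValueError(f"empty fraction library for {key}")
    e_rpm = early / e_lib * 1e6
    l_rpm = late / l_lib * 1e6
    mask = (early + late) >= floor
    values = np.full(early.shape, np.nan)
    values[mask] = np.log2((e_rpm[mask] + epsilon) / (l_rpm[mask] + epsilon))
    return RTProfile(cov.grid, values, mask, key=key, steps=("raw",))


def center_profile(p: RTProfile) -> RTProfile:
    """Subtract the genome-wide median of unmasked values.

    Removes per-sample compositional offsets: a condition in which part of
    the genome genuinely advances has a larger early (and smaller late)
    library, which shifts log2(E_rpm/L_rpm) at every unchanged bin. The
    median is robust to the changed fraction.
    """
    vals = p.unmasked
    if vals.size == 0:
        raise ValueError("no unmasked values to center")
    out = p.values.copy()
    out[p.mask] -= np.median(vals)
    return p.with_values(out, "centered")


def quantile_normalize(target: RTProfile, reference: RTProfile) -> RTProfile:
    """Map unmasked target values onto the reference distribution by rank.

    When the two profiles have the same number of unmasked bins, the sorted
    output equals the sorted unmasked reference exactly; otherwise reference
    quantiles are linearly interpolated. Tied target values receive the mean
    of the tied reference quantiles (average ranks). Masked bins untouched.
    """
    if target.grid is not reference.grid and target.grid != reference.grid:
        raise ValueError("profiles are on different grids")
    ref_vals = np.sort(reference.unmasked)
    tgt = target.unmasked
    if ref_vals.size == 0 or tgt.size == 0:
        raise ValueError("no unmasked bins to normalize")
    ranks = rankdata(tgt, method="average")
    x = (ranks - 0.5) / tgt.size
    xp = (np.arange(ref_vals.size) + 0.5) / ref_vals.size
    mapped = np.interp(x, xp, ref_vals)
    values = target.values.copy()
    values[target.mask] = mapped
    return target.with_values(values, "quantile-normalized")


def scale_profile(
    p: RTProfile,
    lo_q: float = 0.005,
    hi_q: float = 0.995,
    bound: float = 3.0,
    clip: bool = False,
) -> RTProfile:
    """Affine map sending the (lo_q, hi_q) quantiles to (-bound, +bound).

    Compresses the raw dynamic range (roughly -7..7 for deep Repli-seq) to a
    conventional display range (roughly -3..3). Values beyond the quantiles
    map linearly outside +-bound unless ``clip`` is set. Display only — never
    feed scaled values to the significance tests.
    """
    vals = p.unmasked
    if vals.size == 0:
        raise ValueError("no unmasked values to scale")
    q_lo, q_hi = np.quantile(vals, [lo_q, hi_q])
    if q_hi == q_lo:
        raise ValueError("degenerate spread: scaling quantiles coincide")
    out = p.values.copy()
    scaled = (out[p.mask] - (q_lo + q_hi) / 2.0) * (2.0 * bound) / (q_hi - q_lo)
    if clip:
        scaled = np.clip(scaled, -bound, bound)
    out[p.mask] = scaled
    return p.with_values(out, "scaled")


def smooth_profile(p: RTProfile, window_bp: int = 300_000) -> RTProfile:
    """Centered moving average over the window, per chromosome, mask-aware.

    The window holds ``window_bp / bin_size`` bins (offsets -w//2 .. w-w//2-1
    around the center) and shrinks at chromosome ends. Masked bins enter
    neither numerator nor denominator; a window with no unmasked bins leaves
    the center masked.
    """
    bs = p.grid.bin_size
    if window_bp < bs:
        raise ValueError("smoothing window smaller than the bin size")
    w = max(1, int(round(window_bp / bs)))
    values = np.full(p.values.shape, np.nan)
    mask = np.zeros(p.mask.shape, dtype=bool)
    for chrom in p.grid.layout.names:
        sl = p.grid.chrom_slice(chrom)
        v = np.where(p.mask[sl], p.values[sl], 0.0)
        m = p.mask[sl].astype(float)
        csum_v = np.concatenate([[0.0], np.cumsum(v)])
        csum_m = np.concatenate([[0.0], np.cumsum(m)])
        n = len(v)
        idx = np.arange(n)
        lo = np.clip(idx - w // 2, 0, n)
        hi = np.clip(idx - w // 2 + w, 0, n)
        num = csum_v[hi] - csum_v[lo]
        den = csum_m[hi] - csum_m[lo]
        ok = den > 0
        out = np.full(n, np.nan)
        out[ok] = num[ok] / den[ok]
        values[sl] = out
        mask[sl] = ok
    return p.with_values(values, "smoothed", mask=mask)
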