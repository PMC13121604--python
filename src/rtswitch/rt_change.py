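"""Per-window RT-change significance, FDR control, stitching, allelic advance.

Two test modes are provided for the per-window difference in mean RT between
two conditions:

* ``monte_carlo_window_test`` — an empirical null built from within-condition
  replicate differences pooled genome-wide. Each null draw is a replicate-pair
  difference rescaled to the standard error of the observed mean-difference
  statistic, so the test is calibrated without any distributional assumption.
  Suited to 2-replicate allelic designs.
* ``ttest_window_test`` — closed-form Welch (default) or paired t-test per
  window. Suited to multi-replicate genome-wide designs; Welch is the default
  because a paired test on a handful of pairs has too few degrees of freedom
  to reach FDR-adjusted per-window significance levels.

Windows significant at ``q <= q_cut`` are stitched per direction with a gap
tolerance into switching regions.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_core import merge_with_gap
from .rt_profile import RTProfile

__all__ = [
    "bh_qvalues",
    "monte_carlo_window_test",
    "ttest_window_test",
    "call_switch_regions",
    "allelic_rt_advance",
    "significance_vs_wt",
]

DEFAULT_Q_CUT = 0.001     # per-window q-value threshold for switch calling
DEFAULT_P_CUT = 0.01      # per-window MC p-value threshold vs WT
DEFAULT_GAP_BP = 300_000  # stitching gap between significant windows


@contextmanager
def _nan_slices_ok():
    """All-masked windows legitimately produce all-NaN slices."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", "Mean of empty slice", RuntimeWarning)
        warnings.filterwarnings("ignore", "Degrees of freedom", RuntimeWarning)
        yield


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values propagate as NaN.

    q_i = min over j with p_j >= p_i of (m * p_j / rank_j), capped at 1,
    where m counts the non-NaN tests.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    if np.any((pv <= 0) | (pv > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(qv, 1.0)
    q[ok] = out
    return q


# ---------------------------------------------------------------------------
# Window tests
# ---------------------------------------------------------------------------

def _stack(profiles: list[RTProfile]) -> tuple[np.ndarray, np.ndarray]:
    """(n_rep, n_bins) value matrix with NaN at masked bins, plus the grid check."""
    if not profiles:
        raise ValueError("need at least one replicate profile")
    grid = profiles[0].grid
    vals = np.full((len(profiles), grid.n_bins), np.nan)
    for i, p in enumerate(profiles):
        if p.grid != grid:
            raise ValueError("replicate profiles are on different grids")
        vals[i, p.mask] = p.values[p.mask]
    return vals, grid


def _windows_frame(grid, idx: np.ndarray) -> pd.DataFrame:
    bins = grid.bins_frame().iloc[idx].reset_index(drop=True)
    return bins[["chrom", "start", "end"]]


def _null_pool(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Within-condition replicate-pair differences, pooled over the genome."""
    pool = []
    for mat in (a, b):
        n = mat.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                d = mat[i] - mat[j]
                pool.append(d[np.isfinite(d)])
    pool = np.concatenate(pool) if pool else np.empty(0)
    return pool


def _delta_offset(a: np.ndarray, b: np.ndarray, center: bool) -> float:
    """Genome-wide median of the per-window mean difference.

    Subtracting it removes compositional offsets (a condition whose genome
    partly advances has a larger early library, shifting log2(E/L) at every
    unchanged window). The median over windows is robust as long as changed
    windows are a minority.
    """
    if not center:
        return 0.0
    with np.errstate(invalid="ignore"), _nan_slices_ok():
        d = np.nanmean(b, axis=0) - np.nanmean(a, axis=0)
    return float(np.nanmedian(d))


def monte_carlo_window_test(
    profiles_a: list[RTProfile],
    profiles_b: list[RTProfile],
    n_mc: int = 10_000,
    seed: int | np.random.Generator = 0,
    center: bool = False,
) -> pd.DataFrame:
    """Empirical-null test of |mean_B - mean_A| per window.

    The null pools within-condition replicate differences across all genome
    windows; each of the ``n_mc`` draws (with replacement) is rescaled by
    sqrt((1/nA + 1/nB)/2) so its variance matches that of the observed
    mean-difference statistic. p = (1 + #{|null| >= obs}) / (1 + n_mc), so p
    is never 0. Windows without unmasked data on either side are skipped.
    """
    if n_mc <= 0:
        raise ValueError("n_mc must be positive")
    a, grid = _stack(profiles_a)
    b, _ = _stack(profiles_b)
    if b.shape[1] != a.shape[1]:
        raise ValueError("conditions are on different grids")
    pool = _null_pool(a, b)
    if pool.size == 0:
        raise ValueError(
            "empty null pool: need >= 2 replicates in at least one condition "
            "to form within-condition differences (t-test mode is likewise "
            "unavailable with single replicates)"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = np.sqrt((1.0 / a.shape[0] + 1.0 / b.shape[0]) / 2.0)
    null = np.sort(np.abs(rng.choice(pool, size=n_mc, replace=True) * scale))

    b = b - _delta_offset(a, b, center)
    with _nan_slices_ok():
        mean_a = np.nanmean(a, axis=0)
        mean_b = np.nanmean(b, axis=0)
    tested = np.isfinite(mean_a) & np.isfinite(mean_b)
    delta = (mean_b - mean_a)[tested]
    obs = np.abs(delta)
    ge = n_mc - np.searchsorted(null, obs, side="left")
    p = (1.0 + ge) / (1.0 + n_mc)

    out = _windows_frame(grid, np.flatnonzero(tested))
    out["delta_rt"] = delta
    out["p"] = p
    out["q"] = bh_qvalues(p)
    out["direction"] = np.where(delta > 0, "advance", np.where(delta < 0, "delay", "none"))
    out["n_a"] = np.sum(np.isfinite(a), axis=0)[tested]
    out["n_b"] = np.sum(np.isfinite(b), axis=0)[tested]
    return out


def ttest_window_test(
    profiles_a: list[RTProfile],
    profiles_b: list[RTProfile],
    paired: bool = False,
    center: bool = False,
) -> pd.DataFrame:
    """Two-sided t-test per window on replicate RT values (Welch or paired).

    Zero-variance windows: if the observed difference is also zero the test
    is a perfect null (t=0, p=1); otherwise no finite p exists and NaN is
    emitted (excluded from BH, reported for the log).
    """
    a, grid = _stack(profiles_a)
    b, _ = _stack(profiles_b)
    if paired and a.shape[0] != b.shape[0]:
        raise ValueError("paired mode needs equal replicate counts")
    b = b - _delta_offset(a, b, center)
    n_a = np.sum(np.isfinite(a), axis=0)
    n_b = np.sum(np.isfinite(b), axis=0)

    with np.errstate(invalid="ignore", divide="ignore"), _nan_slices_ok():
        if paired:
            d = b - a
            n_d = np.sum(np.isfinite(d), axis=0)
            tested = n_d >= 2
            md = np.nanmean(d, axis=0)
            sd = np.nanstd(d, axis=0, ddof=1)
            se = sd / np.sqrt(n_d)
            df = n_d - 1.0
            t = md / se
            delta = md
        else:
            tested = (n_a >= 2) & (n_b >= 2)
            ma, mb = np.nanmean(a, axis=0), np.nanmean(b, axis=0)
            va = np.nanvar(a, axis=0, ddof=1)
            vb = np.nanvar(b, axis=0, ddof=1)
            se2 = va / n_a + vb / n_b
            se = np.sqrt(se2)
            df = se2**2 / (
                (va / n_a) ** 2 / (n_a - 1.0) + (vb / n_b) ** 2 / (n_b - 1.0)
            )
            t = (mb - ma) / se
            delta = mb - ma
        p = 2.0 * stats.t.sf(np.abs(t), df)
        zero_var = se == 0
        p = np.where(zero_var & (delta == 0), 1.0, p)
        t = np.where(zero_var & (delta == 0), 0.0, t)
        p = np.where(zero_var & (delta != 0), np.nan, p)

    idx = np.flatnonzero(tested)
    out = _windows_frame(grid, idx)
    out["delta_rt"] = delta[idx]
    out["t"] = t[idx]
    out["p"] = p[idx]
    out["q"] = bh_qvalues(p[idx])
    out["direction"] = np.where(
        delta[idx] > 0, "advance", np.where(delta[idx] < 0, "delay", "none")
    )
    out["n_a"] = n_a[idx]
    out["n_b"] = n_b[idx]
    return out


# ---------------------------------------------------------------------------
# Stitching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwitchRegion:
    """A stitched run of significant same-direction windows."""

    chrom: str
    start: int
    end: int
    direction: str
    mean_delta_rt: float
    min_q: float
    n_windows: int

    @property
    def span(self) -> int:
        return self.end - self.start


def call_switch_regions(
    results: pd.DataFrame,
    q_cut: float = DEFAULT_Q_CUT,
    gap_bp: int = DEFAULT_GAP_BP,
) -> pd.DataFrame:
    """Stitch windows with q <= q_cut into direction-pure switching regions.

    Advance and delay windows are merged separately (never across direction);
    each region reports the mean delta RT, minimum q and count over its
    constituent significant windows.
    """
    regions: list[SwitchRegion] = []
    for direction in ("advance", "delay"):
        sig = results[
            (results["q"] <= q_cut) & (results["direction"] == direction)
        ]
        if sig.empty:
            continue
        merged = merge_with_gap(sig[["chrom", "start", "end"]], gap_bp)
        for chrom, start, end in merged.itertuples(index=False):
            inside = sig[
                (sig["chrom"] == chrom) & (sig["start"] >= start) & (sig["end"] <= end)
            ]
            regions.append(
                SwitchRegion(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    direction=direction,
                    mean_delta_rt=float(inside["delta_rt"].mean()),
                    min_q=float(inside["q"].min()),
                    n_windows=int(len(inside)),
                )
            )
    df = pd.DataFrame(
        [
            (r.chrom, r.start, r.end, r.direction, r.mean_delta_rt, r.min_q,
             r.n_windows, r.span)
            for r in regions
        ],
        columns=[
            "chrom", "start", "end", "direction", "mean_delta_rt", "min_q",
            "n_windows", "span",
        ],
    )
    return df.sort_values(["chrom", "start"]).reset_index(drop=True) if not df.empty else df


# ---------------------------------------------------------------------------
# Allelic advance
# ---------------------------------------------------------------------------

def _mean_profile(profiles: RTProfile | list[RTProfile]) -> tuple[np.ndarray, np.ndarray, object]:
    if isinstance(profiles, RTProfile):
        profiles = [profiles]
    vals, grid = _stack(profiles)
    with _nan_slices_ok():
        mean = np.nanmean(vals, axis=0)
    return mean, np.isfinite(mean), grid


def allelic_rt_advance(
    mut_mus: RTProfile | list[RTProfile],
    mut_cas: RTProfile | list[RTProfile],
    wt_mus: RTProfile | list[RTProfile],
    wt_cas: RTProfile | list[RTProfile],
    region: tuple[str, int, int],
) -> tuple[float, np.ndarray]:
    """Allelic RT advance over a region, normalized for baseline asynchrony.

    Per bin: d = (mut_mus - mut_cas) - (wt_mus - wt_cas), i.e. the allelic RT
    difference in the perturbed sample corrected for the allelic difference
    already present in the unperturbed one. Replicate lists are averaged.
    Returns (mean over unmasked region bins, per-bin vector).
    """
    mm, mm_mask, grid = _mean_profile(mut_mus)
    mc, mc_mask, _ = _mean_profile(mut_cas)
    wm, wm_mask, _ = _mean_profile(wt_mus)
    wc, wc_mask, _ = _mean_profile(wt_cas)
    chrom, start, end = region
    i0, i1 = grid.bin_range(chrom, start, end)
    mask = (mm_mask & mc_mask & wm_mask & wc_mask)[i0:i1]
    if not mask.any():
        raise ValueError(f"all bins masked in region {chrom}:{start}-{end}")
    d = (mm - mc - (wm - wc))[i0:i1]
    return float(np.nanmean(d[mask])), d


def significance_vs_wt(
    sample_profiles: list[RTProfile],
    wt_profiles: list[RTProfile],
    n_mc: int = 10_000,
    seed: int | np.random.Generator = 0,
    p_cut: float = DEFAULT_P_CUT,
) -> pd.DataFrame:
    """MC window test of a sample against WT; flags windows with p < p_cut."""
    out = monte_carlo_window_test(wt_profiles, sample_profiles, n_mc=n_mc, seed=seed)
    out["significant"] = out["p"] < p_cut
    return out
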