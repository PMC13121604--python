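"""Genome layout, fixed-width binning, interval algebra, and text-format IO.

Coordinates are 0-based half-open (BED convention) everywhere, including
bedGraph. Interval collections are plain pandas DataFrames with at least
``chrom``, ``start`` and ``end`` columns; helper functions below validate and
operate on them. Gap-merging follows ``bedtools merge -d`` semantics
(separation <= gap merges, book-ended intervals merge at gap 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "BinGrid",
    "validate_intervals",
    "merge_with_gap",
    "complement",
    "intersect_count",
    "gene_count_histogram",
    "shuffle_into",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
]


# ---------------------------------------------------------------------------
# Layout and bin grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with their lengths in bp."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate chromosome names")
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if any(length <= 0 for length in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(sizes), tuple(int(v) for v in sizes.values()))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))

    def drop(self, excluded: set[str] | list[str]) -> "GenomeLayout":
        """Layout with the given chromosomes removed (e.g. a homozygous chr)."""
        excluded = set(excluded)
        keep = [(n, l) for n, l in zip(self.names, self.lengths) if n not in excluded]
        if not keep:
            raise ValueError("excluding every chromosome leaves an empty layout")
        return GenomeLayout(tuple(n for n, _ in keep), tuple(l for _, l in keep))

    @property
    def total_bp(self) -> int:
        return int(sum(self.lengths))


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width half-open bins tiling every chromosome of a layout.

    The last bin of each chromosome is truncated at the chromosome end. Bins
    are addressed by a flat global index in chromosome order; ``offsets[c]``
    is the global index of chromosome ``c``'s first bin.
    """

    layout: GenomeLayout
    bin_size: int
    offsets: dict[str, int] = field(init=False, repr=False, compare=False)
    n_bins: int = field(init=False, compare=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin size must be positive")
        offsets: dict[str, int] = {}
        total = 0
        for name, length in zip(self.layout.names, self.layout.lengths):
            offsets[name] = total
            total += -(-length // self.bin_size)
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "n_bins", total)

    def n_bins_of(self, chrom: str) -> int:
        return -(-self.layout.length_of(chrom) // self.bin_size)

    def chrom_slice(self, chrom: str) -> slice:
        off = self.offsets[chrom]
        return slice(off, off + self.n_bins_of(chrom))

    def bin_range(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Global [i0, i1) index range of bins overlapping [start, end)."""
        if chrom not in self.offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= self.layout.length_of(chrom)):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds"
            )
        off = self.offsets[chrom]
        return off + start // self.bin_size, off + -(-end // self.bin_size)

    def bins_frame(self) -> pd.DataFrame:
        """All bins as a (chrom, start, end) DataFrame in global order."""
        rows = []
        for name, length in zip(self.layout.names, self.layout.lengths):
            starts = np.arange(0, length, self.bin_size, dtype=np.int64)
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def bin_lengths(self) -> np.ndarray:
        cached = getattr(self, "_bin_lengths", None)
        if cached is not None:
            return cached
        out = np.empty(self.n_bins, dtype=np.int64)
        for name, length in zip(self.layout.names, self.layout.lengths):
            sl = self.chrom_slice(name)
            n = sl.stop - sl.start
            out[sl] = self.bin_size
            out[sl.stop - 1] = length - (n - 1) * self.bin_size
        object.__setattr__(self, "_bin_lengths", out)
        return out

    # -- coverage ----------------------------------------------------------

    def bin_coverage(self, track: pd.DataFrame, value_col: str = "value") -> np.ndarray:
        """Apportion bedGraph entries onto the grid by overlap length.

        Total signal is conserved: an entry spanning several bins contributes
        to each in proportion to the overlap.
        """
        validate_intervals(track, self.layout)
        out = np.zeros(self.n_bins, dtype=float)
        if track.empty:
            return out
        chroms = track["chrom"].to_numpy()
        starts = track["start"].to_numpy(dtype=np.int64)
        ends = track["end"].to_numpy(dtype=np.int64)
        values = track[value_col].to_numpy(dtype=float)
        off = np.array([self.offsets[c] for c in chroms], dtype=np.int64)
        first = off + starts // self.bin_size
        last = off + (ends - 1) // self.bin_size
        single = first == last
        np.add.at(out, first[single], values[single])
        for i in np.flatnonzero(~single):
            density = values[i] / (ends[i] - starts[i])
            b0, b1 = first[i], last[i]
            # fractional first and last bins, full interior bins
            bs = self.bin_size
            first_end = (starts[i] // bs + 1) * bs
            out[b0] += density * (first_end - starts[i])
            last_start = ((ends[i] - 1) // bs) * bs
            out[b1] += density * (ends[i] - last_start)
            if b1 > b0 + 1:
                out[b0 + 1 : b1] += density * bs
        return out

    def reads_in_interval(
        self, counts: np.ndarray, chrom: str, start: int, end: int
    ) -> float:
        """Reads inside [start, end), apportioning edge bins by overlap."""
        i0, i1 = self.bin_range(chrom, start, end)
        lens = self.bin_lengths()
        total = float(counts[i0:i1].sum())
        bs = self.bin_size
        off = self.offsets[chrom]
        first_start = ((i0 - off) * bs)
        total -= counts[i0] * (start - first_start) / lens[i0]
        last_end = min((i1 - off) * bs, self.layout.length_of(chrom))
        total -= counts[i1 - 1] * (last_end - end) / lens[i1 - 1]
        return total


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def validate_intervals(df: pd.DataFrame, layout: GenomeLayout | None = None) -> None:
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"interval frame missing column {col!r}")
    if df.empty:
        return
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(f"empty or inverted interval {bad['chrom']}:{bad['start']}-{bad['end']}")
    if layout is not None:
        known = layout.as_dict()
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in known:
                raise KeyError(f"unknown chromosome {chrom!r}")
            if sub["start"].min() < 0 or sub["end"].max() > known[chrom]:
                raise ValueError(f"interval outside bounds of {chrom}")


def _sorted(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_with_gap(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Merge intervals whose separation (next.start - prev.end) is <= gap.

    Matches ``bedtools merge -d gap``: overlapping or book-ended intervals
    always merge; intervals on different chromosomes never merge.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    validate_intervals(df)
    if df.empty:
        return df[["chrom", "start", "end"]].copy()
    df = _sorted(df)
    out: list[tuple[str, int, int]] = []
    cur_chrom, cur_start, cur_end = None, 0, 0
    for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
        if chrom == cur_chrom and start - cur_end <= gap:
            cur_end = max(cur_end, end)
        else:
            if cur_chrom is not None:
                out.append((cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = chrom, start, end
    out.append((cur_chrom, cur_start, cur_end))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def complement(genes: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    """Intergenic space: per-chromosome set complement of the merged genes."""
    validate_intervals(genes, layout)
    merged = merge_with_gap(genes, 0) if not genes.empty else genes
    out: list[tuple[str, int, int]] = []
    for chrom, length in zip(layout.names, layout.lengths):
        pos = 0
        if not genes.empty:
            for start, end in merged[merged["chrom"] == chrom][["start", "end"]].itertuples(index=False):
                if start > pos:
                    out.append((chrom, pos, start))
                pos = max(pos, end)
        if pos < length:
            out.append((chrom, pos, length))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def intersect_count(regions: pd.DataFrame, genes: pd.DataFrame) -> np.ndarray:
    """Number of genes overlapping each region by >= 1 bp (region order kept)."""
    validate_intervals(regions)
    validate_intervals(genes)
    counts = np.zeros(len(regions), dtype=np.int64)
    if regions.empty or genes.empty:
        return counts
    by_chrom = {c: (sub["start"].to_numpy(), sub["end"].to_numpy())
                for c, sub in genes.groupby("chrom", sort=False)}
    for i, (chrom, start, end) in enumerate(
        zip(regions["chrom"], regions["start"], regions["end"])
    ):
        if chrom not in by_chrom:
            continue
        gs, ge = by_chrom[chrom]
        counts[i] = int(np.count_nonzero((gs < end) & (ge > start)))
    return counts


def gene_count_histogram(counts: np.ndarray) -> dict[str, int]:
    """Bucket per-region gene counts into {0, 1, >1}."""
    counts = np.asarray(counts)
    return {
        "0": int((counts == 0).sum()),
        "1": int((counts == 1).sum()),
        ">1": int((counts > 1).sum()),
    }


def shuffle_into(
    regions: pd.DataFrame,
    allowed: pd.DataFrame,
    n_shuffles: int,
    seed: int | np.random.Generator,
    same_chrom: bool = False,
    no_self_overlap: bool = False,
) -> list[pd.DataFrame]:
    """Place each region uniformly at random fully inside the allowed set.

    Placement is uniform over eligible integer start positions; lengths are
    preserved. By default placements are independent (shuffled regions may
    overlap one another) and may land on any chromosome, matching bedtools
    shuffle defaults; ``same_chrom`` restricts to the source chromosome and
    ``no_self_overlap`` rejection-samples non-overlapping placements.
    """
    validate_intervals(regions)
    validate_intervals(allowed)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    allowed = _sorted(allowed)
    a_chrom = allowed["chrom"].to_numpy()
    a_start = allowed["start"].to_numpy(dtype=np.int64)
    a_len = (allowed["end"] - allowed["start"]).to_numpy(dtype=np.int64)

    shuffles: list[pd.DataFrame] = []
    for _ in range(n_shuffles):
        placed: list[tuple[str, int, int]] = []
        for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
            length = end - start
            ok = a_len >= length
            if same_chrom:
                ok &= a_chrom == chrom
            slots = a_len[ok] - length + 1
            if slots.size == 0:
                raise ValueError(
                    f"region {chrom}:{start}-{end} (len {length}) does not fit "
                    "in any allowed interval"
                )
            idx = np.flatnonzero(ok)
            for _attempt in range(1000):
                j = idx[rng.choice(slots.size, p=slots / slots.sum())]
                new_start = int(a_start[j] + rng.integers(a_len[j] - length + 1))
                cand = (str(a_chrom[j]), new_start, new_start + length)
                if not no_self_overlap or not any(
                    c == cand[0] and s < cand[2] and e > cand[1] for c, s, e in placed
                ):
                    placed.append(cand)
                    break
            else:
                raise RuntimeError("could not place region without self-overlap")
        shuffles.append(pd.DataFrame(placed, columns=["chrom", "start", "end"]))
    return shuffles


# ---------------------------------------------------------------------------
# Text-format IO (bedGraph / BED / chrom.sizes)
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("track", "browser", "#")


def _read_table(path, names: list[str]) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            rows.append(line.split())
    if not rows:
        return pd.DataFrame(columns=names)
    width = min(len(names), min(len(r) for r in rows))
    df = pd.DataFrame([r[:width] for r in rows], columns=names[:width])
    return df


def read_bedgraph(path) -> pd.DataFrame:
    """4-column bedGraph; tolerates track/browser/comment lines, tab or space."""
    df = _read_table(path, ["chrom", "start", "end", "value"])
    if "value" not in df.columns:
        raise ValueError(f"{path}: bedGraph needs 4 columns")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    out = _sorted(df)[["chrom", "start", "end", "value"]].copy()
    # keep integer counts integer so round-trips are exact
    vals = out["value"].to_numpy()
    if np.all(vals == np.floor(vals)):
        out["value"] = out["value"].astype(np.int64)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """BED up to 6 columns (chrom, start, end, name, score, strand)."""
    df = _read_table(path, ["chrom", "start", "end", "name", "score", "strand"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if "score" in df.columns:
        try:
            df["score"] = pd.to_numeric(df["score"])
        except (ValueError, TypeError):
            pass  # non-numeric scores (e.g. ".") stay as strings
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in df.columns]
    _sorted(df)[cols].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path) -> GenomeLayout:
    df = _read_table(path, ["chrom", "length"])
    return GenomeLayout(tuple(df["chrom"]), tuple(df["length"].astype(np.int64)))


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(layout.names, layout.lengths):
            fh.write(f"{name}\t{length}\n")
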