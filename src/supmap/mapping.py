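"""Hawaiian-SNP frequency mapping.

The causal region of a selected recombinant pool is depleted of the
polymorphic strain's marker alleles.  This module computes the per-marker
B-allele (Hawaiian) frequency track from pooled counts, tiles it into
fixed-size windows, calls contiguous low-frequency intervals (absence mode
for recessive suppressors, reduction mode for dominant/semi-dominant ones),
subtracts the known introgression gaps, and classifies the run outcome.

The interval caller is this package's codification of what is, in the
original protocol, a visual inspection of the SNP-frequency plot; every
constant lives in :class:`MappingParams` and is recorded in output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd


@dataclass
class MappingParams:
    window_size: int = 500_000  # bp
    min_markers_per_window: int = 5
    absence_threshold: float = 0.10  # recessive mode
    reduction_threshold: float = 0.30  # dominant/semi-dominant mode (package default,
    #                                    not a protocol constant)
    display_min_freq: float = 0.20  # plotting view only
    min_depth: int = 4  # reads
    merge_gap: int = 1  # windows bridged between low runs
    min_interval_span: int = 500_000  # bp
    min_residual_span: int | None = None  # after gap subtraction; defaults to above

    def __post_init__(self):
        if not 0.0 <= self.absence_threshold < self.reduction_threshold < 0.5:
            raise ValueError(
                "need 0 <= absence_threshold < reduction_threshold < 0.5")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")

    def threshold(self, mode: str) -> float:
        if mode == "recessive":
            return self.absence_threshold
        if mode in ("dominant", "semidominant"):
            return self.reduction_threshold
        raise ValueError(f"unknown mapping mode {mode!r}")


@dataclass
class IntervalCall:
    chrom: str
    start: int  # outermost sub-threshold marker positions, 1-based
    end: int
    mean_freq: float
    n_markers: int
    mode: str
    unique: bool = True

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("interval start must be below end")

    @property
    def span(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end

    def to_dict(self) -> dict:
        return asdict(self)


def marker_frequencies(pool_df: pd.DataFrame, markers_df: pd.DataFrame,
                       min_depth: int = 4) -> tuple[pd.DataFrame, dict]:
    """Observed B-allele frequency per known marker.

    Only marker sites are used (novel variants are ignored); markers below
    ``min_depth`` — including markers absent from the pool file, treated as
    depth 0 — are dropped and tallied in the coverage report.
    """
    pool_markers = (pool_df[pool_df["is_marker"].astype(bool)]
                    if "is_marker" in pool_df else pool_df)
    merged = markers_df[["chrom", "pos"]].merge(
        pool_markers[["chrom", "pos", "freq", "depth"]], on=["chrom", "pos"], how="left")
    merged["depth"] = pd.to_numeric(merged["depth"]).fillna(0).astype(int)
    merged["freq"] = pd.to_numeric(merged["freq"])
    missing = int(merged["freq"].isna().sum())
    track = merged[merged["depth"] >= max(min_depth, 1)].reset_index(drop=True)
    report = {
        "n_markers": int(len(merged)),
        "n_missing_from_pool": missing,
        "n_below_min_depth": int(len(merged) - len(track)),
        "n_in_track": int(len(track)),
        "min_depth": int(min_depth),
    }
    track = track.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return track, report


def display_filter(track: pd.DataFrame, display_min_freq: float = 0.20) -> pd.DataFrame:
    """The plotting view: only frequencies strictly above the display floor.
    Never used for interval calling."""
    return track[track["freq"] > display_min_freq].reset_index(drop=True)


def window_stats(track: pd.DataFrame, params: MappingParams,
                 chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Tile each chromosome into fixed windows and average marker frequencies.

    Every tile appears in the output (marker count possibly 0); windows with
    fewer than ``min_markers_per_window`` markers are flagged uninformative
    and excluded from interval calling.  Window means are unweighted: one
    marker, one vote.
    """
    w = params.window_size
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = track[track["chrom"] == chrom]
        idx = ((sub["pos"] - 1) // w).astype(int) if len(sub) else pd.Series(dtype=int)
        grouped = sub.groupby(idx)["freq"] if len(sub) else None
        means = grouped.mean() if grouped is not None else {}
        counts = grouped.size() if grouped is not None else {}
        n_windows = int(np.ceil(length / w))
        for i in range(n_windows):
            n = int(counts.get(i, 0)) if len(sub) else 0
            mean = float(means.get(i, np.nan)) if n else np.nan
            rows.append((chrom, i, i * w + 1, min((i + 1) * w, length), mean, n,
                         n >= params.min_markers_per_window))
    return pd.DataFrame(rows, columns=["chrom", "window", "start", "end", "mean_freq",
                                       "n_markers", "informative"])


def call_intervals(windows: pd.DataFrame, track: pd.DataFrame, mode: str,
                   params: MappingParams) -> list[IntervalCall]:
    """Contiguous runs of informative low-frequency windows -> intervals.

    Runs may bridge up to ``merge_gap`` intervening windows; interval bounds
    snap to the outermost sub-threshold marker positions inside the run's low
    windows; intervals narrower than ``min_interval_span`` are dropped.
    """
    thr = params.threshold(mode)
    informative = windows[windows["informative"]]
    if informative.empty:
        warnings.warn("no informative windows; cannot call intervals", stacklevel=2)
        return []
    intervals: list[IntervalCall] = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        low = sub[(sub["informative"]) & (sub["mean_freq"] <= thr)]["window"].to_numpy()
        if low.size == 0:
            continue
        runs: list[list[int]] = [[int(low[0])]]
        for i in low[1:]:
            if int(i) - runs[-1][-1] <= params.merge_gap + 1:
                runs[-1].append(int(i))
            else:
                runs.append([int(i)])
        w = params.window_size
        for run in runs:
            in_low_windows = track[
                (track["chrom"] == chrom)
                & (((track["pos"] - 1) // w).isin(run))]
            if in_low_windows.empty:
                continue
            sub_thr = in_low_windows[in_low_windows["freq"] <= thr]
            if sub_thr.empty:
                continue
            start, end = int(sub_thr["pos"].min()), int(sub_thr["pos"].max())
            if end - start < params.min_interval_span:
                continue
            intervals.append(IntervalCall(
                chrom, start, end, float(in_low_windows["freq"].mean()),
                int(len(in_low_windows)), mode))
    return intervals


def subtract_known_gaps(intervals: list[IntervalCall],
                        gaps: list[tuple[str, int, int]],
                        min_residual_span: int) -> list[IntervalCall]:
    """Flag intervals explained by the introgression gaps.

    Gaps are half-open genomic ranges.  Intervals fully inside the gap union
    are marked non-unique; partial overlaps are trimmed to their largest
    residual outside the gaps and kept (unique) only if the residual spans at
    least ``min_residual_span``.
    """
    out = []
    for iv in intervals:
        pieces = [(iv.start, iv.end)]
        for chrom, gstart, gend in gaps:
            if chrom != iv.chrom:
                continue
            nxt = []
            for s, e in pieces:
                if e <= gstart or s > gend:  # no overlap (gap covers (gstart, gend])
                    nxt.append((s, e))
                    continue
                if s <= gstart:
                    nxt.append((s, min(e, gstart)))
                if e > gend:
                    nxt.append((max(s, gend), e))
            pieces = [(s, e) for s, e in nxt if e > s]
        pieces = [(s, e) for s, e in pieces if e - s >= min_residual_span]
        if not pieces:
            out.append(IntervalCall(iv.chrom, iv.start, iv.end, iv.mean_freq,
                                    iv.n_markers, iv.mode, unique=False))
        else:
            s, e = max(pieces, key=lambda p: p[1] - p[0])
            out.append(IntervalCall(iv.chrom, s, e, iv.mean_freq, iv.n_markers,
                                    iv.mode, unique=True))
    return out


def classify_outcome(intervals: list[IntervalCall],
                     target_gene_hits: int = 0) -> tuple[str, dict]:
    """Run outcome from the unique intervals that survive gap subtraction.

    Exactly one unique interval -> ``extragenic_mapped``; none but a
    qualifying new variant in the target gene -> ``linked_to_target``;
    neither -> ``unmapped``; several unique intervals -> ``ambiguous`` with
    all of them listed.
    """
    unique = [iv for iv in intervals if iv.unique]
    details = {
        "n_intervals": len(intervals),
        "n_unique": len(unique),
        "unique_intervals": [iv.to_dict() for iv in unique],
        "target_gene_hits": int(target_gene_hits),
    }
    if len(unique) == 1:
        return "extragenic_mapped", details
    if len(unique) > 1:
        return "ambiguous", details
    if target_gene_hits > 0:
        return "linked_to_target", details
    return "unmapped", details
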