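"""50-nt window partitioning of 3'UTRs, hotspot calling and window features.

Expressed 3'UTRs are tiled with non-overlapping 50-nt windows (a trailing
remainder is kept as a shorter final window). Each positive-enrichment
CLIP cluster contributes its RBP to the single window containing the
cluster center; a window with >= 5 distinct RBPs is a hotspot. miRNA
target seeds are uniquely assigned to the window they overlap by more
than 5 nt, otherwise discarded.

The independence null redistributes each RBP's occupied-window count
uniformly over all windows (10000 simulations by default) and reports the
per-size count distribution with a 2.5-97.5 percentile envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mirna_sites import TargetSite

WINDOW_WIDTH = 50
MIN_HOTSPOT_RBPS = 5
SITE_WINDOW_MIN_OVERLAP = 5

MIRNA_NONE = "none"
MIRNA_EXPRESSED = "expressed"
MIRNA_UNEXPRESSED = "unexpressed"


@dataclass
class Window:
    utr_id: str
    index: int
    start: int
    end: int
    rbps: set[str] = field(default_factory=set)
    mirna_overlap: str = MIRNA_NONE
    mean_phylop: float = np.nan
    maf_sum: float = 0.0
    accessibility: float = np.nan
    composition: dict[str, float] | None = None
    are_count: int = 0
    background_flag: bool = False

    @property
    def n_rbps(self) -> int:
        return len(self.rbps)


def partition_windows(utr_len: int, utr_id: str, width: int = WINDOW_WIDTH) -> list[Window]:
    """Tile a UTR with consecutive windows [0,50), [50,100), ...; the
    trailing remainder is kept as a shorter final window."""
    if utr_len <= 0:
        raise ValueError("UTR length must be positive")
    starts = range(0, utr_len, width)
    return [
        Window(utr_id, i, s, min(s + width, utr_len))
        for i, s in enumerate(starts)
    ]


def assign_cluster_centers(
    windows: list[Window],
    centers_by_rbp: dict[str, list[int]],
    width: int = WINDOW_WIDTH,
) -> list[Window]:
    """Add each RBP to the single window containing each cluster center.

    Multiple clusters of one RBP in one window count once. Centers must be
    transcript-frame positions inside the UTR.
    """
    utr_len = windows[-1].end
    for rbp, centers in centers_by_rbp.items():
        for c in centers:
            if not 0 <= c < utr_len:
                raise ValueError(
                    f"cluster center {c} outside UTR {windows[0].utr_id}"
                )
            windows[c // width].rbps.add(rbp)
    return windows


def assign_sites_to_windows(
    windows: list[Window],
    sites: list[TargetSite],
    expressed_flags: dict[str, bool],
    min_overlap: int = SITE_WINDOW_MIN_OVERLAP,
) -> tuple[list[Window], list[TargetSite]]:
    """Uniquely assign each seed site to the window it overlaps by more
    than ``min_overlap`` nt; sites with no such window are discarded.

    ``expressed_flags`` maps mirna_id to its expression flag; a window is
    labeled 'expressed' if any assigned site involves an expressed miRNA.
    Returns (windows, assigned sites).
    """
    assigned = []
    for s in sites:
        best, best_ov = None, min_overlap
        for w in windows:
            ov = min(s.seed_end, w.end) - max(s.seed_start, w.start)
            if ov > best_ov:
                best, best_ov = w, ov
        if best is None:
            continue
        assigned.append(s)
        expressed = any(expressed_flags.get(m, False) for m, _ in s.mirnas)
        if expressed:
            best.mirna_overlap = MIRNA_EXPRESSED
        elif best.mirna_overlap == MIRNA_NONE:
            best.mirna_overlap = MIRNA_UNEXPRESSED
    return windows, assigned


def call_hotspots(windows: list[Window], min_rbps: int = MIN_HOTSPOT_RBPS) -> np.ndarray:
    """Hotspot flag per window: >= min_rbps distinct RBPs."""
    return np.array([w.n_rbps >= min_rbps for w in windows])


@dataclass
class UniformNull:
    """Null distribution of window-size counts under independent uniform
    placement of each RBP's occupied windows."""

    n_sims: int
    size_counts: np.ndarray  # (n_sims, max_size+1); column k = windows with exactly k RBPs
    lo: np.ndarray  # per-size 2.5th percentile
    hi: np.ndarray  # per-size 97.5th percentile

    def hotspot_count_band(self, min_rbps: int = MIN_HOTSPOT_RBPS) -> tuple[float, float, np.ndarray]:
        """(2.5th, 97.5th percentile, per-sim counts) of windows with
        >= min_rbps RBPs."""
        per_sim = self.size_counts[:, min_rbps:].sum(axis=1)
        return (
            float(np.percentile(per_sim, 2.5)),
            float(np.percentile(per_sim, 97.5)),
            per_sim,
        )


def simulate_uniform_null(
    per_rbp_window_counts: dict[str, int],
    total_windows: int,
    rng,
    n_sims: int = 10000,
) -> UniformNull:
    """Redistribute each RBP's occupied windows uniformly without
    replacement over all windows, ``n_sims`` times."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    counts = list(per_rbp_window_counts.values())
    for rbp, c in per_rbp_window_counts.items():
        if c > total_windows:
            raise ValueError(
                f"{rbp} occupies {c} windows > total {total_windows}"
            )
    n_rbps = len(counts)
    size_counts = np.zeros((n_sims, n_rbps + 1), dtype=np.int64)
    occupancy = np.zeros(total_windows, dtype=np.int16)
    for s in range(n_sims):
        occupancy[:] = 0
        for c in counts:
            occupancy[rng.choice(total_windows, size=c, replace=False)] += 1
        bc = np.bincount(occupancy, minlength=n_rbps + 1)
        size_counts[s] = bc[: n_rbps + 1]
    lo = np.percentile(size_counts, 2.5, axis=0)
    hi = np.percentile(size_counts, 97.5, axis=0)
    return UniformNull(n_sims, size_counts, lo, hi)


def positional_bin_profile(
    item_positions: dict[str, np.ndarray],
    utr_lengths: dict[str, int],
    n_bins: int = 50,
) -> np.ndarray:
    """Per-bin density of items along length-normalized 3'UTRs, as the
    ratio to the across-bin mean.

    ``item_positions`` maps utr_id to item positions (nt). Each UTR is
    divided into ``n_bins`` equal bins; the per-nucleotide item density per
    bin is averaged over UTRs, then expressed relative to the mean bin
    value. Returns NaN everywhere if there are no items.
    """
    sums = np.zeros(n_bins)
    n_utrs = 0
    for uid, l in utr_lengths.items():
        pos = np.asarray(item_positions.get(uid, ()), dtype=float)
        binned = np.zeros(n_bins)
        if pos.size:
            idx = np.minimum((pos / l * n_bins).astype(int), n_bins - 1)
            binned = np.bincount(idx, minlength=n_bins).astype(float)
        sums += binned / (l / n_bins)
        n_utrs += 1
    profile = sums / max(n_utrs, 1)
    mean = profile.mean()
    if mean == 0:
        return np.full(n_bins, np.nan)
    return profile / mean


def count_are(sequence: str, motif: str = "AUUUA") -> int:
    """Overlapping occurrences of the ARE core pentamer."""
    seq = sequence.upper().replace("T", "U")
    count = start = 0
    while True:
        idx = seq.find(motif, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def window_feature_stats(
    window: Window,
    conservation: np.ndarray | None = None,
    mafs: list[tuple[int, float]] | None = None,
    accessibility: float | np.ndarray | None = None,
    sequence: str | None = None,
) -> Window:
    """Fill a window's feature fields from transcript-frame tracks.

    conservation: per-position phyloP with NaN for unalignable positions
    (mean over defined positions; NaN if none). mafs: (position, MAF) pairs
    of qualifying variants over the UTR; summed within the window.
    accessibility: per-window scalar or per-position values (averaged).
    sequence: the full UTR sequence; composition and overlapping AUUUA
    counts are computed on the window slice.
    """
    s, e = window.start, window.end
    if conservation is not None:
        vals = np.asarray(conservation[s:e], dtype=float)
        defined = vals[~np.isnan(vals)]
        window.mean_phylop = float(defined.mean()) if defined.size else np.nan
    if mafs is not None:
        window.maf_sum = float(sum(m for pos, m in mafs if s <= pos < e))
    if accessibility is not None:
        acc = np.asarray(accessibility, dtype=float)
        window.accessibility = float(acc.mean()) if acc.ndim else float(acc)
    if sequence is not None:
        sub = sequence[s:e].upper().replace("T", "U")
        n = len(sub)
        window.composition = {b: sub.count(b) / n for b in "AUCG"}
        window.are_count = count_are(sub)
    return window


def windows_to_frame(windows: list[Window], min_rbps: int = MIN_HOTSPOT_RBPS) -> pd.DataFrame:
    """Flatten windows into a table (one row per window)."""
    return pd.DataFrame(
        {
            "utr_id": [w.utr_id for w in windows],
            "index": [w.index for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_rbps": [w.n_rbps for w in windows],
            "rbps": [";".join(sorted(w.rbps)) for w in windows],
            "hotspot": [w.n_rbps >= min_rbps for w in windows],
            "mirna_overlap": [w.mirna_overlap for w in windows],
            "mean_phylop": [w.mean_phylop for w in windows],
            "maf_sum": [w.maf_sum for w in windows],
            "accessibility": [w.accessibility for w in windows],
            "are_count": [w.are_count for w in windows],
            "background_flag": [w.background_flag for w in windows],
        }
    )


def feature_vs_rbp_correlation(
    table: pd.DataFrame,
    feature: str,
    stratum: str | None = None,
) -> tuple[float, float]:
    """Spearman correlation of per-window RBP count vs a feature column,
    optionally within one mirna_overlap stratum."""
    df = table if stratum is None else table[table["mirna_overlap"] == stratum]
    df = df.dropna(subset=[feature])
    if len(df) < 10:
        raise ValueError(f"fewer than 10 windows in stratum {stratum!r}")
    if df[feature].nunique() == 1:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(df["n_rbps"], df[feature])
    return float(rho), float(p)


def filter_background_windows(
    windows: list[Window],
    gfp_centers: dict[str, list[int]],
    min_rbps: int = MIN_HOTSPOT_RBPS,
    width: int = WINDOW_WIDTH,
) -> tuple[list[Window], dict[str, float]]:
    """Flag and drop windows containing a background (GFP) cluster center.

    ``gfp_centers`` maps utr_id to transcript-frame centers of GFP clusters
    processed identically to RBP clusters. Returns the filtered windows and
    {fraction of hotspot windows flagged, fraction of GFP centers landing
    in hotspot windows}.
    """
    by_key: dict[tuple[str, int], Window] = {
        (w.utr_id, w.index): w for w in windows
    }
    n_gfp = n_gfp_in_hotspot = 0
    for uid, centers in gfp_centers.items():
        for c in centers:
            w = by_key.get((uid, c // width))
            if w is None:
                continue
            w.background_flag = True
            n_gfp += 1
            if w.n_rbps >= min_rbps:
                n_gfp_in_hotspot += 1
    hotspots = [w for w in windows if w.n_rbps >= min_rbps]
    flagged_hot = sum(w.background_flag for w in hotspots)
    kept = [w for w in windows if not w.background_flag]
    stats_out = {
        "frac_hotspots_flagged": flagged_hot / len(hotspots) if hotspots else 0.0,
        "frac_gfp_in_hotspots": n_gfp_in_hotspot / n_gfp if n_gfp else 0.0,
    }
    return kept, stats_out
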