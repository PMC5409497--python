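"""Distance-lagged positional correlation of RBP enrichment profiles.

For two enrichment tracks x, y on the same 3'UTR of length l, the lag-d
Pearson correlation is computed over the overlapping index range
(i in [0, l-d) for d >= 0; i in [-d, l) for d < 0), for every lag d in
[-max_lag, +max_lag]. Per-lag correlations are averaged over 3'UTRs
(UTRs shorter than 400 nt are discarded).

The null preserves the clustering of CLIP tags: contiguous runs with
enrichment above a small threshold are relocated, order preserved, to
uniformly random positions with at least one empty position between
clusters. Repeating the shuffle (default 100 times) gives a per-lag null
mean and sd from which z-scores for the unshuffled data are computed.

All-lag correlations are evaluated with an FFT cross-correlation plus
prefix-sum moments; :func:`lagged_pearson` is the direct sliced-slice
formula used both as the simple API and as an internal cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

MAX_LAG = 200
MIN_UTR_LEN = 400
SIGNAL_THRESHOLD = 1e-6

_VAR_RTOL = 1e-9


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def lagged_pearson(
    x: np.ndarray,
    y: np.ndarray,
    d: int,
    *,
    min_len: int = MIN_UTR_LEN,
    max_lag: int = MAX_LAG,
) -> float:
    """Pearson correlation of x[i] with y[i+d] over the overlap window.

    Returns NaN if either slice has zero variance. Tracks shorter than
    ``min_len`` are rejected (callers filter UTRs < 400 nt upstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    l = len(x)
    if len(y) != l:
        raise ValueError("tracks must have equal length")
    if l < min_len:
        raise ValueError(f"track length {l} < minimum {min_len}")
    if abs(d) > max_lag:
        raise ValueError(f"|lag| {abs(d)} exceeds max_lag {max_lag}")
    if d >= 0:
        a, b = x[: l - d], y[d:]
    else:
        a, b = x[-d:], y[: l + d]
    va = a.var()
    vb = b.var()
    if va <= _VAR_RTOL * max(1.0, (a * a).mean()) or vb <= _VAR_RTOL * max(
        1.0, (b * b).mean()
    ):
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _batch_lagged_pearson(X: np.ndarray, Y: np.ndarray, max_lag: int) -> np.ndarray:
    """All-lag Pearson for paired rows of X and Y, shape (T, l) each.

    Returns (T, 2*max_lag+1) with lag order -max_lag..+max_lag; undefined
    (zero-variance) entries are NaN.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    l = X.shape[1]
    nfft = next_fast_len(l + max_lag)
    fx = rfft(X, nfft, axis=1)
    fy = rfft(Y, nfft, axis=1)
    return _pair_from_ffts(X, Y, fx, fy, nfft, max_lag)


def lagged_pearson_all(
    x: np.ndarray, y: np.ndarray, max_lag: int = MAX_LAG
) -> np.ndarray:
    """All-lag Pearson profile for one track pair; lag order -max_lag..max_lag."""
    return _batch_lagged_pearson(x[None, :], y[None, :], max_lag)[0]


@dataclass
class LagCorrelationProfile:
    """Per-lag Pearson correlation averaged over 3'UTRs."""

    rbp_a: str
    rbp_b: str
    lags: np.ndarray
    r_mean: np.ndarray
    n_utrs: np.ndarray


@dataclass
class ShuffleNull:
    """Per-lag mean and sd of the averaged correlation over shuffles."""

    n_shuffles: int
    mean: np.ndarray
    sd: np.ndarray


def average_profile(per_utr: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted per-lag mean over UTRs, skipping undefined (NaN) values.

    Returns (mean, n_contributing); lags with zero contributors are NaN.
    """
    stack = np.vstack(per_utr)
    counts = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, np.nansum(stack, axis=0) / np.maximum(counts, 1), np.nan)
    return mean, counts


def extract_signal_clusters(
    x: np.ndarray, threshold: float = SIGNAL_THRESHOLD
) -> list[tuple[int, int]]:
    """Maximal runs of positions with value > threshold, in order."""
    mask = np.asarray(x) > threshold
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def shuffle_clusters(
    x: np.ndarray, rng, threshold: float = SIGNAL_THRESHOLD
) -> np.ndarray:
    """Relocate signal clusters to uniformly random positions.

    Cluster order and each cluster's internal value sequence are preserved;
    at least one empty position separates consecutive clusters; background
    is zero. The gap composition is drawn uniformly over all feasible
    arrangements (stars-and-bars sampling), so placement is exactly uniform.
    """
    rng = _as_rng(rng)
    x = np.asarray(x, dtype=float)
    n = len(x)
    clusters = extract_signal_clusters(x, threshold)
    out = np.zeros(n)
    m = len(clusters)
    if m == 0:
        return out
    lengths = [e - s for s, e in clusters]
    total = sum(lengths)
    slack = n - total - (m - 1)
    if slack < 0:
        raise ValueError(
            f"cannot place {m} clusters of total length {total} with unit gaps "
            f"in a track of length {n}"
        )
    # uniform composition of `slack` into m+1 non-negative gaps
    if m == 1:
        parts = np.zeros(2, dtype=int)
        parts[0] = rng.integers(0, slack + 1)
        parts[1] = slack - parts[0]
    else:
        bars = np.sort(rng.choice(slack + m, size=m, replace=False))
        padded = np.concatenate(([-1], bars, [slack + m]))
        parts = np.diff(padded) - 1
    pos = int(parts[0])
    for (s, e), extra in zip(clusters, parts[1:]):
        out[pos : pos + (e - s)] = x[s:e]
        pos += (e - s) + 1 + int(extra)
    return out


def pair_lag_profile(
    tracks_a: dict[str, np.ndarray],
    tracks_b: dict[str, np.ndarray],
    *,
    max_lag: int = MAX_LAG,
    min_len: int = MIN_UTR_LEN,
    rbp_a: str = "A",
    rbp_b: str = "B",
) -> LagCorrelationProfile:
    """Observed lag-correlation profile for one RBP pair over shared UTRs."""
    per_utr = []
    for uid, x in tracks_a.items():
        y = tracks_b.get(uid)
        if y is None or len(x) < min_len:
            continue
        per_utr.append(_batch_lagged_pearson(x[None, :], y[None, :], max_lag)[0])
    if not per_utr:
        raise ValueError("no UTR passes the length filter for this pair")
    mean, counts = average_profile(per_utr)
    lags = np.arange(-max_lag, max_lag + 1)
    return LagCorrelationProfile(rbp_a, rbp_b, lags, mean, counts)


def shuffle_null_profile(
    tracks_a: dict[str, np.ndarray],
    tracks_b: dict[str, np.ndarray],
    rng,
    *,
    n_shuffles: int = 100,
    max_lag: int = MAX_LAG,
    min_len: int = MIN_UTR_LEN,
    threshold: float = SIGNAL_THRESHOLD,
) -> ShuffleNull:
    """Cluster-preserving shuffle null for one pair.

    Each shuffle relocates the clusters of both tracks on every UTR, then
    the per-lag UTR-averaged correlation is recorded; the per-lag mean and
    sample sd over shuffles are returned.
    """
    rng = _as_rng(rng)
    n_lags = 2 * max_lag + 1
    sums = np.zeros((n_shuffles, n_lags))
    counts = np.zeros((n_shuffles, n_lags))
    used = 0
    for uid, x in tracks_a.items():
        y = tracks_b.get(uid)
        if y is None or len(x) < min_len:
            continue
        X = np.vstack([shuffle_clusters(x, rng, threshold) for _ in range(n_shuffles)])
        Y = np.vstack([shuffle_clusters(y, rng, threshold) for _ in range(n_shuffles)])
        r = _batch_lagged_pearson(X, Y, max_lag)
        ok = ~np.isnan(r)
        sums += np.where(ok, r, 0.0)
        counts += ok
        used += 1
    if used == 0:
        raise ValueError("no UTR passes the length filter for this pair")
    with np.errstate(invalid="ignore"):
        r_mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ShuffleNull(
        n_shuffles, np.nanmean(r_mean, axis=0), np.nanstd(r_mean, axis=0, ddof=1)
    )


def zscore_profile(observed: LagCorrelationProfile, null: ShuffleNull) -> np.ndarray:
    """Per-lag z = (r_obs - null_mean) / null_sd; NaN where sd == 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (observed.r_mean - null.mean) / null.sd
    z[~np.isfinite(z)] = np.nan
    return z


@dataclass
class ZScoreMatrix:
    """Z-scores for ordered RBP pairs (rows) by lag (columns)."""

    pairs: list[tuple[str, str]]
    lags: np.ndarray
    z: np.ndarray
    row_normalized: bool = False
    n_quantile_bins: int = 1000

    def row_normalize(self) -> "ZScoreMatrix":
        """(z - row mean) / row sd per pair row."""
        mean = np.nanmean(self.z, axis=1, keepdims=True)
        sd = np.nanstd(self.z, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            zn = (self.z - mean) / sd
        return ZScoreMatrix(self.pairs, self.lags, zn, True, self.n_quantile_bins)

    def quantile_bins(self) -> np.ndarray:
        """Bin index (0 .. n_quantile_bins-1) of each finite z value, for
        quantile-based color mapping."""
        flat = self.z[np.isfinite(self.z)]
        order = np.argsort(np.argsort(flat))
        return (order * self.n_quantile_bins) // len(flat)


def pairwise_zscore_matrix(
    profiles_by_rbp: dict[str, dict[str, np.ndarray]],
    rng,
    *,
    n_shuffles: int = 100,
    max_lag: int = MAX_LAG,
    min_len: int = MIN_UTR_LEN,
    threshold: float = SIGNAL_THRESHOLD,
) -> ZScoreMatrix:
    """Observed-vs-null z-scores for all ordered RBP pairs (self included).

    All pairs are evaluated over the same UTR universe (UTRs >= min_len
    present for every RBP). Each RBP's track on each UTR is shuffled
    ``n_shuffles`` times; the same shuffle replicates are shared across all
    pairs involving that RBP, matching a shuffle-everything-then-correlate
    protocol. Replicate t of track a is correlated with replicate t of
    track b, and r(a, b, d) == r(b, a, -d) is exploited so each unordered
    pair is computed once.
    """
    rng = _as_rng(rng)
    rbps = sorted(profiles_by_rbp)
    utr_ids = sorted(
        set.intersection(*(set(profiles_by_rbp[r]) for r in rbps))
    )
    utr_ids = [
        u for u in utr_ids if len(profiles_by_rbp[rbps[0]][u]) >= min_len
    ]
    if not utr_ids:
        raise ValueError("no UTR passes the length filter")
    n_lags = 2 * max_lag + 1
    T = n_shuffles + 1  # row 0 observed, rows 1..T shuffled
    unordered = [(a, b) for i, a in enumerate(rbps) for b in rbps[i:]]
    sums = {p: np.zeros((T, n_lags)) for p in unordered}
    counts = {p: np.zeros((T, n_lags)) for p in unordered}

    for uid in utr_ids:
        l = len(profiles_by_rbp[rbps[0]][uid])
        nfft = next_fast_len(l + max_lag)
        reps: dict[str, np.ndarray] = {}
        ffts: dict[str, np.ndarray] = {}
        for r in rbps:
            x = profiles_by_rbp[r][uid]
            A = np.empty((T, l))
            A[0] = x
            for t in range(1, T):
                A[t] = shuffle_clusters(x, rng, threshold)
            reps[r] = A
            ffts[r] = rfft(A, nfft, axis=1)
        for a, b in unordered:
            if a == b:
                # pair each shuffle with a different shuffle of the same
                # track, else the self-pair null is degenerate (r == 1 at
                # d = 0 in every replicate)
                perm = np.concatenate(([0], np.roll(np.arange(1, T), -1)))
                r_ab = _pair_from_ffts(
                    reps[a], reps[b][perm], ffts[a], ffts[b][perm], nfft, max_lag
                )
            else:
                r_ab = _pair_from_ffts(
                    reps[a], reps[b], ffts[a], ffts[b], nfft, max_lag
                )
            ok = ~np.isnan(r_ab)
            sums[(a, b)] += np.where(ok, r_ab, 0.0)
            counts[(a, b)] += ok

    pairs = [(a, b) for a in rbps for b in rbps]
    z = np.full((len(pairs), n_lags), np.nan)
    for row, (a, b) in enumerate(pairs):
        key, flip = ((a, b), False) if (a, b) in sums else ((b, a), True)
        with np.errstate(invalid="ignore"):
            r_mean = np.where(
                counts[key] > 0, sums[key] / np.maximum(counts[key], 1), np.nan
            )
        if flip:
            r_mean = r_mean[:, ::-1]
        null_mean = np.nanmean(r_mean[1:], axis=0)
        null_sd = np.nanstd(r_mean[1:], axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            zr = (r_mean[0] - null_mean) / null_sd
        zr[~np.isfinite(zr)] = np.nan
        z[row] = zr
    return ZScoreMatrix(pairs, np.arange(-max_lag, max_lag + 1), z)


def _pair_from_ffts(A, B, fa, fb, nfft, max_lag):
    """All-lag Pearson for paired replicate rows given precomputed FFTs."""
    T, l = A.shape
    cc = irfft(np.conj(fa) * fb, nfft, axis=1)
    zero = np.zeros((T, 1))
    cx = np.concatenate([zero, np.cumsum(A, axis=1)], axis=1)
    cx2 = np.concatenate([zero, np.cumsum(A * A, axis=1)], axis=1)
    cy = np.concatenate([zero, np.cumsum(B, axis=1)], axis=1)
    cy2 = np.concatenate([zero, np.cumsum(B * B, axis=1)], axis=1)
    lags = np.arange(-max_lag, max_lag + 1)
    e = np.abs(lags)
    n = (l - e).astype(float)
    pos = lags >= 0
    sx = np.where(pos, cx[:, l - e], cx[:, [l]] - cx[:, e])
    sxx = np.where(pos, cx2[:, l - e], cx2[:, [l]] - cx2[:, e])
    sy = np.where(pos, cy[:, [l]] - cy[:, e], cy[:, l - e])
    syy = np.where(pos, cy2[:, [l]] - cy2[:, e], cy2[:, l - e])
    sxy = cc[:, lags % nfft]
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    bad = (vx <= _VAR_RTOL * np.maximum(1.0, n * sxx)) | (
        vy <= _VAR_RTOL * np.maximum(1.0, n * syy)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (n * sxy - sx * sy) / np.sqrt(np.where(bad, 1.0, vx * vy))
    r[bad] = np.nan
    return r


def max_lag_summary(
    matrix: ZScoreMatrix, window: int = 9
) -> tuple[dict[tuple[str, str], bool], float]:
    """Per ordered non-self pair: does the z profile peak within +/- window nt?

    Returns (per-pair flags, fraction of pairs flagged)."""
    flags: dict[tuple[str, str], bool] = {}
    for row, pair in enumerate(matrix.pairs):
        if pair[0] == pair[1]:
            continue
        zr = matrix.z[row]
        if np.all(np.isnan(zr)):
            flags[pair] = False
            continue
        d = matrix.lags[int(np.nanargmax(zr))]
        flags[pair] = abs(int(d)) <= window
    frac = float(np.mean(list(flags.values()))) if flags else float("nan")
    return flags, frac
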