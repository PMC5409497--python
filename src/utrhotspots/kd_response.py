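"""Knockdown response of transcripts with blocked vs free target sites.

A 50-nt window is drawn around each anchor site (for miRNA hisites: 35 nt
upstream of the seed 3' end through 14 nt downstream, shrunk to fit the
transcript). Counting the distinct non-focal RBPs in that window, a site
is *free* if <= 2 bind and *blocked* if >= 5 bind. Transcripts are grouped
by their number of blocked sites (0 = all free, 1, 2+); transcripts whose
sites include a 3-4-RBP window but no blocked site fit neither definition
and are excluded as unclassified; transcripts without anchor sites form
the no-sites control. Group log2 fold-change distributions are compared
with two-sided two-sample Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FREE_MAX_RBPS = 2
BLOCKED_MIN_RBPS = 5

GROUP_NO_SITES = "no_sites"
GROUP_ALL_FREE = "0"
GROUP_ONE_BLOCKED = "1"
GROUP_TWO_PLUS = "2+"
GROUP_UNCLASSIFIED = "unclassified"


def site_window(site_end: int, utr_len: int) -> tuple[int, int]:
    """50-nt window around a seed 3' end: [end-35, end+15), shrunk to fit
    inside the transcript."""
    if not 0 <= site_end < utr_len:
        raise ValueError(f"site end {site_end} outside UTR of length {utr_len}")
    return max(site_end - 35, 0), min(site_end + 15, utr_len)


def centered_window(center: int, utr_len: int, width: int = 50) -> tuple[int, int]:
    """Symmetric window around an RBP binding-site center, shrunk to fit."""
    half = width // 2
    return max(center - half, 0), min(center + width - half, utr_len)


@dataclass
class SiteBlockClass:
    transcript_id: str
    n_sites: int
    n_free: int
    n_blocked: int
    group: str


def classify_transcript(
    transcript_id: str, per_site_rbp_counts: list[int]
) -> SiteBlockClass:
    """Group a transcript by its blocked anchor sites.

    ``per_site_rbp_counts`` holds, for each anchor site, the number of
    distinct non-focal RBPs in the site's window.
    """
    n = len(per_site_rbp_counts)
    if n == 0:
        return SiteBlockClass(transcript_id, 0, 0, 0, GROUP_NO_SITES)
    n_free = sum(c <= FREE_MAX_RBPS for c in per_site_rbp_counts)
    n_blocked = sum(c >= BLOCKED_MIN_RBPS for c in per_site_rbp_counts)
    if n_blocked >= 2:
        group = GROUP_TWO_PLUS
    elif n_blocked == 1:
        group = GROUP_ONE_BLOCKED
    elif n_free == n:
        group = GROUP_ALL_FREE
    else:
        # some site sits in a 3-4-RBP window: neither free nor blocked
        group = GROUP_UNCLASSIFIED
    return SiteBlockClass(transcript_id, n, n_free, n_blocked, group)


def cumulative_fractions(
    kd: pd.Series, classes: dict[str, str]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-group ECDF of log2 fold changes on a shared grid.

    ``kd`` maps transcript_id to log2FC; ``classes`` maps transcript_id to
    group label. Empty groups are omitted. Returns group -> (grid, ecdf).
    """
    values: dict[str, np.ndarray] = {}
    for tid, group in classes.items():
        if tid in kd.index:
            values.setdefault(group, []).append(kd[tid])
    grid = np.sort(kd.loc[[t for t in classes if t in kd.index]].to_numpy())
    out = {}
    for group, vals in values.items():
        vals = np.sort(np.asarray(vals, dtype=float))
        ecdf = np.searchsorted(vals, grid, side="right") / len(vals)
        out[group] = (grid, ecdf)
    return out


def ks_compare(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample KS statistic and p-value."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("each group needs >= 5 values")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def ks_comparison_plan(
    kd: pd.Series, classes: dict[str, str]
) -> pd.DataFrame:
    """Fixed comparison plan: each blocked group vs the all-free group and
    all-free vs the no-sites control."""
    groups: dict[str, np.ndarray] = {}
    for tid, g in classes.items():
        if tid in kd.index:
            groups.setdefault(g, []).append(float(kd[tid]))
    rows = []
    plan = [
        (GROUP_ONE_BLOCKED, GROUP_ALL_FREE),
        (GROUP_TWO_PLUS, GROUP_ALL_FREE),
        (GROUP_ALL_FREE, GROUP_NO_SITES),
    ]
    for a, b in plan:
        if a not in groups or b not in groups:
            continue
        va, vb = np.asarray(groups[a]), np.asarray(groups[b])
        if len(va) < 5 or len(vb) < 5:
            continue
        d, p = ks_compare(va, vb)
        rows.append({"comparison": f"{a}_vs_{b}", "D": d, "p": p,
                     "n_a": len(va), "n_b": len(vb)})
    return pd.DataFrame(rows)


def expression_matched_control(
    classes: dict[str, str],
    expression: pd.Series,
    n_per_group: int,
    rng,
    n_bins: int = 10,
) -> dict[str, list[str]]:
    """Per-group subsample matched to the pooled expression distribution.

    Expression deciles of the pooled classified transcripts define the
    target histogram; from each group, transcripts are drawn per bin in
    those proportions. Raises if a group lacks transcripts in a needed bin.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    tids = [t for t in classes if t in expression.index]
    pooled = expression.loc[tids]
    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    bin_of = pd.cut(pooled, edges, labels=False, include_lowest=True)
    # target counts per bin, proportional to the pooled histogram
    target = np.bincount(bin_of, minlength=n_bins) / len(pooled)
    quota = np.round(target * n_per_group).astype(int)
    deficit = n_per_group - quota.sum()
    quota[np.argmax(target)] += deficit
    out: dict[str, list[str]] = {}
    groups = sorted(set(classes[t] for t in tids))
    for g in groups:
        members = [t for t in tids if classes[t] == g]
        if len(members) < n_per_group:
            raise ValueError(f"group {g} smaller than n_per_group={n_per_group}")
        chosen: list[str] = []
        for b in range(n_bins):
            pool = [t for t in members if bin_of[t] == b]
            if len(pool) < quota[b]:
                raise ValueError(
                    f"group {g} has {len(pool)} transcripts in expression bin "
                    f"{b}, needs {quota[b]}"
                )
            idx = rng.choice(len(pool), size=quota[b], replace=False)
            chosen.extend(pool[i] for i in idx)
        out[g] = chosen
    return out
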