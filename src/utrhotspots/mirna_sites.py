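"""miRNA target-site selection, tiers, random site sets, and site-centered
RBP enrichment statistics.

Target-site predictions (>= 6-mer seed match) are filtered to expressed
miRNAs (top 20% by mature-miRNA read count), overlapping seeds are resolved
(identical seeds merge with summed expression; otherwise the seed of the
most highly expressed miRNA wins), and resolved sites are split into three
equally sized total-expression tiers — the top tier are the "hisites".

Significance of site-centered statistics is assessed against 100 random
site sets that preserve each site's relative position within its 3'UTR,
resampled within 30 UTR-length groups, via an add-one empiric p-value
p = (1 + #{random >= observed}) / (1 + n_sets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .enrichment import EnrichmentProfile

TIER_HIGH = "high"
TIER_MODERATE = "moderate"
TIER_LOW = "low"
TIER_UNEXPRESSED = "unexpressed"

REGION_PROXIMAL = "proximal"
REGION_MEDIAL = "medial"
REGION_DISTAL = "distal"

MIN_SEED_LEN = 6


@dataclass
class MiRNAExpression:
    mirna_id: str
    mature_read_count: float
    expressed_flag: bool = False


@dataclass
class TargetSite:
    """A (possibly merged) miRNA seed site in transcript-frame coordinates."""

    utr_id: str
    seed_start: int
    seed_end: int
    mirnas: list[tuple[str, float]] = field(default_factory=list)
    tier: str = TIER_UNEXPRESSED
    region_class: str | None = None

    def __post_init__(self) -> None:
        if self.seed_end - self.seed_start < MIN_SEED_LEN:
            raise ValueError(
                f"seed length {self.seed_end - self.seed_start} < {MIN_SEED_LEN}"
            )

    @property
    def total_expression(self) -> float:
        return sum(e for _, e in self.mirnas)

    @property
    def top_expression(self) -> float:
        return max((e for _, e in self.mirnas), default=0.0)


def flag_expressed_mirnas(
    counts: list[MiRNAExpression], top_fraction: float = 0.2
) -> list[MiRNAExpression]:
    """Flag the top ``top_fraction`` of miRNAs by mature read count as
    expressed; ties at the cutoff count are all included."""
    if not counts:
        raise ValueError("empty miRNA expression list")
    n_top = int(np.ceil(top_fraction * len(counts)))
    cutoff = sorted((c.mature_read_count for c in counts), reverse=True)[n_top - 1]
    for c in counts:
        c.expressed_flag = c.mature_read_count >= cutoff
    return counts


def resolve_overlapping_sites(sites: list[TargetSite]) -> list[TargetSite]:
    """Resolve overlapping seed sites on one UTR into a non-overlapping set.

    Seeds with identical coordinates merge, summing their miRNAs'
    expression. Among overlapping non-identical seeds, the one whose top
    miRNA expression is highest is kept; ties break by leftmost seed then
    lexicographic miRNA id.
    """
    merged: dict[tuple[int, int], TargetSite] = {}
    for s in sites:
        key = (s.seed_start, s.seed_end)
        if key in merged:
            merged[key].mirnas.extend(s.mirnas)
        else:
            merged[key] = TargetSite(s.utr_id, s.seed_start, s.seed_end, list(s.mirnas))
    ranked = sorted(
        merged.values(),
        key=lambda s: (
            -s.top_expression,
            s.seed_start,
            min((m for m, _ in s.mirnas), default=""),
        ),
    )
    kept: list[TargetSite] = []
    for s in ranked:
        if all(
            s.seed_end <= k.seed_start or s.seed_start >= k.seed_end for k in kept
        ):
            kept.append(s)
    kept.sort(key=lambda s: s.seed_start)
    return kept


def assign_tiers(sites: list[TargetSite]) -> list[TargetSite]:
    """Split resolved sites into three equal total-expression tiers.

    Sites are sorted by total expression; remainders go to the lower tiers,
    so the top third (hisites) is never larger than the other tiers.
    """
    if len(sites) < 3:
        raise ValueError("need at least 3 sites to form tiers")
    order = sorted(range(len(sites)), key=lambda i: sites[i].total_expression)
    n = len(sites)
    base, rem = divmod(n, 3)
    n_low = base + (1 if rem >= 1 else 0)
    n_mod = base + (1 if rem >= 2 else 0)
    for rank, idx in enumerate(order):
        if rank < n_low:
            sites[idx].tier = TIER_LOW
        elif rank < n_low + n_mod:
            sites[idx].tier = TIER_MODERATE
        else:
            sites[idx].tier = TIER_HIGH
    return sites


def classify_position(site: TargetSite, utr_len: int) -> str:
    """Proximal/medial/distal by the seed midpoint's third of the UTR."""
    mid = (site.seed_start + site.seed_end) // 2
    third = utr_len / 3
    if mid < third:
        cls = REGION_PROXIMAL
    elif mid < 2 * third:
        cls = REGION_MEDIAL
    else:
        cls = REGION_DISTAL
    site.region_class = cls
    return cls


@dataclass
class RandomSiteSet:
    set_id: int
    sites: list[TargetSite]


def generate_random_site_sets(
    real_sites: list[TargetSite],
    utr_lengths: dict[str, int],
    rng,
    *,
    n_sets: int = 100,
    n_length_groups: int = 30,
) -> list[RandomSiteSet]:
    """Position-preserving random site sets.

    UTRs carrying sites are split into ``n_length_groups`` equal-size groups
    by 3'UTR length; each site is reassigned to a UTR drawn uniformly from
    its group, keeping its relative position (new_start = round(rel * new_L));
    coordinates are clamped so the seed fits inside the new UTR. Every set
    has exactly the real set's cardinality.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    site_utrs = sorted({s.utr_id for s in real_sites})
    if len(site_utrs) < n_length_groups:
        raise ValueError(
            f"{len(site_utrs)} UTRs with sites < {n_length_groups} length groups"
        )
    by_len = sorted(site_utrs, key=lambda u: (utr_lengths[u], u))
    groups = np.array_split(np.array(by_len), n_length_groups)
    group_of = {u: gi for gi, grp in enumerate(groups) for u in grp}
    out = []
    for set_id in range(1, n_sets + 1):
        new_sites = []
        for s in real_sites:
            grp = groups[group_of[s.utr_id]]
            new_utr = str(grp[rng.integers(len(grp))])
            old_l = utr_lengths[s.utr_id]
            new_l = utr_lengths[new_utr]
            seed_len = s.seed_end - s.seed_start
            start = int(round(s.seed_start / old_l * new_l))
            start = min(max(start, 0), max(new_l - seed_len, 0))
            new_sites.append(
                TargetSite(new_utr, start, start + seed_len, list(s.mirnas), s.tier)
            )
        out.append(RandomSiteSet(set_id, new_sites))
    return out


def site_meta_profile(
    profiles: dict[str, EnrichmentProfile],
    sites: list[TargetSite],
    flank: int = 50,
) -> np.ndarray:
    """Mean enrichment at each offset in [-flank, +flank] relative to seed
    starts, over all sites on profiled UTRs; offsets falling outside a UTR
    are skipped for that site."""
    width = 2 * flank + 1
    sums = np.zeros(width)
    counts = np.zeros(width)
    used = 0
    for s in sites:
        prof = profiles.get(s.utr_id)
        if prof is None:
            continue
        e = prof.e
        lo = s.seed_start - flank
        a, b = max(lo, 0), min(s.seed_start + flank + 1, len(e))
        if a >= b:
            continue
        sums[a - lo : b - lo] += e[a:b]
        counts[a - lo : b - lo] += 1
        used += 1
    if used == 0:
        raise ValueError("no usable site on a profiled UTR")
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def empiric_site_pvalue(
    observed: float, random_values: np.ndarray
) -> float:
    """Add-one empiric p-value: (1 + #{random >= observed}) / (1 + n_sets)."""
    random_values = np.asarray(random_values, dtype=float)
    n = len(random_values)
    if n < 20:
        raise ValueError(f"need >= 20 random sets, got {n}")
    return float((1 + np.sum(random_values >= observed)) / (1 + n))


def random_envelope(
    per_set_profiles: np.ndarray, lo: float = 5.0, hi: float = 95.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position 5th/95th percentile envelope across random sets."""
    return (
        np.percentile(per_set_profiles, lo, axis=0),
        np.percentile(per_set_profiles, hi, axis=0),
    )


def _overlap_fractions(
    cluster_coords: dict[str, list[tuple[int, int]]],
    sites: list[TargetSite],
) -> tuple[float, float]:
    """(fraction of clusters overlapping a site, fraction of sites covered
    by a cluster); overlap means >= 1 shared nt."""
    by_utr: dict[str, list[TargetSite]] = {}
    for s in sites:
        by_utr.setdefault(s.utr_id, []).append(s)
    n_cl = sum(len(v) for v in cluster_coords.values())
    n_cl_hit = 0
    hit_sites: set[int] = set()
    for uid, coords in cluster_coords.items():
        utr_sites = by_utr.get(uid, [])
        for start, end in coords:
            hit = False
            for s in utr_sites:
                if start < s.seed_end and s.seed_start < end:
                    hit = True
                    hit_sites.add(id(s))
            n_cl_hit += hit
    frac_clusters = n_cl_hit / n_cl if n_cl else float("nan")
    frac_sites = len(hit_sites) / len(sites) if sites else float("nan")
    return frac_clusters, frac_sites


def overlap_permutation_test(
    cluster_coords: dict[str, list[tuple[int, int]]],
    hisites: list[TargetSite],
    random_sets: list[RandomSiteSet],
) -> dict[str, float]:
    """Fractions of clusters on hisites / hisites covered by clusters, with
    add-one empiric p-values against the random site sets.

    ``cluster_coords`` maps utr_id to transcript-frame cluster footprints
    (positive-enrichment filtered).
    """
    obs_cl, obs_si = _overlap_fractions(cluster_coords, hisites)
    rand_cl = np.array(
        [_overlap_fractions(cluster_coords, rs.sites)[0] for rs in random_sets]
    )
    rand_si = np.array(
        [_overlap_fractions(cluster_coords, rs.sites)[1] for rs in random_sets]
    )
    return {
        "frac_clusters_on_sites": obs_cl,
        "frac_sites_covered": obs_si,
        "p_clusters": empiric_site_pvalue(obs_cl, rand_cl),
        "p_sites": empiric_site_pvalue(obs_si, rand_si),
    }


def enrichment_expression_correlation(
    site_enrichment: np.ndarray, site_expression: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of log10 site enrichment vs log10 summed miRNA
    expression; zero-enrichment sites are excluded."""
    e = np.asarray(site_enrichment, dtype=float)
    x = np.asarray(site_expression, dtype=float)
    ok = (e > 0) & (x > 0)
    if ok.sum() < 3:
        raise ValueError("need >= 3 sites with positive enrichment and expression")
    r, p = stats.pearsonr(np.log10(e[ok]), np.log10(x[ok]))
    return float(r), float(p)
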