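"""Expression normalization and per-nucleotide CLIP enrichment.

For gene k with 3'UTR length l_k, RNA-seq base calls r_j at position j and
library size M, the normalized mean expression is

    m_k = sum_j r_j / (M * l_k)

and the CLIP enrichment at position i, given c_i CLIP read counts inside
significant clusters (FDR < 0.01) and N total uniquely mapped CLIP reads, is

    e_{i,k} = c_i / (m_k * N)

Positions outside significant clusters have e = 0. Genes with m_k = 0 must
be excluded upstream by the expression filter; there are no pseudocounts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_tracks import GenomicInterval, Track

FDR_THRESHOLD = 0.01


@dataclass
class CoverageTrack:
    """RNA-seq base-call counts per transcript-frame position plus the
    experiment-wide library size M."""

    utr_id: str
    r: np.ndarray
    M: float

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if np.any(self.r < 0):
            raise ValueError("coverage counts must be non-negative")
        if self.M <= 0:
            raise ValueError("library size M must be positive")


@dataclass
class GeneExpression:
    utr_id: str
    m: float
    l: int
    covered_fraction: float


@dataclass
class Cluster:
    """One significant CLIP cluster with its peak-calling metadata."""

    interval: GenomicInterval
    read_count: float
    fdr: float
    enrichment: float = np.nan

    def __post_init__(self) -> None:
        if not 0 <= self.fdr <= 1:
            raise ValueError(f"FDR must be in [0, 1], got {self.fdr}")
        if self.read_count < 1:
            raise ValueError("cluster read count must be >= 1")


@dataclass
class ClusterSet:
    """One RBP's clusters plus its CLIP library size N."""

    rbp_name: str
    clusters: list[Cluster] = field(default_factory=list)
    N: float = 1.0

    def significant(self, fdr_threshold: float = FDR_THRESHOLD) -> "ClusterSet":
        """Clusters passing the peak-calling FDR filter."""
        return ClusterSet(
            self.rbp_name,
            [c for c in self.clusters if c.fdr < fdr_threshold],
            self.N,
        )


@dataclass
class EnrichmentProfile:
    utr_id: str
    rbp_name: str
    e: np.ndarray

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)


def mean_expression(cov: CoverageTrack, l: int) -> GeneExpression:
    """Normalized mean expression m = sum(r) / (M * l) and the fraction of
    covered positions."""
    if l == 0:
        raise ValueError("3'UTR length must be positive")
    if l != len(cov.r):
        raise ValueError(f"length mismatch: l={l} but len(r)={len(cov.r)}")
    m = float(cov.r.sum() / (cov.M * l))
    covered = float(np.count_nonzero(cov.r) / l)
    return GeneExpression(cov.utr_id, m, l, covered)


def is_expressed(ge: GeneExpression, min_covered: float = 0.5) -> bool:
    """Expressed-gene filter: >= 50% of 3'UTR positions covered by RNA-seq."""
    return ge.covered_fraction >= min_covered


def clip_enrichment(
    clusters: ClusterSet,
    per_position_counts: Track | None,
    ge: GeneExpression,
    cluster_coords: list[tuple[int, int]] | None = None,
) -> EnrichmentProfile:
    """Per-nucleotide enrichment e_i = c_i / (m * N) over one 3'UTR.

    ``cluster_coords`` gives each significant cluster's transcript-frame
    [start, end); if ``per_position_counts`` is None, each cluster's total
    read count is spread uniformly over its footprint. Positions outside
    significant clusters are zero.
    """
    if ge.m == 0:
        raise ValueError(
            f"gene {ge.utr_id} has zero expression; filter non-expressed genes first"
        )
    sig = clusters.significant()
    e = np.zeros(ge.l)
    coords = cluster_coords if cluster_coords is not None else [
        (c.interval.start, c.interval.end) for c in sig.clusters
    ]
    denom = ge.m * clusters.N
    for cl, (start, end) in zip(sig.clusters, coords):
        start, end = max(0, start), min(ge.l, end)
        if start >= end:
            continue
        if per_position_counts is not None:
            c = per_position_counts.values[start:end]
        else:
            c = np.full(end - start, cl.read_count / (end - start))
        e[start:end] = c / denom
    return EnrichmentProfile(ge.utr_id, clusters.rbp_name, e)


def cluster_center(iv: GenomicInterval) -> int:
    """Cluster center in half-open coordinates; even lengths round left."""
    return (iv.start + iv.end - 1) // 2


def mean_cluster_enrichment(profile: EnrichmentProfile, start: int, end: int) -> float:
    start, end = max(0, start), min(len(profile.e), end)
    if start >= end:
        return 0.0
    return float(profile.e[start:end].mean())


def positive_enrichment_filter(
    cs: ClusterSet,
    profiles: dict[str, EnrichmentProfile],
    cluster_utr: dict[int, str],
    cluster_coords: dict[int, tuple[int, int]],
) -> ClusterSet:
    """Keep clusters with positive enrichment over RNA-seq, i.e. mean e > 1
    (equivalently positive mean log2 CLIP/RNA-seq ratio) over the cluster
    footprint. Strict inequality: mean e exactly 1 is dropped.

    ``cluster_utr``/``cluster_coords`` map cluster index (into cs.clusters)
    to its UTR and transcript-frame coordinates; clusters on UTRs without a
    profile are dropped.
    """
    kept = []
    for idx, cl in enumerate(cs.clusters):
        uid = cluster_utr.get(idx)
        if uid is None or uid not in profiles:
            continue
        start, end = cluster_coords[idx]
        if mean_cluster_enrichment(profiles[uid], start, end) > 1.0:
            kept.append(cl)
    return ClusterSet(cs.rbp_name, kept, cs.N)
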