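"""Synthetic 3'UTR regulatory landscape generator.

Generates every input the analysis consumes — UTR models with AU-biased
sequences, per-RBP CLIP cluster tracks with tunable co-binding, RNA-seq
coverage, miRNA target sites with a long-tailed expression distribution,
conservation / minor-allele-frequency / accessibility tracks, and
knockdown fold changes — together with a ground-truth ledger (designated
hotspot windows, per-transcript blocked/free status) sufficient to score
recovery.

Co-binding structure: a fraction ``hotspot_fraction`` of 50-nt windows is
designated; each RBP places a cluster at each designated window with
probability ``co_binding_fraction`` (per-window recruitment), centered on
that window's fixed anchor plus ~N(0, 3 nt) jitter, emulating the
near-exact co-localization of regulatory factors the analysis is designed
to detect; background clusters are placed uniformly at the configured
rate. Designated windows also carry the configured conservation shift,
MAF deficit, accessibility boost and AU-enriched sequence.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import Cluster, ClusterSet, CoverageTrack
from .io_tracks import (
    GenomicInterval,
    UtrModel,
    from_transcript_frame,
)

WINDOW = 50


@dataclass
class SyntheticConfig:
    """Study conditions for the generator; defaults give a minutes-scale
    dataset with the statistical structure the analysis assumes."""

    n_genes: int = 500
    utr_length_log_mean: float = float(np.log(1080.0))  # median ~1.08 kb -> mean ~1.2 kb
    utr_length_log_sd: float = 0.45
    utr_min_len: int = 150
    utr_max_len: int = 6000
    n_rbps: int = 12
    cluster_rate_per_kb: float = 1.2
    cluster_len_log_mean: float = float(np.log(26.0))
    cluster_len_log_sd: float = 0.30
    cluster_min_len: int = 10
    cluster_max_len: int = 60
    co_binding_fraction: float = 0.6
    co_binding_rbps: list[str] | None = None  # None = all RBPs
    cobind_jitter_sd: float = 3.0
    hotspot_fraction: float = 0.05
    gfp_rate_per_kb: float = 0.3
    n_mirnas: int = 60
    mirna_expression_exponent: float = 1.3
    site_rate_per_kb: float = 0.8
    # probability a target site is placed inside a designated window of its
    # UTR (hotspots carry miRNA target sites); remaining sites mix uniform
    # placement with a 3'UTR-edge bias
    site_in_hotspot_fraction: float = 0.25
    conservation_effect: float = 0.5
    maf_variant_rate: float = 0.12  # qualifying variants per nt (AC >= 2 of 5008)
    maf_deficit: float = 0.6
    accessibility_boost: float = 0.15
    kd_shift: float = 0.2
    noise_sd: float = 1.0
    low_coverage_fraction: float = 0.12
    clip_library_scale: float = 4.0  # N = clip_library_scale * total cluster reads
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "co_binding_fraction",
            "hotspot_fraction",
            "maf_deficit",
            "low_coverage_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cluster_rate_per_kb <= 0 or self.site_rate_per_kb <= 0:
            raise ValueError("rates must be positive")


@dataclass
class SyntheticDataset:
    """All generated inputs, transcript-frame, plus the ground truth."""

    config: SyntheticConfig
    utrs: dict[str, UtrModel]
    coverage: dict[str, CoverageTrack]
    cluster_sets: dict[str, ClusterSet]  # includes the "GFP" background set
    cluster_locs: dict[str, list[tuple[str, int, int]]]  # rbp -> [(utr, s, e)]
    mirna_counts: pd.DataFrame  # mirna_id, count
    site_table: pd.DataFrame  # utr_id, seed_start, seed_end, mirna_id
    conservation: dict[str, np.ndarray]
    mafs: dict[str, list[tuple[int, float]]]
    accessibility: pd.DataFrame  # utr_id, window_index, value
    kd_table: pd.DataFrame  # transcript_id, log2fc
    truth_windows: dict[str, set[int]]  # designated window indices per UTR
    truth_groups: pd.DataFrame  # transcript_id, n_sites, n_blocked, group

    @property
    def rbp_names(self) -> list[str]:
        return [r for r in self.cluster_sets if r != "GFP"]

    def utr_lengths(self) -> dict[str, int]:
        return {uid: u.length for uid, u in self.utrs.items()}

    def write(self, outdir) -> list[Path]:
        return write_dataset(self, outdir)


def _sample_lengths(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    raw = rng.lognormal(cfg.utr_length_log_mean, cfg.utr_length_log_sd, cfg.n_genes)
    return np.clip(raw, cfg.utr_min_len, cfg.utr_max_len).astype(int)


def _sequence(l: int, designated: set[int], rng: np.random.Generator) -> str:
    au_prob = np.full(l, 0.60)
    for w in designated:
        au_prob[w * WINDOW : min((w + 1) * WINDOW, l)] = 0.75
    is_au = rng.random(l) < au_prob
    second = rng.random(l) < 0.5
    letters = np.where(is_au, np.where(second, "A", "U"), np.where(second, "C", "G"))
    return "".join(letters)


def _place_clusters(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    lengths: dict[str, int],
    designated: dict[str, list[int]],
    anchors: dict[str, dict[int, int]],
    rate_per_kb: float,
    cobind: float,
) -> list[tuple[str, int, int]]:
    """(utr_id, start, end) cluster footprints for one RBP.

    Each designated window recruits a cluster with probability ``cobind``
    (centered on the window anchor with small jitter); background clusters
    arrive at ``rate_per_kb`` uniformly. Same-RBP overlaps are resolved in
    favor of the recruited clusters, then left-to-right.
    """
    out = []
    for uid, l in lengths.items():
        placed: list[tuple[int, int]] = []

        def _clen() -> int:
            return int(
                np.clip(
                    rng.lognormal(cfg.cluster_len_log_mean, cfg.cluster_len_log_sd),
                    cfg.cluster_min_len,
                    min(cfg.cluster_max_len, l),
                )
            )

        def _try_place(start: int, clen: int) -> None:
            start = min(max(start, 0), l - clen)
            end = start + clen
            if not any(start < pe and ps < end for ps, pe in placed):
                placed.append((start, end))

        for w in designated.get(uid, []):
            if rng.random() < cobind:
                clen = _clen()
                center = anchors[uid][w] + int(
                    round(rng.normal(0, cfg.cobind_jitter_sd))
                )
                _try_place(center - clen // 2, clen)
        n_background = rng.poisson(rate_per_kb * l / 1000.0)
        for _ in range(n_background):
            clen = _clen()
            _try_place(int(rng.integers(0, max(l - clen, 1))), clen)
        out.extend((uid, s, e) for s, e in sorted(placed))
    return out


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full dataset; deterministic given ``config.rng_seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    lengths_arr = _sample_lengths(cfg, rng)
    utr_ids = [f"UTR{i:04d}" for i in range(cfg.n_genes)]
    lengths = dict(zip(utr_ids, (int(x) for x in lengths_arr)))

    # designated hotspot windows and their co-binding anchor positions
    truth_windows: dict[str, set[int]] = {}
    designated: dict[str, list[int]] = {}
    anchors: dict[str, dict[int, int]] = {}
    for uid, l in lengths.items():
        n_full = l // WINDOW
        des = [w for w in range(n_full) if rng.random() < cfg.hotspot_fraction]
        truth_windows[uid] = set(des)
        designated[uid] = des
        anchors[uid] = {
            w: w * WINDOW + int(rng.integers(10, WINDOW - 10)) for w in des
        }

    # genome placement (alternating strands) and AU-biased sequences
    utrs: dict[str, UtrModel] = {}
    offset = 0
    for i, uid in enumerate(utr_ids):
        l = lengths[uid]
        strand = "+" if i % 2 == 0 else "-"
        iv = GenomicInterval(f"chr{i % 5 + 1}", offset, offset + l, strand, uid)
        utrs[uid] = UtrModel(uid, f"{uid}.t1", iv, _sequence(l, truth_windows[uid], rng))
        offset += l + 100

    # RNA-seq coverage; a fraction of genes fails the 50%-coverage filter
    levels = rng.lognormal(np.log(3.0), 0.8, cfg.n_genes)
    r_arrays = {}
    for uid, lam in zip(utr_ids, levels):
        r = rng.poisson(lam, lengths[uid]).astype(float)
        if rng.random() < cfg.low_coverage_fraction:
            mask = rng.random(lengths[uid]) < 0.6
            r[mask] = 0.0
        r_arrays[uid] = r
    M = float(sum(r.sum() for r in r_arrays.values()))
    coverage = {uid: CoverageTrack(uid, r, M) for uid, r in r_arrays.items()}

    # CLIP clusters per RBP (+ a GFP background set, never co-binding)
    rbp_names = [f"RBP{i:02d}" for i in range(cfg.n_rbps)]
    cobind_set = set(cfg.co_binding_rbps) if cfg.co_binding_rbps else set(rbp_names)
    cluster_sets: dict[str, ClusterSet] = {}
    cluster_locs: dict[str, list[tuple[str, int, int]]] = {}
    for rbp in rbp_names + ["GFP"]:
        rate = cfg.gfp_rate_per_kb if rbp == "GFP" else cfg.cluster_rate_per_kb
        cobind = cfg.co_binding_fraction if rbp in cobind_set else 0.0
        locs = _place_clusters(cfg, rng, lengths, designated, anchors, rate, cobind)
        clusters = []
        for uid, s, e in locs:
            reads = 5 + int(rng.poisson(20))
            fdr = (
                float(rng.random() * 0.009)
                if rng.random() < 0.92
                else float(0.011 + rng.random() * 0.1)
            )
            iv_genome = from_transcript_frame(s, e, utrs[uid])
            iv = GenomicInterval(
                iv_genome.chrom, iv_genome.start, iv_genome.end,
                iv_genome.strand, rbp, reads,
            )
            clusters.append(Cluster(iv, reads, fdr))
        total_reads = sum(c.read_count for c in clusters) or 1.0
        cluster_sets[rbp] = ClusterSet(rbp, clusters, cfg.clip_library_scale * total_reads)
        cluster_locs[rbp] = locs

    # miRNA expression: power-law ranks shuffled over ids
    mirna_ids = [f"miR-{i:03d}" for i in range(cfg.n_mirnas)]
    ranks = rng.permutation(cfg.n_mirnas) + 1
    counts = np.floor(5000.0 / ranks**cfg.mirna_expression_exponent) + rng.poisson(
        3, cfg.n_mirnas
    )
    mirna_counts = pd.DataFrame({"mirna_id": mirna_ids, "count": counts.astype(float)})

    # target-site predictions with duplicates and overlaps to resolve
    site_rows = []
    for uid, l in lengths.items():
        n = rng.poisson(cfg.site_rate_per_kb * l / 1000.0)
        des = designated.get(uid, [])
        for _ in range(n):
            seed_len = 7 if rng.random() < 0.85 else 6
            if des and rng.random() < cfg.site_in_hotspot_fraction:
                w = des[rng.integers(len(des))]
                lo = w * WINDOW
                start = int(lo + rng.integers(0, WINDOW - seed_len))
            else:
                rel = rng.random() if rng.random() < 0.5 else rng.beta(0.5, 0.5)
                start = int(rel * (l - seed_len))
            mir = mirna_ids[rng.integers(cfg.n_mirnas)]
            site_rows.append((uid, start, start + seed_len, mir))
            u = rng.random()
            if u < 0.15:  # shared seed: second miRNA on identical coordinates
                other = mirna_ids[rng.integers(cfg.n_mirnas)]
                site_rows.append((uid, start, start + seed_len, other))
            elif u < 0.25:  # overlapping, non-identical seed
                shift = int(rng.integers(1, 4))
                s2 = min(start + shift, l - seed_len)
                other = mirna_ids[rng.integers(cfg.n_mirnas)]
                site_rows.append((uid, s2, s2 + seed_len, other))
    site_table = pd.DataFrame(
        site_rows, columns=["utr_id", "seed_start", "seed_end", "mirna_id"]
    )

    # conservation (phyloP-like), MAF and accessibility tracks
    conservation = {}
    mafs: dict[str, list[tuple[int, float]]] = {}
    acc_rows = []
    for uid, l in lengths.items():
        cons = rng.normal(0.3, 1.0, l)
        des = truth_windows[uid]
        for w in des:
            cons[w * WINDOW : min((w + 1) * WINDOW, l)] += cfg.conservation_effect
        cons[rng.random(l) < 0.05] = np.nan
        conservation[uid] = cons
        var_pos = np.flatnonzero(rng.random(l) < cfg.maf_variant_rate)
        var_maf = 10.0 ** rng.uniform(-3.0, -1.0, len(var_pos))
        pairs = []
        for p, m in zip(var_pos, var_maf):
            if (p // WINDOW) in des:
                m *= 1.0 - cfg.maf_deficit
            pairs.append((int(p), float(m)))
        mafs[uid] = pairs
        n_win = -(-l // WINDOW)
        base = rng.beta(8.0, 12.0, n_win)
        for w in range(n_win):
            v = base[w] + (cfg.accessibility_boost if w in des else 0.0)
            acc_rows.append((uid, w, float(np.clip(v, 0.0, 1.0))))
    accessibility = pd.DataFrame(
        acc_rows, columns=["utr_id", "window_index", "value"]
    )

    # knockdown fold changes driven by the generative blocked/free truth:
    # a site of an expressed miRNA is "blocked" iff its seed midpoint lies
    # in a designated window; free-site transcripts respond to the KD
    n_top = int(np.ceil(0.2 * cfg.n_mirnas))
    cutoff = np.sort(counts)[::-1][n_top - 1]
    expressed_mirnas = {
        mid for mid, c in zip(mirna_ids, counts) if c >= cutoff
    }
    truth_rows = []
    kd_rows = []
    for uid, l in lengths.items():
        sub = site_table[
            (site_table["utr_id"] == uid)
            & site_table["mirna_id"].isin(expressed_mirnas)
        ]
        mids = ((sub["seed_start"] + sub["seed_end"]) // 2).to_numpy()
        n_sites = len(set(map(int, mids)))
        n_blocked = len(
            {int(m) for m in mids if (int(m) // WINDOW) in truth_windows[uid]}
        )
        if n_sites == 0:
            group = "no_sites"
        elif n_blocked == 0:
            group = "0"
        elif n_blocked == 1:
            group = "1"
        else:
            group = "2+"
        truth_rows.append((uid, n_sites, n_blocked, group))
        shift = cfg.kd_shift if group == "0" else 0.0
        kd_rows.append((uid, float(rng.normal(shift, cfg.noise_sd))))
    truth_groups = pd.DataFrame(
        truth_rows, columns=["transcript_id", "n_sites", "n_blocked", "group"]
    )
    kd_table = pd.DataFrame(kd_rows, columns=["transcript_id", "log2fc"])

    return SyntheticDataset(
        cfg, utrs, coverage, cluster_sets, cluster_locs, mirna_counts,
        site_table, conservation, mafs, accessibility, kd_table,
        truth_windows, truth_groups,
    )


def generate_kd_dataset(
    n_transcripts: int = 12000,
    kd_shift: float = 0.2,
    noise_sd: float = 1.0,
    rng=0,
) -> tuple[pd.Series, dict[str, list[int]]]:
    """Dedicated knockdown-analysis dataset at KS-power scale.

    Returns (kd Series indexed by transcript, per-transcript anchor-site
    non-focal RBP counts). Site window RBP counts are drawn so that sites
    are free (<= 2 RBPs) with probability ~0.55, intermediate (3-4) with
    ~0.15 and blocked (>= 5) with ~0.30; the KD shift applies to
    transcripts whose sites are all free (group 0), as when free miRNA
    target sites respond to AGO2 depletion. Group sizes were chosen by a
    power analysis of the two-sample KS test at the configured shift.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    counts_dist = np.array([0.22, 0.18, 0.15, 0.08, 0.07, 0.12, 0.09, 0.05, 0.04])
    counts_dist = counts_dist / counts_dist.sum()
    kd = {}
    site_counts: dict[str, list[int]] = {}
    for i in range(n_transcripts):
        tid = f"T{i:05d}"
        n_sites = 0 if rng.random() < 0.25 else 1 + rng.poisson(1.2)
        cts = list(rng.choice(len(counts_dist), size=n_sites, p=counts_dist))
        site_counts[tid] = [int(c) for c in cts]
        n_blocked = sum(c >= 5 for c in cts)
        free_group = n_sites > 0 and all(c <= 2 for c in cts)
        shift = kd_shift if (free_group and n_blocked == 0) else 0.0
        kd[tid] = float(rng.normal(shift, noise_sd))
    return pd.Series(kd, name="log2fc"), site_counts


def write_dataset(ds: SyntheticDataset, outdir) -> list[Path]:
    """Write the dataset as the plain-text formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(path: Path) -> Path:
        written.append(path)
        return path

    with open(_w(outdir / "utrs.bed"), "w") as fh:
        for uid, u in ds.utrs.items():
            iv = u.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{uid}\t0\t{iv.strand}\n")
    with open(_w(outdir / "utrs.fa"), "w") as fh:
        for uid, u in ds.utrs.items():
            fh.write(f">{uid}\n{u.sequence}\n")
    for rbp, cs in ds.cluster_sets.items():
        with open(_w(outdir / f"clusters_{rbp}.bed"), "w") as fh:
            for c in cs.clusters:
                iv = c.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rbp}\t{c.read_count:g}"
                    f"\t{iv.strand}\t{c.fdr:.6g}\t0\n"
                )
    with open(_w(outdir / "library_sizes.tsv"), "w") as fh:
        fh.write("sample\ttotal_mapped_reads\n")
        fh.write(f"RNAseq\t{next(iter(ds.coverage.values())).M:g}\n")
        for rbp, cs in ds.cluster_sets.items():
            fh.write(f"{rbp}\t{cs.N:g}\n")
    with open(_w(outdir / "coverage.bedgraph"), "w") as fh:
        for uid, cov in ds.coverage.items():
            _write_rle(fh, uid, cov.r)
    with open(_w(outdir / "conservation.bedgraph"), "w") as fh:
        for uid, cons in ds.conservation.items():
            _write_rle(fh, uid, cons, skip_nan=True)
    ds.mirna_counts.to_csv(_w(outdir / "mirna_expression.tsv"), sep="\t", index=False)
    ds.site_table.to_csv(_w(outdir / "mirna_sites.tsv"), sep="\t", index=False)
    with open(_w(outdir / "maf.tsv"), "w") as fh:
        fh.write("utr_id\tposition\tmaf\n")
        for uid, pairs in ds.mafs.items():
            for pos, m in pairs:
                fh.write(f"{uid}\t{pos}\t{m:.6g}\n")
    ds.accessibility.to_csv(_w(outdir / "accessibility.tsv"), sep="\t", index=False)
    ds.kd_table.to_csv(_w(outdir / "kd.tsv"), sep="\t", index=False)
    truth = ds.truth_groups.copy()
    truth.to_csv(_w(outdir / "truth_groups.tsv"), sep="\t", index=False)
    with open(_w(outdir / "truth_windows.tsv"), "w") as fh:
        fh.write("utr_id\twindow_index\n")
        for uid, wins in ds.truth_windows.items():
            for w in sorted(wins):
                fh.write(f"{uid}\t{w}\n")
    with open(_w(outdir / "config.yaml"), "w") as fh:
        import yaml

        yaml.safe_dump({k: v for k, v in asdict(ds.config).items()}, fh)
    return written


def _write_rle(fh, uid: str, values: np.ndarray, skip_nan: bool = False) -> None:
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        return
    key = np.where(np.isnan(vals), np.inf, vals)
    change = np.flatnonzero(key[1:] != key[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [vals.size]))
    for s, e in zip(starts, ends):
        v = vals[s]
        if np.isnan(v):
            if skip_nan:
                continue
            v = 0.0
        fh.write(f"{uid}\t{s}\t{e}\t{v:.8g}\n")


def truth_score(
    ds: SyntheticDataset,
    called_hotspots: dict[str, set[int]],
    pair_peak_flags: dict[tuple[str, str], bool] | None = None,
    evaluated_utrs: set[str] | None = None,
) -> dict[str, float]:
    """Score pipeline outputs against the generator's ground truth.

    ``called_hotspots`` maps utr_id to hotspot window indices found by the
    analysis; recall/precision are computed against the designated windows.
    ``evaluated_utrs`` restricts the truth to the UTRs the analysis could
    see (designated windows on expression-filtered UTRs are unobservable).
    """
    truth_pairs = {
        (uid, w)
        for uid, wins in ds.truth_windows.items()
        for w in wins
        if evaluated_utrs is None or uid in evaluated_utrs
    }
    called_pairs = {
        (uid, w) for uid, wins in called_hotspots.items() for w in wins
    }
    tp = len(truth_pairs & called_pairs)
    recall = tp / len(truth_pairs) if truth_pairs else float("nan")
    precision = tp / len(called_pairs) if called_pairs else float("nan")
    out = {"hotspot_recall": recall, "hotspot_precision": precision}
    if pair_peak_flags is not None:
        out["cobinding_peak_fraction"] = (
            float(np.mean(list(pair_peak_flags.values())))
            if pair_peak_flags
            else float("nan")
        )
    return out
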