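"""Stage orchestration: enrichment -> positional correlation -> miRNA
sites -> hotspots -> knockdown response, on an in-memory dataset bundle or
a directory of input files.

Each stage draws its randomness from a dedicated stream derived from the
master seed and the stage name, so toggling one stage does not perturb
another's random numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import hotspots as hot
from . import io_tracks as iot
from . import kd_response as kdr
from . import mirna_sites as mir
from . import positional_correlation as pcor
from .synthetic_data import SyntheticDataset

logger = logging.getLogger("utrhotspots")


@dataclass
class PipelineParams:
    """Analysis parameters; defaults are the study's stated values."""

    seed: int
    window: int = 50
    min_rbps: int = 5
    max_lag: int = 200
    min_utr_len: int = 400
    n_shuffles: int = 100
    n_sims: int = 10000
    flank: int = 50
    n_random_sets: int = 100
    n_length_groups: int = 30
    fdr_threshold: float = 0.01
    min_covered: float = 0.5
    focal_rbp: str = "RBP00"
    # number of UTRs (seeded subsample) used for the all-pairs z-matrix;
    # keeps the 100-shuffle matrix minutes-scale
    corr_max_utrs: int = 40


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent per-stage RNG stream derived from the master seed."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode()) & 0x7FFFFFFF])


# ---------------------------------------------------------------- enrichment


def expression_stage(ds: SyntheticDataset, params: PipelineParams):
    """Per-gene normalized expression and the expressed-UTR universe."""
    expr = {
        uid: enr.mean_expression(cov, ds.utrs[uid].length)
        for uid, cov in ds.coverage.items()
    }
    expressed = {
        uid: ge
        for uid, ge in expr.items()
        if enr.is_expressed(ge, params.min_covered) and ge.m > 0
    }
    logger.info("expression: %d/%d UTRs expressed", len(expressed), len(expr))
    return expr, expressed


def profile_stage(
    ds: SyntheticDataset, expressed: dict, params: PipelineParams
) -> dict[str, dict[str, enr.EnrichmentProfile]]:
    """Per-RBP, per-UTR enrichment profiles (FDR-filtered clusters, uniform
    within-cluster read spread)."""
    profiles: dict[str, dict[str, enr.EnrichmentProfile]] = {}
    for rbp, cs in ds.cluster_sets.items():
        by_utr: dict[str, list[tuple[enr.Cluster, tuple[int, int]]]] = {}
        for cl, (uid, s, e) in zip(cs.clusters, ds.cluster_locs[rbp]):
            if uid in expressed and cl.fdr < params.fdr_threshold:
                by_utr.setdefault(uid, []).append((cl, (s, e)))
        profiles[rbp] = {}
        for uid, items in by_utr.items():
            sub = enr.ClusterSet(rbp, [c for c, _ in items], cs.N)
            profiles[rbp][uid] = enr.clip_enrichment(
                sub, None, expressed[uid], [coord for _, coord in items]
            )
    return profiles


def positive_clusters(
    ds: SyntheticDataset, profiles: dict, expressed: dict, params: PipelineParams
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """Transcript-frame footprints of significant clusters with positive
    enrichment over RNA-seq (mean e > 1), per RBP per UTR."""
    out: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for rbp, cs in ds.cluster_sets.items():
        kept: dict[str, list[tuple[int, int]]] = {}
        for cl, (uid, s, e) in zip(cs.clusters, ds.cluster_locs[rbp]):
            prof = profiles.get(rbp, {}).get(uid)
            if prof is None or cl.fdr >= params.fdr_threshold:
                continue
            if enr.mean_cluster_enrichment(prof, s, e) > 1.0:
                kept.setdefault(uid, []).append((s, e))
        out[rbp] = kept
    return out


def footprint_centers(
    footprints: dict[str, dict[str, list[tuple[int, int]]]]
) -> dict[str, dict[str, list[int]]]:
    return {
        rbp: {
            uid: [(s + e - 1) // 2 for s, e in coords]
            for uid, coords in by_utr.items()
        }
        for rbp, by_utr in footprints.items()
    }


# --------------------------------------------------------------- correlation


def correlation_stage(
    profiles: dict[str, dict[str, enr.EnrichmentProfile]],
    params: PipelineParams,
    utr_lengths: dict[str, int],
    rbps: list[str] | None = None,
):
    """All-pairs lag z-score matrix over a seeded UTR subsample.

    The UTR universe is every expressed UTR >= min_utr_len; an RBP without
    clusters on a UTR contributes an all-zero track there, whose lags are
    undefined and drop out of the average (per the zero-variance skip
    rule), so each pair is effectively averaged over the UTRs where both
    partners have signal while all pairs share one universe.
    """
    rng = stage_rng(params.seed, "correlate")
    rbps = rbps if rbps is not None else sorted(r for r in profiles if r != "GFP")
    universe = sorted(
        u for u, l in utr_lengths.items() if l >= params.min_utr_len
    )
    if len(universe) > params.corr_max_utrs:
        idx = rng.choice(len(universe), size=params.corr_max_utrs, replace=False)
        universe = [universe[i] for i in sorted(idx)]
    tracks = {
        rbp: {
            u: (
                profiles[rbp][u].e
                if u in profiles[rbp]
                else np.zeros(utr_lengths[u])
            )
            for u in universe
        }
        for rbp in rbps
    }
    logger.info("correlation: %d RBPs over %d UTRs", len(rbps), len(universe))
    matrix = pcor.pairwise_zscore_matrix(
        tracks,
        rng,
        n_shuffles=params.n_shuffles,
        max_lag=params.max_lag,
        min_len=params.min_utr_len,
    )
    flags, frac = pcor.max_lag_summary(matrix)
    return matrix, flags, frac


# --------------------------------------------------------------------- sites


def sites_stage(
    ds: SyntheticDataset,
    profiles: dict,
    footprints: dict,
    expressed: dict,
    params: PipelineParams,
):
    """Resolve target sites, assign tiers, build random sets, and compute
    site-centered enrichment statistics."""
    rng = stage_rng(params.seed, "sites")
    mirna = [
        mir.MiRNAExpression(row.mirna_id, row.count)
        for row in ds.mirna_counts.itertuples()
    ]
    mir.flag_expressed_mirnas(mirna)
    expr_flags = {m.mirna_id: m.expressed_flag for m in mirna}
    counts = {m.mirna_id: m.mature_read_count for m in mirna}

    resolved: list[mir.TargetSite] = []
    for uid, sub in ds.site_table.groupby("utr_id"):
        if uid not in expressed:
            continue
        sites = [
            mir.TargetSite(
                uid, int(r.seed_start), int(r.seed_end),
                [(r.mirna_id, counts[r.mirna_id])],
            )
            for r in sub.itertuples()
            if expr_flags.get(r.mirna_id, False)
        ]
        if sites:
            resolved.extend(mir.resolve_overlapping_sites(sites))
    if len(resolved) < 3:
        raise ValueError("too few resolved target sites of expressed miRNAs")
    mir.assign_tiers(resolved)
    lengths = {uid: ds.utrs[uid].length for uid in expressed}
    for s in resolved:
        mir.classify_position(s, lengths[s.utr_id])
    hisites = [s for s in resolved if s.tier == mir.TIER_HIGH]

    random_sets = mir.generate_random_site_sets(
        resolved, lengths, rng,
        n_sets=params.n_random_sets,
        n_length_groups=min(params.n_length_groups, len({s.utr_id for s in resolved})),
    )

    # per-RBP meta-profiles around hisites with the random-set envelope
    meta: dict[str, dict] = {}
    for rbp in sorted(r for r in profiles if r != "GFP"):
        prof = profiles[rbp]
        try:
            observed = mir.site_meta_profile(prof, hisites, params.flank)
        except ValueError:
            continue
        rand_means = []
        rand_profiles = []
        for rs in random_sets:
            try:
                rp = mir.site_meta_profile(prof, rs.sites, params.flank)
            except ValueError:
                continue
            rand_profiles.append(rp)
            rand_means.append(np.nanmean(rp))
        rand_profiles = np.array(rand_profiles)
        p5, p95 = mir.random_envelope(rand_profiles)
        meta[rbp] = {
            "profile": observed,
            "p5": p5,
            "p95": p95,
            "p_empiric": mir.empiric_site_pvalue(
                float(np.nanmean(observed)), np.array(rand_means)
            ),
        }

    overlap = {
        rbp: mir.overlap_permutation_test(footprints[rbp], hisites, random_sets)
        for rbp in sorted(r for r in footprints if r != "GFP")
    }
    return resolved, hisites, random_sets, meta, overlap, expr_flags


# ------------------------------------------------------------------ hotspots


def hotspot_stage(
    ds: SyntheticDataset,
    expressed: dict,
    centers: dict[str, dict[str, list[int]]],
    resolved_sites: list[mir.TargetSite],
    expr_flags: dict[str, bool],
    params: PipelineParams,
):
    """Window the expressed UTRs, call hotspots, simulate the uniform null
    and compute per-window features."""
    rng = stage_rng(params.seed, "hotspots")
    acc_lookup = {
        (r.utr_id, r.window_index): r.value
        for r in ds.accessibility.itertuples()
    }
    sites_by_utr: dict[str, list[mir.TargetSite]] = {}
    for s in resolved_sites:
        sites_by_utr.setdefault(s.utr_id, []).append(s)

    all_windows: list[hot.Window] = []
    rbp_names = sorted(r for r in centers if r != "GFP")
    for uid in sorted(expressed):
        utr = ds.utrs[uid]
        wins = hot.partition_windows(utr.length, uid, params.window)
        per_rbp = {
            rbp: centers[rbp].get(uid, [])
            for rbp in rbp_names
            if centers[rbp].get(uid)
        }
        hot.assign_cluster_centers(wins, per_rbp, params.window)
        hot.assign_sites_to_windows(wins, sites_by_utr.get(uid, []), expr_flags)
        cons = ds.conservation.get(uid)
        mafs = ds.mafs.get(uid, [])
        for w in wins:
            hot.window_feature_stats(
                w, cons, mafs, acc_lookup.get((uid, w.index), np.nan), utr.sequence
            )
        all_windows.extend(wins)

    gfp_centers = centers.get("GFP", {})
    kept, gfp_stats = hot.filter_background_windows(
        all_windows, gfp_centers, params.min_rbps, params.window
    )
    table = hot.windows_to_frame(all_windows, params.min_rbps)
    observed_hotspots = int(table["hotspot"].sum())

    per_rbp_counts = {
        rbp: len(
            {
                (uid, c // params.window)
                for uid, cl in centers[rbp].items()
                if uid in expressed
                for c in cl
            }
        )
        for rbp in rbp_names
    }
    null = hot.simulate_uniform_null(
        per_rbp_counts, len(all_windows), rng, params.n_sims
    )
    lo, hi, per_sim = null.hotspot_count_band(params.min_rbps)
    logger.info(
        "hotspots: %d observed, null band [%.1f, %.1f]", observed_hotspots, lo, hi
    )
    return {
        "windows": all_windows,
        "windows_kept": kept,
        "table": table,
        "observed_hotspots": observed_hotspots,
        "null": null,
        "null_band": (lo, hi),
        "gfp_stats": gfp_stats,
        "per_rbp_window_counts": per_rbp_counts,
    }


# ------------------------------------------------------------------------ kd


def kd_stage(
    ds: SyntheticDataset,
    hisites: list[mir.TargetSite],
    centers: dict[str, dict[str, list[int]]],
    expressed: dict,
    params: PipelineParams,
):
    """Classify transcripts by blocked/free hisites (focal factor excluded)
    and compare KD log2FC distributions."""
    non_focal = sorted(
        r for r in centers if r not in ("GFP", params.focal_rbp)
    )
    by_utr: dict[str, list[mir.TargetSite]] = {}
    for s in hisites:
        by_utr.setdefault(s.utr_id, []).append(s)
    classes: dict[str, str] = {}
    for uid in sorted(expressed):
        utr_len = ds.utrs[uid].length
        site_counts = []
        for s in by_utr.get(uid, []):
            ws, we = kdr.site_window(s.seed_end - 1, utr_len)
            n = sum(
                1
                for rbp in non_focal
                if any(ws <= c < we for c in centers[rbp].get(uid, []))
            )
            site_counts.append(n)
        classes[uid] = kdr.classify_transcript(uid, site_counts).group
    kd = ds.kd_table.set_index("transcript_id")["log2fc"]
    classified = {
        t: g for t, g in classes.items() if g != kdr.GROUP_UNCLASSIFIED
    }
    ks_table = kdr.ks_comparison_plan(kd, classified)
    ecdfs = kdr.cumulative_fractions(kd, classified)
    group_sizes = pd.Series(classes).value_counts().to_dict()
    return {"classes": classes, "ks": ks_table, "ecdfs": ecdfs,
            "group_sizes": group_sizes}


# ------------------------------------------------------------------ run all


def run_all(ds: SyntheticDataset, params: PipelineParams) -> dict:
    """Run every stage on a dataset; returns a nested results dict."""
    expr, expressed = expression_stage(ds, params)
    profiles = profile_stage(ds, expressed, params)
    footprints = positive_clusters(ds, profiles, expressed, params)
    centers = footprint_centers(footprints)
    corr_lengths = {uid: ds.utrs[uid].length for uid in expressed}
    matrix, pair_flags, pair_frac = correlation_stage(profiles, params, corr_lengths)
    resolved, hisites, random_sets, meta, overlap, expr_flags = sites_stage(
        ds, profiles, footprints, expressed, params
    )
    hs = hotspot_stage(ds, expressed, centers, resolved, expr_flags, params)
    kd = kd_stage(ds, hisites, centers, expressed, params)
    feature_corr = {}
    for feat in ("mean_phylop", "maf_sum", "accessibility"):
        try:
            feature_corr[feat] = hot.feature_vs_rbp_correlation(hs["table"], feat)
        except ValueError:
            feature_corr[feat] = (float("nan"), float("nan"))
    return {
        "expressed": expressed,
        "profiles": profiles,
        "footprints": footprints,
        "centers": centers,
        "zmatrix": matrix,
        "pair_flags": pair_flags,
        "pair_peak_fraction": pair_frac,
        "sites": resolved,
        "hisites": hisites,
        "meta": meta,
        "overlap": overlap,
        "hotspots": hs,
        "kd": kd,
        "feature_corr": feature_corr,
    }


# ------------------------------------------------------------------- outputs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(results: dict, params: PipelineParams, outdir) -> Path:
    """Write stage outputs as TSV/JSON plus a checksum manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[tuple[str, Path]] = []

    m = results["zmatrix"]
    rows = []
    for i, (a, b) in enumerate(m.pairs):
        for j, d in enumerate(m.lags):
            rows.append((a, b, int(d), m.z[i, j]))
    zdf = pd.DataFrame(rows, columns=["rbp_a", "rbp_b", "lag", "z"])
    p = outdir / "lag_zscores.tsv"
    zdf.to_csv(p, sep="\t", index=False, float_format="%.6g")
    files.append(("correlate", p))

    sites_df = pd.DataFrame(
        [
            (s.utr_id, s.seed_start, s.seed_end, s.total_expression, s.tier,
             s.region_class)
            for s in results["sites"]
        ],
        columns=["utr_id", "seed_start", "seed_end", "total_expression",
                 "tier", "region_class"],
    )
    p = outdir / "resolved_sites.tsv"
    sites_df.to_csv(p, sep="\t", index=False, float_format="%.6g")
    files.append(("sites", p))

    meta_rows = []
    for rbp, d in results["meta"].items():
        prof = d["profile"]
        flank = (len(prof) - 1) // 2
        for off, (v, lo, hi) in enumerate(zip(prof, d["p5"], d["p95"])):
            meta_rows.append((rbp, off - flank, v, lo, hi))
    p = outdir / "site_meta_profiles.tsv"
    pd.DataFrame(
        meta_rows,
        columns=["rbp", "offset", "mean_enrichment", "rand_p5", "rand_p95"],
    ).to_csv(p, sep="\t", index=False, float_format="%.6g")
    files.append(("sites", p))

    p = outdir / "overlap_tests.tsv"
    pd.DataFrame(
        [
            {"rbp": rbp, **vals}
            for rbp, vals in results["overlap"].items()
        ]
    ).to_csv(p, sep="\t", index=False, float_format="%.6g")
    files.append(("sites", p))

    p = outdir / "windows.tsv"
    results["hotspots"]["table"].to_csv(p, sep="\t", index=False, float_format="%.6g")
    files.append(("hotspots", p))

    lo, hi = results["hotspots"]["null_band"]
    summary = {
        "observed_hotspots": results["hotspots"]["observed_hotspots"],
        "null_band_lo": lo,
        "null_band_hi": hi,
        "gfp_stats": results["hotspots"]["gfp_stats"],
        "pair_peak_fraction": results["pair_peak_fraction"],
        "feature_corr": {
            k: {"rho": v[0], "p": v[1]} for k, v in results["feature_corr"].items()
        },
        "kd_group_sizes": {
            str(k): int(v) for k, v in results["kd"]["group_sizes"].items()
        },
    }
    p = outdir / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True, default=float))
    files.append(("summary", p))

    p = outdir / "kd_ks.tsv"
    results["kd"]["ks"].to_csv(p, sep="\t", index=False, float_format="%.6g")
    files.append(("kd", p))

    params_path = outdir / "params.json"
    params_path.write_text(json.dumps(asdict(params), indent=2, sort_keys=True))
    files.append(("params", params_path))

    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("stage\tfile\tsha256\n")
        for stage, path in files:
            fh.write(f"{stage}\t{path.name}\t{_sha256(path)}\n")
    return manifest


# -------------------------------------------------------------- file loading


def load_dataset(indir) -> SyntheticDataset:
    """Rebuild a dataset bundle from a directory written by
    :func:`utrhotspots.synthetic_data.write_dataset`.

    Genome-frame cluster BEDs are projected back into the transcript frame
    of their UTRs.
    """
    import yaml

    from .enrichment import Cluster, ClusterSet, CoverageTrack
    from .synthetic_data import SyntheticConfig

    indir = Path(indir)
    cfg = SyntheticConfig(**yaml.safe_load((indir / "config.yaml").read_text()))

    utr_ivs = iot.read_bed(indir / "utrs.bed")
    seqs: dict[str, str] = {}
    uid = None
    for line in (indir / "utrs.fa").read_text().splitlines():
        if line.startswith(">"):
            uid = line[1:].strip()
            seqs[uid] = ""
        elif uid:
            seqs[uid] += line.strip()
    utrs = {
        iv.name: iot.UtrModel(iv.name, f"{iv.name}.t1", iv, seqs.get(iv.name))
        for iv in utr_ivs
    }
    lengths = {uid: u.length for uid, u in utrs.items()}
    by_chrom: dict[str, list[iot.UtrModel]] = {}
    for u in utrs.values():
        by_chrom.setdefault(u.interval.chrom, []).append(u)

    lib = pd.read_csv(indir / "library_sizes.tsv", sep="\t")
    lib_sizes = dict(zip(lib["sample"], lib["total_mapped_reads"]))

    cov_tracks = iot.bedgraph_to_tracks(
        iot.read_bedgraph(indir / "coverage.bedgraph"), lengths
    )
    M = float(lib_sizes["RNAseq"])
    coverage = {uid: CoverageTrack(uid, t.values, M) for uid, t in cov_tracks.items()}

    cluster_sets: dict[str, ClusterSet] = {}
    cluster_locs: dict[str, list[tuple[str, int, int]]] = {}
    for path in sorted(indir.glob("clusters_*.bed")):
        rbp = path.stem.removeprefix("clusters_")
        clusters, locs = [], []
        with open(path) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                iv = iot.GenomicInterval(
                    f[0], int(f[1]), int(f[2]), f[5], f[3], float(f[4])
                )
                fdr = float(f[6])
                # locate the containing UTR and project
                for u in by_chrom.get(iv.chrom, ()):
                    if iv.start >= u.interval.start and iv.end <= u.interval.end:
                        s, e = iot.to_transcript_frame(iv, u)
                        clusters.append(Cluster(iv, float(f[4]), fdr))
                        locs.append((u.gene_id, s, e))
                        break
        cluster_sets[rbp] = ClusterSet(rbp, clusters, float(lib_sizes[rbp]))
        cluster_locs[rbp] = locs

    mirna_counts = pd.read_csv(indir / "mirna_expression.tsv", sep="\t")
    site_table = pd.read_csv(indir / "mirna_sites.tsv", sep="\t")
    cons_tracks = iot.bedgraph_to_tracks(
        iot.read_bedgraph(indir / "conservation.bedgraph"), lengths, fill=np.nan
    )
    conservation = {uid: t.values for uid, t in cons_tracks.items()}
    maf_df = pd.read_csv(indir / "maf.tsv", sep="\t")
    mafs: dict[str, list[tuple[int, float]]] = {uid: [] for uid in utrs}
    for r in maf_df.itertuples():
        mafs[r.utr_id].append((int(r.position), float(r.maf)))
    accessibility = pd.read_csv(indir / "accessibility.tsv", sep="\t")
    kd_table = pd.read_csv(indir / "kd.tsv", sep="\t")

    truth_windows: dict[str, set[int]] = {uid: set() for uid in utrs}
    tw_path = indir / "truth_windows.tsv"
    if tw_path.exists():
        for r in pd.read_csv(tw_path, sep="\t").itertuples():
            truth_windows[r.utr_id].add(int(r.window_index))
    tg_path = indir / "truth_groups.tsv"
    truth_groups = (
        pd.read_csv(tg_path, sep="\t") if tg_path.exists() else pd.DataFrame()
    )

    return SyntheticDataset(
        cfg, utrs, coverage, cluster_sets, cluster_locs, mirna_counts,
        site_table, conservation, mafs, accessibility, kd_table,
        truth_windows, truth_groups,
    )
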