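# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open (BED convention). Every
per-nucleotide computation runs in the *transcript frame*: position 0 is
the 5' end of the 3'UTR in sense orientation, so for minus-strand genes
genome coordinates are reflected at the reader boundary
(`rel_start = utr_end − genome_end`). "Downstream" therefore always means
toward the 3' end, on both genomic strands. Intervals that partially
overlap a UTR are clipped to it rather than dropped, preserving signal
mass at UTR edges — the densest region of the data. One UTR per gene
(longest protein-coding transcript) is assumed throughout; clusters
straddling a CDS/UTR boundary take the UTR label, and a cluster touching
both UTRs of a transcript takes the larger overlap (3'UTR on a tie).

## Expression normalization and enrichment

Expression is m = Σr / (M·l); a gene is *expressed* when ≥ 50 % of its
3'UTR positions have RNA-seq coverage (boundary inclusive). Enrichment is
e = c / (m·N) per position, zero outside FDR < 0.01 clusters, with no
pseudocounts — genes with m = 0 are excluded by the expression filter
before enrichment is computed. When only per-cluster read totals are
available (the default input shape), reads are spread uniformly over the
cluster footprint; per-base pileups are accepted where provided. A
cluster has *positive enrichment* when its mean e exceeds 1 (equivalently
a positive mean log2 CLIP/RNA-seq ratio); exactly 1 is excluded. Cluster
centers use floor((start + end − 1)/2), i.e. the left-of-middle position
for even lengths.

## Lagged positional correlation

For tracks x, y on one UTR of length l, the lag-d correlation is the
Pearson correlation of x[i] with y[i+d] over the overlap window. The
engine evaluates all 401 lags at once from an FFT cross-correlation plus
prefix-sum moments, and is tested for ≤ 1e-10 agreement with a direct
sliced implementation. A slice with (numerically) zero variance gives an
undefined correlation, which is skipped when averaging over UTRs; a lag
with no contributing UTR is undefined, never silently zero. UTRs shorter
than 400 nt are discarded.

The shuffle null relocates contiguous signal runs (values > 1e-6) to
positions drawn uniformly over all order-preserving arrangements with at
least one empty position between clusters, via stars-and-bars sampling of
the gap composition — exact, rejection-free, and verified uniform against
enumeration. 100 shuffles (the default) give per-lag mean and sample sd
(ddof = 1), from which z-scores for the unshuffled data follow. In the
all-pairs matrix the same shuffle replicates of a track are shared by
every pair involving it (shuffle everything once per replicate, then
correlate); for a self-pair, replicate t is paired with replicate t+1 of
the same track, because pairing a shuffle with itself makes the self-null
degenerate (r ≡ 1 at d = 0). The matrix stores ordered pairs and exploits
r(a,b,d) = r(b,a,−d). Row normalization and 1000-quantile color binning
are provided as metadata operations.

The z-matrix stage is O(pairs × shuffles × UTRs), so the pipeline
computes it over a seeded subsample of UTRs (`corr_max_utrs`, default
40) — enough for stable peak-lag detection while keeping the default
end-to-end run at minutes scale; the per-pair functions accept any UTR
set. The pair universe is every expressed UTR ≥ 400 nt; an RBP with no
clusters on a UTR contributes an all-zero track whose lags drop out via
the undefined-value rule, so all pairs share one universe without
discarding informative UTRs.

## miRNA target sites

Only predictions with ≥ 6-mer seeds and expressed miRNAs (top 20 % of
mature-miRNA read counts; ties at the cutoff included) are used. Identical
seeds merge, summing expression; among overlapping non-identical seeds
the one whose single most-expressed miRNA is highest wins (ties: leftmost
seed, then lexicographic miRNA id). Resolved sites are sorted by total
expression and cut into three equal tertiles — remainders go to the lower
tiers so the hisite tier is never the largest. Proximal/medial/distal
classification uses the seed midpoint's third of the UTR.

Random site sets (100 by default) preserve each site's relative position:
UTRs carrying sites are split into 30 equal-size length groups, each site
is reassigned uniformly within its group, and new_start =
round(rel_pos · new_L), clamped so the seed fits. Empiric p-values use
the add-one rule (1 + #{random ≥ observed}) / (1 + n) so finite
permutation sets never give p = 0. Site-centered meta-profiles anchor at
the seed start with a ± 50 nt default flank (configurable; the flank is a
presentation choice, not a claim). Cluster–site overlap means ≥ 1 shared
nucleotide.

## Windows, hotspots and features

Expressed UTRs are tiled with 50-nt windows; the trailing remainder is
kept as a shorter final window and flagged by its length, so either
convention is recoverable downstream. Each positive-enrichment cluster
votes its RBP into the single window containing its center (deduplicated
per RBP); a window with ≥ 5 distinct RBPs is a hotspot. A seed site is
assigned to the one window it overlaps by > 5 nt, else discarded. The
uniform null redraws each RBP's occupied-window count uniformly without
replacement over all windows, 10 000 times by default, reporting per-size
count distributions and a 2.5–97.5 percentile envelope; the identity
Σ_k k·count(k) = Σ_R n_R holds in every simulation by construction.

Window features: mean phyloP over alignable (non-NaN) positions; MAF sum
over qualifying variants (allele count ≥ 2 of 5008 haplotypes, MAF = 1 −
major-allele frequency); accessibility consumed as precomputed per-window
(or averaged per-position) unpaired probabilities; base composition and
AUUUA counts (overlapping occurrences counted) from the sequence.
Feature–occupancy associations use Spearman rank correlation of per-window
RBP count against the feature, optionally within a miRNA-overlap stratum;
constant features return NaN rather than an error. Background control:
windows containing a GFP cluster center (GFP processed identically to
RBPs) are flagged and removed, with the flagged fractions reported.

## Knockdown response

The anchor window for a miRNA hisite is [seed_end − 35, seed_end + 15),
shrunk to fit the transcript; for RBP-centered analyses a symmetric 50-nt
window around the cluster center is used. Counting distinct non-focal
RBPs per anchor window (the focal factor, e.g. the silencing machinery
being depleted, is excluded), a site is free (≤ 2) or blocked (≥ 5);
transcripts group as 0 (all free), 1, 2+ blocked, with a no-sites
control. Transcripts whose sites include a 3–4-RBP window but no blocked
site fit neither definition and are excluded as unclassified; their count
is reported so alternative rules can be compared. The fixed comparison
plan is each blocked group vs group 0 and group 0 vs no-sites, by
two-sided two-sample KS. An expression-matched control resamples each
group to the pooled expression decile histogram (10 bins) and reruns the
comparison as a confound check.

## Synthetic data: what it emulates and what it does not

The generator produces every input the pipeline reads, plus a ground-truth
ledger never consumed by the analysis. Defaults (500 genes, log-normal
UTR lengths with mean ~1.2 kb, 12 RBPs at 1.2 background clusters/kb with
log-normal lengths around 26 nt, 60 miRNAs with power-law expression,
5 % of windows designated) are sized so permutation and KS analyses have
power at minutes-scale runtimes.

Co-binding is modeled as *per-window recruitment*: each RBP places a
cluster at each designated window with probability `co_binding_fraction`
(default 0.6), centered on a fixed per-window anchor with N(0, 3 nt)
jitter. The jittered common anchor reflects the structure the analysis is
designed to detect — near-exact co-localization, with peak positional
correlation within a few nucleotides — rather than mere co-occupancy of a
50-nt window, which would spread the cross-correlation peak over ± 49 nt.
Designated windows also carry a +0.5 phyloP shift, a 60 % multiplicative
MAF reduction, a +0.15 accessibility boost over a Beta(8,12) base, and
75 % AU sequence content vs 60 % background; a quarter of miRNA seeds are
placed inside designated windows and the rest mix uniform placement with
a 3'UTR-edge bias. Knockdown log2 fold changes are N(kd_shift, noise_sd)
for transcripts whose expressed-miRNA sites all avoid designated windows
(free responders) and N(0, noise_sd) otherwise. Effect sizes were
calibrated once, before release, so each injected effect is recoverable
at the default scale (~10⁴ windows; a full-scale study has 10⁵+, so the
per-window effects here are deliberately larger than real data would
show); with all effects zeroed the pipeline's p-values are verified
uniform. A separate KD generator (`generate_kd_dataset`, 12 000
transcripts) provides the sample sizes a KS comparison of a 0.2-sd shift
needs, chosen by a power analysis of the two-sample KS test.

Not emulated: read-level artifacts (mapping error, T→C conversion,
duplicate structure), peak-calling behavior (FDR values are generated
labels), isoform complexity (one transcript per gene), genuine sequence
motifs beyond AU content, and correlations between features other than
those injected. Passing tests therefore demonstrate the statistics behave
correctly under the assumed generative structure, not that real data
satisfies that structure.

## Numerical and design choices

* Zero-variance correlation slices → NaN, excluded from averages;
  divisions guard against NaN/inf and flag rather than zero-fill.
* Shuffle-null sd uses ddof = 1; z is NaN where sd = 0.
* The empiric p-value's add-one rule bounds p in [1/(n+1), 1].
* Tie-breaks are deterministic everywhere (stable sorts; documented
  left-of-middle centers; leftmost-then-lexicographic site resolution),
  so a fixed seed reproduces byte-identical outputs.
* Each pipeline stage draws from an RNG stream derived from the master
  seed and the stage name (seed sequence [seed, crc32(stage)]), so
  toggling one stage does not perturb another's randomness.
* Performance: the lag engine is FFT-based with shared per-track
  transforms across the pair matrix; the uniform null is vectorized per
  simulation. Default problem sizes (40-UTR correlation subsample, 10⁴
  hotspot simulations, 100 shuffles and random sets) are the package's
  chosen operating point for interactive use.

## Known limitations

* The uniform hotspot null pools windows across UTRs; short trailing
  windows have slightly lower real occupancy than the null assumes. The
  effect is far inside the envelope width at default scale.
* The positive-enrichment threshold (mean e > 1) is scale-dependent
  through library sizes; callers supplying real data should check the
  enrichment distribution before relying on the default.
* `corr_max_utrs` trades z-matrix stability for speed; increase it for
  final analyses on real data.
* The expression-matched control requires every expression decile to be
  populated in every group and raises otherwise (naming the bin) instead
  of silently reweighting.
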