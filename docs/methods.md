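# Methods

## Scope and data model

`pacpipe` quantifies alternative polyadenylation (APA) from aligned
3′-end sequencing evidence and scores the G-quadruplex (G4) propensity
of the sequence flanking each polyA cluster. The raw unit is an
*end-read record*: chromosome, strand, the 0-based coordinate of the
read's last templated nucleotide (the cleavage position), and the
length of its untemplated-A tail. Alignment, trimming and tail
extraction are upstream of this package. Internally all coordinates are
0-based half-open; GTF (1-based closed) is converted at the boundary.
One transcript per gene is assumed (the longest when several are
annotated): the analysis concerns last-exon/3′-UTR events, for which 5′
isoform structure is irrelevant.

## Site calling and artifact removal

A polyA site is a nucleotide position supported by reads whose tail
length is at least `min_tail` (25 nt) and whose pooled count across all
samples is at least `min_reads` (5). Pooling (rather than a per-sample
threshold) builds one project-wide site catalogue that every sample is
then quantified against; per-sample counts are retained.

Internal priming — the oligo(dT) primer annealing to a templated
genomic A-tract rather than a real tail — is removed at the site level:
a site is discarded when the `ip_window` (10) genomic nucleotides
immediately 3′ of the cleavage position on the sense strand contain at
least `ip_max_a` (7) adenines in total or a run of at least
`ip_max_run` (6). These thresholds follow common 3′-seq practice and
are configurable; the tail filter deliberately cannot catch these
artifacts in our simulations (decoy reads carry passing tails), so the
genomic filter is what is exercised.

## Clustering and annotation

Sites on one chromosome and strand merge into polyA clusters (PACs) by
single-linkage chaining with gap `cluster_gap` (10 nt): consecutive
sorted sites at distance ≤ 10 join the same cluster, so sites at 100,
108, 116 form one PAC. The representative position is the member site
with the largest pooled count — the best single-nucleotide summary of
the cleavage distribution — with ties broken toward the 3′ end in
transcription direction.

Each PAC is assigned to the same-strand gene whose span contains its
representative position; antisense PACs are intergenic. Regions are
`UTR3_last_exon` (in the last exon, 3′ of the stop codon),
`internal_exon`, `intron`, or `intergenic`. `dist_from_stop` is the
*exonic* (transcript-coordinate) distance from the stop codon, so an
intron between the stop and a downstream PAC does not inflate
distality. When overlapping same-strand genes both contain a PAC, the
gene whose stop codon lies nearest 5′ of it wins and the ambiguity is
logged.

## Differential statistics

Both tests are deliberately lightweight, calibration-checked stand-ins
for heavier GLM machinery; the pipeline's contribution is its logic and
thresholds, not the test internals.

**Gene-level expression.** Gene counts (sum of the gene's PAC counts
per sample) are scaled by median-of-ratios size factors (geometric-mean
reference over zero-free genes; total-count fallback below 10 such
genes). The Wald statistic on the log2 fold change uses a
method-of-moments negative-binomial dispersion, pooled within
condition and floored at 0.01, and is referred to a t distribution with
n₁+n₂−2 degrees of freedom — with triplicates the dispersion estimate
is noisy, and the normal reference is visibly anticonservative. A 0.5
pseudocount keeps zero-count conditions finite. P-values are
Benjamini–Hochberg adjusted; a gene is called at fold change strictly
greater than `fc_min` (1.5) in either direction and padj < `padj_max`
(0.1).

**PAC usage.** Usage is the PAC's share of its gene's reads in one
sample; samples with a zero gene total are missing. Only PACs with
pooled-mean occupancy ≥ `occupancy_min` (0.05), in genes with ≥2 such
PACs, are tested. The fractional change is the difference of
condition-mean usages (absolute percentage points); the p-value is a
Welch t-test on arcsine-square-root transformed replicate usages
(variance-stabilizing for proportions), BH-adjusted over all tested
PACs. Significance requires padj < 0.1 **and** |change| ≥
`usage_change_min` (0.10, inclusive). Arms with fewer than two
informative replicates are untested (p = 1). BH stands in for
independent-hypothesis weighting; no covariate weighting is attempted.

**Boundary semantics.** Fold change is strict (">1.5-fold"); usage
change is inclusive ("at least 10%"); the candidate ΔPDUI filter is
inclusive at 0.12 (events *below* 0.12 are removed).

## PDUI and event classification

For a gene whose retained (occupancy-passing) PACs all sit in the last
exon at distances d₁ ≤ … ≤ d_K from the stop codon, each PAC gets the
linear distality weight wᵢ = (dᵢ−d₁)/(d_K−d₁) and

PDUI = Σᵢ ūᵢ·wᵢ,

where ūᵢ is the condition-mean usage renormalized over the retained
PACs. Condition means (not pooled raw counts) keep replicate-depth
differences from biasing the index. The two-PAC case reduces exactly to
LU/(LU+SU), the long-isoform share, which is also how the
band-intensity helper `pdui_from_intensities` computes it (after
dividing each band by its loading control). ΔPDUI = PDUI(treated) −
PDUI(control); positive = lengthening.

Classification uses retained PACs only: no event without ≥2 retained
and ≥1 significant; `splicing` when they span more than one exon or
include an intron; otherwise `both` when a strictly internal PAC among
≥3 is significant; otherwise the sign of ΔPDUI decides
lengthening/shortening. An exact ΔPDUI of 0 falls back to the sign of
the distal-most significant PAC's usage change, and a still-undecided
gene is no event. A gene whose retained PACs sit in one exon but
include one 5′ of the stop codon has no defined distal index and
yields no event.

## G4 scoring

**G4Hunter.** Per-base scores: each base of a maximal G-run of length k
scores min(k, 4); C-runs score −min(k, 4); others 0. The sequence score
is the maximum over all sliding windows (width `g4h_window` = 25, or
the sequence length if shorter) of the window mean; range [−4, 4],
positive above `g4h_min` = 0.9. The specifics (run caps, window, max
over windows) follow the original G4Hunter formulation.

**cG/cC.** Each maximal G-run of length k contributes k(k+1)/2 to cG,
C-runs likewise to cC; the score is cG / max(cC, 1), positive above
`cgcc_min` = 4.5. The superlinear weighting rewards consecutiveness and
the unit denominator floor reproduces the large values of C-free G-rich
regions. The exact weighting of the published screener is not
documented; this triangular form is this package's documented variant,
and no parity with printed third-party scores is claimed.

**Windows.** Each PAC's flank is the sense-strand (transcribed)
sequence at representative position ± `flank` (100 nt), reverse-
complemented for minus-strand PACs and truncated at chromosome ends. A
window is positive when at least one score exceeds its threshold; the
provenance (`G4H`, `cGcC`) is recorded. The neural-network score of the
G4RNA screener family is not implemented — its trained weights are not
published — so the disjunctive rule runs over the two sequence scores,
and `g4nn_min` is carried in the configuration only for completeness.

## Candidate selection

Events with category lengthening/shortening/both whose retained PACs
are confined to a single last exon pass the structural filter
(enforced on occupancy-passing PACs, consistent with how `splicing` is
defined); then at least one of the gene's retained-PAC flanks must be
G4-positive; then |ΔPDUI| ≥ `dpdu_min` (0.12). Windows positive *only*
by cG/cC are flagged `cgcc_only` and, with `exclude_cgcc_only` on (the
default), do not satisfy the G4 requirement — a mechanized, reproducible
equivalent of manually curating cG/cC-only false positives. The run
report counts genes per funnel stage (analyzed → significant APA →
non-splicing → with pG4 → ΔPDUI-passing); stages are nested, so counts
are monotone non-increasing.

## The synthetic-data generator

The generator emulates a two-condition, three-replicate PAC-seq
experiment with known truth. Defaults and rationale:

- **Layout**: one 50-kb chromosome per 10 genes; each gene has a 300-nt
  first exon, 200-nt intron and 3-kb last exon, the stop codon 60 nt
  into the last exon, and 2–4 PASs at 250–400 nt then 400–700 nt
  spacings downstream of the stop — wide enough that distinct isoforms
  are resolvable and clusters never bridge.
- **Background composition**: i.i.d. with A/T = 0.32, C/G = 0.18 (~36%
  GC, typical of AT-rich 3′-UTR neighbourhoods). Composition matters:
  under a uniform composition about a quarter of random 201-nt flanks
  already exceed the 0.9 G4Hunter threshold somewhere (a max over 177
  windows), which would drown any planted-motif contrast. At 36% GC the
  motif-free flank positivity is ~4–6%.
- **DSE**: a 12-nt U-rich element (poly-T on the sense strand) directly
  3′ of every PAS, as at real polyadenylation sites. A side effect is a
  guarantee that genuine, cleavage-jittered sites can never trip the
  internal-priming filter, so that filter is exercised exclusively by
  the planted decoys.
- **Counts**: per-gene per-sample totals are negative-binomial
  (`depth_mean` 1000, dispersion 0.05 — typical bulk-RNA-seq
  overdispersion); allocation over PASs is multinomial on the
  condition's usage vector, so per-gene read sums are conserved by
  construction.
- **Cleavage heterogeneity**: symmetric truncated-geometric jitter
  (p = 0.5, max ±5 nt) around the true PAS keeps ≥95% of reads within
  the 10-nt chaining gap.
- **Tails**: tail length is 25 + Poisson(15) for genuine and decoy
  reads; a 1% "degraded" fraction gets uniform sub-25 tails at random
  3′-UTR positions to exercise the tail filter.
- **Decoys**: one A₁₀ tract per gene planted mid-intron; 5% of the
  gene's reads cleave exactly there with passing tails, so only the
  genomic A-content rule can remove them.
- **Planted effects**: APA genes are two-PAC genes whose
  (proximal, distal) usage moves from `apa_usage_control` (0.63, 0.37)
  to `apa_usage_treated` (0.45, 0.55) — an expected ΔPDUI of +0.18,
  matching a distal-usage gain from 37% to 55% — with a (GGGN)₃GGG
  motif (N ∈ {A,T}) planted 25–80 nt from the shifted distal PAS.
  Splicing genes carry a third PAS mid-first-exon whose usage rises
  0.25 → 0.50. Null genes share one Dirichlet(5) usage vector across
  conditions; a `g4_planted_fraction` of them also receive a motif so
  G4 presence is not confounded with APA.
- **Controls**: for every planted motif, a dinucleotide-shuffled copy of
  the flank *as it read before the motif went in* is parked in the
  gene's intergenic control slot. This control asks whether the scorers
  fire on the neighbourhood's composition alone. Shuffling the
  motif-bearing flank instead would not work as a negative control for
  run-content scores: a dinucleotide shuffle preserves the GG adjacency
  count exactly, hence the motif's G-run mass, and such shuffles remain
  G4Hunter-positive in 30–70% of draws at any background composition —
  measured here, and the reason trained models exist alongside
  composition scores.
- **Determinism**: one seeded generator drives every draw in a fixed
  order; identical configurations give byte-identical files.

What the generator does *not* model: sequencing errors and quality,
alignment ambiguity, transcript-level isoform structure beyond one
transcript per gene, chromatin or expression covariates, PAS-motif
grammar (hexamer strength, CFIm sites), and any ligand chemistry.
Passing tests on these simulations therefore establishes the internal
correctness and calibration of the chain — not parity with any
dataset-level numbers from real sequencing runs, which depend on
genome build, depth and the full screener including its trained
component.

## Verification problem sizes

The acceptance machinery (tests and `scripts/acceptance.py`) uses:
1,000 random site sets (n ≤ 50) against an O(n²) single-linkage
oracle; 2,000 random count pairs for the two-PAC PDUI identity
(≤ 1e-12); 1,000 random 50–300-nt sequences against exhaustive G4Hunter
and cG/cC re-implementations; 2,000-gene 3v3 null simulations for both
test calibrations; 100 single-gene simulations at depth 1500 and
dispersion 0.02 (≥200 reads/PAC/replicate) for the 0.37 → 0.55
recovery; 400 planted motif/control pairs (the ~6% control positivity
has a ~1.2-point Monte-Carlo error at this size); a 100-gene cohort
with 10 planted APA+G4 genes and 5 splicing genes for funnel recovery;
and two full reruns for bitwise determinism.

## Known limitations

- The distance-linear PDUI weighting is a faithful reading of a
  verbally described index; other monotone weightings are possible and
  would differ for ≥3-PAC genes.
- BH in place of covariate-weighted multiple-testing adjustment; no
  dispersion shrinkage across genes; no GLM covariates beyond the
  two-condition design.
- cG/cC run weighting is this package's documented variant.
- "Fractional change" is absolute (percentage points), not relative.
- G4 positivity here is two-score; a cG/cC-only call is flagged rather
  than adjudicated, and no thermodynamic or trained-model score is
  computed.
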