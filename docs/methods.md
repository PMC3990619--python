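# Methods

This note documents the models and conventions implemented in
barcodekit, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the package's known
limitations.

## Quality control

A sequence fails QC — with the first matching reason recorded — when

1. its non-gap length is below 220 bp (`TOO_SHORT`);
2. its fraction of non-ACGT symbols strictly exceeds 1%
   (`AMBIGUITY_EXCESS`) — "more than 1%" is read as a strict
   inequality, and only IUPAC ambiguity codes count, not alignment
   gaps, which are stripped before any check;
3. its best reading frame still contains an internal stop codon under
   the invertebrate mitochondrial code, translation table 5
   (`STOP_CODON`).

The reading frame is chosen as the frame (0, 1, 2; optionally both
strands) minimising internal stops, ties broken to the lowest index.
The trailing partial codon is ignored, and a stop that is the final
complete codon is not counted as internal. QC is a partition of the
input (every record appears exactly once in passed or failed) and is
idempotent on its passed set.

Chromatogram-level artefacts ("double peaks") cannot be recovered from
FASTA input and are out of scope; that filter from trace-based
workflows is a documented gap here.

Length-eligibility gates for OTU algorithms read "greater than"
strictly: BIN-like algorithms require > 500 bp, others > 400 bp.

## Distances

Pairwise comparisons use **pairwise deletion**: any site with a gap or
ambiguity code in either sequence is excluded from the overlap. From
transition fraction P and transversion fraction Q over the overlap, the
Kimura 2-parameter distance is

    d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q).

A cell is masked *undefined* (never clamped) when the unambiguous
overlap is below 60% of the shorter sequence's non-gap length — a
comparability floor applied to every pair — or when either logarithm
argument is non-positive (saturation).

Distances are stored as proportions; report layers convert to percent
with two decimals.

**Species summaries.** For each species: `max_intra`/`mean_intra` over
all defined conspecific pairwise distances (undefined for singletons,
rendered as a hyphen); `nn_distance` = minimum defined distance from
any member to any heterospecific individual; `barcode_gap = present`
iff `nn_distance > max_intra` strictly — an exact tie counts as
absent. The study-level mean intraspecific divergence is the
*unweighted mean over species* (with ≥ 2 records) of the per-species
mean of all conspecific pairwise distances, not a specimen-weighted
mean and not a mean of maxima. An "excluding deep divergence" variant
drops species whose maximum exceeds the deep threshold (default 2%).

**Genus summaries** average member species' NN distances unweighted;
sampling completeness is 100 × sampled / known when a known-species
count is supplied in the metadata (these counts are user inputs; no
registry is queried).

**Divergence times** convert % K2P to million years as t = d / rate
with a default rate of 2% per My. The rate is interpreted as *pairwise*
divergence per million years (so a 5.9% split dates to ~2.95 My); a
per-lineage reading would halve the rate and double the ages. The
choice is configurable and flagged here rather than asserted.

## Neighbour joining

Standard Saitou–Nei agglomeration: join the pair minimising
Q(i,j) = (n−2)·d(i,j) − R(i) − R(j); branch lengths from the
rate-corrected split formula; the final two clusters joined by a single
edge (yielding a degree-3 unrooted root). Determinism and robustness
choices:

* Q-ties break to the lexicographically smallest pair of cluster
  labels (each cluster labelled by its smallest member id), so trees
  are reproducible.
* Negative branch lengths are clamped to zero with the deficit moved to
  the sister branch, the usual practical convention.
* Masked cells: the default policy drops, greedily, the taxa with the
  most undefined cells until the submatrix is complete; `strict` raises
  instead, listing offending pairs.

On additive inputs (four-point condition) NJ provably recovers the
generating topology and branch lengths; the test suite verifies this
exactly against a least-squares enumeration oracle over all unrooted
topologies for 4 and 5 taxa, and cross-checks patristic distances
against an independent NJ implementation.

**Deep-divergence reports.** Species whose `max_intra` strictly exceeds
2% are flagged. Their leaves are grouped into maximal clades that are
conspecific; a clade is further split at its root while the branches
joining its children sum to more than the threshold (as a proportion),
so a monophyletic species with one deep split yields its two lineages.
Each lineage carries its member ids and localities, and the case an age
estimate from `max_intra`.

## OTU delimitation

**Threshold clustering** takes single-linkage connected components of
the graph with edges d ≤ threshold (≤, so a distance exactly at the
threshold joins); masked cells are never edges. The default 2%
threshold corresponds to round(0.02 × 648) = 13 bp differences over the
full barcode. The original MOTU tool's BLAST prefilter is replaced by
the 60% minimum-overlap mask already applied in the distance matrix — a
documented divergence from that tool. BIN/RESL is not re-implemented
(server-side, unpublished); only its > 500 bp gate is modelled, with
threshold clustering as the comparison partner.

**Barcode-gap discovery** (ABGD-style). For each prior P on a
log-spaced grid from 0.0006 to 0.17 (10 steps; the original priors, a
stand-in grid size) the ranked pairwise distances are scanned for the
first significant gap *beyond the prior*: consecutive observed
distances (lo, hi) with hi > P and hi − lo > X · max(lo, P), X = 1.5.
The group is split by single-linkage at lo and each subgroup re-scanned
recursively; no qualifying gap terminates the recursion. The interval
below the smallest observed distance is not a candidate, so a uniform
cluster never shatters. OTU counts are non-increasing in the prior.
One partition ("scheme") is emitted per prior; the selected scheme is
the longest run of consecutive priors with an equal OTU count,
excluding the degenerate all-merged tail when an alternative exists and
breaking ties toward larger priors (very low priors systematically
over-split). A manual scheme override reproduces a curated choice.
This is a reimplementation of the barcode-gap idea, not a byte-level
replica of the original ABGD program.

**Congruence** between partitions is the fraction of shared-sequence
pairs on which the two partitions agree (both co-clustered or both
separated): 1 iff the groupings are identical, 0 when they disagree on
every pair.

## Indels and COI structure

**Alignment.** Queries are aligned to a stop-free frame-0 reference.
The primary route translates both under table 5 and aligns the proteins
globally (BLOSUM62, gap open −11 / extend −1, free end gaps, so
genuinely truncated barcodes pay nothing at their ends), then threads
the amino-acid alignment back onto nucleotides — gaps therefore open in
whole codons. Queries whose translation retains internal stops fall
back to nucleotide-level alignment and are marked frame-shifted, so
sub-codon gaps remain representable. Queries below 50% amino-acid
identity (or 60% nucleotide identity, or 50% coverage) are excluded as
unalignable and listed on the result. The by-eye alignment step of
manual workflows is thus automated; the pipeline picks as default
reference a sequence of the modal length among QC-passed records, since
indel carriers are longer or shorter than the bulk.

**Events.** Maximal gap runs per sequence become events anchored to
1-based codon sites in the reference frame. An insertion between
reference codons k−1 and k is reported at site k (the site it
precedes), keeping neighbouring insertion-at-37 and deletion-at-36
events distinct. Events identical in (kind, site, length) are merged
across sequences, accumulating (species, family) pairs. Gap runs
touching the aligned ends are truncation, not indels, and are skipped;
in addition, events overlapping the outermost 4 codons of the reference
are suppressed, because terminal gap placement can be traded against
end mismatches and is not reliable.

**Pseudogene screen.** A sequence is flagged `PUTATIVE_PSEUDOGENE` iff
it carries a frame-shifting indel or an internal stop at/downstream of
its first indel site; in-frame (codon-multiple) indels alone are
consistent with a functional gene and are not flagged. Flagged
sequences are excluded from distance/clustering stages by default but
retained in indel reports.

**Structure mapping.** Events are labelled by a codon-interval region
table covering the 216-codon barcode — transmembrane helices
alternating with external/internal loops, the first external loop at
codons 31–42 — shipped as an editable TSV resource. The boundaries are
an approximation derived from the standard COI membrane topology;
region *labels* near boundaries may differ from other published
mappings even where sites agree, which is why events within 2 codons of
a boundary also carry `near:<region>` tags. Sites hit by events from
two or more families are reported as hotspots.

## Composition statistics

* GC content is 100·(G+C)/(A+C+G+T) over unambiguous bases; species-
  level composition pools counts across conspecific sequences (pooling
  chosen over averaging; both give identical results for equal-length
  sequences).
* Homogeneity of base frequencies among species is a Pearson chi-square
  on the species × {A,C,G,T} count table, df = (k−1)·3, computed within
  each class (an across-class variant is a call away). Expected counts
  below 5 warn but do not abort.
* The GC–NN relationship across genera uses Pearson's r (Spearman
  available) with a t-distribution p-value and a seeded percentile
  bootstrap 95% CI over genera; fixed seeds make the CI bit-reproducible.
* Divergence-vs-sample-size regressions are ordinary least squares on
  species with ≥ 2 records, reporting slope, R² and p. Under a null
  with divergence independent of n, the empirical type-I error at
  α = 0.05 is calibrated to [0.03, 0.07] over 2,000 replicates in the
  test suite.
* NN-vs-completeness uses one-way ANOVA over completeness bins, default
  20-percentage-point categories (configurable; empty bins are dropped
  with a warning; zero-variance input is flagged degenerate rather than
  tested).
* Success rates are 100·sequences/specimens to one decimal, with an
  optional k×2 chi-square of (success, failure) across classes.

## Synthetic data generator

The generator produces a library with known truth so that every stage
is testable offline; its defaults describe the study conditions the
package targets.

**Substitution model.** A discrete two-parameter process: at distance d
with transition/transversion rate ratio κ (default 3, typical for COI),
each site independently experiences a transition with probability

    P(d) = ¼ + ¼·e^{−4βd} − ½·e^{−2(α+β)d}

and a transversion with probability Q(d) = ½·(1 − e^{−4βd}), where
β = 1/(κ+2), α = κβ, so the expected number of substitutions per site
is d and the K2P estimator is consistent for d (`simulate_pair` exposes
exactly this process as the estimator-recovery oracle). There is no
rate heterogeneity across sites — none of the implemented analyses
assumes any.

**Library structure.** One stop-free ancestor (exact-composition draw
at the target GC, default 37%; stop codons are repaired by
composition-preserving swaps so neither the stop constraint nor
sampling noise biases GC). Species roots evolve from the ancestor at
half a uniform draw from the interspecific range (default 8–16%
pairwise), so interspecific distances stay inside the range instead of
saturating; specimens evolve from their species root at half the
intraspecific scale (default 0.5% pairwise, matching the
well-under-1% intraspecific divergence typical of molluscan barcodes).
About 35% of species are singletons; the rest have 2 + Poisson
specimens (mean 8). Deep-split species get two sub-lineages joined at a
configured depth (default 6%), labelled Pacific/Atlantic to emulate
trans-Arctic partitions. Derived codons that would be stops revert to
their parent state — a negligible distance bias that keeps all clean
sequences QC-passing. Composition drifts slightly toward 50% GC along
deep branches (about +1 to +1.5 percentage points at the default
interspecific depths); the emitted library's mean GC therefore sits
just above the nominal target.

**Planted indels** are specified as (codon site, length, kind, species)
and applied to every specimen of the species, high-coordinate first so
sites stay in ancestor coordinates. To make recovery well-defined, the
affected block's amino acids must differ from both flanking amino acids
(deletion blocks on the ancestor are redrawn until this holds;
insertion blocks are drawn to satisfy it), and a ±10-codon window
around each indel is held free of substitutions so that every carrier
presents the ancestral local context and the alignment anchors the
event at exactly the planted site. Planted sites flush against the
sequence ends are rejected, matching the detector's edge margin.

**QC failures** are appended as extra records — truncations below
220 bp, reads with ~1.5% N's, and frameshifted pseudogene-like copies —
each verified against `qc_filter` at generation time and listed in the
truth manifest.

**What it does not emulate** — and hence what passing tests do *not*
show about real data: coalescent genealogies within species,
selection, rate variation among sites or lineages, compositional bias
in the substitution process, heteroplasmy/doubly uniparental
inheritance, contamination, chromatogram noise, or the long-tailed
length distribution of degraded amplicons (lengths here are full-length
minus planted truncations). Results on real libraries depend on those
factors; the synthetic results certify the algorithms, not the biology.

## Problem sizes

The default test suite and the acceptance script are sized to run
comfortably on one CPU: 1,000 random (P,Q) pairs for the K2P oracle
check; 50 random additive matrices each for 4 and 5 taxa; ≥ 200
randomized planted-indel fixtures (5 species × ~3 specimens); 50 seeds
of a 12-species library for OTU recovery; 1,000 simulated pairs per
distance for estimator calibration; 2,000 replicates for regression
calibration; and a study-scale pipeline run of 100 species (~35%
singletons, 5 deep splits, 8 planted indels at the hotspot sites,
~560 sequences). The whole suite completes in well under a minute;
`scripts/acceptance.py` in ~15 seconds.

## Known limitations

* "Double peak" (heterozygous/heteroplasmic trace) filtering is not
  possible from FASTA input.
* The barcode-gap discovery scheme follows the published idea, not the
  original program's exact gap statistic; scheme counts can differ from
  the original tool on the same data even when the selected partition
  agrees.
* The COI region map is an approximate topology; site assignments are
  exact, region labels near boundaries are not guaranteed to match
  other mappings.
* Indel calls within 4 codons of the reference termini are suppressed
  as unreliable; genuine terminal indels are therefore invisible.
* The default alignment reference (modal-length QC-passed sequence) can
  be wrong in pathological libraries where indel carriers form the
  majority; pass an explicit reference in that case.
* NJ is O(n³): fine for hundreds of sequences, slow beyond a few
  thousand.
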