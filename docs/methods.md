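# Methods

This note documents the models, estimation procedures and numerical
choices behind `coldadapt`, and what its synthetic-data tests do and do
not demonstrate about real genomes.

## Conventions

Coordinates are 1-based inclusive on the forward strand throughout (the
GFF3 convention); nothing internal uses half-open intervals, which keeps
off-by-one drift out of the window arithmetic.  The nucleotide alphabet is
restricted to {A, C, G, T, N}: other IUPAC codes become N on read, with a
warning.  GC% excludes N from numerator and denominator — an all-N
assembly has undefined GC, reported as NaN.  Peptides never carry a
terminal stop; a codon containing N translates to X, and X residues are
excluded from both sides of every flexibility percentage (an unknown
residue carries no flexibility information).

## Small ORFs

A smORF is an ATG followed by the first in-frame stop, with total span
(stop included) of 30–300 nt.  All six frames are scanned exhaustively;
nested ATGs each report their own ORF; alternative starts (GTG/TTG) are
not considered, ORFs never wrap contig ends, and N-containing codons are
neither starts nor stops.  These conventions are stated explicitly because
published smORF totals are notoriously sensitive to them; the testable
surface of the scanner is exact agreement with a brute-force six-frame
enumeration on random sequence, plus 100% recall of generator-planted
ORFs.

Positional classes are assigned by *containment*, not overlap: an ORF
wholly inside a CDS interval (strand-agnostic) is a `CDSSmORF`; otherwise
wholly inside the 1,000-nt window upstream of some CDS — upstream being
defined by that CDS's strand — a `5'SmORF`; otherwise downstream, a
`3'SmORF`; otherwise intergenic.  Precedence CDS > 5′ > 3′ guarantees one
class per ORF and avoids double counting.  Matching against reference
peptide sets uses deterministic Smith–Waterman; "similarity" is percent
identity over aligned columns (not a positives-based score), with the
50%-identity / 50%-query-coverage default thresholds.

## Protein flexibility

Flexibility metrics are pure composition statistics: the percentage of
residues in the very-flexible set {E,G,K,N,Q,S}, the moderately flexible
set {A,D,H,I,P,R,T,V}, and their complement {C,F,L,M,W,Y}, which is
treated as the rigid class (the residue index itself names only the first
two sets; the rigid set is their complement by construction).  Vf + Mf +
rigid = 100 up to floating error, and percentages are invariant under
peptide permutation — both are asserted property-wise.  Externally
predicted per-protein flexibility classes (M0/M1/M2, rigid to flexible)
enter as an optional table and are *not* recomputed here: the predictor is
an external deep-learning service, and the pipeline's contract is
metric-agnostic — Vf, VMf, M2 and M1+2 flow through identical aggregation
and statistics.  Rows must sum to 100 ± 0.5 (rounded inputs are
renormalised); per-protein percentages, not residue-pooled counts, are the
observations fed to ANOVA, because the comparisons of interest are between
distributions of protein scores.

## Growth kinetics

Gr is defined as the slope of ln(A600) against time over the exponential
phase, in reciprocal units of the input time axis (per day for daily
readings).  OTG is the temperature whose maximum A600 *during the
exponential phase* is highest; this is deliberately not argmax-Gr — a
strain can divide fastest at 4 °C yet accumulate its largest
exponential-phase biomass at 15 °C — and exact ties resolve to the lower
temperature.

Exponential-phase detection is fully automatic and deterministic.  All
contiguous windows of ≥3 readings are fitted by weighted least squares in
log space, with weights a_i² (the inverse variance of ln A under constant
absorbance noise).  The absorbance noise variance is estimated robustly
from second differences of ln(A600), each normalised by its propagated
variance, taking the median of the squares and dividing by 0.4549 (the
median of a χ²₁ variable) so the estimate is unbiased under pure noise
yet insensitive to curvature, lag or plateau kinks.  A window qualifies
when its weighted SSE is at most 3(n−2) times that variance — roughly a
99.9% acceptance region for pure noise — and the *longest* qualifying
window is selected (ties: later end, then larger slope).  For noise-free
series the pure-error estimate degenerates and a classical R² ≥ 0.95 gate
applies instead.  If nothing qualifies, the steepest 3-point window is
returned flagged low-confidence; flat curves (absorbance range < 0.01)
are flagged "no growth" with Gr = 0.

Two selection rules were rejected during design, both after measurement.
Picking the *steepest* qualifying window — the textbook rule — inherits
the maximum of the window noise: with daily readings, absorbance noise of
0.01 and rates near 0.1/day it overestimates Gr by +0.02 to +0.06.
Gating on R² alone is scale-dependent: slow growers with the same noise
never reach R² = 0.95 over their full (genuinely exponential) series and
fall back to noisy short windows.  The longest-window/lack-of-fit design
measured bias below 0.003/day across rates 0.05–0.2 at that noise level.
Its known limitation: on a curve whose plateau is reached *within* the
series, trailing plateau points are excluded by the lack-of-fit gate, but
a mild saturation bend that stays within the noise band can leak into the
window and bias the slope a few percent low.

## Cross-species statistics

Per (pathway × metric) cell, species are compared by one-way
fixed-effects ANOVA followed by Tukey HSD p-values from the studentized
range distribution with the Tukey–Kramer unequal-n adjustment (protein
counts per pathway differ across species).  Normality is assumed; a QQ
export is available but there is no automatic nonparametric fallback.  No
multiple-testing correction is applied across pathways — the headline
heatmaps *count* raw Tukey p < α outcomes per species pair, and a
correction would change their meaning; α is an explicit parameter.  Cells
with fewer than two usable groups, or zero variance, are recorded
untested rather than given a p-value.  Note that because Tukey HSD
controls the familywise error, the expected *fraction* of significant
pairs under the null is below α; the property tested is that the
familywise rate, and the per-test ANOVA rate, sit near α.

Species (or species groups defined by OTG or Gr class) are clustered by
average-linkage agglomeration on the Euclidean distances between rows of
the significance-count matrix, rendered as an ultrametric dendrogram.
Difference-vs-difference regressions take, for each significant cell and
growth parameter, the pairwise between-species differences in group mean
metric (y) against the differences in OTG or Gr (x) and fit OLS with
intercept.  Two-point regressions have r² ≡ 1 and are flagged as such
rather than suppressed, since distinguishing them from genuinely strong
correlations is the reader's job.  Gene redundancy counts CDSs sharing an
identical annotation label per species, ranked by cross-species total
(ties alphabetical); unannotated CDSs are excluded and reported, and the
annotated-CDS-to-distinct-label ratio summarises overall redundancy.

## Phylogeny

Pairwise alignment uses Biopython's `PairwiseAligner` (BLOSUM62, gap open
−10, extend −0.5 by default; match/mismatch scoring for nucleotides),
taking the library's deterministic first-listed optimum; alignment scores
are verified against an exhaustive dynamic program in the tests.
p-distances remove gap columns pairwise (maximising usable sites for
short groups; complete deletion is available as a flag).  Distances are
k-state Jukes–Cantor, `d = -((k-1)/k) ln(1 - p·k/(k-1))`, with k = 20 for
proteins and k = 4 for nucleotides — the Poisson-style generalisation is
the faithful reading of applying "Jukes–Cantor" to amino-acid data.
Saturated p (≥ (k−1)/k) yields an infinite, flagged distance.

Neighbor joining is the canonical Saitou–Nei agglomeration with the
Studier–Keppler Q-criterion; Q-ties break toward the smallest index pair,
negative branch lengths are clamped to zero with the deficit moved to the
sister edge, and the unrooted result carries a trifurcating root.  NJ is
exact on additive matrices (asserted, along with the patristic
round-trip, on trees the generator evolved), and agrees topologically
with an independent implementation.  Bootstrap resamples alignment
columns with replacement; each replicate reruns p-distance → Jukes–Cantor
→ NJ, replicates with saturated or undefined distances are dropped and
counted (warning above 10%), and supports are the percentage of retained
replicates containing each bipartition of the full-data tree —
bit-reproducible for a fixed seed.

Ortholog groups are annotation labels present in at least `min_species`
species (optionally required to include specific species), one
representative peptide per species (longest, ties to smallest id).
Multiple alignment per group is a star alignment: every member is
globally aligned to the longest one and reference gap patterns are merged
("once a gap, always a gap" on the reference).  This deterministic scheme
keeps the pipeline self-contained; pre-aligned input is also accepted,
and concatenation joins group alignments in sorted label order over an
identical species set.

## Synthetic data

The generator emulates the study system — four Alpine yeast species with
GC near 51–61%, OTG between 10 and 20 °C, peak growth rates 0.07–0.18 per
day, redundant families, smORFs of all four classes — at desk scale:
three contigs of 100 kb per species rather than tens of Mb, 30 CDSs of
70–180 codons, so the full test suite runs in minutes on one CPU.  Per
species and data stream, generators are spawned from a single seed
sequence, making every emission a deterministic function of (spec, seed).

Genomes are i.i.d. backgrounds with P(G)+P(C) equal to the GC target.
CDS peptides are sampled from SwissProt-like residue frequencies, with
the very-flexible share shifted additively per species (the planted
effect size aggregation tests must recover); codons are drawn uniformly
among synonyms, so no stop can arise in frame.  CDS-internal smORFs are
embedded at frame offset +1 inside a host CDS, resampling until the host
frame remains stop-free; 5′/3′ smORFs are placed wholly inside the 1-kb
window on the strand-correct side of their anchor; intergenic smORFs keep
more than 1 kb clear of every CDS.  Layout margins (≥1.3 kb between any
smORF and any unrelated CDS boundary) make every planted class
unambiguous, so recall and class accuracy are tested at 100%.  The random
background still contains incidental ORFs — as real genomes do — so
truth-based tests assert recall of planted elements, never precision
against the background.

Growth curves follow `A(t) = min(A0·e^{r(T)·t}, K)` with A0 = 0.1, daily
readings for 10 days, per-species K uniform in 1.0–1.5, Gaussian
absorbance noise (sd 0.01 by default) clipped at zero, and r(T) a concave
quadratic peaking at the species' optimum and vanishing at its viability
bounds.  The exponential phase carries *exactly* the planted rate —
deliberately, because Gr is defined as that phase's log-slope, so
recovery tests compare like with like.  A logistic parameterisation was
considered and rejected: starting from A0/K ≈ 0.08, a logistic's realised
early-phase log-slope is r(1−A0/K) ≈ 0.92r, meaning no slope estimator
could legitimately return the planted r; planting the realised slope
removes that confound.  The generator has no lag phase and no
temperature-dependent carrying capacity — so it cannot exercise the
distinction between argmax-Gr and OTG that real slow growers show, nor
lag-robustness of the detector; passing its tests demonstrates estimator
correctness under the stated noise model, not robustness to every
real-world curve shape.

Protein families evolve along random join trees with uniform branch
lengths; substitutions are Poisson (rate × length × sites) with uniform
replacement over the 19 alternatives and no indels.  Unsaturated regimes
(pairwise p < 0.5) are used for the NJ recovery tests.

## Problem sizes used by the checks

The property and recovery suites use: 100 random 5-kb contigs for the ORF
scanner oracle; 500 random 8-mer pairs for the alignment oracle; 2,000
null replicates (4 groups × n = 20) for the ANOVA type-I rate; 200
simulated strains for OTG/Gr recovery; 100 evolved families for NJ
topology recovery; and 20 batches of triplicate curves per strain for the
growth-rate recovery script.  These sizes give the binomial/standard
errors the stated tolerances assume while keeping a full run to a few
minutes on one CPU.
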