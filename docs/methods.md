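# Methods

## Super-enhancer calling

Enhancer peaks (H3K27ac intervals with a per-region signal density) are
merged transitively when their gap on one chromosome is at most the
stitching window (default **12,500 bp**, the standard ROSE choice; the
underlying studies rarely publish their exact value). Peaks lying fully
within a TSS-exclusion radius (off by default; 2,500 bp when enabled) can
be removed first to keep promoter acetylation from inflating enhancer
scores. Each stitched region scores the sum of member-peak signal with
per-peak background subtraction floored at zero — flooring per peak, not
per region, so a few deeply negative-background peaks cannot erase a real
cluster.

The super/typical split uses the rank-curve tangent rule: sort scores
ascending, scale rank index and score to `[0, 1]`, and take the cutoff at
`argmax(x − y)`, the point where a line of slope 1 is tangent below the
convex curve. Numerical conventions, all of which matter for exact
reproducibility:

- ties in `x − y` resolve to the **largest x** (the highest-scoring of the
  tied points), so the SE set is the smallest consistent one;
- regions must score **strictly above** the cutoff; the tangent point
  itself stays typical;
- a flat curve (`max(x − y) ≤ 1e−12`, e.g. all scores equal) returns a
  `+inf` sentinel — no super-enhancers;
- fewer than 3 stitched regions → all typical (a tangent on a 1–2 point
  curve is meaningless).

The partition is invariant under score rescaling; with power-of-two
factors the invariance is bit-exact, with arbitrary factors it holds up
to floating-point rounding of the min–max normalization.

## Enhancer → circRNA assignment

A circRNA's promoter is its host-gene TSS when annotated, otherwise the
5′ end of the back-spliced span (span start on `+`, span end on `−`).
Each enhancer region is assigned to the single promoter minimizing the
point-to-region distance (0 inside; otherwise base pairs to the nearest
covered base), capped at the assignment window (default **50,000 bp**, a
common SE-to-target convention; equidistant promoters resolve to the
lexicographically smallest circRNA id). Assignment runs enhancer →
promoter; labels then aggregate per circRNA: any super assignment makes
an SE-circRNA, otherwise any typical assignment makes a TE-circRNA,
otherwise "other". Distances use the region boundary rather than its
midpoint so very wide SEs do not penalize promoters sitting just outside
them.

## Specificity

Tissue specificity of a non-negative profile `p` (mean RPM per tissue) is
`1 − sqrt(JSD₂(p/Σp, e))` with `e` one-hot at the argmax tissue (first
tissue on ties) and JSD the Jensen–Shannon divergence in log base 2, so
the score lies in `[0, 1]`: 1 for a perfectly restricted profile, about
0.44 for a uniform 2-tissue profile and decreasing with breadth. The
binary "tissue-specific" call uses a closed threshold (default **τ =
0.8**). The score is scale-invariant and permutation-equivariant, and
adding mass to the argmax tissue never decreases it.

A super-enhancer is **stage-specific** when the union of the other
stage's SEs covers less than a fraction (default **0.5**) of its bases.

Association tests: Fisher's exact test (two-sided, hypergeometric
enumeration semantics; odds ratio reported as the sample `ad/bc`, `inf`
when `bc = 0 < ad`, NA when both products vanish) and a two-sided
Mann–Whitney U for SE- vs TE-circRNA expression — exact null when both
groups have ≤ 10 observations and no ties, normal approximation with
continuity correction otherwise. Both are delegated to scipy and verified
against full-enumeration oracles in the test suite.

## Candidate funnel

Stage fold change is `(m₂ + pc) / (m₁ + pc)` on stage-mean RPM with
pseudocount **pc = 0.1 RPM** (the published fold-change plots show the
±1.5 interval but no zero-handling rule; a small pseudocount keeps
zero-expression circRNAs finite and the forward/reverse product exactly
1). A circRNA is differential when the ratio is ≥ **1.5** or ≤ 1/1.5
(closed thresholds, both directions kept). No p-value gates the call by
default, matching how such fold-change windows are usually drawn at n=3.

Conservation requires a complete row in a three-species ortholog table.
Sequence-level identity uses global Needleman–Wunsch with fixed scoring
(match +1, mismatch −1, gap −2) and a deterministic traceback
(diagonal > up > left), so percent identity — matches over alignment
columns — is reproducible to the digit. Candidates are the intersection
SE-circRNA ∩ differential ∩ conserved, ranked by |log2FC| descending,
then specificity, then id.

## Circular seed scan

Scanning runs on `seq + seq[:k−1]` (k = probe length), which shows every
circular occurrence exactly once; positions are reported modulo the
circle length and junction-spanning sites flagged. Sites anchor on the
reverse complement of miRNA seed positions 2–7; the m8 match upstream and
an A downstream upgrade the class (8mer > 7mer-m8 > 7mer-A1 > 6mer), and
each anchor reports once with its strongest class at the start of that
class's matched string. This is pure seed complementarity: no pairing
thermodynamics or context scoring, so site counts are comparable to, but
not identical with, energy-based predictors — a deliberate divergence,
since the free-energy model adds parameters that cannot be audited here.

A reference-species site (class ≥ 7mer) counts as conserved when every
other species has a ≥ 7mer site within **2 nt** (shift tolerance) of its
alignment-mapped position.

PWM scanning: probabilities get a **0.01** pseudocount, scores are
log₂-odds against a background (uniform by default) summed per column,
both strands are scanned, and windows containing N never score.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical shape of the study inputs at
desk scale, with a planted truth ledger:

- **Enhancer catalog** — 500 typical peaks with log-normal(0, 1) signal
  densities (the heavy tail is what makes the rank curve convex and the
  tangent cutoff meaningful) plus 25 planted clusters of 3–5 peaks inside
  one stitching window, each peak scaled as `multiplier × (1 + LogN(0,1))`
  with multiplier **20**. At that multiplier every cluster totals ≥ 60
  while the maximum of 500 log-normal draws almost never reaches it, so
  cluster scores dominate the typical tail; a couple of extreme typical
  peaks may still clear the tangent cutoff, which is exactly the
  false-positive behaviour real catalogs show.
- **Geometry** — planted SE-circRNA promoters sit 3–15 kb from their
  cluster; all other promoters keep > 50 kb clearance from clusters
  (55 kb lead-in, 70 kb tail buffer), typical peaks are spaced beyond the
  stitching window, and "other" circRNAs sit > 50 kb from any peak. On
  noiseless settings classification against the planted SE regions is
  therefore exact by construction.
- **Expression** — 5 tissues × 2 stages × 3 replicates. Base abundance is
  log-normal with class-dependent location (SE-circRNAs highest), tissue
  profiles put 90% of mass in a home tissue for SE-circRNAs vs 45%/35%
  for TE/other (SE-circRNAs more tissue-restricted), and stage factors
  `1/√r, √r` plant an exact stage-mean ratio `r`. The planted fold is
  **4.0** — comfortably inside the range stage-regulated circRNAs show —
  so the ±1.5 decision is made by the pipeline, not by the pseudocount
  nibbling at a borderline ratio. Multiplicative log-normal noise with a
  configurable CV; the default **CV = 0** is the noiseless mode used for
  exact recovery checks.
- **Orthologs and sequences** — 5 planted candidates appear in complete
  3-species rows; 5 SE + differential decoys lack one species; ~60% of
  the remaining circRNAs are conserved. Pseudo-species sequences carry
  ~2% substitutions outside planted sites (identity stays ≥ 95%). Each
  candidate carries three ≥ 7mer sites for one synthetic miRNA — one
  7mer-m8 straddling the junction, one 8mer, one 7mer-A1 — and all
  background sequence is scrubbed of stray seed cores (with redraw on
  the rare unfixable clash), so scan output equals the ledger exactly.
- **Randomness** — one integer seed; each facet (layout, signal,
  expression, orthologs, sequences) draws from
  `default_rng([seed, offset])`, so outputs are byte-identical per seed
  and facets are independent.

Not emulated: read-level ChIP-seq (no fragment pileup, no peak calling),
mappability or GC structure, chromatin domains, correlated biological
replicates, indels between species, and competition between overlapping
enhancer targets. Passing the planted-recovery checks therefore
demonstrates the pipeline's correctness and determinism, not its
sensitivity on real, noisy catalogs — on real data the SE/TE boundary and
the fold-change filter both sit in continua that the planted design
deliberately separates.

## Problem sizes

The default study (≈600 peaks, 200 circRNAs, 25 Mb of synthetic genome,
5 × 2 × 3 expression design) keeps a full generate-run-measure cycle
under ten seconds; the exhaustive test-oracle sweeps (all 2×2 tables
with N ≤ 30, all 4-vs-4 rank splits, 1,000 random cutoff curves, all
rotations of 200 random 30-mers) complete in about a minute. These sizes
were chosen so the planted structure is unambiguous while the whole
suite stays interactive.

## Known limitations

- The SE cutoff is the geometric tangent rule only; no signal-level
  alternative (e.g. fitted mixture models) is provided.
- Enhancer–promoter assignment is purely proximity-based; chromatin
  contact data is out of scope.
- Seed matching ignores hybridization energy, 3′-supplementary pairing
  and site context; conserved-site counts depend on the 2 nt shift
  tolerance through pairwise (not multiple) alignments.
- `percent_identity` is O(n·m) dynamic programming in Python — fine for
  circRNA-sized sequences (≤ a few kb), not for chromosomes.
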