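# Methods

## The two-isoform change-point model

Coverage along a 3′UTR expressing two poly(A) isoforms is modelled as a step
function: the long isoform contributes a constant depth α over the full UTR
and the short isoform adds β upstream of the proximal poly(A) site, so
`E[depth(x)] = α + β·1[x < b]` with α, β ≥ 0.  For a fixed breakpoint b the
least-squares solution is the pair of segment means (α̂ = distal mean,
α̂ + β̂ = proximal mean); when the profile rises toward the 3′ end the
unconstrained β̂ would be negative and the fit is clamped to the boundary
(β = 0, α = grand mean) and flagged degenerate.  PDUI = α/(α+β) ∈ [0, 1].

Assumptions worth stating: uniform coverage within each segment (no 3′ bias
model), exactly one proximal site per gene, and a breakpoint that is a
property of the gene — it is estimated *jointly* over all samples of both
groups by minimising the summed per-sample RSS over a candidate grid.  Ties
go to the smallest candidate.  The grid keeps a margin of
max(50 bp, 5% of UTR length) off each end (step estimates inside these
margins are dominated by edge noise) and uses stride 1 up to 2 kb UTRs,
`ceil(len/2000)` beyond, which bounds per-gene work while staying exact at
the scale where single-base resolution matters.  The grid RSS is computed
from prefix sums in O(length) per sample; the test suite checks it against a
naive per-candidate enumeration.

**Coverage filter.**  A sample contributes to a gene only when its mean
depth over the 5′-most 100 bp of the UTR is ≥ 30.  The proximal window is
covered by both isoforms, so this measures total transcript abundance
rather than penalising genes with low distal usage (a whole-UTR mean would
reject a highly expressed gene whose distal segment is short or silent).
A gene is fitted when at least half of each group's samples pass.  Both the
floor (30), the window (100 bp) and the group fraction (0.5) are arguments.

**Event calling.**  ΔPDUI = median(case) − median(control).  Per-gene
significance is a two-sided Wilcoxon rank-sum on per-sample PDUI — exact
enumeration when both groups have ≤ 10 untied values, tie-corrected normal
approximation otherwise.  Lengthened: ΔPDUI > 0.1 and p ≤ 0.05; shortened:
ΔPDUI < −0.1 and p ≤ 0.05; genes with fewer than 3 usable values per group
are not testable.  Raw p is the published decision rule; `bh_adjust=True`
switches classing to BH q-values for users who want multiplicity control.

## DPAU from isoform abundances

DPAU = 100 × Σ(abundance at the maximal poly(A) offset) / Σ(all isoforms).
Isoforms at intermediate sites count only in the denominator, which
generalises the distal-vs-all definition beyond two isoforms.  Quantification
itself is an input (any TSV of per-isoform abundances); a gene is
quantifiable in a sample when its total abundance reaches `min_total`
(default 1, in the abundance unit of the table).  Event calling reuses the
PDUI machinery on the 0–100 scale with a ±10 delta cut.

## Differential expression and preprocessing

- mRNA: transcripts kept when max FPKM across samples ≥ 1.
- Protein: iBAQ → FOT (value / per-sample sum over detected proteins; FOT
  columns sum to 1) → iFOT = FOT × 10⁵; proteins kept when detected in at
  least ⌈n/10⌉ samples (the "at least one-tenth" rule rounds up).  Missing
  values are NaN throughout — a zero is a measured abundance, absence of
  detection is not.
- Test: per-gene two-sided Wilcoxon rank-sum on available values, BH FDR
  across tested genes.  Fold change = ratio of group medians (robust and
  consistent with the rank test); when a median is exactly 0, half the
  smallest positive value in the matrix is added to both medians.  Signed
  folds report ratios < 1 as −1/ratio.  Significant: FC ≥ 2 or ≤ 1/2 and
  FDR ≤ 0.01.
- Shapiro–Wilk normality p-values are advisory only; the pipeline never
  switches to t-tests.
- PCA operates on log2(x+1), gene-centred values via SVD (complete rows
  only); each axis is sign-fixed so its largest-magnitude gene loading is
  positive, making coordinates reproducible.

## Integration and the RBP screen

Matched genes = intersection of the two DE tables.  "Unchanged" = significant
at neither layer; "de_any" = significant at either.  The protein-per-mRNA FC
ratio uses linear case/control ratios so log10 is defined; the identity
log10(ratio) = log10 FC_protein − log10 FC_mrna holds to machine precision
and is asserted.  The differential set's characteristic bimodality is
summarised by the medians and proportions of its positive- and negative-sign
log10 subpopulations, not by a mixture fit.  The de-vs-unchanged contrast is
a two-sided Mann-Whitney U.

The extended region of a lengthened gene is [breakpoint, UTR end); a site is
gained when it overlaps by ≥ 1 bp (`min_overlap` configurable).  For the
enhancement screen, "bound" means ≥ 1 site for that RBP anywhere in the
3′UTR (binding can act on both isoforms; gain counting is the separate,
lengthened-restricted analysis).  Effect = median(log2 FC ratio | bound) −
median(| unbound); two-sided Wilcoxon p; enhancer flag at positive effect
and raw p < 0.05, with BH q reported alongside.  RBPs need ≥ 5 bound matched
genes to be testable.

## The synthetic cohort

The generator plants every quantity the pipeline later estimates.  Defaults
describe a reduced-scale case/control study: 2000 genes, 25 vs 25 samples
(analyses in the tests and acceptance script run at 10 vs 10), UTR lengths
uniform 300–1500 bp, proximal site at 25–75% of the UTR, 50 reads/base
proximal depth, 30% lengthened / 2% shortened genes (the ~95:5 imbalance
direction), planted usage shifts ΔPDUI uniform in [0.25, 0.5].

- **Usage.**  Control group-mean PDUI comes from Beta(2,2) rescaled so the
  planted shift fits inside [0, 1]; per-sample usage is Beta-distributed
  around the group mean with concentration κ = 60 (sd ≈ 0.065 at usage 0.5,
  a realistic within-group spread for bulk cohorts).
- **Coverage noise.**  Poisson per base by default; gamma-Poisson when
  `depth_dispersion > 0`; `noise_model="none"` produces exact expectations
  for machine-precision tests.
- **Isoform quantification** shares the same latent per-sample usage (total
  set to the gene's mRNA value) with 0.05 log2 multiplicative noise, so the
  two callers see consistent but not identical data.
- **Expression.**  log2 FPKM baseline ~ N(4, 2), within-group sd 0.5 log2;
  15% of genes get a planted mRNA fold change uniform in [2, 6], half down.
  Protein: log2 protein = log2 mRNA + gene offset (sd 1 log2) + boost·1[case]
  + noise (sd 0.5 log2), where boost = 0.5 log2 per gained enhancer site for
  lengthened genes and 0 otherwise.  Per sample, protein values below the
  10% quantile are censored to missing (left-censoring mimics detection
  limits and exercises the one-tenth filter).
- **Sites.**  50 RBPs, 8 enhancers.  Each enhancer places a 10-bp site in a
  lengthened gene's extended region with probability 0.25; every RBP also
  binds any gene uniformly with probability 0.15.  `enhancer_sites_gained`
  is counted from the realised intervals (including background sites that
  land in the extended region), so the truth table always matches interval
  arithmetic.

What the generator does **not** emulate: positional coverage bias, multiple
proximal sites per gene, shared-peptide protein inference, batch effects,
mRNA–protein delay, or compositionality beyond what FOT normalisation itself
introduces.  Passing tests therefore demonstrate correctness of the
estimators and decision rules under the stated model, not robustness to
those real-data artefacts.

A consequence worth knowing: planted translation boosts raise case-sample
protein totals, so FOT normalisation deflates all other proteins in cases —
unchanged genes then show a slightly negative median log10 FC ratio on
boosted cohorts.  This is a property of fraction-of-total scaling, not an
estimator bug; the null-calibration checks use boost-free cohorts where the
median converges to 0 as noise shrinks.

## Problem sizes and determinism

The acceptance script analyses a 500-gene recovery cohort and the 2000-gene
default cohort at 10 vs 10 samples, plus a 20-seed null sweep at 120 genes /
6 vs 6 — sizes chosen so a full run completes in a few minutes on one core
while leaving every rate estimated from hundreds of genes.  All randomness
flows from `numpy.random.default_rng(seed)`; a fixed config reproduces
byte-identical output files (writers stamp a version + config hash, never a
timestamp).

## Known limitations

Single breakpoint per gene (no >2-isoform coverage model); no intronic or
internal-exon APA; annotation-free UTR discovery is out of scope; the
Wilcoxon exact path is skipped in the presence of ties; FOT compositional
effects are not corrected; the usage–protein correlation is reported per
gene without shrinkage.
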