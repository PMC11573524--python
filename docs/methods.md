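# Methods

## Scope and data model

`mrmediate` performs two-sample summary-statistics MR: all computation
consumes per-SNP association summaries (effect, SE, p, allele pair, EAF,
N), never genotypes. A `GwasTable` is a validated pandas DataFrame plus
trait metadata (trait type, effect scale, genome build — declarative only;
no liftover). File coordinates are 1-based inclusive, the GWAS convention;
the cis-window test `start − flank ≤ pos ≤ end + flank` is inclusive on
both ends, asserted at the exact boundary in tests. Rows violating record
invariants (non-positive SE, identical or non-ACGT alleles, out-of-range p
or EAF) are dropped with per-reason counts rather than failing the read;
p-values of exactly 0 are replaced by the smallest positive float so
downstream log-space arithmetic is defined.

## Harmonization

The outcome effect of every shared SNP is re-expressed per copy of the
exposure's effect allele. Non-palindromic pairs resolve by allele matching
in four orientations (direct, swapped → negate β and mirror EAF,
strand-complemented, complemented + swapped); anything else drops with
reason `allele_mismatch`. Palindromic SNPs (A/T, G/C) carry no strand
information in their alleles, so the default policy infers strand from
allele frequency: keep only if both studies' minor-allele frequencies are
below 0.42 (configurable), aligning the effect allele to the same side of
0.5; otherwise drop. Missing EAF on either side also drops the SNP — with
no frequency there is nothing to infer from. The published studies this
mirrors do not state their harmonization rules; these are this package's
own (conservative, field-standard) choices. Harmonization is idempotent and
the double allele swap is an involution; both are property-tested, and
`|shared| = |harmonized| + Σ drops` always holds.

## Instrument selection

Drug-target instruments: SNPs within ±100 kb of the target gene
(flank measured from gene start/end), p < 5×10⁻⁸ (strict inequality), and
EAF > 0.01 applied to the stored effect-allele frequency literally; a
strict-MAF variant (min(EAF, 1−EAF) > 0.01) is available but off by
default. Greedy clumping takes SNPs most-significant-first (ties broken by
position, then lexicographic id, making output invariant to row order) and
removes remaining candidates within the window whose r² with the chosen
index exceeds the threshold, so every retained pair satisfies r² ≤
threshold. The adaptive rule runs at r² < 0.3 and, only when fewer than
three instruments survive, reruns from scratch at r² < 0.4 — exactly three
survivors stand, resolving the ambiguity in "more/fewer than three" wording
in favour of not relaxing. pQTL (mediator) instruments use p < 5×10⁻⁶ and
r² < 0.001 in a 10,000 kb window, with no cis restriction. LD is a user
input (square matrix or long-format triplets); a SNP missing from the
matrix is a configuration error, never assumed independent. Confounder
removal consumes a user-supplied blocklist TSV (snp_id, trait) — no live
trait-lookup service is queried. Instrument strength is F*ⱼ* = (β*ⱼ*/SE*ⱼ*)²
with the arithmetic mean reported; mean F ≤ 10 raises a weak-instrument
flag but does not abort.

## Estimators

Weights use the first-order (σ_Γ-only) convention, w*ⱼ* = γ̂*ⱼ*²/σ*Γⱼ*², so
the ratio-space IVW and the through-origin WLS formulation coincide to
machine precision (asserted against an independent normal-equations solve
at 1e-10). Fixed-effect SEs are the unscaled (XᵀWX)^(−1/2); the
multiplicative-random-effects variant scales by √max(1, Q/df), floored at 1
so heterogeneity can only widen CIs. The default pipeline mode is "auto":
fixed-effect IVW, escalating to MRE when Cochran's Q has p < 0.05. All
p-values are two-sided standard normal, including Egger's (no small-sample
t correction; documented convention of the multiplicative-effects normal
approximation). Egger orients instruments to γ̂ ≥ 0 before regression, so
the fit is invariant to joint sign flips. A single instrument falls back to
the Wald ratio Γ̂/γ̂ with SE σ_Γ/|γ̂|.

The weighted median orders ratios by value, assigns cumulative-weight
midpoints p*ⱼ* = S*ⱼ₋₁* + w′*ⱼ*/2, and interpolates at p = 0.5; outside
[p₁, p_J] (possible only with degenerate weights) it returns the nearest
ratio without extrapolation. Its SE is the SD over n_boot = 1000 (default)
parametric-bootstrap replicates drawing γ* ~ N(γ̂, σ_γ), Γ* ~ N(Γ̂, σ_Γ)
per SNP from a seeded generator; identical seeds give identical SEs.

## Sensitivity battery

Cochran's Q uses ratio weights about the IVW estimate (df = J−1) or the
weighted residual sum of squares about the Egger fit (df = J−2), referenced
to the upper χ² tail. Leave-one-out re-estimates IVW J times and flags an
omission that flips the 95% CI across zero or moves the estimate by more
than half (configurable) of the full-set CI half-width.

MR-PRESSO follows the published construction. Observed statistic:
RSS = Σ*ⱼ* (Γ̂*ⱼ* − γ̂*ⱼ* β̂₋*ⱼ*)²/σ*Γⱼ*², with β̂₋*ⱼ* the IVW estimate
excluding SNP *j* (computed in O(J) by sum-subtraction, which also lets the
whole simulation be vectorized). The null distribution re-draws
γ\** ~ N(γ̂, σ_γ) and Γ\** ~ N(γ̂β̂₋ⱼ, σ_Γ) n_sim times (default 1000) and
recomputes RSS identically; the global p is the add-one-smoothed upper-tail
proportion, so it is never exactly zero and the run is bit-reproducible
given the seed. The outlier test compares each SNP's observed residual term
with its own simulated distribution — two-sided empirical p, multiplied by
J (Bonferroni) and capped at 1 — flagging adjusted p < 0.05. Note the
interaction between n_sim and J: the smallest achievable two-sided adjusted
p is 2J/(n_sim+1), so detecting outliers at J = 20 needs n_sim ≥ ~800; the
default 1000 covers the instrument counts this pipeline produces. The
distortion test compares the relative estimate change after removing the
flagged SNPs against removal of equally many random SNPs (vectorized
random-subset draws). The pipeline applies one detect→remove→re-estimate
pass and reports both passes, mirroring the positive-control workflow of
removing a single flagged variant and rerunning.

## Mediation

Two-step MR: α from the exposure's instruments against the outcome, β₁ from
the same instruments against the mediator, β₂ from the mediator's pQTL
instruments against the outcome. Because the exposure's instruments may
also be pQTLs, the default overlap policy (`drop-shared`) removes any
mediator instrument that is also an exposure instrument before estimating
β₂, preventing the exposure pathway from re-entering the mediator effect;
`none` disables this. Indirect effect β₁β₂ with Sobel SE
√(β₁²SE₂² + β₂²SE₁²); proportion mediated β₁β₂/α with first-order delta SE
treating (β₁, β₂, α) as independent — samples in real applications overlap
partially (the same outcome GWAS appears in α and β₂), so this SE is
approximate; the point decomposition is exact by construction
(direct + indirect = α bitwise). A zero total effect leaves the proportion
undefined (NaN), never an exception. The pipeline computes mediation only
along chains whose links pass their Bonferroni families
(screen-then-mediate); family size m defaults to the number of configured
hypotheses and is overridable, since published analyses sometimes fix m by
the screened set rather than the carried-forward set.

`pval_from_or_ci` back-calculates a two-sided normal p from a printed
OR and 95% CI (SE = (ln hi − ln lo)/(2·1.959964)); it reconciles published
forest rows to within a few percent, limited by 3-decimal rounding of the
printed ORs. One published mediator row (MMP-1-type: OR 0.837, CI
0.764–0.918, p 1.534E-05) is internally inconsistent — its CI implies
p ≈ 1.5E-04 — and is treated as a typo, excluded from reconciliation tests.

## Synthetic studies

The generator emulates the three-table design at realistic scale: exposure
GWAS N = 441,016 (a UK-Biobank-sized lipid trait), mediator GWAS N = 14,824
(an Olink-panel pQTL study), outcome GWAS N = 1,030,836 with case fraction
0.0588 (an AF-sized case/control meta-analysis). Per-SNP truth follows

    exposure_j = γ_j,   mediator_j = β₁γ_j + δ_j,
    outcome_j  = (α_direct + β₁β₂)γ_j + β₂δ_j + θ_j,

with γ_j ≠ 0 only for cis SNPs (|γ| ~ U(0.03, 0.12), random sign — mean F
≈ 1000 at these sample sizes) and δ_j ≠ 0 only for mediator-specific pQTLs
(|δ| ~ U(0.15, 0.60)). The pQTL class exists because β₂ is not identifiable
from the exposure's instruments: regressing outcome on mediator over cis
SNPs returns α_total/β₁, not β₂. Default effects α_direct = −0.1456,
β₁ = −0.20, β₂ = 0.072 give a total effect of exactly −0.16 (OR ≈ 0.852)
and proportion mediated exactly 0.09, the regime of the mediation analyses
this package targets. Pleiotropy θ_j on the cis SNPs is N(0, τ) (balanced)
or |N(0, τ)|·sign(γ_j) (directional — positive on the oriented scale, since
allele coding makes raw signs arbitrary). Standard errors derive from
sample size and allele frequency, σ = 1/√(2np(1−p)) for standardized
quantitative traits and σ = 1/√(2nφ(1−φ)p(1−p)) for a binary outcome
(case fraction φ, log-OR scale); observed effects add independent noise per
table, enforcing two-sample independence. The LD matrix is block-diagonal
(within-block r² = ρ²) and is an input to clumping only — the summary
effects themselves are drawn independently, not LD-convolved, so the
generator exercises clumping logic but does not reproduce the correlated-
statistics structure of real cis regions. Other omissions relative to real
data: no winner's curse, no allele-frequency mismatch between studies, no
sample overlap, no liability-scale conversion for the binary outcome
(effects are generated directly as log-ORs to keep truth interpretable).
Passing recovery tests therefore demonstrates estimator correctness under
the assumed model, not robustness to those real-data features.

## Test and simulation sizes

Deterministic oracles (statsmodels WLS for IVW/Egger, brute-force
interpolation for the weighted median) run on 100 random fixtures at 1e-10
tolerance. Monte-Carlo properties use 500 replicates for IVW bias/coverage
and for null calibration of the Egger-intercept and MR-PRESSO global tests
(n_sim = 500 within each replicate), 200 replicates for mediation-proportion
recovery, and 100 replicates for 10σ outlier-detection power (n_sim = 1000,
J = 20 — see the n_sim·J floor above). These sizes put Monte-Carlo error
well inside the asserted bands while keeping the whole suite around ten
seconds.

## Known limitations

- Confounder exclusion is only as good as the supplied blocklist; no trait
  catalogue is bundled.
- LD must be provided; instrument counts therefore depend on the user's
  reference panel, and exact counts from any published analysis are not
  reproducible without it.
- The proportion-mediated SE ignores covariance between α and β₁β₂.
- Egger inference uses normal quantiles; with very few instruments its CI
  is anti-conservative.
- No multivariable MR, Steiger filtering, mode-based estimators, or
  reverse-direction analyses.
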