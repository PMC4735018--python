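# Methods

This note documents the models, conventions and numerical choices behind
`propellerevo`, and what the synthetic-data tests do and do not establish.

## Sequence identity and repeat detection

All identity statistics rest on one metric: global alignment
(Needleman–Wunsch, BLOSUM62, gap open 10, gap extend 0.5) with identity =
matches / columns where neither sequence is gapped. Gapped columns are
excluded from the denominator; for near-equal-length repeat motifs the
optimal alignment is usually ungapped, so the choice is mild, but it is a
convention and is stated here because "internal identity" depends on it.

Internal repeats are detected by a simplified Radar-like procedure: every
candidate period p in [min_period, max_period] (defaults 20–60 residues,
capped at half the sequence length) is scored as the summed BLOSUM62
self-alignment score at lag p. Random sequence scores negative in
expectation, so the best period must score positive at all; the motif
frame (start offset) is chosen to maximise agreement of the k windows with
their own consensus, and the multi-motif call requires the mean
motif-vs-consensus score to reach 0.25 × the consensus self-score. This
threshold was calibrated on simulated families so that repeats near 30%
internal identity are still detected while random proteins are not. The
detector does not reproduce Radar bit-for-bit; only the downstream
statistics matter. Coordinates are 0-based half-open internally, 1-based
inclusive in all reports.

## Substitution model and distances

The JTT amino-acid model (published exchangeabilities and stationary
frequencies) is embedded as module constants in the standard PAML residue
order `ARNDCQEGHILKMFPSTWYV` and normalised to one expected
substitution per site per unit time. P(t) = exp(Qt) is computed through
the symmetrised eigendecomposition, which is exact and fast for a
reversible model. Pairwise tree distances are maximum-likelihood
inversions of observed identity: d(ι) solves Σᵢ πᵢ[P(d)]ᵢᵢ = ι by Brent's
method, capped at 12 substitutions/site for saturated pairs. Rates are
uniform across sites (no gamma); the model is pluggable by id and the
suite registers a uniform model where a residue-exchangeable null is
needed.

## Alignment, tree and ancestral posteriors

Motifs are multiply aligned by center-star progressive alignment around
the motif with the highest summed pairwise identity; pairwise gap patterns
against the center are merged by taking the maximum insertion count before
each center position. For the near-equal-length, ≥40%-identity motifs this
package targets, center-star is accurate and deterministic; it is not a
general-purpose MSA.

Trees are neighbour-joining on the ML distances, midpoint-rooted
(deterministic given input order), with negative NJ branch lengths clamped
to zero, followed by one round of per-branch Brent optimisation of the
total log-likelihood (bounds 1e-8–10 subs/site, xatol 1e-4). Likelihoods
use Felsenstein's pruning algorithm; gapped leaves contribute a vector of
ones (missing data), the convention of marginal ancestral reconstruction
tools. The root posterior over the 20 residues is πₐ times the product of
the root's children's propagated conditionals, normalised per column.
Columns gapped in half or more of the rows are dropped from the reported
positions, so the ancestor is an ungapped motif. The MPA takes the
per-position argmax with ties (within 1e-12) broken alphabetically.

On 10-leaf, 47-column star families at total pairwise depth 0.6 the MPA
recovers ≥85% of ancestral positions on average (seeded test), and the
pruning likelihood is verified against brute-force enumeration over all
internal-node states on 4-leaf trees to 1e-10.

## Construct design

Permutation frames: the Velcro frame (V) is the identity; intact-blade
frames (B) are circular left rotations by blade_shift + polish_offset,
with polish offsets −2..+2, giving six frames at the default polishing
range. `blade_shift` (default 36 of 47) is the rotation that brings strand
IV to the front; it is structural knowledge supplied per family, not
inferred from sequence. Library cutoffs are strict inequalities
(posterior > cutoff) and the MPA residue is never listed as its own
alternative, so n_variants = |frames| · Π(1+kᵢ) counts distinct sequences.
Variant emission order is deterministic: positions ascending, residues
alphabetical, frames V first then B by offset. Error-prone mutagenesis is
a protein-level Poisson model (counts ~ Poisson(rate), distinct uniform
positions, uniform non-identical target residue); codon structure and
transition/transversion bias are deliberately out of scope.

## Genomic clock analysis

The homology search is Smith–Waterman (BLOSUM62, gap open 11 / extend 1)
of the propeller's consensus motif against every proteome entry, with
e-values from the Karlin–Altschul formula using the standard gapped
BLOSUM62 parameters λ = 0.267, K = 0.041 and search space m × N (query
length × total proteome residues). Hits must also be single-motif proteins
by the repeat detector. On composition-matched decoy proteomes of ~10⁴
residues the e < 10⁻³ cutoff yields zero hits in ≥99/100 seeded trials.

Clock points carry, per propeller, the internal identity and the
average/maximum identity of its motifs to the candidate single motif
(percent, reported to one decimal; correlations use unrounded values).
Pearson r and its two-sided t-transform p-value require ≥3 propellers and
non-degenerate variance. The directionality test simulates, per propeller,
k identities as Binomial(47, mean/100) column-match fractions —
the exchangeable, equidistant null — and compares the observed maximum
max-minus-average gap across propellers with the 99th percentile of the
null maximum (family-wise 1% level, 2000 resamples, seeded). Exceeding it
flags "co-option suspected". The binomial null slightly overstates the
spread of alignment-based identities, making the test conservative: young
co-opted donors near the detection threshold can escape the flag.

## Unfolding models and fits

Chemical denaturation uses the linear-extrapolation formalism with
RT = 0.592 kcal/mol (25 °C). Two-state: f_N = 1/(1+exp(m(x−Cm)/RT)) with
linear native and denatured baselines. Three-state N⇌I⇌D:
K₁ = exp(m₁(x−Cm₁)/RT), K₂ = exp(m₂(x−Cm₂)/RT), f_N = 1/(1+K₁+K₁K₂),
f_I = K₁f_N, f_D = K₁K₂f_N, with the intermediate baseline an intercept
only (slope fixed to zero — standard practice for a baseline the data
rarely determine). Fractions are computed in log space so predictions are
stable far outside the measured range. Oligomers are fitted without a
concentration term, so all parameters are flagged apparent.

Numerical choices: midpoint starts come from the smoothed |dy/dx| maxima;
the three-state fit adds a deterministic start grid over m ∈ {2.5, 6} and
ΔCm ∈ {0.2, 0.5, guess} plus five seeded jittered restarts, keeping the
best SSE. m-values are bounded at 10 kcal·mol⁻¹·M⁻¹: an unbounded slope
lets the optimiser hide a near-vertical transition between grid points and
absorb ΔCm into it. A fit is rejected (FitError) when a straight line
fits the data essentially as well or when the fitted transition amplitude
is indistinguishable from noise, so flat data never yield a midpoint.
A three-state optimum whose midpoints coincide (ΔCm < 0.02 M) raises a
degenerate-model error recommending the two-state fit. Model selection is
by BIC (n·ln(SSE/n) + k·ln n, k = 6 or 9), ties resolving to two-state;
BIC was chosen over an F-test because the baseline parameters make the
models non-nested in practice.

Identifiability, not optimisation, limits how small an inter-inflection
interval can be measured: when the intermediate's signal sits at the
midpoint of the flanking baselines, a three-state curve with small ΔCm is
statistically indistinguishable from two-state at 1% noise. The canonical
synthetic curves therefore place the intermediate distinctly off-center
(intercept 0.45 vs baselines ~1.0 and ~0.15 AU) with m₁ = m₂ = 6
kcal·mol⁻¹·M⁻¹ and sample 121 points across 0–6 M GdmCl — conditions
under which both transitions are spectroscopically resolved, as they are
in the measured curves these fits emulate. Under those conditions ΔCm
values of 0.3–1.2 M are recovered within 0.1 M at 1% noise across seeds.

A note on the collapse limit: with Cm₂−Cm₁ → 0 and the intermediate
baseline at the mean of the flanking baselines, the three-state signal
(1+K/2)/(1+K+K²) is not exactly a logistic; the best two-state
approximation leaves a residual of ≈4×10⁻³ of the amplitude regardless of
m. The exact collapse to two-state occurs when the intermediate is never
populated (its transition pushed out of range), which the test suite
asserts, together with monotone convergence as the intermediate
population vanishes.

Thermal melts use a logistic transition in temperature with linear
baselines. A melt is censored — reported as a bound, never a point Tm —
when the fitted midpoint exceeds the configurable limit (default 90 °C),
when the upper baseline is undetermined within the scan (Tm + 2·width
beyond the last point), or when no transition is detected.

Folding-yield shapes: "bell" requires an interior maximum exceeding both
endpoints by more than the noise margin (default 0.1 of the normalised
yield); "monotone_decreasing" requires a first-to-last drop beyond the
margin with a negative rank correlation; anything else is "flat". Three
concentrations are accepted as a minimum since a bell is already definable
on three points.

Trait PCA operates on the Pearson correlation matrix (not covariance) of
complete cases, reporting eigenvalues, variance fractions λᵢ/Σλ and
loadings with the sign convention that each component's largest-magnitude
loading is positive; a constant trait raises an error naming the column.

## Synthetic data: what it emulates and what it does not

`simulate_family` implements duplication–fusion–divergence literally: an
ancestor motif drawn from JTT stationary frequencies; per propeller a stem
branch (stem_fraction × age, making its motifs monophyletic) followed by
independent per-motif branches of length age (substitutions/site); ages
log-uniform over the configured spread (default 0.1–1.5) so clock plots
are populated evenly; 5–7 motifs per propeller; a single-motif protein of
81 residues (47-residue core, 17-residue stationary-composition flanks).
Scenario A evolves the single motif from the ancestor (divergence 0.1);
scenario B copies it from one repeat of an extant propeller (divergence
0.05) — the donor is the oldest propeller young enough (age ≤ 0.35) to
survive a ≥50%-identity scan, since a co-option signature carried only by
undetectable propellers would be invisible to the analysis by
construction. Indels are off by default (motif boundaries are exact), so
repeat detection on simulator output is easier than on real proteins;
passing tests show the statistics behave correctly under the model, not
that boundary calling is robust to real indel histories. Curve simulation
evaluates the fit models exactly plus Gaussian noise; it shares the model
code with the fitting routines on purpose (the tests of parameter
recovery are about estimation, not model mis-specification).

All generators are pure functions of (spec, seed); reruns are
byte-identical.

## Problem sizes in the test suite

The seeded suites use 100 replicates for repeat-detection recovery and
e-value calibration, 50 for clock correlation and MPA recovery, 40 for
model selection, 25 for tree-clade recovery and 20 scenario pairs for the
directionality test; curves carry 61–121 points. These sizes make the
binomial pass thresholds (≥95%, ≥90%, ≥80%) meaningful while keeping the
default test run fast.

## Known limitations

- Center-star alignment and the diagonal-scoring repeat detector are
  tuned for high-identity tandem repeats; neither is a general MSA or a
  profile-based repeat finder.
- Ancestral inference is marginal (per column) with uniform rates; no
  indel history, no joint reconstruction, no tree search beyond NJ plus
  branch-length polish.
- E-value statistics use fixed published Karlin–Altschul parameters, not
  composition-adjusted ones.
- Unfolding fits ignore oligomer concentration dependence (apparent
  parameters) and report delta-method uncertainty only through the fit
  SSE; intermediate-fraction confidence bands are not bootstrapped.
- The directionality null treats motif identities as independent binomial
  draws, which is conservative.
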