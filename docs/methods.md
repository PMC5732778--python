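# Methods

## Data model

A screen is a batch of K replicate plates on a shared two-drug grid. The
survival index of a well is its background-corrected, control-normalized
fluorescence, `S = (f_exposed − f_blank) / (f_control − f_blank)`, computed
per plate from that plate's mean blank and mean control signal. Indices are
0-based with index 0 meaning "drug absent", so the data form K matrices of
shape (J+1) × (I+1): row 0 and column 0 are the single-drug responses and
cell (0, 0) the growth controls (mean survival 1 by construction). S is not
clamped; values slightly below 0 or above 1 are legitimate noisy readings.

Assay acceptance requires a control/blank mean ratio strictly greater than
5 and a control-well coefficient of variation strictly below 30%. A failed
plate stops the pipeline (exit code 3) unless `--force` is given, because
the in-silico analogue of "repeat the assay" does not exist.

## Outlier screening

For every cell, while the sample CV of its replicates exceeds 30% and more
than `min_keep = 2` replicates remain, the replicate with the largest
absolute deviation from the current mean is removed and mean/CV are
recomputed. "Largest contribution to the CV" is read as largest squared
deviation; ties are broken by removing the larger value, since high
outliers (evaporation, edge effects) are the common plate artifact. The CV
uses the sample (n−1) standard deviation. Cells whose mean is numerically
zero have no meaningful CV; they are flagged and left untouched. The
procedure is idempotent and never drops a cell below two replicates.

Known limitation: a relative criterion degrades for wells with survival
near zero, where even clean replicates have CV ≈ σ/|mean| → ∞ and the rule
trims to the floor of 2 replicates, shrinking the residuals of deep-kill
wells. The sliding-window pooling (below) dilutes but does not remove this.

## Interaction indices

Both models share one sign convention, *predicted minus observed*:

* Bliss: `I_Bliss(i,j) = <S(i,0)> · <S(0,j)> − <S(i,j)>`.
* Loewe: `I_Loewe(i,j) = S_Loewe(i,j) − <S(i,j)>`, where the predicted
  level solves the linear isobole equation
  `cA/R_A⁻¹(s) + cB/R_B⁻¹(s) = 1`.

For two-parameter Hill curves the isobole functional is strictly increasing
in s and spans (0, ∞) on s ∈ (0, 1), so the "closest to 1" formulation is
exactly a root-finding problem; it is solved by bisection on
s ∈ (1e−9, 1−1e−9) to an absolute tolerance of 1e−9 (config
`loewe_bisection_tol`), verified in the tests against a brute-force 1e−6
grid search. Boundary cases: `(0,0) → 1`, one drug absent → that drug's own
Hill response.

Hill curves are fitted to the outlier-cleaned single-drug means by
unweighted least squares over (log c50, log H) (positivity built in), with
asymptotes fixed at 1 and 0 exactly. Start values come from the closed-form
two-point solution of the Hill equation, preferring the pair of responses
bracketing s = 0.5; responses are clamped to [1e−6, 1−1e−6] only inside
that start-value formula, never in the objective. Three deterministic
starts (the closed form plus two perturbations) guard against local
minima. A curve is declared *not computable* — and every Loewe quantity
downstream becomes NA — when the observed or fitted dynamic range over the
tested ladder falls below 0.1, when the fitted c50 leaves
[min conc/100, max conc × 100], or when the optimizer fails. This
operationalizes "almost constant concentration-response relationship"; the
0.1 floor is a package choice. An optional untreated anchor point (c = 0,
s = 1) is accepted for interface completeness but is inert: the fixed-
asymptote model reproduces it for every parameter value.

## Heteroscedastic residual bootstrap

Residuals `e(i,j,k) = S(i,j,k) − <S(i,j,k)>` estimate the experimental
error distribution, which in viability data depends strongly on the effect
level. Each cell therefore owns a *sliding window*: the w = round(0.10 · N)
wells (N = all wells with a defined mean, single-drug and control cells
included; minimum w = 2, the cell itself always a member) whose means are
closest to its own. The cell's simulated errors are drawn with replacement
from the pooled residuals of its window and sign-flipped with probability
1/2 (symmetric, otherwise distribution-free).

Residuals about a K-replicate mean have expected mean square
`((K−1)/K) σ²`; they are rescaled by `sqrt(K_cell/(K_cell−1))` before
pooling (config `rescale_residuals`, default on) so that simulated errors
match the sampling noise of the observed statistics. Without this standard
correction the bootstrap noise is 13% too small at K = 4 and the omnibus
test's false-positive rate is inflated far beyond nominal.

Each of B = 1000 batches rebuilds a full screen
`S_b(i,j,k) = <S(i,j,k)> + e_b(i,j,k)` and recomputes the entire index
matrix; for Loewe this includes refitting both Hill curves to the batch's
simulated single-drug rows (single start from the observed fit, for speed
and stability; batches whose refit degenerates are dropped, and the
analysis aborts if more than 20% fail). The same simulated screens serve
both models when both are requested, so Bliss and Loewe are judged against
identical resampled noise.

## Decisions

*Per well*: the bootstrap interval `[a_ij, b_ij]` is the 2.5/97.5
percentile span (linear interpolation between order statistics) of the
uncentered per-well index distribution; synergy if the interval lies
entirely above zero, antagonism entirely below. These calls are descriptive
and not multiplicity-corrected.

*Global (omnibus)*: the null distribution of the extremal statistic is the
per-batch maximum (minimum) of the *null-centered* indices
`I(b,i,j) − I(i,j)` over combination wells (i ≥ 1, j ≥ 1; single-drug
wells have index ≈ 0 by construction and would only dilute the extremum).
Global synergy is declared when the observed I_max strictly exceeds the
97.5-percentile of the centered maximum distribution; global antagonism
when the observed I_min falls strictly below the 2.5-percentile of the
minimum distribution. Centering is what makes the resampled surface obey
the null hypothesis: the uncentered bootstrap maximum straddles the
observed maximum by construction and could never reject. Both flags can be
raised at once (synergy and antagonism at different concentration ranges);
the joint symbol is then "XO". The bootstrap intervals are not
coverage-calibrated confidence intervals; the omnibus test is the headline
inference.

Operating characteristics, measured by `scripts/acceptance.py` and the
test suite on the synthetic null (7 × 9 grid, K = 4, heteroscedastic
Gaussian noise): the global synergy test rejects in ≈ 2.5–4% of null
screens at the nominal one-sided 2.5% level. Known limitation: the
antagonism tail is mildly anticonservative (≈ 7–8% measured) because the
bootstrap index spread scales with the observed single-drug means, which
co-fluctuate positively with the observed index — the upper threshold
tracks observed maxima while the lower threshold anti-tracks minima. A
studentized bootstrap would symmetrize this but is deliberately out of
scope.

## Synthetic screens

The generator emulates the reference layout: I = 8, J = 6, K = 4 (two-fold
ladders centered on each drug's c50), truth surfaces `bliss_null` (product
of Hill curves), `loewe_null` (isobole surface) or `exponential`
(`S = e^{αcA+βcB}`, the one surface that is simultaneously
Bliss-independent and Loewe-additive), additive interaction shifts at
chosen wells (δ > 0 lowers survival, the synergy direction), symmetric
Gaussian or scaled-t (df = 4) noise with piecewise SD 0.03/0.06/0.09 for
true survival < 0.3 / < 0.7 / ≥ 0.7 (package choices emulating
level-dependent error), and multiplicative outliers (factor 2–5) at a
configurable rate. Optionally the screen is back-transformed to raw
fluorescence (`f = f_blank + S · (f_control − f_blank)`) to exercise the
QC path.

What passing tests on these fixtures do *not* show about real screens:
plate-position (edge) effects, drift between replicate plates, asymmetric
error distributions and exposure-time or drug-sequence effects are not
modeled; the generator's noise is exactly the symmetric, level-dependent
kind the bootstrap assumes.

The exponential-equivalence check is a *local* statement — drugs with
exponential responses over a limited effect range — and the two-parameter
Hill family can track an exponential closely only in that shallow regime
(best sup-norm agreement ≈ 0.03 once responses fall to ~0.1, since
combination effective doses extend well past the fitted single-drug
range). The fixture therefore uses a shallow ladder (single-drug survival
0.86–0.99), where the Loewe index deviates from zero by < 0.01.

## Numerical and degenerate-input policy

Percentiles: linear interpolation (NumPy default). Window ranking: stable
sort on |mean difference| with the cell itself forced first, so equal-mean
cells are mutual neighbors. Missing wells are allowed at read time; a cell
with fewer than two finite replicates is excluded entirely and recorded in
the provenance log, and indices needing it become NA. All randomness flows
from a single seed through `numpy.random.SeedSequence`; identical seed and
input reproduce results bit-exactly, including `summary.json`.
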