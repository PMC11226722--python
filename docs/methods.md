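# Methods

## The network and its sufficient statistic

BS_b(m, n), m, n ≥ 1, has order `8mn + 2m + 2n`, size `12mn`, degrees in
{1, 2, 3}. All descriptors implemented here are vertex-degree-based edge
sums, so the *edge partition* — counts of edges per unordered endpoint
degree pair — is a sufficient statistic, and the engine
(`bsbnet.indices.edge_sum`) never materializes a graph: it evaluates
`Σ_classes count × f(d_u, d_v)`. Class counts are exact integers and
integer-valued contributions (M1, M2, HM, F, ReZG3) are summed in integer
arithmetic, so those indices carry no floating-point error at any (m, n).

The published vertex-class counts are internally inconsistent: they sum to
`2mn + 2m + 2n + 2` rather than the stated order, and their degree sum is
`6mn + 5` rather than `24mn` (the handshake value implied by the — fully
self-consistent — edge partition). `bsb_vertex_partition` therefore ships
two modes. The default `consistent` counts are derived by incidence
counting from the edge partition: every (1,3) edge contributes its one
degree-1 endpoint, every (2,3) edge its one degree-2 endpoint, and the
degree-3 incidences close the system, giving
`deg1 → 2m+2n+1, deg2 → 2(m+n−1), deg3 → 8mn−2(m+n)+1`,
which satisfies both the order identity and the handshake lemma for all
m, n. `as_printed` preserves the published counts for audit;
`validate()` reports (never raises) size/order/handshake/per-degree
incidence failures.

## Closed forms, coefficient sets, errata

Each index's closed form lives in the basis {mn, m, n, 1}; for a
contribution f the exact coefficients are
`c_mn = 12 f(3,3)`, `c_m = c_n = 2 f(1,3) + 4 f(2,3) − 6 f(3,3)`,
`c_0 = f(1,3) − 4 f(2,3) + 3 f(3,3)`, computed at full floating
precision. Alongside these the published 4-decimal coefficients are stored
verbatim (`coefficients="paper"`, the default, for table reproduction;
`"exact"` for analytic work). Where the published *statement* is wrong but
its numeric table is right, a `corrected` variant (default) fixes the
statement and an `as_printed` variant preserves it: the R_½ m-term sign
and the ABC n-term. The Balaban index uses the prefactor
`size/(size − order + 2) = 12mn/(4mn − 2m − 2n + 2)` — the convention of
the worked derivation and of the value table — rather than the
order-over-cyclomatic form that appears in the definition line; its value
table reproduces only under the *rounded*-coefficient product form
(±1e-3), the exact form landing up to 8e-3 higher.

Known printing defects are first-class data (`errata()`), including two
defective table columns: the HM cell printed `34,082` (closed form 3408)
and the ReZG3 column, which exceeds the stated closed form by exactly
`144k` at m = n = k; the published ReZG3 fitted-model normalization
(mean 1.561e4) follows the defective column, and the packaged model keeps
those constants with a note. A third defect was found during validation:
the ABC column drifts from any derivable formula by ≈0.00267k (0.0216 at
k = 8), consistent with a per-k coefficient 0.92549 in place of the exact
0.92284; the regression tests pin this drift rather than reproduce it, and
the exact engine is treated as authoritative.

## Curve fitting

Normalization is the z-score with the *sample* (n−1) standard deviation —
the only convention that reproduces the published constants (e.g. the R₁
diagonal series has mean 2544 and sdev 2324.35 → printed 2324).

`fit_rational` minimizes `Σ (y_i − P(x_i)/Q(x_i))²` over numerator
coefficients and the monic denominator's tail, via Levenberg–Marquardt
from multiple starts: start 0 is the deterministic linearized solution of
`y·Q(x) = P(x)` (ordinary least squares, which is exact for noiseless
data), followed by `starts` standard-normal draws from a generator seeded
by `FitOptions.seed` — so identical options and data give bitwise-identical
results. Converged candidates whose denominator has a real root inside
[min x, max x] are rejected during selection; if every candidate has one,
the best is kept and flagged `pole_warning`.

Statistics follow the published conventions, all verified against the 14
printed blocks: `RMSE = √(SSE/(n − p))` (every printed SSE→RMSE pair
reproduces to 4 s.f. under this and no other convention), `R² = 1 −
SSE/SST`, `adj R² = 1 − (1 − R²)(n − 1)/(n − p)`, and 95% bounds
`θ̂ ± t_{0.975, n−p} · SE` with SEs from the residual-variance-scaled
inverse of J'J (singular J'J → infinite bounds plus a warning, not an
exception). Monte-Carlo calibration in the test suite checks ~95%
empirical coverage (100 rational-fit and 500 linear-model replicates).

## Heat of formation

`HOF = (standard molar HOF / N_A) × formula units`, N_A = 6.02214076e23
mol⁻¹. The standard molar enthalpy of BS_b is cited but never printed, so
absolute HOF values cannot be reproduced; the package exposes (a) the
formula for user-supplied enthalpies, with formula units defaulting to a
rule proportional to the size 12mn (per-edge factor configurable — the
published per-(m,m) counts are unknowable), and (b) reconstruction of the
*normalized* HOF series by evaluating the packaged published models on
their own index series. All 14 printed coefficient blocks are packaged
verbatim, including their defects: the R_½ block duplicates the R_₋₁
block's coefficients *and* normalization constants (flagged; the true R_½
model is unrecoverable), and several CI bounds are astronomically wide
(±1e8 against SSE ≈ 1e-4), which is why reconstructions from different
blocks agree only to ~12% where |HOF| ≈ 1 (k = 1) although they agree to
~10⁻⁵ relative at k = 8. A green reconstruction-consistency test therefore
establishes mutual coherence of the printed models at the 15% level, not
recovery of the unpublished data.

## Synthetic data

`random_graph` draws Erdős–Rényi G(n, p) graphs (networkx, explicit seed)
as edge lists for partition/validator property tests — these exercise
combinatorial correctness, not chemical realism. `synthetic_fit_data`
samples a stated rational model on an even grid with seeded Gaussian noise
(σ = 0.01 and n = 50 in the calibration tests, matching the scale of the
published residuals), rejecting specs with a pole inside the x-range. All
generators are pure functions of their spec; there is no global random
state. A green parameter-recovery or coverage test establishes that the
fitter and its intervals are calibrated on well-specified data; it says
nothing about model adequacy on real thermochemical measurements.

## Numerical choices and limitations

* Table comparisons use absolute 1e-2 (4-decimal columns) and 1e-3 for the
  Balaban column, reflecting 4-decimal coefficient rounding amplified by
  class counts; engine-vs-closed-form agreement is exact for integer
  indices and ≤ 0.05 over m, n ≤ 20 for rounded ones.
* Degree pairs are stored unordered (all contributions are symmetric);
  duplicate edges and self-loops are rejected rather than coerced.
* The Balaban index is undefined here for empty edge sets and non-positive
  prefactor denominators (domain errors).
* Randić α is an arbitrary real; non-negative integer α is summed exactly.
* No distance-based or spectral descriptors, no atom-level geometry, no
  periodic-crystal handling, and no model selection across rational
  degrees — out of scope by design.
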