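# bsbnet

Degree-based topological indices of the benzyl sulfamoyl network
**BS_b(m, n)**, with the closed-form polynomial evaluators, heat-of-formation
(HOF) utilities, and the rational curve-fitting apparatus used to model HOF
against each index.

## Who this is for

Chemical graph theorists and QSPR practitioners who want reproducible values
of the standard vertex-degree-based descriptors for the BS_b family — and a
fitting toolkit whose statistics (SSE, R², adjusted R², RMSE, 95% bounds)
follow the exact conventions used in the descriptor literature, so printed
results can be audited.

## The model

BS_b(m, n) (m, n ≥ 1) is a molecular graph family with order
`8mn + 2m + 2n`, size `12mn`, and vertex degrees in {1, 2, 3}. Its edge
partition by unordered endpoint-degree pairs is

| (ℑ(ϑ), ℑ(ϖ)) | count |
|---|---|
| (1, 3) | 2m + 2n + 1 |
| (2, 3) | 4(m + n − 1) |
| (3, 3) | 12mn − 6(m + n) + 3 |

Every index here is an edge sum `Σ_{ϑϖ∈E} f(ℑ(ϑ), ℑ(ϖ))` over that
partition: the generalized Randić index `R_α = Σ (d_u d_v)^α`, the Zagreb
indices `M1 = Σ (d_u + d_v)` and `M2 = Σ d_u d_v`, the atom-bond
connectivity index `ABC = Σ √((d_u + d_v − 2)/(d_u d_v))`, the
geometric-arithmetic index `GA = Σ 2√(d_u d_v)/(d_u + d_v)`, the
hyper-Zagreb `HM = Σ (d_u + d_v)²`, the forgotten index
`F = Σ (d_u² + d_v²)`, the redefined Zagreb indices ReZG1–3, and the
Balaban index `J = (|E|/(|E| − |V| + 2)) · Σ 1/√(d_u d_v)`.

Each index also has a closed form in the basis {mn, m, n, 1}
(e.g. `M1 = 72mn − 8m − 8n + 2`). The published statements contain several
printing defects (a sign typo in R_½, a dropped n-term in ABC, defective
table cells); the package carries both `corrected` and `as_printed`
variants, validates everything against the engine, and enumerates the
defects via `bsbnet.closed_forms.errata()`.

For heat of formation, `HOF = (standard molar HOF / N_A) × formula units`;
since the absolute molar enthalpy of BS_b is not published, HOF enters
either through a user-supplied `ThermoSpec` or by evaluating the packaged
published rational models `HOF ~ P(z)/Q(z)` (z the z-score-normalized
index, monic Q), available via `bsbnet.models.packaged_models()`.

## Worked example

```python
from bsbnet import (GridParams, bsb_edge_partition, bsb_order_size,
                    compute_all, BalabanContext)

p = GridParams(5, 5)
ep = bsb_edge_partition(p)           # {(1,3): 21, (2,3): 36, (3,3): 243}
order, size = bsb_order_size(p)      # (220, 300)
for name, iv in compute_all(ep, BalabanContext(order, size)).items():
    print(name, iv.value)
```

prints the 13-entry catalog for BS_b(5, 5):

```
R_-1 40.0   R_0.5 853.5547   R_-0.5 107.8213
M1 1722     M2 2466          ABC 204.6023    GA 296.4592
HM 9984     F 5052           ReZG1 220.0     ReZG2 423.45
ReZG3 14454 J 394.4681
```

`M2 = 2466` is also `R_1` (α = 1); `ReZG1 = 220` reproduces the order
identity `ReZG1 = 8mn + 2m + 2n`; integer-valued indices are computed in
exact integer arithmetic. The same catalog is available from the shell:

```sh
bsbnet indices --m 5 --n 5            # JSON catalog
bsbnet tables --kmax 8 --outdir out/  # CSV tables + errata report
bsbnet models show M1                 # a packaged published HOF model
bsbnet fit --x x.csv --y y.csv --num-degree 2 --den-degree 2 --seed 1
```

Fitting synthetic data from a known rational model recovers the true
coefficients to ~1e-6 relative in the noiseless case, with seeded
multi-start determinism (`FitOptions(seed=...)`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
rebuilds the BS_b(k, k) edge partitions for k = 1..8, runs the index
engine over them, and writes the diagonal-grid summary statistics
(means and sample standard deviations of the R₁, R₋₁, M1, F, GA, ReZG1,
ReZG2, HM series, plus the Balaban series via its rounded-coefficient
product form) as JSON. Everything is deterministic desk-scale arithmetic;
it finishes in about a second.
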