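# Methods

## Scope

`elmbloom` implements weekly chlorophyll-a regression for pairs of river
weirs: data assembly with the one-week autoregressive lag, an extreme
learning machine (ELM) core, three reference models (multiple linear
regression, a backpropagation network, ANFIS with fuzzy c-means rules),
evaluation and model selection, and a synthetic weir-pair generator that
supplies data with the statistical structure the analysis assumes.

## Feature assembly

For a target week *t* the canonical predictors are AT, RF, SR, TN, TP and
NP at week *t* (contemporaneous) and chlorophyll-a at *t*−1; the ELM2
variant appends upstream chlorophyll-a at *t*−1. Keeping the exogenous
drivers contemporaneous and lagging only the chlorophyll terms keeps the
autoregression causal while using the most recent driver information; both
lags are arguments of `assemble_features` for sensitivity work. Rows with
any missing value are dropped (listwise deletion — no imputation), weeks
are aligned between sites by calendar week-start date, and mismatched
weekly anchors are an error rather than a silent shift. The 50/50
train/test split is chronological by default (first half trains), because
random splitting leaks information through the strong week-to-week
autocorrelation; a seeded random mode exists for sensitivity runs.

## ELM core

Hidden weights and biases are drawn once, i.i.d. uniform, and never
updated; output weights solve the least-squares problem through an SVD
pseudoinverse with singular values below `max(N, L)·eps·σ_max` treated as
zero, so rank-deficient hidden matrices yield the minimum-norm solution
rather than an error.

Two design choices deserve explanation:

* **Weight range.** Input weights default to uniform on [−1/√d, 1/√d]
  (`weight_scale="auto"`; biases stay on [−1, 1], RBF widths on (0, 1]).
  With a fixed range the pre-activation standard deviation grows like √d,
  so models with different feature-set sizes get systematically different
  hidden-unit steepness — a pure artifact that contaminates exactly the
  comparison this package exists for (7-input ELM1 vs 8-input ELM2 on the
  same data). Scaling by 1/√d makes the random feature map's bandwidth
  invariant to d. Plain [−1, 1] weights remain available via
  `weight_scale=1.0`.
* **Per-node seeding.** Node *i* draws from a stream keyed by
  `(seed, i)`, so the L+1-node layer extends the L-node layer under the
  same seed. Nested layers make mean training RMSE provably non-increasing
  in L (each sweep step only adds a column to H), which stabilises the
  capacity sweep.

Inputs are z-scored with training-set statistics by default; on raw scales
(mg/L next to μg/L next to mm) sigmoid nodes saturate immediately. The
hidden-node count is selected by the test-minimum rule over L = 2…30,
averaging each candidate over several hidden-layer draws; ties go to the
smaller L (parsimony).

## Baselines

*Multiple linear regression* is ordinary least squares with intercept
(minimum-norm fallback plus a warning when the design is rank-deficient).

*NN-BP* is one sigmoid hidden layer with linear output trained by
full-batch gradient descent on ½·ΣSE, learning rate 0.001 and 1000 epochs
by default, inputs and target standardised internally (predictions are
returned on the original scale). Its hidden-node count is matched to the
ELM-selected L for capacity-fair comparisons.

*ANFIS-FCM* places one first-order Takagi–Sugeno rule per fuzzy c-means
cluster. Gaussian membership centres come from FCM (fuzzifier 2);
per-feature spreads are membership-weighted standard deviations scaled by
2 — unscaled spreads produced nearly disjoint memberships that degenerate
into a nearest-centre lookup with poor generalisation. Consequents are
fitted in a single least-squares pass on the rule-weighted design matrix.
All membership geometry lives in standardised feature space (the scaler is
part of the model): with raw units spanning four orders of magnitude no
single gradient step size can serve the hybrid backward pass, and training
error failed to decrease until this was fixed (the analytic gradients are
verified against finite differences in the test suite). Construction
refuses rule counts with `r·(d+1) ≥ N` consequent parameters — the
least-squares pass must stay overdetermined; in the weekly regime
(d = 7, N ≈ 100 training rows) this admits r = 2 and 3 and rejects larger
rule counts. The hybrid-learning loop (per epoch: least-squares forward
pass for consequents, clipped gradient backward pass for centres and
spreads, step 0.01, global norm clip 3.0) exists to demonstrate that on
small noisy datasets antecedent tuning lowers training error while raising
test error, which is why the one-pass model is the one compared.

## Evaluation

R² is the Nash–Sutcliffe form `1 − Σ(Y−Ŷ)²/Σ(Y−Ȳ)²` (coefficient of
determination against the observed series; can be negative); a
squared-Pearson variant sits behind a flag. RMSE is in μg/L. AIC uses the
Gaussian-likelihood form `n·ln(SSE/n) + 2k` with k the fitted-parameter
count (ELM: L; LR: d+1; ANFIS: r·(d+1); NN: all weights and biases).
Improvement percentages between two fit reports are `(after−before)/before`
for R² and `(before−after)/before` for RMSE, positive meaning improvement,
displayed at one decimal.

## Synthetic weir pairs

The generator emulates a temperate monsoon climate and eutrophic river
chemistry:

* **Weather.** AT and SR are annual sinusoids (means 14 °C and
  14.4 MJ/m²/day, amplitudes 11 and 7, coldest mid-January) plus Gaussian
  noise; weekly rainfall is gamma (shape 0.7, scale 20 mm) with the scale
  inflated up to 4× around a late-July monsoon peak, giving annual totals
  of roughly 800–1500 mm.
* **Nutrients.** TN and TP are positive mean-reverting AR(1) series
  (means 3.0 and 0.055 mg/L, persistence 0.6) with rainfall-driven runoff
  pulses and a mild winter-high TN season; NP = TN/TP.
* **Chlorophyll.** A multiplicative bloom recursion:
  `Chla(t) = base + inflow(t) + (ar + g(t))·e^(−k·RF(t))·Chla(t−1)/(1 + Chla(t−1)/K) + ε(t)`,
  where the growth rate `g = g_max · logistic((AT−16)/2.5) · TP/(TP+0.03) ·
  SR/S̄` is temperature-gated, phosphorus-limited and light-scaled
  (g_max = 1.5/week), rainfall washes out standing biomass
  (k = 0.02/mm), and logistic self-limitation at K = 90 μg/L caps blooms.
  Observation noise is Gaussian (sd 3 μg/L); a persistent latent forcing
  shared by both sites (sd 3 μg/L, AR(1) persistence 0.85) represents
  unmeasured common hydrology/cloudiness. The downstream site additionally
  receives `coupling` (default 0.5) times upstream chlorophyll lagged one
  week. Series are clamped to [0.1, 300] μg/L and a configuration whose
  noise-free recursion hits the ceiling is rejected as divergent.

Defaults were calibrated once so that, over 50 generator seeds, the
downstream mean sits in the 19–26 μg/L band with maxima below 150 μg/L,
annual rainfall lands in [700, 2000] mm in ≥95% of seeds, and mean TN lies
in [2.0, 4.5] mg/L — the envelopes of eutrophic monsoon-river monitoring.
The rate × biomass and rain × biomass products are the generator's
essential nonlinearity: without them weekly chlorophyll is almost linear
in the assembled predictors and no nonlinear learner can beat ordinary
regression. The shared latent forcing plays a second role: it makes the
upstream series mildly informative in itself (two sites share unmeasured
forcing), sized so that with the transfer switched off the upstream
predictor has no *net* value — what remains of the coupled/uncoupled
contrast is then attributable to transfer alone.

What the generator does **not** emulate: flow routing and residence-time
hydraulics, nutrient–biomass feedback (nutrients do not deplete during
blooms), species succession, censored or irregular sampling, and
instrument drift. Tests passing on this generator therefore demonstrate
that the pipeline extracts upstream transfer and nonlinear driver
responses where they exist — not that any particular river behaves this
way.

## Headline experiments

* **Upstream information** (`experiments.paired_variant_comparison`): on
  50 independent pairs — one generator seed each — ELM1 and ELM2 are fitted
  on the pair's chronological split, each at its sweep-selected L (mean
  test RMSE over 5 hidden draws), and compared by a paired sign test.
  With coupling 0.5 ELM2 wins on the large majority of pairs (p ≪ 0.05);
  with coupling 0 the difference is statistically indistinguishable.
* **Hybrid-learning overfitting** (`experiments.anfis_overfit_rate`):
  ANFIS (r = 2) hybrid-trained for 100 epochs on small noisy pairs
  (50 weeks, observation noise 4 μg/L, random split) lowers training RMSE
  while raising test RMSE in ≥80% of seeds.
* **Recovery oracle**: data generated noise-free from a fixed, known
  5-node network on unit-scale inputs; refitting with the generator's own
  hidden layer recovers β to machine precision, and fresh 30-node layers
  predict held-out points to well under 1% of the target's standard
  deviation.

## Numerical choices and degenerate inputs

Pseudoinverse cutoff `max(N, L)·eps·σ_max`; zero-variance features scale
to 1 in the z-scorer; FCM assigns crisp membership when a point coincides
with a centre and rejects all-identical inputs; ANFIS firing strengths are
computed in log space and fall back to uniform weights when all rules are
numerically silent; AIC refuses SSE ≤ 0 (a perfect fit is flagged rather
than reported as −∞); sweep candidates whose training fails are flagged
with infinite RMSE rather than aborting the sweep; rainfall and
chlorophyll are clamped non-negative everywhere.

## Known limitations

Single upstream/downstream pair (no multi-weir cascades); no gap
imputation; no residence-time model (extra feature columns are the
supported route); the NN baseline is plain gradient descent by design —
no momentum or adaptive optimisers; problem sizes in the test suite are
chosen for fast, deterministic runs and are stated in each test.
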