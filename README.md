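# elmbloom

Chlorophyll-a prediction for weir-regulated rivers with extreme learning
machines (ELM), plus the classical baselines they are judged against and a
synthetic upstream/downstream weir-pair generator that makes the whole
pipeline testable without any field data.

## The problem

Harmful algal blooms in regulated rivers are tracked through weekly
chlorophyll-a concentration (μg/L), the standard proxy for phytoplankton
biomass. Forecasting next week's chlorophyll-a from routinely monitored
drivers — air temperature (AT), rainfall (RF), solar radiation (SR), total
nitrogen (TN), total phosphorus (TP), the N/P ratio and last week's
chlorophyll-a — supports water-supply management and bloom warnings. Two
feature designs are compared:

* **ELM1** — downstream drivers at week *t* plus downstream Chla(*t*−1);
* **ELM2** — ELM1 plus the *upstream* weir's Chla(*t*−1), exploiting the
  fact that water (and biomass) moves downstream between weirs.

## The model

An ELM is a single-hidden-layer feedforward network whose hidden parameters
are random and frozen; only the output weights are estimated, by least
squares:

```
f_L(x) = Σ_{i=1..L} β_i G(w_i, b_i, x),          β = H⁺ T
```

where `H[n,i] = G(w_i, b_i, x_n)` is the hidden output matrix, `H⁺` its
Moore–Penrose pseudoinverse (SVD-based), and `G` a sigmoid, Gaussian-RBF or
sine node. Training is a single linear solve — no backpropagation. The
hidden-node count L is chosen by sweeping L = 2…30 and taking the minimum
mean test RMSE. Skill is reported as RMSE (μg/L) and the Nash–Sutcliffe
form of R², `1 − Σ(Y−Ŷ)²/Σ(Y−Ȳ)²`, plus AIC `n·ln(SSE/n) + 2k`.

Baselines: multiple linear regression, a single-hidden-layer network
trained by full-batch backpropagation (lr 0.001, 1000 epochs), and a
first-order Takagi–Sugeno ANFIS whose rules come from fuzzy c-means
clustering, fitted in one least-squares pass (with an optional
hybrid-learning loop that demonstrates why one pass is enough).

## Worked example

```python
from elmbloom import *

cfg = SynthConfig(seed=7)                       # 4 years of weekly data
up, down, truth = generate_pair(cfg)            # upstream + downstream weir
sset = assemble_features(down, "ELM2", up=up)   # 8 predictors, Chla target
split = split_half(sset)                        # first half train, rest test
sweep = select_hidden_nodes(split.train, split.test,
                            L_range=range(2, 31), seeds=range(5))
model = train_elm(split.train, sweep.selected_L, seed=0)
report = evaluate_model(model, split, label="ELM2")
```

prints, via the obvious formatting:

```
selected hidden nodes: 16
train R2 0.93  RMSE 5.6 ug/L
test  R2 0.91  RMSE 6.0 ug/L
multiple LR test RMSE 7.9 ug/L
```

The ELM2 model explains most of the held-out variance and beats multiple
linear regression by about 2 μg/L of test RMSE on this realisation — the
generator's bloom dynamics (rate × biomass growth, rainfall washout) are
exactly the interactions a linear model cannot represent.

The same pipeline is scriptable:

```bash
elmbloom simulate --seed 3 --outdir run/       # up.csv, down.csv, truth.csv
elmbloom fit --variant ELM2 --outdir run/      # sweep.csv, model.json, report.csv
elmbloom compare --outdir run/                 # comparison.csv, improvement.csv
```

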