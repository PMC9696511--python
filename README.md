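# polysol

Kernel least-squares support vector regression (LS-SVR) for modelling the
solubility temperature of drugs in polymeric carriers.

## The problem

Amorphous solid dispersions (ASDs) stabilise poorly water-soluble drugs by
molecularly dispersing them in a polymer. Whether a formulation is
thermodynamically stable depends on the drug's solubility in the carrier:
for each drug–polymer pair, the solubility temperature `T_sol` — the
temperature at which a given drug loading is fully dissolved in the polymer —
traces a monotone curve in drug load that terminates at the drug's melting
point at 100 wt% drug. Measuring these curves is slow and difficult
(viscous melts, no standard protocol), so a regression model that predicts
`T_sol` across many drug–polymer systems from a handful of descriptors is a
practical screening tool for formulation scientists.

`polysol` models `T_sol` (°C) from three features: drug molecular weight,
polymer molecular weight, and drug load (wt%). Drug and polymer identity
enter only through the molecular weights.

## The model

LS-SVR replaces the ε-insensitive loss of classical SVR with a squared loss:

    min_{w,b}  ½ wᵀw + (γ/2) Σₙ eₙ²,    eₙ = yₙ − wᵀφ(xₙ) − b

With a kernel K(x, x′) = φ(x)ᵀφ(x′) — linear `xᵀx′`, polynomial
`(xᵀx′ + t)^d`, or Gaussian `exp(−‖x−x′‖²/2σ²)` — the optimum is the exact
solution of one linear KKT system in the dual variables α and bias b:

    [ 0   1ᵀ        ] [ b ]   [ 0 ]
    [ 1   K + I/γ   ] [ α ] = [ y ],        ŷ(x) = Σᵢ αᵢ K(xᵢ, x) + b

Training is therefore deterministic; the search effort goes into the
hyperparameters (γ, σ², t, d), which are tuned by simulated annealing with
Nelder–Mead simplex refinement against a cross-validated RMSE objective
(leave-one-out or 10-fold). Competing kernel × CV cells are compared on four
metrics — MARDP (%), MADP (°C), RMSE (°C) and an R-value (1 − SSE/SST) — and
the winner is chosen by averaging the four per-metric ranks. Data validity
is assessed with a Williams plot: standard residuals AD/SD against leverage
(hat-matrix diagonal), flagging records with leverage above
CL = 3(p+1)/N or |SR| > 3.

Because the curated experimental compilation this methodology targets is not
redistributable here, the package ships a synthetic generator
(`polysol.synthetic`) that produces structurally faithful corpora from
Flory–Huggins melting-point-depression curves plus measurement noise,
including a 278-record "literature-like" stand-in with 16 drugs, 13 polymers
and six study groups.

## Worked example

```python
import polysol as ps

ds = ps.literature_like_corpus(seed=1)          # 278 synthetic records
sp = ps.split(ds, ratio=0.85, seed=1)           # 236 train / 42 test
tr = ps.tune(sp.train, "gaussian", ps.CVScheme("kfold", k=10, seed=1), seed=1)
res = ps.LSSVR.from_dataset(sp.train, tr.kernel, tr.gamma).fit()
print(res.summary())
```

Or end to end from the shell:

```bash
polysol run-all --seed 3 --outdir study_out
```

which on a small noisy synthetic corpus prints, for example:

```
best cell: gaussian+kfold10
  training  MARDP=  1.13%  MADP=  1.82  RMSE=  2.64  R= 0.9963
  testing   MARDP=  1.90%  MADP=  3.13  RMSE=  3.92  R= 0.9917
  overall   MARDP=  1.23%  MADP=  2.00  RMSE=  2.85  R= 0.9957
AD_ave=0.16  SD=2.85  valid=36  outliers=0
```

`best cell` is the kernel × cross-validation combination with the lowest
averaged rank; MARDP is the mean absolute relative deviation of predicted
from observed `T_sol`; `AD_ave`/`SD` summarise the residuals (°C); `valid`/
`outliers` are the Williams-plot classification counts. All tables (metrics,
ranks, tuned parameters, residuals, Williams data) are written to
`--outdir` with a hash manifest, and the run is reproducible from the seed.

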