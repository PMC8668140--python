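# fosnet

Regional **c-Fos coactivation networks** for the rat conditioned taste
aversion (CTA) paradigm, together with the paradigm's behavioral scores.

When an animal performs a task, brain regions that were recently active
express the immediate-early gene *c-fos*; counting Fos-positive cells per
region gives a per-animal activation snapshot. If two regions' counts
covary across animals within a condition, the regions are "coactivated".
`fosnet` turns per-subject Fos count tables into:

- **per-condition coactivation networks** — for every pair of the 11
  sampled regions (vmPFC, aIC, gIC5/6, gIC4, NAcC, NAcS, SON, BLA, CeA,
  PVN, VTA), the Pearson correlation *r* is tested with
  *t = r·√(n−2)/√(1−r²)* (df = n−2, two-tailed); pairs with *p* < α
  (default 0.05) keep their signed *r* as an edge, every other
  correlation is set to 0. Connected components of the retained graph
  are the network's independent substructures; regions with no retained
  edges are isolates.
- **differential (subtraction) networks** — to contrast a task condition
  (e.g. BLT, the CTA-expression task) with its control (COT, context
  only), every raw correlation is Fisher-transformed
  (*z = ½·ln((1+r)/(1−r))*), the control *z* is subtracted, the
  difference is back-transformed (*r_diff = tanh(z_task − z_control)*)
  and re-tested with the same *t* formula.
- **behavioral scores** — the CTA strength ratio D2/D1 (day-2 over
  day-1 intake of the conditioned flavor, with a 1 mL day-1 eligibility
  minimum), weight-adjusted intake (mL/kg), ultrasonic-vocalization
  block scores (percentage of ten 1-minute blocks with >10 55 kHz calls
  or >1 22 kHz call) with per-condition emitter tallies, and
  time-sampled nausea scores (pica, lying-on-belly, ptosis; 0–3 per
  15-second block, 24 blocks per hour-long session).
- **synthetic cohorts** — a generator that draws per-subject Fos counts
  from a truncated multivariate Gaussian calibrated to published group
  means (±SEM), with user-planted region-pair correlations per
  condition, plus dose-dependent drinking, USV and nausea data; every
  pipeline stage is testable against known ground truth.

The audience is behavioral-neuroscience labs running Fos coactivation
analyses, and methodologists studying the statistical behavior of
significance-thresholded and z-subtraction correlation networks.

## Worked example

```python
from fosnet import DifferentialCoactivationNetwork
from fosnet.simulate import SyntheticFosConfig, simulate_fos

config = SyntheticFosConfig(
    planted_edges={"BLT": [("CeA", "VTA", 0.85), ("BLA", "CeA", 0.45)]},
    n_per_condition=12,
    seed=17,
)
table, truth = simulate_fos(config)
res = DifferentialCoactivationNetwork(table, "BLT", "COT").fit(alpha=0.05)
print(res.summary())
```

```
         Differential coactivation network [BLT - COT]
================================================================
alpha                   0.05
n rule                  task_n
excluded pairs          0
edges                   10
components              1
isolates                NAcS, PVN
----------------------------------------------------------------
pair                  r_diff           p     n  sign
vmPFC-gIC5/6          -0.899   6.884e-05    12  -
vmPFC-CeA             -0.615     0.03315    12  -
aIC-gIC4              -0.769    0.003428    12  -
gIC5/6-NAcC            0.614     0.03352    12  +
gIC5/6-SON             0.759    0.004239    12  +
gIC4-BLA              -0.855    0.000394    12  -
NAcC-CeA               0.685     0.01405    12  +
SON-CeA                0.716    0.008834    12  +
BLA-CeA                0.742    0.005776    12  +
CeA-VTA                0.590     0.04326    12  +
----------------------------------------------------------------
degree ranking: CeA(5), gIC5/6(3), vmPFC(2), gIC4(2), NAcC(2), SON(2), BLA(2), aIC(1), VTA(1), NAcS(0), PVN(0)
```

Both planted task-only correlations (CeA–VTA and BLA–CeA) are retained
and CeA tops the degree ranking. The additional edges illustrate a real
property of the subtraction procedure: because the re-test treats
`r_diff` as a single correlation estimated from *n* subjects, its null
false-positive rate exceeds the nominal α (see `docs/methods.md`), so a
12-subject contrast retains several chance edges alongside the planted
ones.

The same analyses are available from the shell:

```bash
fosnet simulate --seed 17 --out data/
fosnet score-behavior --drinking data/drinking.csv --usv data/usv.csv \
    --nausea data/nausea.csv --out scores/
fosnet build-networks --fos data/fos.csv --conditions COT,BOT,BLT --out nets/
fosnet diff-networks --fos data/fos.csv --task BLT --control COT --out nets/
fosnet run --config pipeline.yaml   # full pipeline + reproducibility manifest
```

Networks are written as edge-list TSV, symmetric adjacency CSV (absent
edges as 0) and GraphML.

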