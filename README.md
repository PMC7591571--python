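# jhtriage

Analysis pipeline for dual-luciferase high-throughput screens that hunt for
**juvenile-hormone (JH) signaling inhibitors** in insect cell lines. JH keeps
larvae larval; compounds that block the Met/SRC → *Kr-h1* signaling axis
trigger precocious metamorphosis and are candidate insect growth regulators.
The assay reads two channels per well: firefly luciferase (**Fluc**) driven by
a JH response element reports pathway activity, and constitutively driven
Renilla luciferase (**Rluc**) reports cell viability, so cytotoxic false
positives can be recognized and removed.

The package is aimed at screening scientists and computational biologists who
need a tested, scriptable version of this triage rather than spreadsheet
arithmetic: plate-level normalization and QC, the multi-stage hit cascade,
dose–response fitting, antagonist-mode pharmacology, and qPCR validation —
plus a synthetic plate simulator with known ground truth for validating every
step.

## The statistics at the core

Per-plate normalization of a well reading *S* between the plate's own DMSO
(positive, baseline) and 1 nM JH I (negative, full-signal) controls:

```
InH (%) = 100 × (1 − (S − mean_p) / (mean_n − mean_p))
```

so InH = 0% at the negative-control mean (no inhibition) and 100% at the
positive-control mean (complete inhibition). Plate quality is gated on

```
Z′ = 1 − (3·SD_p + 3·SD_n) / |mean_n − mean_p|
```

The hit cascade keeps compounds with InH ≥ 26% at 5 µM (primary, n = 1), mean
InH ≥ 20% on confirmation (n = 4, adherence-flagged wells excluded), InH > 10%
at the lowest dose of a three-point series, and InH > 15% at 0.5 µM with
InH > −10% at 0.05 µM in the analog/dose test; compounds losing > 50% of the
Rluc viability signal at the top dose are excluded as cytotoxic.

Dose–response curves use the four-parameter logistic
`R(c) = bottom + (top − bottom) / (1 + (EC50/c)^h)`. Antagonist mode is called
from JH curves measured with and without inhibitor: a significant drop in the
maximal response (equal-variance Student's *t*, p < 0.001) means
noncompetitive; otherwise a fitted EC50 dose ratio ≥ 2 at the top inhibitor
dose (Gaddum shift, DR = 1 + [I]/K_i) means competitive-like. qPCR validation
uses relative expression by 2^−ΔΔCt against a constitutive reference gene.

## Worked example

Simulate a 960-compound campaign with a realistic latent-class mix (~3%
planted actives), run the full cascade, and characterize a hit:

```python
import json, numpy as np
import jhtriage as j

lib, truth = j.simulate_library(960, seed=7)
config = j.SimulationConfig(seed=7)          # EC50_JH = 3.7e-10 M, 5%/10% CV
plates, layouts = j.simulate_screen(lib, config)
result = j.run_cascade(plates, layouts)
print(json.dumps(result.counts))
zs = [q.z_prime for q in result.qc]
print("Z' mean +/- sd: %.2f +/- %.2f over %d plates"
      % (np.mean(zs), np.std(zs), len(zs)))
```

prints

```
{"screened": 960, "stage1_hits": 25, "stage2_hits": 24, "stage3_hits": 23, "stage4_hits": 23, "final_active": 13}
Z' mean +/- sd: 0.84 +/- 0.03 over 114 plates
```

All 13 final actives are planted inhibitors (9 competitive, 4 noncompetitive);
the planted pure cytotoxics are excluded by the Rluc rule with reason
`"cytotoxic"`. Fitting the inhibition dose–response of a competitive inhibitor
whose ground-truth cellular EC50 is 3.2e-7 M (n = 3, 10% CV noise):

```python
fit = j.fit_4pl(curve, weighting="absolute")   # curve: InH % vs inhibitor conc
```

returns `EC50 = 3.46e-07 M, hill 1.12, top 99.7, bottom 3.9` — the planted
potency recovered well inside the fit's expected log-scale scatter. The
antagonist-mode classifier on the same compound's JH-curve grid returns
`competitive_like` with a non-significant maximal-effect test (p = 0.88) and a
large fitted dose ratio, the signature of a surmountable antagonist.

A thin CLI wraps the same library functions:

```bash
jhtriage simulate --n 960 --seed 7 --out sim/
jhtriage qc sim/stage1.csv
jhtriage screen sim/ --out report.tsv
```

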