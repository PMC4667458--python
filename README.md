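# lipidtrn

Analysis pipeline for nutrient-starvation expression time courses in microalgae:
from an FPKM transcript x timepoint matrix to (1) differentially regulated
transcripts, (2) temporally ordered *transcriptional waves* of co-regulated
modules, (3) a time-lagged transcriptional-regulator (TR) influence network,
and (4) a flux-balance-analysis (FBA) knockdown screen that ranks metabolic
genes by predicted storage-lipid (TAG) gain per unit biomass.

The pipeline targets the nitrogen-starvation response of *Chlamydomonas
reinhardtii* — the transition from growth into lipid accumulation — but every
stage is generic over any starvation time course with a pre-stress reference
sample. A synthetic-data module generates complete input bundles with planted
ground truth, so the whole chain is testable without external downloads.

## The methods

**Filtering.** For transcript *i* with FPKM *x*, the log2 ratio against the
pre-starvation reference is

    r_i(t) = log2((x_i(t) + 1) / (x_i(0) + 1))

A transcript is differentially regulated when |r| > 1 either (rule 1) at the
lipid-accumulation timepoints (8, 12, 24, 48 h), or (rule 2) with constant
sign across consecutive samples spanning >= 30 min.

**Waves.** Module mean trajectories are smoothed with a cubic smoothing
spline (GCV-automatic penalty) onto a 1-min grid, classified as *monotonic*
(a new steady state) or *transient* (returns to pre-starvation levels), and
stamped with the first time |r| crosses the twofold threshold. Modules sharing
class, direction and quantized timestamp form a wave; timestamps map onto
early (0–18 min), mid (18–60 min) and late (1–8 h) response stages.

**TR influences.** Smoothed profiles are divided by their maximum absolute
value; the distance between a regulator profile f and a module profile g at
lag L is the RMS of f(t) − g(t + L) over the overlap, scored against −g as
well (repression), minimized over the physiological lag window 15–90 min. A
TR → module influence is called when a pair's best distance falls below the
5th percentile of the pooled best distances.

**Knockdown screen.** Starting from a stoichiometric model whose biomass
objective has been split into BM_TAG (biomass without TAG species) and EX_TAG
(a TAG exchange with the biomass TAG composition), a gene knockdown caps every
reaction lost under its GPR rule at 1/16 of the wild-type flux (parsimonious
FBA), and the dimensionless score

    rho = (TAG_pert / TAG_WT) / (BM_TAG_pert / BM_TAG_WT)

flags genes whose loss yields more TAG per unit biomass (rho > 1) while
retaining at least 10 % of wild-type biomass flux (viability).

## Worked example

Generate a synthetic bundle and run the chain with the numbered drivers:

```sh
python analysis/01_simulate.py            # writes results/sim/
python analysis/02_filter.py
python analysis/03_waves.py
python analysis/04_trn.py
python analysis/05_knockdown_screen.py
```

`03_waves.py` prints, for the noiseless wave benchmark:

```
12 modules -> 6 waves
  W01: monotonic/up crossing 14.0 min (early), modules M01,M02
  W02: transient/up crossing 27.9 min (mid), modules M05,M06
  W03: monotonic/down crossing 36.4 min (mid), modules M07,M08
  ...
dynamics classes correct: 12/12
worst timestamp error vs analytic crossing: 1.40 min
```

i.e. every planted dynamics class is recovered and the minute-resolution
crossing timestamps are within 1.4 min of the analytic crossings. `04_trn.py`
reports `precision 1.000, recall 1.000 ... signs correct 60/60` for the 10
planted wave influences (60 TR → module edges) among 1,200 scored pairs, and
`05_knockdown_screen.py` shows the branch-fixture knockdown doubling TAG per
biomass (`gC: rho 2, biomass ratio 0.5, viable True`) while the shared-chain
knockdown leaves rho at 1.

The same stages are available as a CLI (`lipidtrn simulate|filter|waves|trn|kd|run`);
`lipidtrn run --config examples/config.yaml` executes everything from a single
YAML file and writes a manifest with parameter records and output hashes.

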