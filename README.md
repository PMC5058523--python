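# snailrisk

Invasion-risk analysis for a forest-endemic land snail spreading into
cardamom plantations, built as a reproducible pipeline on raster
landscapes. The package is aimed at spatial ecologists who want a fully
scriptable, presence-background species distribution workflow — from
predictor screening through suitability modeling, habitat-overlap
statistics, an additive invasion-risk score, and a dispersal-constrained
cellular-automaton projection — that can be validated end to end on
synthetic landscapes with known ground truth.

## The model

**Habitat suitability** is a presence-background maximum-entropy model:
the environment at occupied cells constrains a Gibbs distribution over
the landscape,

    q(x) = exp(Σ_j λ_j f_j(x)) / Z,

where the features f_j are linear, quadratic, and pairwise-product
transforms of the environmental predictors (standardized over a
background sample) and Z normalizes over that background. The
coefficients λ maximize the L1-penalized mean presence log-likelihood;
the penalty βΣ|λ_j|/√m (m presences) keeps uninformative features at
exactly zero. Suitability is reported on the logistic scale
r·e^H/(1 + r·e^H), with r the raw Gibbs density and H the entropy of the
fitted background distribution.

**Evaluation** uses rank-based AUC against background pseudo-absences
and the true skill statistic TSS = sensitivity + specificity − 1, with
the operating threshold chosen to maximize sensitivity + specificity
(MTSS). Replicate models on random 70/30 presence splits give the mean
(SD) summaries. Predictors are screened beforehand: of any pair with
Pearson |r| > 0.7, the lower-priority member is dropped.

**Invasion risk** on crop-suitable cells is the rescaled unweighted sum
of three [0, 1] components: the snail's (categorical) suitability, a
binary forest/transformed land-cover term, and proximity to known snail
records (rescaled inverse Euclidean distance).

**Dispersal** is a MIGCLIM-style cellular automaton on a 0–1000
suitability scale: cells at or above `rcThreshold` are colonizable,
occupied cells below it are lost, colonization pressure comes from
mature neighbors through a distance kernel (with optional rare
long-distance events), and transformed land acts as an impermeable
barrier. Unlimited- and no-dispersal scenarios bracket the automaton.

## Worked example

Run the whole chain on the default 60×60 synthetic landscape (6
correlated, spatially autocorrelated predictors; 150 occurrences per
species; a 4-period drifting future series):

```sh
snailrisk run --seed 1 --outdir out
```

or equivalently from Python:

```python
from snailrisk import load_config, run_pipeline
cfg = load_config(overrides={"seed": 1, "outdir": "out"})
run_pipeline(cfg)
```

`out/report/summary.json` then contains (seed 1):

```
snail: auc_train_mean 0.821  auc_test_mean 0.820  tss_mean 0.525  mtss 0.390
crop:  auc_train_mean 0.725  auc_test_mean 0.706  tss_mean 0.267  mtss 0.509
overlap: snail 1238 cells, crop 1062 cells, 827 shared,
         proportional overlap 0.779
dispersal (final period, occupied cells):
         unlimited 127, none 127, constrained 59
demography: adults t = 4.66, p = 5.3e-04
```

Reading these: both species' suitability models discriminate presences
from background well above chance (AUC ≈ 0.82 / 0.71); binarizing at
each species' MTSS threshold, 77.9 % of the smaller suitable area is
shared between snail and crop; under the declining environmental series
the dispersal-constrained snail occupies fewer cells (59) than the
suitability ceiling allows (127), because barriers and stepwise spread
slow it down; and demographic densities at highly suitable sites exceed
those at poor/unsuitable sites (Welch t-test, p < 0.001).

Every stage writes plain-text artifacts (Esri ASCII grids, CSV, JSON)
plus a manifest of content hashes; rerunning with the same config and
seed reproduces the hashes bit for bit. Individual stages are available
as subcommands (`snailrisk simulate`, `snailrisk screen`, ...).

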