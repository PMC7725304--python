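# dmhapto

Hapto-electric signaling analysis for the Venus flytrap (*Dionaea
muscipula*) trigger hair: a mechanistic model of action-potential (AP)
driven K⁺/anion fluxes and turgor pressure in the hair's mechanosensory
cells, Boltzmann/pH gating analysis of the trigger-hair-specific K⁺
channel KDM1, and the Shannon-entropy × differential-expression procedure
that calls bona fide tissue-specific genes from multi-tissue RNA-seq.

The package is aimed at plant electrophysiologists and systems biologists
who want to simulate trigger-hair excitability budgets, fit
voltage-clamp gating data, or run an entropy-based tissue-specificity
screen — each component is usable on its own.

## The models

**AP/turgor model.** Two compartments (cell, and an apoplast α times its
volume) exchange K⁺ and a monovalent counter-anion A⁻. During the ~1 s
depolarized phase of an AP (binary flag *trigger* = 1) both ions leave the
cell at

    j_efflux = k · (V_excited − E_K),      E_K = RT/F · ln([K⁺]apo/[K⁺]cell)

and during recovery (*trigger* = 0) an energized uptake pathway returns
them at the β-times slower rate

    j_influx = min(0, k · β · (V_rest − E_K + V₀))

which stops once the resting gradient (E_K = V_rest + V₀) is restored.
The salt movement changes the osmotic, hence hydrostatic, pressure
difference dP = RT·Δc across the membrane — the cell's turgor. A
mechanical stimulus only fires an AP while relative turgor is above a
critical threshold (~50%), which reproduces the dropout patterns seen
under high-frequency stimulation and their aggravation when the uptake
channel is blocked by Cs⁺ (modelled as reduced β). Integration is explicit
Euler at dt = 0.05 s with defaults α = 15, V_excited = −60 mV,
V_rest = −170 mV, k = 1 mol/(l·V·s), β = 0.01, RT/F = 25 mV,
[K⁺]cell,0 = [A⁻]cell,0 = 100 mM, [K⁺]apo,0 = [A⁻]apo,0 = 1 mM.

**KDM1 gating.** Open probability follows a Boltzmann curve
po = 1/(1 + exp(aF/RT·(V − V₁ᐟ₂))); external acidification shifts the
midpoint per a combined Boltzmann / law-of-mass-action model

    V₁ᐟ₂(pH) = V₁ᐟ₂,∞ − RT/(aF) · ln[(10^pH + 10^pK_C)/(10^pH + 10^pK_O)]

with pK_O > pK_C for this acid-activated channel. Fitters are
scikit-learn estimators (`BoltzmannCurveFit`, `PHCurveFit`); standard
voltage-clamp analyses (tail-current normalization, per-cell I–V
normalization, Nernst slope, fractional block) are included.

**Tissue specificity.** Per gene, H = −Σ p_t log₂ p_t over tissue
expression shares and Q_t = H − log₂ p_t; low Q marks genes specific to
tissue t. The specificity cutoff is either fixed (3.9 bits) or the lower
1%-area quantile of a Laplace fit to the Q distribution. Genes below the
cutoff that are also ≥2-fold up versus *every* other tissue
(BH-adjusted p < 0.001, focal counts > 50) are bona fide tissue-specific.

A seeded synthetic-data module generates the 7-tissue × 3-replicate
negative-binomial count design (with planted specific genes), matching DE
tables, and noisy gating datasets, so every pipeline is testable against
known ground truth.

## Worked example

```python
from dmhapto import (ModelParams, single_ap_summary, operating_range,
                     recovery_time, v_half_at_ph, WT_PH_PARAMS)

params = ModelParams()                      # printed defaults
print(single_ap_summary(params))
# {'k_cell_decrease_pct': 31.511509946022557,
#  'k_apo_final_pct_of_initial': 310.07673297348384,
#  'k_apo_increment_pct': 210.07673297348384,
#  'dp_decrease_pct': 33.951795228037795}

print(operating_range(params, frequency=0.05, n_stimuli=60))
# {'min_pct': 50.78760575848862, 'max_pct': 60.236613503780326,
#  'converged': True, 'dropout_in_final_cycle': False}

print(recovery_time(ModelParams(beta=0.002)) / recovery_time(params))
# 5.000907646922914  -- 5x slower recovery when uptake is blocked 5-fold

print(v_half_at_ph(4.0, WT_PH_PARAMS), v_half_at_ph(7.0, WT_PH_PARAMS))
# -95.60252952468345 -176.52763414948237  (mV)
```

A single AP thus spends ~30% of the cytosolic K⁺ pool, triples
apoplastic K⁺, and drops turgor by ~34%; repetitive 0.05-Hz stimulation
settles into a 51–60% operating band of resting turgor, always above the
50% firing threshold. The gating model evaluated at the fitted wild-type
parameters reproduces the measured half-activation voltages at pH 4 and
pH 7 within a millivolt.

The same runs from the shell:

```
dmhapto simulate-ap --times 0 --t-end 2 --out run     # trajectory + events TSV
dmhapto recovery --beta 0.002
dmhapto synth expr --seed 1 --out synth/              # planted-truth study
dmhapto spec classify --expr synth/means.tsv --de synth/de --q-thresh auto \
    --out calls.tsv
```

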