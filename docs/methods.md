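# Methods

## The AP/turgor model

The model is a deliberately minimal salt-and-water budget for a single
mechanosensory cell at the trigger-hair base. Two well-mixed compartments
— the cell and an apoplastic shell of volume α·Vol_cell — exchange K⁺ and
one monovalent counter-anion. The membrane voltage is not a dynamical
variable: it is prescribed as a two-level signal, V_excited during the
~1-s depolarized phase of an AP and V_rest during recovery, switched by a
binary `trigger`. The anion flux equals the K⁺ flux at all times
(electroneutral salt movement), so K⁺ and A⁻ trajectories are identical
when initialized identically. Water is assumed to equilibrate fast
relative to the salt fluxes, so the change in osmotic pressure difference
maps directly onto the hydrostatic (turgor) pressure difference
dP = RT·(c_cell − c_apo). Volumes are fixed; there is no spatial
propagation and no kinetic channel gating inside this model.

Flux laws (flux densities in mM/s, voltages in mV):

* efflux (trigger = 1): `j = k·(V_excited − E_K)` with
  `E_K = RT/F·ln([K⁺]apo/[K⁺]cell)`;
* influx (trigger = 0): `j = min(0, k·β·(V_rest − E_K + V₀))`.

The `min(0, ·)` clamp implements the statement that uptake *stops* when
the gradient is re-established: past the fixed point the linear drive
would change sign and the uptake pathway would unphysically leak salt
back out.

### Parameters

| name | default | units | meaning |
|---|---|---|---|
| alpha | 15 | – | apoplast/cell volume ratio |
| v_excited | −60 | mV | voltage in the excited state |
| v_rest | −170 | mV | voltage in the recovery state |
| v0 | resolved (54.87) | mV | resting offset; uptake stops at E_K = v_rest + v0 |
| k | 1 | mol/(l·V·s) | flux rate constant a_K/Vol_cell |
| beta | 0.01 | – | uptake efficiency (energized, ~100× slower) |
| rt_over_f | 25 | mV | thermal voltage; also fixes RT for pressure |
| dt | 0.05 | s | explicit-Euler step |
| excited_duration | 1.0 | s | depolarized phase per fired stimulus |
| turgor_threshold | 0.5 | – | relative dP below which stimuli fail |
| K_cell0/A_cell0 | 100 | mM | initial cytosolic concentrations |
| K_apo0/A_apo0 | 1 | mM | initial apoplastic concentrations |

Design choices where the setup was genuinely open:

* **Exact resting fixed point.** The nominal rounded V₀ = 55 mV leaves a
  residual uptake drive of ~0.13 mV at the initial composition, which
  would cause a slow artificial drift over long simulations. By default
  V₀ is therefore resolved at construction to E_K0 − V_rest =
  54.87 mV, making rest an exact equilibrium; the literal 55 mV can be
  set explicitly and changes nothing beyond 0.2%.
* **One temperature.** RT used for pressure is derived from the
  configured RT/F via RT = (RT/F)·F (24.12 bar·l/mol at 25 mV), so a
  single parameter controls both the Nernst term and the osmotic
  conversion. The default composition then gives dP₀ = 4.78 bar (~5 bar).
* **Integration.** Explicit Euler at dt = 0.05 s, no adaptive stepping —
  the reference numbers include first-order discretization effects, and
  halving dt changes the end-of-AP cytosolic K⁺ by < 0.4%. A step that
  would produce a negative concentration raises an error (dt too large).
  The per-step pressure decrement is −2·RT·(α+1)/α·j·dt, which keeps the
  incrementally integrated dP equal to RT·Δc recomputed from the state to
  float accuracy, and K_cell + α·K_apo is conserved exactly by
  construction.
* **Stimulus semantics.** The excited phase spans [t_s, t_s + 1 s) in
  half-open convention (exactly 20 Euler steps at the default dt). The
  turgor threshold is evaluated instantaneously at the stimulus time. A
  stimulus arriving during an ongoing excited phase is recorded as a
  skipped non-event — neither an AP nor a dropout — since the reference
  protocols never stimulate inside the 1-s window and arbitrary protocols
  need an explicit rule.
* **Recovery time.** The approach to rest is asymptotic, so "full
  recovery" is quantified as relative dP ≥ 99% of resting (tol = 0.01,
  configurable). Because the recovery field scales linearly with β, the
  recovery-time ratio between two β values equals their inverse ratio
  independent of the tolerance (up to one Euler step), which is why a
  5-fold β reduction gives a 5.001× slowdown at the defaults.
* **Operating range.** Under periodic stimulation the per-cycle extrema
  of relative dP converge to a band; the first max(10, n/2) cycles are
  discarded as transient and convergence is declared when consecutive
  cycles' extrema agree within 0.1 percentage points. At 0.05 Hz × 60
  stimuli the band is 50.8–60.2% of resting.

## KDM1 gating analysis

Open probability is the two-parameter Boltzmann
po = 1/(1 + exp(a/(RT/F)·(V − V₁ᐟ₂))), decreasing in V
(hyperpolarization-activated). The pH dependence of V₁ᐟ₂ follows a
law-of-mass-action scheme with apparent protonation constants of the open
and closed state; with the wild-type constants (V₁ᐟ₂,∞ = −177.048 mV,
pK_O = 5.1328, pK_C = 4.04, RT/(aF) = 42 mV) the model evaluates to
−95.60 mV at pH 4 and −176.53 mV at pH 7, and for the pH-sensor mutant
H147S (V₁ᐟ₂,∞ = −153.632 mV, pK_O = 4.6285, pK_C = 4.1914) the pH 7→4
shift compresses to 30.2 mV.

Fitting uses bounded-free Levenberg–Marquardt least squares
(`scipy.optimize.least_squares`) with 5 multi-starts: the V₁ᐟ₂ start is
the voltage whose relative open probability is nearest 0.5 (spread over
the voltage range), and the pK starts sit at the data pH extremes to
guard the pK_O/pK_C exchange degeneracy. Fits are unweighted by default
(per-point weighting is possible by pre-scaling); standard errors come
from the Jacobian at the optimum. Curves with fewer than 5 distinct
voltages or a dynamic range below 0.2 are rejected; a fitted a < 0 is
returned but flagged as inconsistent with hyperpolarization activation.
Relative open probabilities slightly above 1 from noise are retained, not
clipped — clipping would bias V₁ᐟ₂.

Tail currents are normalized by the maximum |tail| (sign shared across
the curve); I–V datasets are normalized per cell by |I| at a stated
reference condition/voltage (default −150 mV) before across-cell
averaging, making the analysis invariant to the large cell-to-cell
amplitude variance of oocyte expression. Fractional block is
1 − I_block/I_control at the reference voltage, clipped to [0, 1] with
out-of-range raw values flagged.

## Tissue specificity

Entropy scoring follows the standard entropy-specificity scheme:
proportions are formed over mean per-tissue expression (replicate means,
not per-replicate values), H is in bits, and Q_t = H − log₂ p_t. A
pseudocount (default 10⁻³ expression units) handles zeros; with
pseudocount 0, zero-share tissues get Q = +∞ and all-zero genes are
flagged and left unscored. Both H and Q are invariant under global
rescaling of a gene's profile, so expression units are immaterial.

The data-driven Q cutoff fits a Laplace distribution to the focal-tissue
Q values by maximum likelihood — location = median, scale = mean absolute
deviation from the median — and takes the lower quantile
μ + b·ln(2·area) at area = 1% (one-tailed on Q itself). On the synthetic
default design this lands at ≈3.8–3.9 bits. The fixed 3.9-bit mode is
retained because the exact published cutoff is a property of the study's
full expression data and cannot be re-derived without it; for the same
reason the package makes no attempt to reproduce the published gene
counts (810 intersection DEGs, 495 bona fide genes), covering the
procedure instead with planted-truth recovery and null calibration.

DE tables are *inputs* to the intersection step; the package does not
reimplement a published RNA-seq DE method. Classification requires, per
gene: Q_focal below the cutoff, and log2FC > 1 with BH-adjusted
p < 0.001 in every pairwise comparison plus focal normalized counts > 50.
Ranking of the highly expressed (focal expression > 20) bona fide genes
is by ascending Q, ties broken by descending focal expression then gene
id — deterministic by construction.

## Synthetic data

The expression generator emulates the study design: 7 tissues × 3
replicates, 2,000 genes with log-normal baseline means (log-mean 3,
log-sd 1, i.e. typical means ~20 counts spanning two orders of
magnitude), negative-binomial noise (gamma–Poisson, dispersion 0.1), and
100 planted genes over-expressed 16-fold in the focal tissue. These
defaults are chosen so the planted effect is strong and unambiguous — the
published specific genes are enriched well over an order of magnitude —
while keeping every recovery property checkable in seconds. All
generators are pure functions of (parameters, seed).

The stand-in DE step is a two-sample test on log(count + 1) with
per-comparison BH adjustment. At n = 3 replicates a plain per-gene t test
(4 df) cannot resolve p-values small enough to survive BH at 0.001, so
the per-gene pooled variances are shrunk toward their across-gene mean
with a fixed prior of 20 df and the reference distribution is t with
4 + 20 df — a fixed-prior moderated t in the spirit of limma-trend. This
keeps the null well behaved (0 BH-0.001 discoveries across 20 null seeds
in the test suite) while giving the planted 16-fold genes essentially
full power (pipeline precision median 1.0, recall median 0.97 over 20
seeds).

What the generator does *not* emulate: gene-length variation (all genes
nominally 1 kb, fixed library size, so "FPKM" is numerically the count —
inconsequential because scoring is scale-invariant), correlated genes,
batch effects between sequencing runs, multi-mapping artifacts, and
realistic DE-method behaviour. Passing tests therefore demonstrate that
the scoring/intersection logic is correct and well calibrated under the
assumed count model, not that the thresholds are optimal for any real
tissue panel.

The gating generators draw relative open probabilities as
po(V) + N(0, σ) on a 16-voltage grid, and I–V curves from the
open-channel model I = G·po(V; V₁ᐟ₂(pH))·(V − E_K) with per-cell
log-normal amplitude factors and blockers as fractional conductance
scaling — sufficient structure to round-trip every analysis (fit
recovery, Nernst slope, normalization invariance, fractional block) but
no kinetics and no voltage-dependent block.

## Known limitations

* The AP model has no membrane-potential dynamics, no Ca²⁺, no water
  fluxes/volume changes, and no spatial spread; it is a budget model for
  one cell's salt and turgor, valid on the seconds-to-minutes scale.
* Explicit Euler at a fixed dt reproduces the reference discretization
  but is only first-order; quantities read at the end of the excited
  phase carry ~1% discretization sensitivity.
* The Boltzmann fitters assume independent homoscedastic noise on
  relative open probability; no kinetic (time-course) modelling.
* The moderated DE test is plumbing for exercising the intersection
  logic, not a substitute analysis for real RNA-seq data.
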