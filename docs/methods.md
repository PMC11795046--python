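# Methods

This note documents the models, defaults and design decisions behind
`induceopt`: what the digital twin simulates, how the surrogate and the
batch optimizer are configured, and which choices were genuinely open.

## Mix arithmetic

A dose is an abstract fraction pair $(x, e) \in [0,100]^2$ (enzyme absent
in the 1-D system). The mix converter maps fractions to volumes linearly —
$v_\text{ind} = (x/100)\,v_\text{ind}^{max}$ — rounds each component to the
pipetting resolution (0.1 µL, a typical liquid-handler step), and fills
with water so components always sum exactly to the mix total. Final well
concentration of a stock with concentration $c$ is
$c \cdot (v/V_\text{mix}) \cdot (V_\text{transfer}/V_\text{well})$,
returned unrounded; display rounding is formatting.

Two reference recipes are built in:

| recipe | mix total | max inducer | max enzyme | transfer/well |
|---|---|---|---|---|
| 1-D IPTG (20 mM stock) | 100 µL | 100 µL | — | 20 µL / 200 µL |
| 2-D lactose (20 % w/v) + enzyme (1500 U/L) | 95 µL | 75 µL | 20 µL | 20 µL / 200 µL |

With these geometries, x = 7, 9, 100 give 0.14, 0.18 and 2.0 mM IPTG;
75 µL lactose gives 43.8 mM and 7–9 µL enzyme 11–14 U/L in the well. The
lactose stock molarity uses the monohydrate molar mass (360.31 g/mol),
the form actually weighed for w/v stocks; it is the value consistent with
the 43.8 mM ceiling. The two recipes deliberately differ in mix total
(100 vs 95 µL): each total is the one consistent with its system's
concentration arithmetic.

Doses entering a run are snapped to the nearest pipettable fraction
(volume round-trip), so everything in a provenance store is physically
realisable.

## The twin

The twin replaces incubator, plate reader and bacteria with a seeded
simulator. It is *not* a mechanistic model of lac induction; it is the
simplest generator with the qualitative features the optimizer must cope
with.

**Growth.** Logistic with lag:
$\mathrm{OD}(t) = K / (1 + \frac{K - \mathrm{OD}_0}{\mathrm{OD}_0}
e^{-\mu (t - t_\text{lag})})$, with $\mathrm{OD}_0 = 0.1$ (the adjusted
inoculum), $K = 1.6$ (the plateau seen in well cultivations),
$\mu = 0.6\,\mathrm{h^{-1}}$, $t_\text{lag} = 1$ h. With hourly readings
the mean-OD 0.6 induction trigger fires at t = 5 h, later than the 4 h
readout delay, so by the time any plate needs doses all earlier plates
have been read out — the serial plate chain never requires lookahead.
After induction the growth rate is reduced by up to 10 % at x = 100
(expression burden), keeping trigger timing mildly dose-dependent.

**Response.** Noiseless GFP signal
$g(x) = b + v_{max}\,x^n/(k^n + x^n)$ with $b = 2$, $v_{max} = 100$,
$k = 5$, $n = 2$ (arbitrary fluorescence units): near-zero induction at
x = 0, a sharp rise, then a plateau. In the 2-D system this is multiplied
by a unimodal enzyme factor — a Gaussian bell centred at $e_{opt} = 42$
(the 7–9 µL band on the 0–20 µL enzyme axis, rescaled to fractions) with
width 15 and floor $1 - 0.7$ — emulating catabolite repression at high
glucose release. Expression ramps linearly from basal to $g$ over a 4 h
maturation window, so the readout taken 4 h after induction sees the full
signal. Any monotone-saturating / unimodal pair would do; nothing
downstream depends on these exact forms.

**Objective.** $f(x) = \alpha_i x + \alpha_g g(x)$ with
$\alpha_i = -5.05$, $\alpha_g = 1$ (and $\alpha_e = -0.1$ additively in
2-D). $\alpha_i$ was chosen analytically from $f'(x^\star) = 0$ so the
noiseless optimum sits at $x^\star = 8.0$ (exactly, at 0.1-grid
resolution) — the centre of the [7, 9] target band against which hit
counts are scored. Away from the peak the inducer cost dominates
($f(100) \approx -400$), making the objective strongly skewed, which is
the realistic and the hard case for the batch heuristic (see below).

**Noise.** Fluorescence is
$g \cdot (1 + \delta_p)(1 + \varepsilon)$ clipped at zero, with
$\varepsilon \sim N(0, \sigma_w^2)$, $\sigma_w = 0.10$ per well
(multiplicative: noise scales with signal), and $\delta_p$ a per-plate
offset following a Gaussian random walk over the plate index with
increment sd $\sigma_p = 0.05$. The walk makes
$\mathrm{Var}(\delta_p - \delta_q)$ grow linearly in $|p - q|$: drift
between distant plates exceeds drift between consecutive ones, which is
the phenomenon the surrogate's plate axis must absorb. OD readings are
noiseless — the trigger logic, not OD inference, is under test. All
randomness is keyed on (seed, plate, row, column), so a measurement is a
pure function of its coordinates and runs are bit-reproducible.

**Layout.** Rows B–G × 12 columns carry 72 cultures; rows A and H are
media blanks with water in the corner wells (evaporation guard). Blanks
carry no dose and contribute a fixed background. Well-position
(edge/corner) effects are *not* modelled; layout randomization is
supported but the default layout sorts replicates for readability.

**What the twin does not emulate** — and hence what passing tests do not
show about real data: mechanistic induction/transport kinetics, plate
position and evaporation effects, pipetting error, non-Gaussian outliers
(dropped tips, contamination), day-scale batch effects beyond the plate
walk, and any coupling between growth rate and fluorescence yield beyond
the burden factor.

## Surrogate

`sklearn.gaussian_process.GaussianProcessRegressor` with
$k = \sigma_f^2\,\mathrm{RBF}_{\ell}(x, e, p) + \sigma_n^2\,\delta$,
targets standardized internally (`normalize_y`), one length scale per
axis. Defaults:

| parameter | default | bounds | why |
|---|---|---|---|
| dose length scales | 10 | (1, 15) | response features have the width of the Hill constant (~5–10 fraction units); see below |
| plate length scale | 1.5 plates | (0.3, 10) | correlates consecutive plates ~0.8, plates two apart ~0.4 — recency weighting |
| signal variance | 1 | (1e-3, 1e3) | standardized targets |
| noise variance | 0.1 | (1e-8, 10) | learned; replicate scatter identifies it |

Hyperparameters are re-optimized at each true fit (L-BFGS, 5 seeded
restarts) and frozen during constant-liar refits within a batch, for
determinism and speed. Plate index enters as a raw coordinate 1, 2, 3, …

The dose-axis length-scale *upper bound* matters more than its initial
value. The objective is the sum of a broad linear cost trend and a narrow
response peak; a single stationary RBF cannot represent both, and the
marginal likelihood, left free, settles on the trend (fitted scales of
30+, often pinned at a loose bound). The surrogate then oversmooths the
peak, and — worse — a single constant-liar pseudo-observation excavates a
crater half a domain wide, flattening expected improvement everywhere and
reducing the rest of the batch to tie-breaking noise. Capping the scale
at 15 forces the kernel to spend its capacity on structure at the
response's own width; the broad trend is still representable as a
sequence of medium-scale variations. With the cap, batch selections
concentrate around the peak as intended.

With zero configured noise variance the white term is dropped entirely
(jitter 1e-10 only), giving an interpolator for oracle comparisons.
Posterior sd from sklearn includes the learned observation-noise floor;
the acquisition functions therefore reason about new *measurements*,
which is consistent throughout.

## Batch selection

For each plate after the first, 24 distinct doses (3 replicate wells
each; the replicate count is a throughput/variance compromise, the
per-plate point count is configurable up to 72):

1. Fit the GP on all truly observed wells; set $f^\star$ = best observed
   objective, $m$ = median of all observed objectives.
2. Grid-argmax the acquisition at the next plate index (1001 points on
   [0,100] in 1-D; 101×101 in 2-D; ties broken by a seeded grid shuffle).
3. Append the winner with pseudo-target $m$ (the "constant liar"),
   refit with frozen hyperparameters, repeat. UCB's $\kappa$ (default
   2.0) is multiplied by 20 on every refit containing pseudo-points —
   later picks within a batch explore.
4. If an argmax lands within 0.5 fraction units of an earlier pick, the
   process has degenerated; the batch is completed with points at the
   last selection ± k·1.0 (k = 1, 2, …), clipped to bounds. In 2-D the
   fan runs along the inducer axis at the anchor's enzyme level. The
   event is flagged in the decision record.

The median lie is deliberately pessimistic on a skewed objective
(median ≪ best), which repels subsequent picks from already-chosen
points; the fallback guarantees a full batch regardless. EI uses the
closed form $(\mu - f^\star)\Phi(z) + \sigma\phi(z)$, degenerating to
$\max(0, \mu - f^\star)$ at $\sigma = 0$.

Random search draws 72 i.i.d. continuous uniform doses per plate — one
per well, matching the well-level hit accounting whose analytic
expectation over 4×72 wells is $288 \times 0.02 = 5.76$ (≈ 6.05 after
pipetting snap, both rounding to six).

## Loop timing

The first induced plate is dosed at its trigger with uniform random
points (no data exists); each subsequent plate is cloned at its
predecessor's trigger, grows to its own trigger, and is dosed using every
readout complete by that moment. Objective values are computed from the
fluorescence at exactly the 4 h readout. The run ends 4 h after the last
plate's induction. A fifth-plate geometry (master + 4) is available by
setting `n_induced_plates=5`; the default 4×72 matches the hit-count
accounting used throughout.

## Problem sizes

The replicate studies use 20 seeds per algorithm for the closed-loop
comparisons (the smallest set with stable means, and the size used for
the recovery metric) and 1000 replicates for the random baseline, whose
per-run cost is only a dose draw. A full 4-plate GP run takes a couple of
seconds; the complete test suite and the acceptance script each run in
about a minute and a half on one CPU.

## Known limitations

* The fallback fan is 1-D (inducer axis); a degenerate 2-D batch does not
  spread along the enzyme axis.
* The twin's noiseless optimum and the target band are coupled by
  construction; conclusions about hit *counts* transfer to real systems
  only insofar as their response curvature resembles the Hill/bell forms.
* GP fits scale cubically in observations; beyond ~10 plates × 72 wells a
  sparse or batched surrogate would be needed.
* UCB's escalated κ makes its batches strongly exploratory; with very
  small batches (< 5) this leaves little exploitation and EI is the
  better default.
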