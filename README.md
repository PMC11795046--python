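# induceopt

Closed-loop optimization of bacterial induction on a 96-well digital twin.

## The problem

Expressing a heterologous protein (here GFP as a readily measured proxy)
requires choosing how much inducer — IPTG or lactose for lac-family
promoters — to add once a culture reaches the right density. More inducer
means more product, but inducers are a real cost driver, so the interesting
optimum is the best *cost-adjusted* output, not the maximal fluorescence.
In a fed-batch-like microplate setup a second variable appears: the amount
of glucose-release enzyme, which sets the feed rate but also represses
lac induction at high glucose (catabolite repression), making that axis
unimodal.

Robotic platforms can run such dose-finding experiments autonomously:
clone a plate from the previous one, grow to a trigger density, mix and
dispense per-well induction cocktails, read OD600 and fluorescence, and —
the part that usually still needs a human — decide the next plate's doses
from the data. `induceopt` is that decision layer plus a faithful stand-in
for the wet part, so the whole test–learn loop runs on a desk: strategies
can be compared over many seeded replicates before (or instead of)
committing robot time.

## The model and the algorithm

Doses are fractions $x \in [0, 100]$ of a maximal mix volume (and $e$ for
the enzyme in the 2-D system). The objective per well is

$$f(x) = \alpha_i x + \alpha_e e + \alpha_g\,\mathrm{gfp}(x, e),$$

with $\alpha_i, \alpha_e \le 0$ the inducer/enzyme prices and
$\alpha_g > 0$ the product price. $\mathrm{gfp}$ is noisy and slow to
evaluate (hours per plate), which is exactly the setting for surrogate
optimization:

* **Surrogate** — a Gaussian process over $(x, e, p)$ where $p$ is the
  plate index. An anisotropic RBF kernel with a short plate length scale
  (default 1.5 plates) lets predictions for the next plate lean on recent
  plates and discount older ones, absorbing inter-plate drift. Replicate
  wells that disagree are ordinary duplicated inputs; the GP turns them
  into a wider posterior.
* **Acquisition** — expected improvement
  $\mathrm{EI}(x) = \mathbb{E}[\max(0, f(x) - f^\star)]$ or the upper
  confidence bound $\mathrm{UCB}(x) = \mu(x) + \kappa\sigma(x)$.
* **Batching** — plates need 24 distinct doses at once, so a constant-liar
  loop picks a grid argmax, inserts it as a pseudo-observation whose value
  is the median of all truly observed objectives, refits (hyperparameters
  frozen), and repeats; $\kappa$ is escalated $\times 20$ on the
  pseudo-augmented refits. If an argmax collapses onto an earlier pick,
  the batch is completed with points surrounding the last selection.
  The first plate, with no data, is dosed uniformly at random.
* **Baseline** — pure random search, the honest comparator.

The twin behind it simulates logistic growth from OD600 0.1 with an
induction trigger at mean OD 0.6, a Hill-type GFP response (unimodal in
the enzyme axis), multiplicative well noise, and plate-level drift that
grows with plate distance (a random walk over the plate index). A mix
"converter" reproduces the pipetting arithmetic exactly: fractions →
µL of stock → final mM / U L⁻¹ in the cultivation well.

## Worked example

Convert a dose to physical concentrations (x = 7 on the 1-D IPTG system):

```
$ induceopt convert --system 1d -x 7
component    volume µL    final conc
inducer              7      0.14 mM
enzyme               0             —
water               93             —
```

7 µL of 20 mM IPTG in a 100 µL mix, of which 20 µL enter a 200 µL well:
0.14 mM final — the lower edge of the band where the cost-adjusted optimum
lives (x in [7, 9] ⇒ 0.14–0.18 mM).

Run a two-plate random-search loop and summarise it:

```
$ induceopt run --system 1d --algorithm random --plates 2 --seed 5 --out run5
run complete: 144 induced wells in run5
hits in [7,9]: 6; best f = 44.72 at x = 10.2
$ induceopt metrics run5
algorithm          : random
induced wells      : 144
hits in [7,9]      : 6
best observed f    : 44.721 at x=10.2
plate 1: 72 wells, 4 hits, best f 44.72
plate 2: 72 wells, 2 hits, best f 35.44
```

144 wells were induced (72 per plate), 6 of them inside the target band
[7, 9] — about what uniform sampling of a 2-unit band in a 100-unit domain
should give. The best observed objective sat at x = 10.2, near but not at
the true optimum x* = 8; a GP-driven run (`--algorithm gpr-ei`) finds and
then exploits the band instead of stumbling on it. The run directory holds
`config.json`, `doses.csv`, `measurements.csv`, `decisions.jsonl` and
per-plate maps — a complete, diffable provenance record.

`induceopt replicate --n 20` repeats paired-seed runs for all three
algorithms and prints their mean hit counts.

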