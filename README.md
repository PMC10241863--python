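# vitellometrics

Tools for quantifying the mechanics of the avian vitelline membrane (VM) —
the glycoprotein envelope that encloses the yolk and mechanically supports
the early chicken blastoderm — and the embryo phenotypes that respond to it.
The VM weakens over the first two days of incubation; this package
implements the computations needed to measure that weakening from four
complementary modalities and to test its morphogenetic consequences, all
exercisable end-to-end on synthetic data with known ground truth.

## What it computes

**Yolk-puddle shape model (`vitellometrics.shape`).** A yolk resting on a
flat plate takes the shape of an axisymmetric sessile drop whose membrane
tension γ balances gravity. Along the meridian the Young–Laplace relation

    γ (κ₁ + κ₂) = p₀ − ρ g z

holds with hydrostatic interior pressure; because the membrane wraps the
yolk completely and the plate is non-adhesive, the contact angle is π. The
shape is controlled by the Bond number Bo = ρ g V^(2/3) / γ: small Bo gives
a sphere (yolk index H/D → 1), large Bo a pancake of height 2√(γ/ρg). The
*yolk index* — puddle height over maximum diameter, a standard egg-quality
measure — increases strictly with γ, so observed puddle geometry can be
inverted for membrane tension by bracketed root finding. An independent
energy-minimization solver (`vitellometrics.energy`) cross-checks the shape
solutions.

**Scale tensiometry (`vitellometrics.scale`).** A VM strip of width L
suspending a clip weight inside a balance: cutting the supporting filter
paper and then raising the holder produce event weights from which

    γ_native = |m(after_cut) − m(detached)| · g / L
    γ_max    = |m(breaking)  − m(detached)| · g / L

Event detection (cut step, rupture jump, plateau means) is automated.

**Probe indentation (`vitellometrics.probe`).** Traces from a force sensor
advancing at 0.1 mm/s are baseline-corrected, averaged to 1 Hz,
quality-controlled (early rupture, holder hits, no contact) and summarized
by the slope of the best-fitting 20-s linear window — a stiffness readout.

**Morphometrics (`vitellometrics.morphometry`).** Body-axis elongation,
posterior-neural-tube convergence and somite segmentation speeds as
least-squares slopes of landmark series; glycoprotein fibre density as the
white fraction of Otsu-binarized stain images over random ROIs.

**Synthetic data & statistics (`synthetic`, `stats`).** Deterministic
generators emit every input type with truth sidecars; group comparisons use
two-tailed t-tests (Welch by default) and one-way ANOVA, assembled into a
summary panel by `build_report`.

## Worked example

Forward model at two tensions (a ~17 mL yolk, density 1.035 g/cm³):

```console
$ vitellometrics shape forward --gamma 0.5
H = 14.339 mm, D = 44.306 mm, yolk index = 0.3236, Bo = 13.4
$ vitellometrics shape forward --gamma 0.2
H = 9.344 mm, D = 52.612 mm, yolk index = 0.1776, Bo = 33.5
```

Halving the tension visibly flattens the puddle. Inverting the model on a
day-0-like round puddle (yolk index 0.45) and a day-2-like flattened one
(yolk index 0.25):

```pycon
>>> from vitellometrics import invert_tension
>>> invert_tension(0.45, 17e-6, 1035.0)
0.9553305...
>>> invert_tension(0.25, 17e-6, 1035.0)
0.3284993...
```

Both estimates sit in the 0.1–1 N/m range, and the flattened geometry
carries about 34% of the round geometry's tension — the membrane loses
roughly 60% of its tension as the yolk index falls from 0.45 to 0.25.

The full synthetic study runs as a numbered pipeline:

```sh
python analysis/01_simulate.py --seed 0   # all modalities + truth sidecars
python analysis/02_invert_tension.py      # puddle table -> tension per sample
python analysis/03_scale_tension.py       # scale traces -> native/max tension
python analysis/04_probe_stiffness.py     # probe traces -> stiffness slopes
python analysis/05_morphometry.py         # landmarks + fibre images
python analysis/06_report.py              # summary panel + group tests
```

Stage 02, for example, prints

```
tension recovered from noisy puddle geometry (mean +/- SD vs truth):
  D0: 0.791 +/- 0.021 N/m (truth 0.800, n=20)
  D2: 0.325 +/- 0.013 N/m (truth 0.320, n=20)
tension retained D0 -> D2: 41.1% (all estimates within the 0.1-1 N/m order of magnitude: True)
```

i.e. with 0.3 mm of measurement noise on puddle height and diameter, the
inversion recovers the generating tensions and their ~40% day-2/day-0 ratio.

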