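# dimerdeer

Pulsed-EPR analysis of ligand occupancy and binding-site geometry in
homodimeric enzymes.

Obligate homodimers such as pyrrolysyl-tRNA synthetase (PylRS) can carry a
substrate in the catalytic pocket of each monomer — and, as it turns out,
in secondary "waiting" sites at the dimer interface.  When the ligand is a
nitroxide-labelled amino acid, EPR sees all of it: DEER (double
electron–electron resonance) measures the distance between two bound
ligands, the modulation depth counts how many dimers carry a spin *pair*,
and room-temperature CW spectra separate free from rigidly bound ligand.
`dimerdeer` implements that entire inference chain as a tested Python
library, together with a synthetic-data generator that emulates the in
vitro and in-cell experiments for validation.

## The models

**Forward model.** For an inter-spin distance distribution P(r) the DEER
signal is

    V(t) = [(1 − Δ) + Δ ∫ K(t, r) P(r) dr] · exp(−k t),

with the orientation-averaged Pake kernel
K(t, r) = ∫₀¹ cos[(3x² − 1) ω(r) t] dx, ω(r) = 2π·D/r³ and
D = 52.04 MHz·nm³.  Recovering P(r) from V(t) is ill-posed; it is solved
by Tikhonov-regularized non-negative least squares,

    min_{p ≥ 0} ‖K p − f‖² + α²‖L p‖²,

with L the second-difference operator, α chosen by generalized
cross-validation, and uncertainty from a residual bootstrap.  The longest
trustworthy distance scales with the recorded evolution time as
r_max = 3.494 · t_max^{1/3} nm.

**Occupancy counting.** With pump inversion efficiency λ, the modulation
depth is Δ = λ·q where q = 2f₂/(f₁ + 2f₂) is the fraction of bound spins
whose dimer holds a second spin, and the bound-spin signal is
m = f₁ + 2f₂.  Inverting (Δ, m) yields the fractions (f₀, f₁, f₂) of
empty, singly and doubly occupied dimers, which are tested against the
random-binding (binomial) null f₂ = (m/2)² by a multinomial bootstrap.

**CW unmixing.** Free and bound ligand templates (three sharp Lorentzian
lines vs a broad powder pattern), each normalized to unit absorption
double integral, are fit to the measured derivative spectrum by
non-negative least squares; the weights are then spin-count fractions.

**Pairing hypotheses.** The four-site dimer geometry (catalytic a1/b1,
secondary a2/b2) predicts a distance per site pairing — 4.1 nm for both
catalytic sites, 3.0 nm within one monomer, 2.5 nm for the cross pairing
(catalytic + opposite secondary).  Hypotheses are scored against the
recovered P(r) by the overlap coefficient below the reliability limit.

## Worked example

`examples/05_hypothesis_discrimination.py` runs the full chain on a
synthetic in vitro scenario (20 000 dimers, 70/21/9 occupancy split,
cross-pairing geometry, SNR 50):

```
recovered peak: 2.500 nm, reliable up to 4.4 nm
hypothesis ranking (overlap with recovered P(r)):
  cross            score = 0.873  -> consistent
  intra-monomer    score = 0.058  -> excluded
  both-catalytic   score = 0.000  -> excluded
occupancy: f0/f1/f2 = 0.70/0.21/0.09, cooperativity: cooperative
CW free-ligand fraction: 0.090
```

The recovered 2.5 nm peak matches only the cross pairing: one ligand in a
catalytic site, the second in the secondary site of the *other* monomer.
The 9% doubly occupied dimers exceed the binomial expectation of 3.8% at
the same mean load (ratio 2.37, CI excluding 1), so the second binding
event is promoted by the first.  The other examples demonstrate forward
simulation, inversion with uncertainty, occupancy algebra and CW
unmixing individually; each prints the numbers it computes and what they
mean.

A thin CLI wraps the same functions:

```sh
dimerdeer synthesize --preset invitro --out scenario/
dimerdeer run --scenario scenario/ --out report.json
dimerdeer invert --trace scenario/trace.dat --out result
```

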