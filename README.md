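# g4condense

Quantitative analysis of G-quadruplex (G4)-dependent transcription-factor
condensation, for researchers studying how promoter G4 structures modulate
transcription-factor binding and phase separation. The package implements,
as a tested and reusable pipeline, the five quantitative procedures such a
study chains together — each exercised against synthetic data with known
ground truth:

- **Promoter enrichment** (`g4condense.enrichment`) — per-promoter ChIP
  signal in −1000/+500 bp TSS windows, ranked and min-max scaled; a
  threshold placed where a slope-1 tangent touches the convex scaled curve
  (the sample minimising `y_i − x_i`); binding densities
  `count_i / Σ(retained counts)`; and a second tangent pass on the density
  curve to call the enriched promoter set.
- **G4 motif scoring** (`g4condense.gquad`) — enumeration of
  `G_x N_y1 G_x N_y2 G_x N_y3 G_x` candidates (four equal G-tracts, window
  ≤ 30 nt) and an integer G-score
  `24(x−2) + 2(12−Σy) − (max y − min y)` rewarding more tetrads, shorter
  loops, and even loop partitions; candidates with score > 35 are flagged
  stable.
- **Binding kinetics** (`g4condense.kinetics`) — EMSA binding fractions
  `[1 − free/total]×100` fitted to the Hill equation
  `B = B_max·X^h/(K_D^h + X^h)`; BLI sensorgrams fitted with the 1:1 chain
  `Y = Y0 + A(1−e^(−k_obs t))`, `k_a = (k_obs − k_d)/[analyte]`,
  `K_D = k_d/k_a`; and a sequential two-step binding ODE model
  (`G4 + P ⇌ G4P`, `G4P + P ⇌ G4P₂`, response `R1·[G4P] + R2·[G4P₂]`)
  fitted globally across analyte concentrations.
- **FRAP analysis** (`g4condense.frap`) — background/reference correction
  and pre-bleach normalization of three-channel recovery traces, then a
  double-exponential fit reporting the dominant-component tau and the
  amplitude-weighted tau.
- **Condensate quantification** (`g4condense.droplets`) — ImageJ-style
  particle analysis: fixed intensity threshold, 8-connected components,
  area and circularity (`4π·area/perimeter²`, 0.3–1.0) filters, aggregate
  area/size/count statistics, and a rule-based condensed/dilute call for
  phase diagrams.
- **Synthetic data** (`g4condense.synthetic`) — seeded generators for every
  input above, each emitting a `SimTruth` record with the generating
  parameters and truth labels; noiseless output reproduces the closed
  forms exactly.

See `docs/methods.md` for models, assumptions, and numerical choices.

## Worked example

```python
import numpy as np
from g4condense import synthetic as syn, kinetics as kin, frap, gquad

# EMSA: generate a cooperative binding curve (K_D 19.1 nM, h 4.42, 2% noise)
# and refit it
curve, truth = syn.gen_hill_curve(19.1e-9, 4.42, 1.0,
                                  np.geomspace(1e-9, 500e-9, 12),
                                  noise_sd=0.02, seed=42)
fit = kin.fit_hill(curve)
print(f"K_D = {fit.K_D*1e9:.1f} nM, h = {fit.h:.2f}, B_max = {fit.B_max:.2f}")

# FRAP: three-channel trace with a dominant 42.4 s recovery component
trace, _ = syn.gen_frap_trace(tau1=42.4, A1=0.5, tau2=5.0, A2=0.1,
                              bleach_depth=0.7, noise_sd=0.01, seed=3)
corrected, ffit = frap.analyze_frap(trace)
print(f"tau_dominant = {ffit.tau_dominant:.1f} s, "
      f"tau_weighted = {ffit.tau_weighted:.1f} s, plateau = {ffit.plateau:.2f}")

# G4 scoring: the best quadruplex candidate in a G-rich probe
best, score = gquad.max_gscore("TTAGGGAGGGTGGGAGGGTT")
print(f"best candidate at {best.start}, tracts of {best.tract_length} G, "
      f"loops {best.loop_lengths}, G-score {score}, "
      f"stable: {gquad.classify_stable(score)}")
```

prints

```
K_D = 19.5 nM, h = 4.85, B_max = 0.99
tau_dominant = 45.7 s, tau_weighted = 37.5 s, plateau = 0.91
best candidate at 3, tracts of 3 G, loops (1, 1, 1), G-score 42, stable: True
```

The Hill fit recovers the generating constants to within the noise (a 2%
intensity noise moves the apparent K_D by ~2% and h by ~10% at this design);
the FRAP fit identifies the dominant exchange timescale from the corrected
trace; the G4 scan finds the three-tetrad candidate with 1-nt loops and
calls it stable. With `noise_sd=0` all fitted values match the generating
parameters to numerical precision.

A `g4condense` console script exposes the same operations
(`simulate`, `enrich`, `g4score`, `fit-kinetics`, `fit-frap`, `droplets`);
run `g4condense --help`.

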