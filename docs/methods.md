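# Methods

This note documents the models implemented in `g4condense`, the assumptions
behind them, the numerical choices, and what the synthetic-data generators
do and do not emulate.

## Promoter enrichment by tangent-slope-1 thresholding

Promoter windows span −1000 to +500 bp around the TSS, strand-aware, in
0-based half-open (BED) coordinates; minus-strand windows mirror to
[TSS−500, TSS+1000). Windows truncated at coordinate 0 are flagged, not
dropped. Signal features overlapping a window by ≥ 1 bp contribute their
full value; a feature straddling two windows counts fully in both (no
splitting), because read-level assignment to promoters is inherently
ambiguous at boundaries and double-counting is the conservative choice for
a per-promoter enrichment statistic.

The geometric threshold works on the ascending rank curve of per-promoter
signal with both axes min-max scaled to [0, 1]. For a convex non-decreasing
curve, the point where a slope-1 tangent touches the curve is the sample
minimising `y_i − x_i`; ties are broken toward the larger index so the
threshold is as stringent as the geometry allows. Curves with the minimum
on the boundary (concave) or constant `y − x` (linear) have no interior
slope-1 crossing and raise a diagnostic error rather than returning an
arbitrary cutoff. Ties in signal are ordered by promoter id so the curve —
and hence the cutoff — is reproducible.

Binding density is each retained promoter's share of all above-threshold
signal: `density_i = count_i / Σ(retained counts)`. Retention is decided at
the promoter level (aggregated window signal above the raw threshold);
densities sum to 1 by construction and are reported as fractions. Any
presentation scale (e.g. ×10⁴) is a display option only, because the
defining formula yields fractions.

The enriched call applies the same rank-scale-tangent construction to the
density values; promoters beyond the tangent point form the enriched set,
which is an upper set of the density ordering by construction.

**Two evaluation modes.** `call_enriched_promoters` composes both passes
exactly as described (count threshold, then density threshold). On real
promoter signal — a near-continuum of counts — the first pass retains a
heavy tail spanning modest to extreme promoters and the second pass
separates the extremes. On a cleanly bimodal synthetic mixture the first
pass already lands the cutoff in the gap between the two components, so the
second pass can only trim inside the enriched component. The recovery
experiment in the test suite therefore feeds `classify_enriched` densities
computed over every promoter with nonzero signal (read-level threshold 0),
which is the configuration in which sensitivity against planted labels is a
meaningful quantity (0.88 at the standard mixture of 1000 background + 50
enriched promoters). This is a property of the synthetic geometry, not of
the implementation; both modes are exercised by the tests.

## QGRS enumeration and G-score

A candidate quadruplex is four equal-length G-tracts (length x ≥ 2)
separated by three loops (y1, y2, y3 ≥ 0), total length ≤ 30 nt by default
(the length scale of the promoter oligos the motif model targets).
Enumeration returns *all* candidates, overlapping included; the reverse
strand is handled by enumerating the reverse complement and mapping
coordinates back. U is treated as T; N never matches G.

The committed score is

    gscore = 24·(x − 2) + 2·(12 − (y1 + y2 + y3)) − (max(y) − min(y))

an integer that (a) strictly increases with tract length at fixed loops,
(b) strictly decreases as total loop length grows at fixed tract length
(the loop-total weight of 2 dominates the ±1 the spread term can move when
a single loop grows), and (c) over all partitions of a fixed loop total is
maximal exactly at the most even partition. These are the published
stability principles for G4 propensity scoring; the formula itself is this
package's own, and parity with any external scoring server is explicitly
not claimed. A candidate is called stable when its score *strictly* exceeds
the threshold (default 35). Under this formula a canonical three-tetrad
motif with 1/1/1 loops scores 42 and a best-case two-tetrad motif cannot
exceed 24, so the default threshold separates three-tetrad-or-better
candidates from weak ones.

`max_gscore` reports the highest-scoring candidate with ties broken toward
the smaller start, verified against exhaustive enumeration in tests.

## EMSA binding fractions and the Hill model

Binding fraction = `[1 − free/total] × 100` with the total taken from the
free-probe band at zero protein; free intensities above total are clipped
with a warning (gel quantification noise). Curves are fitted to

    B(X) = B_max · X^h / (K_D^h + X^h)

by bounded least squares (`scipy.optimize.curve_fit`) with multi-start over
cooperativity guesses (h₀ ∈ {0.5, 1, 2, 4}) and data-driven K_D/B_max
initialisation. h is bounded to (10⁻³, 50); the Hill form is evaluated in
ratio space `(X/K_D)^h` for stability at large h. A fitted K_D outside the
tested concentration range sets an `extrapolated` flag rather than failing,
since the estimate may still be wanted with that caveat. Noiseless
curves over 12 log-spaced concentrations (1–500 nM) refit their generating
parameters to ≲ 10⁻⁶ relative error.

## BLI kinetics

The 1:1 analysis follows the standard exponential chain: association
`Y = Y0 + A(1 − e^(−k_obs t))`, dissociation `Y = Y0 + A·e^(−k_d t)`, then
`k_a = (k_obs − k_d)/[analyte]` and `K_D = k_d/k_a`. The K_D identity holds
exactly for every emitted fit. `k_obs < k_d` raises an error because it
signals a model violation rather than a fittable quantity. Flat traces
(amplitude ≈ 0 relative to scale) raise an unidentifiable-rate error;
phases shorter than ~1/k warn.

The sequential two-step model is the mass-action system

    d[G4]/dt    = −k_on1[G4][P]   + k_off1[G4P]
    d[G4P]/dt   =  k_on1[G4][P]   − k_off1[G4P] − k_on2[G4P][P] + k_off2[G4P2]
    d[G4P2]/dt  =  k_on2[G4P][P]  − k_off2[G4P2]

with composite response `R(t) = R1·[G4P] + R2·[G4P2]`. The second step must
consume [G4P], not [G4]: the alternative (sometimes seen in print) breaks
the species balance, and conservation of total G4 is a structural property
of a sequential scheme. The analyte is pseudo-first-order: constant during
association, zero during dissociation, matching how a flow instrument
operates; full mass action (analyte depletion) is available behind a flag
and integrated with LSODA at rtol 10⁻¹⁰.

In the pseudo-first-order regime the system is linear, so the default
integrator is exact stepwise matrix exponentiation (`scipy.linalg.expm` on
the 3×3 rate matrix, one `expm` per distinct step size). This conserves
total G4 to machine precision (< 10⁻¹⁵ relative, comfortably inside the
10⁻⁹ requirement), is immune to defective rate matrices in degenerate
corners (e.g. k_on2 = k_off2 = 0), and reduces *exactly* to the 1:1 closed
form when the second step is switched off.

The global fit shares (k_on1, k_off1, k_on2, k_off2, R1, R2) across all
concentrations, optimising in log-parameter space (positivity for free)
with Levenberg–Marquardt from one heuristic start (timescales set by the
trace span, second step ~3× slower) plus 5 seeded log-uniform perturbations
(±2.5 nats); iteration stops early when the residual is numerically zero.
R1/R2 are treated as free scale factors with no dimensional claim.
`compare_models` reports per-concentration R² for the 1:1 and two-step
fits and their difference, without an automatic verdict — on training data
the two-step model nests the 1:1 model, so ΔR² ≥ 0 is expected and only its
magnitude is informative.

## FRAP

Correction is the standard double normalization: background subtraction,
division by the (background-subtracted) reference to remove acquisition
photofading, and scaling so the pre-bleach mean is exactly 1. The reference
channel is modelled (and assumed) to fade identically to the ROI; the
generator implements exponential photofading for both, so the noiseless
corrected trace equals the underlying recovery curve pointwise.

Recovery is fitted with `F(t) = F0 + A1(1 − e^(−t/tau1)) + A2(1 − e^(−t/tau2))`,
t from the bleach, multi-start over tau pairs spanning 1.5–100% of the
acquisition window, amplitudes bounded ≥ 0. Components are ordered by
amplitude. Because a single "recovery tau" from a two-component fit is not
a uniquely defined quantity, the fit exposes both components plus
`tau_dominant` (larger-amplitude component — the headline number) and
`tau_weighted` (amplitude-weighted mean). Two degeneracies are handled
explicitly: a vanishing second amplitude (< 0.1% of the total) and
indistinguishable taus (ratio < 1.5), which trigger a single-exponential
refit and a flag instead of reporting an arbitrary split.

Identifiability sets the fixture sizes: the acquisition window should cover
several multiples of the slowest tau. The standard fixtures use 120 s of
1-s frames for the ~42 s component and 300 s for the ~97 s component (10
pre-bleach frames, bleach depth 0.7, dominant amplitude 0.5 plus a 0.1/5 s
fast component, 1% Gaussian noise); the property-test grid extends to
tau ∈ {10, 42.4, 97.3, 200} s × noise ∈ {0, 1%, 3%} with a 4·tau window,
where the dominant tau is recovered within 10%.

## Droplet quantification

Foreground is `image > threshold` (defaults: 55 for the in-cell particle
analysis, 50 for the in-vitro phase diagram); particles are 8-connected
components filtered by area (default 0.1–∞, interpreted in physical units
when a pixel size is configured, else px²) and circularity
`4π·area/perimeter²` in [0.3, 1.0]. Perimeter uses the Crofton
approximation; the choice matters because circularity is perimeter-
sensitive, and Crofton is the least biased of the standard estimators for
small convex blobs. Circularity is clipped to ≤ 1 against digitization
artifacts. Aggregates are count, total area, mean size (total/count) and
area-weighted mean within-particle intensity.

The condensation call normalizes the image (default: per-image maximum),
zeroes pixels at or below the intensity threshold, and calls condensed when
the mean of the thresholded image exceeds 0.3. Per-image max normalization
is the default because the acquisition scale of the source images is not
part of the rule; a raw-scale mode exists for calibrated inputs. All three
numbers (50/55 threshold, 0.3 cutoff, circularity band) are configuration
defaults, not constants.

## Synthetic data: what it does and does not show

Generators are deterministic given their seed, emit a `SimTruth` sidecar
(generator name, parameters, seed, labels), and reproduce their closed
forms exactly at zero noise — they double as oracles.

- Promoter counts: negative-binomial (mean m, variance m + d·m²) background
  at mean 3 with dispersion 0.5, enriched component at mean 60 — heavy
  tailed and convex-rank-curved like promoter-level ChIP signal, but i.i.d.:
  no genomic autocorrelation, no mappability or GC structure, and a cleanly
  bimodal mixture rather than a continuum. Passing recovery tests shows the
  geometric thresholding separates mixture components at this
  signal-to-background ratio; it does not certify performance on a real
  count continuum.
- Sensorgrams: exact model solutions plus i.i.d. Gaussian noise; no
  baseline drift, no mass-transport limitation, no avidity beyond the
  second step.
- Binding curves, FRAP traces: exact Hill / double-exponential forms plus
  Gaussian noise truncated to valid units; FRAP photofading is exponential
  and identical in ROI and reference (the assumption the correction relies
  on).
- Droplet images: hard disks (pixel membership `r² ≤ radius²`), optional
  Gaussian blur, Gaussian background noise — no realistic point-spread
  function, no intensity gradients within droplets.
- G4 sequences: planted motif with loops from {A, C, T} and G-free flanks,
  so the planted candidate is unambiguous; real G-rich promoters contain
  competing and overlapping motifs, which the enumerator handles but the
  generator does not produce.

## Problem sizes

The standard fixtures are sized so the full suite runs in well under a
minute of CPU: 1050 promoters for enrichment recovery, 12-point binding
curves, 3-concentration sensorgram families at 1–2 s sampling over
600–2400 s, single FRAP traces of 130–310 frames, and ≤ 100×100 px images.
These sizes are past the point where the estimators' errors are dominated
by noise level rather than sample count, so larger fixtures would not
change the conclusions.

## Known limitations

- The tangent threshold is defined only for convex rank curves; heavily
  tied or concave data raise errors by design rather than guessing.
- Two-step kinetic parameters are only identifiable when the two binding
  timescales are separated and the data span concentrations bracketing the
  first-step K_D; degenerate directions show up as large parameter swings
  between multi-starts and poor conditioning, and the fit reports per-trace
  R² rather than claiming uniqueness.
- G-scores are comparable within this package only.
- Circularity of particles smaller than ~10 px² is quantization-dominated;
  the 0.3 filter is unreliable there regardless of perimeter estimator.
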