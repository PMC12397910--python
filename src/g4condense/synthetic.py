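"""Synthetic-data generators with known ground truth for every pipeline input.

Each generator is deterministic given its seed and returns the dataset
together with a :class:`SimTruth` record holding the generating parameters
and per-record truth labels.  Noiseless settings reproduce the underlying
closed forms pointwise, so the generators double as oracles for the
analysis modules.

What is emulated (and what is not): promoter read counts come from a
negative-binomial background plus a shifted enriched component — heavy
tailed like ChIP-seq promoter signal, but with no genomic correlation
structure; sensorgrams are exact model solutions plus Gaussian noise (no
drift or mass-transport artifacts); droplet images are blurred disks on
Gaussian-noise background (no realistic point-spread function).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .enrichment import ReadCountTable
from .errors import InvalidParameterError
from .frap import FrapTrace
from .kinetics import Sensorgram, BindingCurve, hill_model, simulate_two_step


@dataclass
class SimTruth:
    """Provenance of one synthetic dataset: generator, parameters, seed,
    and per-record ground-truth labels."""

    generator_name: str
    params: dict
    seed: int
    labels: dict = field(default_factory=dict)

    def to_json(self, path):
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.integer, np.floating)):
                return v.item()
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            return v
        with open(path, "w") as fh:
            json.dump({"generator_name": self.generator_name,
                       "params": _clean(self.params), "seed": self.seed,
                       "labels": _clean(self.labels)}, fh, indent=2)


def _nb_counts(rng, n, mean, dispersion):
    """Negative-binomial draws parametrized by mean and dispersion
    (variance = mean + dispersion * mean**2)."""
    if dispersion <= 0:
        raise InvalidParameterError("dispersion must be positive")
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def gen_promoter_counts(n_background: int, n_enriched: int,
                        background_scale: float = 3.0,
                        enriched_scale: float = 60.0,
                        dispersion: float = 0.5,
                        seed: int = 0) -> tuple[ReadCountTable, SimTruth]:
    """Heavy-tailed background + shifted enriched promoter count mixture.

    Counts are negative-binomial with the given means; enriched promoters
    use the larger ``enriched_scale`` mean.  Truth labels mark which
    promoters are enriched.
    """
    if n_background < 0 or n_enriched < 0 or n_background + n_enriched < 1:
        raise InvalidParameterError("need at least one promoter")
    if background_scale <= 0 or enriched_scale <= 0:
        raise InvalidParameterError("scales must be positive")
    if n_background > 0 and enriched_scale <= background_scale:
        raise InvalidParameterError("enriched_scale must exceed background_scale")
    rng = np.random.default_rng(seed)
    bg = _nb_counts(rng, n_background, background_scale, dispersion)
    en = _nb_counts(rng, n_enriched, enriched_scale, dispersion)
    counts = np.concatenate([bg, en]).astype(float)
    ids = ([f"bg_{i:05d}" for i in range(n_background)]
           + [f"enr_{i:05d}" for i in range(n_enriched)])
    labels = np.array([False] * n_background + [True] * n_enriched)
    table = ReadCountTable(promoter_ids=ids, counts=counts,
                           truth_labels=labels)
    truth = SimTruth("gen_promoter_counts",
                     {"n_background": n_background, "n_enriched": n_enriched,
                      "background_scale": background_scale,
                      "enriched_scale": enriched_scale,
                      "dispersion": dispersion},
                     seed, {"enriched": {i: bool(l)
                                         for i, l in zip(ids, labels)}})
    return table, truth


def gen_sensorgram(model: str, params: dict, analyte_concentrations,
                   t_assoc: float = 300.0, t_dissoc: float = 300.0,
                   dt: float = 1.0, noise_sd: float = 0.0,
                   seed: int = 0) -> tuple[list[Sensorgram], SimTruth]:
    """BLI-style sensorgrams from the 1:1 or two-step model, plus noise.

    ``model="one_to_one"`` expects params ``k_a`` (1/M/s), ``k_d`` (1/s) and
    optionally ``g4_0``/``R1`` (defaults 1.0); the association phase follows
    ``R1*g4_0*C/(C+K_D) * (1 - exp(-(k_a*C + k_d)*t))`` and the dissociation
    phase decays with ``k_d``.  ``model="two_step"`` expects ``k_on1``,
    ``k_off1``, ``k_on2``, ``k_off2``, ``R1``, ``R2`` and optional ``g4_0``;
    both phases are the exact mass-action solution with the analyte constant
    during association and zero afterwards.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    concs = list(analyte_concentrations)
    if any(c <= 0 for c in concs):
        raise InvalidParameterError("analyte concentrations must be positive")
    if model not in ("one_to_one", "two_step"):
        raise InvalidParameterError(f"unknown model {model!r}")
    for k, v in params.items():
        if k.startswith("k_") and v < 0:
            raise InvalidParameterError(f"rate {k} must be >= 0")

    rng = np.random.default_rng(seed)
    t_a = np.arange(0.0, t_assoc + dt / 2, dt)
    t_d = t_assoc + np.arange(dt, t_dissoc + dt / 2, dt)
    times = np.concatenate([t_a, t_d])
    phases = np.array(["association"] * t_a.size
                      + ["dissociation"] * t_d.size, dtype=object)

    traces = []
    for conc in concs:
        if model == "one_to_one":
            k_a, k_d = params["k_a"], params["k_d"]
            g4_0 = params.get("g4_0", 1.0)
            r1 = params.get("R1", 1.0)
            resp = simulate_two_step(k_a, k_d, 0.0, 0.0, r1, 0.0,
                                     g4_0, conc, times,
                                     t_assoc=t_assoc).response
        else:
            resp = simulate_two_step(
                params["k_on1"], params["k_off1"], params["k_on2"],
                params["k_off2"], params["R1"], params["R2"],
                params.get("g4_0", 1.0), conc, times,
                t_assoc=t_assoc).response
        noisy = resp + rng.normal(0.0, noise_sd, size=resp.size) \
            if noise_sd > 0 else resp
        traces.append(Sensorgram(time=times.copy(), response=noisy,
                                 phase=phases.copy(),
                                 analyte_concentration=conc))
    truth = SimTruth("gen_sensorgram",
                     {"model": model, **params,
                      "analyte_concentrations": concs, "t_assoc": t_assoc,
                      "t_dissoc": t_dissoc, "dt": dt, "noise_sd": noise_sd},
                     seed)
    return traces, truth


def gen_hill_curve(K_D: float, h: float, B_max: float, concentrations,
                   n_replicates: int = 1, noise_sd: float = 0.0,
                   seed: int = 0) -> tuple[BindingCurve, SimTruth]:
    """Hill-shaped binding-fraction curve with optional replicate noise.

    Fractions are ``B_max * X**h / (K_D**h + X**h) + noise``, truncated to
    [0, B_max] when B_max <= 1 (fraction units) or [0, 100] (percent).
    """
    if K_D <= 0 or h <= 0 or B_max <= 0:
        raise InvalidParameterError("K_D, h and B_max must be positive")
    concs = np.asarray(list(concentrations), dtype=float)
    if concs.size == 0:
        raise InvalidParameterError("empty concentration list")
    rng = np.random.default_rng(seed)
    X = np.tile(concs, n_replicates)
    rep = np.repeat(np.arange(n_replicates), concs.size)
    y = hill_model(X, K_D, h, B_max)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    ceiling = 100.0 if B_max > 1.0 else max(B_max, 1.0)
    y = np.clip(y, 0.0, ceiling)
    units = "percent" if B_max > 1.0 else "fraction"
    curve = BindingCurve(concentrations=X, fractions=y, replicate=rep,
                         units=units)
    truth = SimTruth("gen_hill_curve",
                     {"K_D": K_D, "h": h, "B_max": B_max,
                      "concentrations": concs, "n_replicates": n_replicates,
                      "noise_sd": noise_sd}, seed)
    return curve, truth


def gen_frap_trace(tau1: float = 42.4, A1: float = 0.5, tau2: float = 5.0,
                   A2: float = 0.1, bleach_depth: float = 0.7,
                   pre_bleach_n: int = 10, t_max: float = 120.0,
                   dt: float = 1.0, bg_level: float = 0.0,
                   ref_drift: float = 0.0, noise_sd: float = 0.0,
                   seed: int = 0) -> tuple[FrapTrace, SimTruth]:
    """Three-channel FRAP trace with double-exponential recovery.

    The true normalized signal is 1 before the bleach and
    ``(1 - bleach_depth) + A1*(1 - exp(-t/tau1)) + A2*(1 - exp(-t/tau2))``
    after it.  The reference channel photofades exponentially at
    ``ref_drift`` per second; the ROI channel fades identically (so the
    reference correction removes it); the background channel is constant.
    Gaussian noise of ``noise_sd`` is added to every channel.
    """
    if tau1 <= 0 or tau2 <= 0:
        raise InvalidParameterError("taus must be positive")
    if not (0 < bleach_depth <= 1):
        raise InvalidParameterError("bleach_depth must be in (0, 1]")
    if A1 < 0 or A2 < 0 or A1 + A2 > bleach_depth:
        raise InvalidParameterError("amplitudes must satisfy A1 + A2 <= bleach_depth")
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if pre_bleach_n < 1:
        raise InvalidParameterError("need at least one pre-bleach sample")

    rng = np.random.default_rng(seed)
    t_pre = np.arange(-pre_bleach_n, 0) * dt
    t_post = np.arange(0.0, t_max + dt / 2, dt)
    time = np.concatenate([t_pre, t_post])

    signal = np.ones(time.size)
    post = time >= 0
    tp = time[post]
    signal[post] = ((1.0 - bleach_depth)
                    + A1 * (1.0 - np.exp(-tp / tau1))
                    + A2 * (1.0 - np.exp(-tp / tau2)))
    fade = np.exp(-ref_drift * (time - time[0]))
    roi = bg_level + signal * fade
    ref = bg_level + fade
    bg = np.full(time.size, float(bg_level))
    if noise_sd > 0:
        roi = roi + rng.normal(0, noise_sd, time.size)
        ref = ref + rng.normal(0, noise_sd, time.size)
        bg = bg + rng.normal(0, noise_sd, time.size)

    trace = FrapTrace(time=time, roi=roi, reference=ref, background=bg,
                      bleach_index=pre_bleach_n)
    truth = SimTruth("gen_frap_trace",
                     {"tau1": tau1, "A1": A1, "tau2": tau2, "A2": A2,
                      "bleach_depth": bleach_depth,
                      "pre_bleach_n": pre_bleach_n, "t_max": t_max,
                      "dt": dt, "bg_level": bg_level,
                      "ref_drift": ref_drift, "noise_sd": noise_sd}, seed)
    return trace, truth


def gen_droplet_image(width: int = 256, height: int = 256, droplets=(),
                      background_level: float = 10.0, noise_sd: float = 2.0,
                      blur_sigma: float = 0.0,
                      seed: int = 0) -> tuple[np.ndarray, SimTruth]:
    """Disk-like condensates on noisy background.

    ``droplets`` is a list of ``((row, col), radius_px, peak_intensity)``.
    Disks must fit the canvas; overlapping disks are allowed but flagged in
    the truth record.  ``blur_sigma > 0`` applies a Gaussian blur to the
    disks before noise is added.
    """
    from skimage import filters

    img = np.zeros((height, width), dtype=float)
    rr, cc = np.mgrid[0:height, 0:width]
    overlap = False
    for i, (center, radius, peak) in enumerate(droplets):
        r0, c0 = center
        if radius <= 0:
            raise InvalidParameterError("radius must be positive")
        if not (radius <= r0 <= height - 1 - radius
                and radius <= c0 <= width - 1 - radius):
            raise InvalidParameterError(
                f"droplet {i} at {center} r={radius} exceeds the canvas")
        disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
        if np.any(img[disk] > 0):
            overlap = True
        img[disk] = np.maximum(img[disk], peak)
    if blur_sigma > 0:
        img = filters.gaussian(img, sigma=blur_sigma, preserve_range=True)
    img = img + background_level
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    truth = SimTruth("gen_droplet_image",
                     {"width": width, "height": height,
                      "background_level": background_level,
                      "noise_sd": noise_sd, "blur_sigma": blur_sigma},
                     seed,
                     {"droplets": [{"center": list(c), "radius": r,
                                    "peak": p} for c, r, p in droplets],
                      "overlapping": overlap})
    return img, truth


def gen_g4_sequence(n_tetrads: int = 4, tract_length: int = 3,
                    loop_lengths=(1, 1, 1), flank_length: int = 10,
                    gc_background: float = 0.4,
                    seed: int = 0) -> tuple[str, SimTruth]:
    """A G-rich sequence with a planted quadruplex motif.

    Builds ``flank + (G-tract + loop) * (n-1) + G-tract + flank`` with loops
    drawn from {A, C, T} (so no loop can extend a G-tract) and flanks drawn
    from an A/C/G/T alphabet at ``gc_background`` GC content with G excluded
    to keep the planted motif unambiguous.
    """
    if n_tetrads < 2 or tract_length < 2:
        raise InvalidParameterError("need >= 2 tetrads of length >= 2")
    loops = list(loop_lengths)
    if len(loops) != n_tetrads - 1:
        raise InvalidParameterError("need n_tetrads - 1 loop lengths")
    if any(l < 0 for l in loops):
        raise InvalidParameterError("loop lengths must be >= 0")
    if gc_background < 0 or gc_background > 1:
        raise InvalidParameterError("gc_background must be in [0, 1]")

    rng = np.random.default_rng(seed)
    loop_alpha = np.array(list("ACT"))
    # flanks: C carries all GC content; G excluded so flanks cannot create
    # or extend tracts
    flank_p = np.array([(1 - gc_background) / 2, gc_background,
                        (1 - gc_background) / 2])
    flank_alpha = np.array(list("ACT"))

    def flank(n):
        return "".join(rng.choice(flank_alpha, size=n, p=flank_p))

    def loop(n):
        return "".join(rng.choice(loop_alpha, size=n))

    parts = [flank(flank_length)]
    for i in range(n_tetrads):
        parts.append("G" * tract_length)
        if i < n_tetrads - 1:
            parts.append(loop(loops[i]))
    parts.append(flank(flank_length))
    seq = "".join(parts)
    motif_start = flank_length
    truth = SimTruth("gen_g4_sequence",
                     {"n_tetrads": n_tetrads, "tract_length": tract_length,
                      "loop_lengths": loops, "flank_length": flank_length,
                      "gc_background": gc_background}, seed,
                     {"motif_start": motif_start,
                      "motif_length": n_tetrads * tract_length + sum(loops)})
    return seq, truth
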