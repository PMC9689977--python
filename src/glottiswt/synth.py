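"""Synthetic sustained-vowel simulator with known glottal ground truth.

Voiced speech is modeled source-filter style: a train of
Liljencrants-Fant (LF) glottal flow-derivative pulses (which folds the
lip-radiation differentiation into the source, as usual) excites an
all-pole vocal tract built from formant center/bandwidth pairs.
Pathological voice quality is emulated by three perturbations that the
clinical literature ties to dysphonia:

* jitter    - cycle-to-cycle relative perturbation of the period,
* shimmer   - cycle-to-cycle relative perturbation of the pulse amplitude,
* aspiration noise - white Gaussian noise injected at the source and
  calibrated so the rendered signal reaches a target harmonics-to-noise
  ratio (HNR, dB),

plus an optional slow F0 tremor.  Every rendered recording carries its
ground-truth glottal flow and flow derivative (pre-tract, pre-noise), so
inverse-filtering accuracy can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter, resample_poly

from .errors import ConfigError, ParameterError, StabilityError
from .iaif import GlottalSignal
from .preprocess import Recording

DEFAULT_FS_HZ = 22050

#: Formants of a generic adult /a/ — (center Hz, bandwidth Hz).
VOWEL_A_FORMANTS = ((730.0, 90.0), (1090.0, 110.0), (2440.0, 150.0), (3400.0, 200.0), (4500.0, 250.0))


@dataclass(frozen=True)
class LFParams:
    """Shape parameters of one LF glottal flow-derivative pulse.

    f0_hz : fundamental frequency, 60-400 Hz
    oq : open quotient, fraction of the period before main excitation, (0,1)
    am : asymmetry, flow-peak instant as a fraction of the open phase, (0.5,1)
    ta_frac : return-phase time constant as a fraction of the period, (0,0.2)
    ee : magnitude of the negative peak of the flow derivative, > 0
    """

    f0_hz: float = 140.0
    oq: float = 0.6
    am: float = 0.78
    ta_frac: float = 0.028
    ee: float = 1.0

    def __post_init__(self) -> None:
        if not 60.0 <= self.f0_hz <= 400.0:
            raise ParameterError(f"f0_hz must lie in [60, 400], got {self.f0_hz}")
        if not 0.0 < self.oq < 1.0:
            raise ParameterError(f"oq must lie in (0, 1), got {self.oq}")
        if not 0.5 < self.am < 1.0:
            raise ParameterError(f"am must lie in (0.5, 1), got {self.am}")
        if not 0.0 < self.ta_frac < 0.2:
            raise ParameterError(f"ta_frac must lie in (0, 0.2), got {self.ta_frac}")
        if self.ta_frac >= (1.0 - self.oq):
            raise ParameterError("return phase must fit inside the closed phase (ta_frac < 1 - oq)")
        if self.ee <= 0:
            raise ParameterError(f"ee must be positive, got {self.ee}")


@dataclass(frozen=True)
class PathologyProfile:
    """Perturbation magnitudes defining one voice-quality archetype."""

    name: str
    jitter_pct: float = 0.0
    shimmer_pct: float = 0.0
    hnr_db: float = np.inf
    tremor_hz: float = 0.0
    tremor_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.jitter_pct < 0 or self.shimmer_pct < 0:
            raise ParameterError("jitter_pct and shimmer_pct must be >= 0")
        if not (np.isfinite(self.hnr_db) or self.hnr_db == np.inf):
            raise ParameterError("hnr_db must be finite or +inf")
        if not 0.0 <= self.tremor_depth < 1.0:
            raise ParameterError("tremor_depth must lie in [0, 1)")


#: Built-in archetypes: healthy baseline plus three disorder grades whose
#: perturbations mirror the perturbation ranges seen in dysphonic voices.
ARCHETYPES = {
    "healthy": PathologyProfile("healthy", jitter_pct=0.3, shimmer_pct=2.0, hnr_db=30.0),
    "cyst-like": PathologyProfile("cyst-like", jitter_pct=1.5, shimmer_pct=10.0, hnr_db=15.0),
    "paralysis-like": PathologyProfile(
        "paralysis-like", jitter_pct=2.5, shimmer_pct=15.0, hnr_db=12.0, tremor_hz=5.0, tremor_depth=0.08
    ),
    "polyp-like": PathologyProfile("polyp-like", jitter_pct=4.0, shimmer_pct=25.0, hnr_db=8.0),
}


@dataclass(frozen=True)
class TractSpec:
    """All-pole vocal tract given as formant (center, bandwidth) pairs."""

    formants: tuple = VOWEL_A_FORMANTS
    fs_hz: float = DEFAULT_FS_HZ

    def __post_init__(self) -> None:
        for f, b in self.formants:
            if f >= self.fs_hz / 2:
                raise StabilityError(f"formant {f} Hz at/above Nyquist ({self.fs_hz / 2} Hz)")
            if b <= 0:
                raise StabilityError(f"non-positive bandwidth {b} Hz")

    def denominator(self) -> np.ndarray:
        """Coefficients of A(z) with all poles strictly inside the unit circle."""
        a = np.array([1.0])
        for f, b in self.formants:
            r = np.exp(-np.pi * b / self.fs_hz)
            theta = 2 * np.pi * f / self.fs_hz
            a = np.convolve(a, [1.0, -2 * r * np.cos(theta), r * r])
        if len(a) > 1 and np.max(np.abs(np.roots(a))) >= 1.0:
            raise StabilityError("vocal-tract poles not strictly inside the unit circle")
        return a


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _solve_epsilon(ta: float, tb: float) -> float:
    """Return-phase rate: eps*ta = 1 - exp(-eps*tb) with tb the closed phase."""
    return brentq(lambda e: e * ta - 1.0 + np.exp(-e * tb), 1e-3 / ta, 50.0 / ta)


def lf_pulse(params: LFParams, fs_hz: float) -> np.ndarray:
    """One LF flow-derivative pulse of ``round(fs/f0)`` samples (half-up).

    The opening-phase growth factor is solved numerically so the pulse's
    net area vanishes (the flow returns to its start value), and the pulse
    is scaled so its minimum is exactly ``-ee``.
    """
    if fs_hz < 8000:
        raise ParameterError("fs_hz must be >= 8000")
    n = _round_half_up(fs_hz / params.f0_hz)
    return _unit_lf_pulse(n, fs_hz, params.oq, params.am, params.ta_frac) * params.ee


def _unit_lf_pulse(n: int, fs_hz: float, oq: float, am: float, ta_frac: float) -> np.ndarray:
    """LF flow-derivative pulse with n samples, zero net area, minimum -1."""
    t0 = n / fs_hz  # realized period
    te, tp, ta = oq * t0, am * oq * t0, ta_frac * t0
    eps = _solve_epsilon(ta, t0 - te)
    t = np.arange(n) / fs_hz
    open_ph = t <= te

    def pulse(alpha: float) -> np.ndarray:
        e = np.empty(n)
        # opening phase: exponentially growing half-sinusoid through -1 at te
        e0 = -1.0 / (np.exp(alpha * te) * np.sin(np.pi * te / tp))
        e[open_ph] = e0 * np.exp(alpha * t[open_ph]) * np.sin(np.pi * t[open_ph] / tp)
        # return phase: exponential recovery to zero at period end
        tr = t[~open_ph] - te
        e[~open_ph] = -(1.0 / (eps * ta)) * (np.exp(-eps * tr) - np.exp(-eps * (t0 - te)))
        return e

    alpha = brentq(lambda a: float(np.sum(pulse(a / t0))), -200.0, 400.0) / t0
    p = pulse(alpha)
    p -= np.sum(p) / n  # remove residual quantization area exactly
    return p / -p.min()


def render_voice(
    lf: LFParams,
    tract: TractSpec,
    profile: PathologyProfile,
    duration_s: float = 2.0,
    fs_hz: float = DEFAULT_FS_HZ,
    seed: int = 0,
):
    """Render one sustained vowel; returns ``(Recording, GlottalSignal)``.

    Cycle periods and amplitudes are drawn per cycle with relative standard
    deviations ``jitter_pct/100`` and ``shimmer_pct/100``; the fractional
    sample residue of each period is carried forward so the long-run mean
    F0 is exact.  Aspiration noise is injected at the source and scaled so
    the rendered (post-tract) signal meets ``profile.hnr_db``.  The
    ground-truth glottal flow/derivative are stored pre-tract, pre-noise.
    """
    if duration_s < 0.5:
        raise ParameterError("duration_s must be >= 0.5")
    rng = np.random.default_rng(seed)
    n_total = _round_half_up(duration_s * fs_hz)
    # The pulse train is synthesized at 8x oversampling so that cycle
    # onsets quantize to 1/8 sample: integer-sample placement at the output
    # rate would add ~0.5-sample timing noise, comparable to healthy jitter.
    ov = 8
    fs_int = ov * fs_hz
    n_int = ov * n_total
    source_hi = np.zeros(n_int + ov * _round_half_up(2 * fs_hz / lf.f0_hz))

    t_cursor = 0.0  # exact cycle onset time (s)
    marks = []
    pulse_cache: dict = {}
    while t_cursor * fs_hz < n_total:
        f0_i = lf.f0_hz
        if profile.tremor_depth > 0:
            f0_i *= 1.0 + profile.tremor_depth * np.sin(2 * np.pi * profile.tremor_hz * t_cursor)
        period = (1.0 / f0_i) * (1.0 + (profile.jitter_pct / 100.0) * rng.standard_normal())
        period = max(period, 0.25 / f0_i)
        start = _round_half_up(t_cursor * fs_int)
        n_i = _round_half_up((t_cursor + period) * fs_int) - start
        n_i = max(n_i, 4 * ov)
        if n_i not in pulse_cache:
            pulse_cache[n_i] = _unit_lf_pulse(n_i, fs_int, lf.oq, lf.am, lf.ta_frac)
        amp = lf.ee * (1.0 + (profile.shimmer_pct / 100.0) * rng.standard_normal())
        amp = max(amp, 0.05 * lf.ee)
        source_hi[start : start + n_i] += amp * pulse_cache[n_i]
        marks.append(_round_half_up(t_cursor * fs_hz))
        t_cursor += period

    source = resample_poly(source_hi[: n_int], 1, ov)[:n_total]
    a_tract = tract.denominator()
    clean = lfilter([1.0], a_tract, source)

    if np.isfinite(profile.hnr_db):
        noise = rng.standard_normal(n_total)
        noise_out = lfilter([1.0], a_tract, noise)
        target_noise_power = np.mean(clean ** 2) / 10.0 ** (profile.hnr_db / 10.0)
        sigma = np.sqrt(target_noise_power / np.mean(noise_out ** 2))
        speech = clean + sigma * noise_out
    else:
        speech = clean

    flow = lfilter([1.0], [1.0, -0.999], source)  # leaky running integral
    truth = GlottalSignal(flow=flow, flow_derivative=source.copy(), fs_hz=fs_hz)
    rec = Recording(
        samples=speech,
        fs_hz=fs_hz,
        label=profile.name,
        source_id=f"synth:{profile.name}:seed{seed}",
        meta={"f0_hz": lf.f0_hz, "profile": profile.name, "seed": seed, "cycle_marks": marks},
    )
    return rec, truth


def measure_hnr(samples: np.ndarray, fs_hz: float, f0_hz: float, width_bins: int = 1) -> float:
    """Harmonics-to-noise ratio (dB) by comb splitting of the FFT spectrum.

    Power within ``width_bins`` bins of every F0 harmonic counts as
    harmonic; everything else above DC counts as noise.  Accurate when
    the analysis length holds an integer number of periods.
    """
    x = np.asarray(samples, dtype=np.float64)
    spec = np.abs(np.fft.rfft(x)) ** 2
    n = len(x)
    f0_bin = f0_hz * n / fs_hz
    harmonic = np.zeros(len(spec), dtype=bool)
    k = 1
    while k * f0_bin < len(spec) - 1:
        c = int(round(k * f0_bin))
        harmonic[max(c - width_bins, 0) : c + width_bins + 1] = True
        k += 1
    harmonic[:2] = False  # exclude DC drift
    noise_power = spec[2:][~harmonic[2:]].sum()
    harm_power = spec[harmonic].sum()
    if noise_power == 0:
        return np.inf
    return float(10.0 * np.log10(harm_power / noise_power))


@dataclass(frozen=True)
class ClassSpec:
    """One cohort class: label, count, perturbation profile, parameter ranges."""

    name: str
    count: int
    profile: PathologyProfile
    f0_range_hz: tuple = (100.0, 220.0)
    duration_s: float = 2.0
    formant_scale_range: tuple = (0.9, 1.1)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a labeled synthetic cohort."""

    classes: tuple
    fs_hz: float = DEFAULT_FS_HZ

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ConfigError("a cohort needs at least 2 classes")
        for c in self.classes:
            if c.count < 1:
                raise ConfigError(f"class {c.name!r} must have count >= 1")


def binary_cohort_spec(
    n_per_class: int = 60,
    pathology: str = "polyp-like",
    duration_s: float = 2.0,
    fs_hz: float = DEFAULT_FS_HZ,
    formant_scale_range: tuple = (0.9, 1.1),
) -> CohortSpec:
    """Healthy vs one-pathology detection cohort."""
    return CohortSpec(
        classes=(
            ClassSpec("healthy", n_per_class, ARCHETYPES["healthy"], duration_s=duration_s,
                      formant_scale_range=formant_scale_range),
            ClassSpec(pathology, n_per_class, ARCHETYPES[pathology], duration_s=duration_s,
                      formant_scale_range=formant_scale_range),
        ),
        fs_hz=fs_hz,
    )


def multiclass_cohort_spec(
    n_per_class: int = 30, duration_s: float = 2.0, fs_hz: float = DEFAULT_FS_HZ
) -> CohortSpec:
    """Four-class cohort: healthy plus three disorder archetypes."""
    return CohortSpec(
        classes=tuple(
            ClassSpec(name, n_per_class, prof, duration_s=duration_s)
            for name, prof in ARCHETYPES.items()
        ),
        fs_hz=fs_hz,
    )


def make_cohort(spec: CohortSpec, seed: int = 0):
    """Generate the labeled recordings of a cohort; pure in ``(spec, seed)``.

    Returns ``(recordings, truths)`` lists aligned index-wise.  Per-recording
    seeds are spawned deterministically from the cohort seed, so identical
    calls produce bit-identical waveforms.
    """
    recordings, truths = [], []
    for cls_idx, cls in enumerate(spec.classes):
        for rec_idx in range(cls.count):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(cls_idx, rec_idx))
            rng = np.random.default_rng(child)
            f0 = rng.uniform(*cls.f0_range_hz)
            scale = rng.uniform(*cls.formant_scale_range)
            formants = tuple((f * scale, b) for f, b in VOWEL_A_FORMANTS)
            lf = LFParams(f0_hz=f0)
            tract = TractSpec(formants=formants, fs_hz=spec.fs_hz)
            render_seed = int(rng.integers(0, 2 ** 31 - 1))
            rec, truth = render_voice(
                lf, tract, cls.profile, duration_s=cls.duration_s, fs_hz=spec.fs_hz, seed=render_seed
            )
            rec.source_id = f"synth:{cls.name}:{rec_idx}"
            recordings.append(rec)
            truths.append(truth)
    return recordings, truths
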