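"""Synthetic cuff-deflation Korotkoff recordings with known ground truth.

The generator is phenomenological: it does not model the fluid/wall
mechanics of sound genesis, only the observable structure of a cuff
recording —

* cuff pressure falls linearly from above systolic (SBP) to below
  diastolic (DBP) at a controlled deflation rate;
* Korotkoff beats (damped band-limited oscillations) occur at heart-rate
  intervals only while DBP < cuff pressure < SBP;
* beat peak amplitudes follow a unimodal Beta-shaped envelope over the
  window whose temporal asymmetry is set by ``envelope_skew`` (positive
  = amplitude mass early in the window, i.e. at higher cuff pressures —
  the pattern seen in young, compliant arteries; negative = mass late,
  the stiff-artery pattern);
* sinusoidal baseline wander and white measurement noise overlay the
  whole record.

A latent stiffness variable couples the acoustic parameters to a
simulated brachial-ankle pulse-wave velocity (baPWV) through a linear
covariate model in the hospital preset, so covariate-adjusted analyses
have a recoverable ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .io import Recording, Subject

__all__ = [
    "GroundTruthParams",
    "CohortPreset",
    "PRESETS",
    "beta_shapes_from_skew",
    "generate_recording",
    "generate_cohort",
    "calibrate_presets",
]

#: fixed Beta-envelope concentration a + b; bounds the attainable skew to
#: roughly ±1.1 while keeping the density bounded (both shapes > 1)
_BETA_CONCENTRATION = 6.0
MAX_ENVELOPE_SKEW = 1.1


@dataclass
class GroundTruthParams:
    """Complete parameterisation of one synthetic recording."""

    sbp: float = 120.0  # mmHg
    dbp: float = 80.0  # mmHg
    deflation_rate: float = 3.0  # mmHg/s
    start_pressure_offset: float = 30.0  # mmHg above SBP at t=0
    heart_rate: float = 75.0  # bpm
    beat_jitter: float = 0.04  # fractional SD of beat intervals
    beat_center_freq: float = 35.0  # Hz
    beat_bandwidth: float = 10.0  # Hz, spread of per-beat frequencies
    beat_decay: float = 0.04  # s, damping time constant
    envelope_skew: float = 0.0  # signed; >0 = mass early in window
    envelope_peak_amp: float = 1.0  # arbitrary sensor units
    envelope_floor: float = 0.08  # faint-beat pedestal, fraction of peak amp
    drift_amp: float = 0.3  # baseline wander amplitude
    drift_freq: float = 0.4  # Hz
    noise_sd: float = 0.02  # additive white noise SD
    latent_stiffness: float = 0.0  # dimensionless driver of group structure
    seed: int = 0

    def validate(self, fs: float) -> None:
        if not self.sbp > self.dbp:
            raise ValueError(f"requires sbp > dbp, got {self.sbp} <= {self.dbp}")
        if self.deflation_rate <= 0:
            raise ValueError("deflation_rate must be positive")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if self.beat_center_freq >= fs / 2:
            raise ValueError(
                f"beat_center_freq {self.beat_center_freq} Hz >= Nyquist {fs / 2} Hz"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if abs(self.envelope_skew) > MAX_ENVELOPE_SKEW:
            raise ValueError(
                f"|envelope_skew| must be <= {MAX_ENVELOPE_SKEW}, got {self.envelope_skew}"
            )


def beta_shapes_from_skew(skew: float, concentration: float = _BETA_CONCENTRATION):
    """Solve Beta shape parameters (a, b) from the envelope skew dial.

    The envelope is the Beta(a, b) density over the Korotkoff window with
    a + b fixed at ``concentration``.  ``skew`` is the density's standard
    third standardized moment; positive skew puts amplitude mass early.
    The map is monotone (larger ``skew`` -> smaller ``a``), solved by
    bisection on the closed-form Beta skewness.
    """
    nu = concentration

    def beta_skew(a: float) -> float:
        b = nu - a
        return 2.0 * (b - a) * math.sqrt(nu + 1.0) / ((nu + 2.0) * math.sqrt(a * b))

    lo, hi = 1.02, nu - 1.02
    if not beta_skew(hi) <= skew <= beta_skew(lo):
        raise ValueError(f"envelope skew {skew} outside attainable range")
    a = optimize.brentq(lambda a: beta_skew(a) - skew, lo, hi, xtol=1e-12)
    return a, nu - a


def _envelope(u: np.ndarray, skew: float, floor: float = 0.0) -> np.ndarray:
    """Beat-amplitude envelope on normalized window position u in [0, 1].

    A Beta-density bump (peak 1) riding on a small pedestal: Korotkoff
    sounds are loudest mid-deflation but remain faintly audible across
    the whole window until muffling at DBP.
    """
    a, b = beta_shapes_from_skew(skew)
    pdf = stats.beta.pdf(np.clip(u, 0.0, 1.0), a, b)
    mode = (a - 1.0) / (a + b - 2.0)
    bump = pdf / stats.beta.pdf(mode, a, b)
    return floor + (1.0 - floor) * bump


def generate_recording(
    params: GroundTruthParams,
    duration: Optional[float] = None,
    fs: float = 1000.0,
    subject_id: str = "",
):
    """Synthesize one cuff-deflation recording.

    Returns ``(recording, beat_times, window)`` where ``beat_times`` are
    the per-beat waveform peak times in seconds and ``window`` is the
    half-open sample range over which DBP < cuff pressure < SBP.
    Identical ``(params, duration, fs)`` (seed included) give bitwise
    identical output.
    """
    params.validate(fs)
    rate = params.deflation_rate
    p0 = params.sbp + params.start_pressure_offset
    t_start = params.start_pressure_offset / rate
    t_end = t_start + (params.sbp - params.dbp) / rate
    if duration is None:
        duration = t_end + 10.0 / rate  # run down to DBP - 10 mmHg
    if duration < t_end:
        raise ValueError(
            f"duration {duration:.2f} s too short for the cuff to traverse "
            f"[dbp, sbp] (needs {t_end:.2f} s)"
        )
    mean_interval = 60.0 / params.heart_rate
    if t_end - t_start < mean_interval:
        raise ValueError("Korotkoff window shorter than one beat interval")

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    pressure = p0 - rate * t
    rng = np.random.default_rng(params.seed)

    # beat onset times: renewal process at heart-rate intervals inside the window
    onsets = []
    tt = t_start + 0.5 * mean_interval
    while tt < t_end:
        onsets.append(tt)
        jit = np.clip(rng.normal(0.0, params.beat_jitter), -0.5, 0.5)
        tt += mean_interval * (1.0 + jit)
    onsets = np.asarray(onsets)

    sound = np.zeros(n)
    beat_times = []
    kernel_len = int(round(5.0 * params.beat_decay * fs))
    tau = np.arange(kernel_len) / fs
    half_bw = params.beat_bandwidth / 2.0
    for onset in onsets:
        u = (onset - t_start) / (t_end - t_start)
        amp = params.envelope_peak_amp * _envelope(
            np.array([u]), params.envelope_skew, params.envelope_floor
        )[0]
        f_beat = params.beat_center_freq + rng.uniform(-half_bw, half_bw)
        kernel = np.exp(-tau / params.beat_decay) * np.sin(2.0 * np.pi * f_beat * tau)
        peak_idx = int(np.argmax(np.abs(kernel)))
        kernel = kernel * (amp / np.max(np.abs(kernel)))
        i0 = int(round(onset * fs))
        i1 = min(n, i0 + kernel_len)
        sound[i0:i1] += kernel[: i1 - i0]
        beat_times.append(onset + peak_idx / fs)

    if params.drift_amp > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        sound += params.drift_amp * np.sin(2.0 * np.pi * params.drift_freq * t + phase)
    if params.noise_sd > 0:
        sound += rng.normal(0.0, params.noise_sd, size=n)

    w0 = int(np.searchsorted(-pressure, -params.sbp, side="right"))
    w1 = int(np.searchsorted(-pressure, -params.dbp, side="left"))
    rec = Recording(sound, pressure, fs, subject_id=subject_id)
    return rec, np.asarray(beat_times), (w0, w1)


@dataclass
class CohortPreset:
    """Distributional description of one study group.

    Tuples are ``(mean, sd, low, high)`` truncated-normal specs.  The
    hospital preset couples the acoustic dials to a latent stiffness
    variable and emits baPWV from a linear covariate model::

        bapwv = b0 + b_age*age + b_sbp*sbp + b_bmi*bmi + b_dm*diabetes
                + g_latent*latent_stiffness + noise
    """

    name: str
    age: tuple = (45.0, 12.0, 20.0, 79.0)
    bmi: tuple = (23.0, 2.0, 17.0, 38.0)
    sbp: tuple = (120.0, 10.0, 90.0, 175.0)
    dbp: tuple = (78.0, 7.0, 50.0, 110.0)
    heart_rate: tuple = (75.0, 10.0, 45.0, 110.0)
    diabetes_p: float = 0.0
    smoking_p: float = 0.0
    male_p: float = 0.45
    envelope_skew: tuple = (0.0, 0.15, -1.05, 1.05)
    beat_center_freq: tuple = (35.0, 3.0, 15.0, 80.0)
    latent_stiffness: tuple = (0.0, 1.0, -3.0, 3.0)
    skew_vs_latent: float = 0.0  # added to envelope_skew mean per latent unit
    freq_vs_latent: float = 0.0  # added to beat_center_freq mean per latent unit
    bapwv_coefs: Optional[dict] = None  # b0, b_age, b_sbp, b_bmi, b_dm, g_latent, noise_sd
    group_label: str = "none"
    base_params: GroundTruthParams = field(default_factory=GroundTruthParams)


def _trunc_normal(rng: np.random.Generator, spec: tuple) -> float:
    mean, sd, lo, hi = spec
    for _ in range(200):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


#: default study-group presets.  The young and older groups mirror the
#: age-stratified cohort moments (ages 25.9 +/- 2.2 vs 67.5 +/- 6.7 and
#: the matching BMI/BP/heart-rate summaries); their acoustic dials encode
#: the compliant-vs-stiff contrast: young = amplitude mass early
#: (positive envelope skew) and a higher beat frequency band, older the
#: mirror image.  The hospital preset spans adulthood with a latent
#: stiffness variable driving both the acoustics and baPWV.
PRESETS: dict[str, CohortPreset] = {
    "young": CohortPreset(
        name="young",
        age=(25.9, 2.2, 20.0, 30.0),
        bmi=(22.8, 1.1, 20.0, 25.0),
        sbp=(118.0, 6.0, 100.0, 140.0),
        dbp=(77.0, 5.0, 55.0, 95.0),
        heart_rate=(76.0, 9.2, 50.0, 110.0),
        male_p=0.463,
        envelope_skew=(0.55, 0.35, -1.05, 1.05),
        beat_center_freq=(40.0, 5.0, 20.0, 80.0),
        latent_stiffness=(-1.0, 0.5, -3.0, 3.0),
        group_label="young",
    ),
    "older": CohortPreset(
        name="older",
        age=(67.5, 6.7, 60.0, 79.0),
        bmi=(23.4, 1.5, 20.0, 25.0),
        sbp=(120.0, 11.0, 95.0, 160.0),
        dbp=(79.0, 6.0, 55.0, 100.0),
        heart_rate=(78.2, 11.4, 45.0, 115.0),
        male_p=0.394,
        envelope_skew=(-0.55, 0.35, -1.05, 1.05),
        beat_center_freq=(29.0, 4.0, 15.0, 60.0),
        latent_stiffness=(1.0, 0.5, -3.0, 3.0),
        group_label="older",
    ),
    "hospital": CohortPreset(
        name="hospital",
        age=(44.0, 13.0, 20.0, 79.0),
        bmi=(24.5, 3.8, 17.0, 38.0),
        sbp=(128.0, 14.0, 95.0, 175.0),
        dbp=(75.0, 10.0, 50.0, 110.0),
        heart_rate=(73.0, 11.0, 45.0, 115.0),
        diabetes_p=0.19,
        smoking_p=0.13,
        male_p=0.44,
        envelope_skew=(0.0, 0.15, -1.05, 1.05),
        beat_center_freq=(34.0, 2.0, 15.0, 80.0),
        latent_stiffness=(0.0, 1.0, -3.0, 3.0),
        skew_vs_latent=-0.45,
        freq_vs_latent=-4.0,
        bapwv_coefs={
            "b0": 400.0,
            "b_age": 8.0,
            "b_sbp": 4.0,
            "b_bmi": 5.0,
            "b_dm": 80.0,
            "g_latent": 150.0,
            "noise_sd": 120.0,
        },
        group_label="none",
    ),
}


def _subject_seed(cohort_seed: int, index: int) -> int:
    """Per-subject seed: counter scheme via SeedSequence((cohort_seed, index))."""
    return int(np.random.SeedSequence([int(cohort_seed), int(index)]).generate_state(1)[0] % (2**31))


def generate_cohort(
    preset: CohortPreset | str,
    n: int,
    seed: int = 0,
    fs: float = 1000.0,
):
    """Draw ``n`` subjects from a preset and synthesize their recordings.

    Returns ``(recordings, subjects, params_list)``.  For the hospital
    preset, baPWV is emitted from the preset's linear covariate model and
    subjects are labelled high/low baPWV by the cohort median, mirroring
    a median-split hospital design.
    """
    if isinstance(preset, str):
        try:
            preset = PRESETS[preset]
        except KeyError:
            raise ValueError(f"unknown preset {preset!r}") from None
    if n < 1:
        raise ValueError("cohort size must be >= 1")

    recordings, subjects, params_list = [], [], []
    bapwvs: list[Optional[float]] = []
    for i in range(n):
        srng = np.random.default_rng(np.random.SeedSequence([int(seed), int(i)]))
        latent = _trunc_normal(srng, preset.latent_stiffness)
        skew_spec = preset.envelope_skew
        skew = _trunc_normal(
            srng,
            (skew_spec[0] + preset.skew_vs_latent * latent, skew_spec[1], skew_spec[2], skew_spec[3]),
        )
        freq_spec = preset.beat_center_freq
        freq = _trunc_normal(
            srng,
            (freq_spec[0] + preset.freq_vs_latent * latent, freq_spec[1], freq_spec[2], freq_spec[3]),
        )
        sbp = _trunc_normal(srng, preset.sbp)
        dbp = min(_trunc_normal(srng, preset.dbp), sbp - 20.0)
        hr = _trunc_normal(srng, preset.heart_rate)
        params = replace(
            preset.base_params,
            sbp=sbp,
            dbp=dbp,
            heart_rate=hr,
            envelope_skew=float(np.clip(skew, -MAX_ENVELOPE_SKEW + 0.01, MAX_ENVELOPE_SKEW - 0.01)),
            beat_center_freq=freq,
            latent_stiffness=latent,
            seed=_subject_seed(seed, i),
        )
        sid = f"{preset.name}-{seed}-{i:04d}"
        rec, _, _ = generate_recording(params, fs=fs, subject_id=sid)

        age = _trunc_normal(srng, preset.age)
        diabetes = bool(srng.random() < preset.diabetes_p)
        bmi = _trunc_normal(srng, preset.bmi)
        bapwv = None
        if preset.bapwv_coefs is not None:
            c = preset.bapwv_coefs
            bapwv = (
                c["b0"]
                + c["b_age"] * age
                + c["b_sbp"] * sbp
                + c["b_bmi"] * bmi
                + c["b_dm"] * diabetes
                + c["g_latent"] * latent
                + srng.normal(0.0, c["noise_sd"])
            )
            bapwv = float(max(bapwv, 200.0))
        subjects.append(
            Subject(
                subject_id=sid,
                age=age,
                sex="male" if srng.random() < preset.male_p else "female",
                bmi=bmi,
                sbp=sbp,
                dbp=dbp,
                heart_rate=hr,
                diabetes=diabetes,
                smoking=bool(srng.random() < preset.smoking_p),
                group_label=preset.group_label,
                bapwv=bapwv,
            )
        )
        recordings.append(rec)
        params_list.append(params)
        bapwvs.append(bapwv)

    if preset.bapwv_coefs is not None and n >= 2:
        med = float(np.median([b for b in bapwvs if b is not None]))
        for s in subjects:
            s.group_label = "high_baPWV" if (s.bapwv or 0.0) >= med else "low_baPWV"
    return recordings, subjects, params_list


def calibrate_presets(
    presets: Sequence[CohortPreset | str] = ("young", "older"),
    n_per_group: int = 100,
    seed: int = 0,
    family_alpha: float = 0.05,
) -> dict:
    """Check that generated cohorts reproduce the expected group contrast.

    Generates one cohort per preset, extracts the ten acoustic features,
    and asserts the sign structure of the compliant-vs-stiff contrast:
    mean center of mass and envelope skewness positive in the first
    (young-like) group and negative in the second, and mean peak
    frequency higher in the first group.  Also reports which of those
    three features the Bonferroni-corrected group comparison flags.
    Failures are flagged in the returned report, never raised.
    """
    from .features import extract_features
    from .stats import compare_groups

    names = []
    tables = []
    for k, p in enumerate(presets):
        recs, _, _ = generate_cohort(p, n_per_group, seed=seed + 1000 * k)
        rows = []
        for rec in recs:
            try:
                rows.append(extract_features(rec).as_dict())
            except Exception:
                continue
        names.append(p if isinstance(p, str) else p.name)
        tables.append(rows)

    import pandas as pd

    df1, df2 = pd.DataFrame(tables[0]), pd.DataFrame(tables[1])
    m1, m2 = df1.mean(), df2.mean()
    checks = {
        "center_of_mass_signs": bool(m1["center_of_mass"] > 0 > m2["center_of_mass"]),
        "skewness_signs": bool(m1["skewness"] > 0 > m2["skewness"]),
        "peak_frequency_order": bool(m1["peak_frequency"] > m2["peak_frequency"]),
    }
    feat = pd.concat([df1, df2], ignore_index=True)
    labels = np.array([names[0]] * len(df1) + [names[1]] * len(df2))
    comps = compare_groups(feat, labels, family_alpha=family_alpha)
    flagged = {c.feature: c.significant for c in comps}
    report = {
        "groups": names,
        "n": [len(df1), len(df2)],
        "means_group1": m1.to_dict(),
        "means_group2": m2.to_dict(),
        "checks": checks,
        "all_sign_checks_pass": all(checks.values()),
        "flagged": flagged,
        "target_features_flagged": {
            f: bool(flagged.get(f, False))
            for f in ("center_of_mass", "skewness", "peak_frequency")
        },
    }
    return report
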