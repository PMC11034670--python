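"""Synthetic exhalation-like turbulent signals with known multifractality.

No public breath-turbulence corpus exists, so this module is the fixture
layer for the whole pipeline: a seeded generator of positive-valued
exhalation records (onset / plateau / decay envelope) whose fluctuations
carry the multifractal structure of a binomial multiplicative cascade. The
cascade is the one multifractal process with a closed-form singularity
spectrum —

    τ(q) = −log2(p^q + (1−p)^q),
    α_min = −log2(max(p, 1−p)),  α_max = −log2(min(p, 1−p)),
    ω = α_max − α_min = log2(p/(1−p)) for p > 1/2,

so every MFDFA estimate can be checked against an analytic oracle. Users
differ by their cascade multiplier ``p`` (spread controlled by a
``separation`` parameter); trials of one user differ by a small jitter of
``p`` and fresh cascade randomness, emulating intra-subject variability
across the ten recordings of the nominal protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .signal_io import BreathSignal, CohortManifest, save_manifest, write_signal

__all__ = [
    "UserProfile",
    "CascadeOracle",
    "binomial_cascade",
    "generate_trial",
    "generate_profiles",
    "generate_cohort",
    "inject_bad_segments",
]

#: refuse to write more trials than this in one cohort (disk budget)
MAX_COHORT_TRIALS = 5000


@dataclass(frozen=True)
class CascadeOracle:
    """Closed-form multifractal quantities of the binomial cascade."""

    p: float

    def tau(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, float)
        return -np.log2(self.p ** q + (1 - self.p) ** q)

    @property
    def alpha_min(self) -> float:
        return float(-np.log2(max(self.p, 1 - self.p)))

    @property
    def alpha_max(self) -> float:
        return float(-np.log2(min(self.p, 1 - self.p)))

    @property
    def omega_analytic(self) -> float:
        return self.alpha_max - self.alpha_min

    def hq(self, q: np.ndarray) -> np.ndarray:
        """Generalized Hurst exponent h(q) = (τ(q) + 1)/q (q ≠ 0)."""
        q = np.asarray(q, float)
        return (self.tau(q) + 1.0) / q


@dataclass(frozen=True)
class UserProfile:
    """Generator parameters of one synthetic subject."""

    user_id: str
    cascade_p: float = 0.64
    envelope: tuple[float, float, float] = (0.3, 0.8, 0.4)  # rise/plateau/decay s
    envelope_floor: float = 0.1
    ar_color: tuple[float, ...] = (0.3,)
    noise_sigma: float = 0.02
    trial_jitter: float = 0.01
    baseline: float = 0.5
    amplitude: float = 2.0
    intensity: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.cascade_p < 0.95:
            raise ValueError("cascade_p must lie in (0.5, 0.95)")
        if any(abs(c) >= 1 for c in self.ar_color):
            raise ValueError("AR coloration coefficients must have |c| < 1")
        if self.noise_sigma < 0 or self.trial_jitter < 0:
            raise ValueError("noise_sigma and trial_jitter must be >= 0")


def binomial_cascade(p: float, levels: int,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Multiplicative binomial measure of length 2^levels.

    Each node's mass is split p : (1−p) between its children, the larger
    share going left or right at random. Total mass is conserved at 1.
    """
    if not 0.5 < p < 1.0:
        raise ValueError("p must lie in (0.5, 1)")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mass = np.array([1.0])
    for _ in range(levels):
        go_left = rng.random(mass.size) < 0.5
        left = np.where(go_left, p, 1.0 - p)
        out = np.empty(2 * mass.size)
        out[0::2] = mass * left
        out[1::2] = mass * (1.0 - left)
        mass = out
    return mass


def _envelope(t: np.ndarray, rise: float, plateau: float,
              decay: float) -> np.ndarray:
    """Smooth onset/plateau/decay profile in [0, 1]."""
    env = np.zeros_like(t)
    m_rise = t < rise
    env[m_rise] = 0.5 * (1 - np.cos(np.pi * t[m_rise] / rise))
    m_plat = (t >= rise) & (t < rise + plateau)
    env[m_plat] = 1.0
    m_dec = t >= rise + plateau
    td = (t[m_dec] - rise - plateau) / decay
    env[m_dec] = 0.5 * (1 + np.cos(np.pi * np.clip(td, 0, 1)))
    return env


def generate_trial(profile: UserProfile, trial_index: int,
                   duration_s: float = 1.5,
                   fs_hz: float = 10_000.0) -> BreathSignal:
    """Synthesize one exhalation trial, bit-reproducible per (profile, index).

    signal = baseline + amplitude · envelope(t) · (1 + intensity · cascade
    fluctuations colored by an AR filter) + Gaussian sensor noise, floored
    at 1% of the baseline to emulate the anemometer's positive record.
    """
    rise, plateau, decay = profile.envelope
    if abs(rise + plateau + decay - duration_s) > 1e-9:
        raise ValueError("envelope phases must sum to the trial duration")
    n = int(round(duration_s * fs_hz))
    rng = np.random.default_rng(
        np.random.SeedSequence((profile.seed, trial_index)))
    p = float(np.clip(profile.cascade_p
                      + profile.trial_jitter * rng.standard_normal(),
                      0.505, 0.945))
    levels = max(int(np.ceil(np.log2(n))), 8)
    fluct = binomial_cascade(p, levels, rng)[:n]
    fluct = fluct - fluct.mean()
    if profile.ar_color:
        fluct = lfilter([1.0], np.r_[1.0, -np.asarray(profile.ar_color)],
                        fluct)
    sd = fluct.std()
    if sd > 0:
        fluct = fluct / sd
    t = np.arange(n) / fs_hz
    # acquisition is triggered by the exhalation itself, so the recorded
    # window never sees truly zero flow: the envelope is floored
    env = np.maximum(_envelope(t, rise, plateau, decay),
                     profile.envelope_floor)
    values = (profile.baseline
              + profile.amplitude * env * (1.0 + profile.intensity * fluct)
              + profile.noise_sigma * rng.standard_normal(n))
    values = np.maximum(values, 0.01 * profile.baseline)
    return BreathSignal(values, fs_hz, user_id=profile.user_id,
                        trial_id=f"trial{trial_index:02d}")


def generate_profiles(n_users: int, separation: float = 1.0,
                      master_seed: int = 0, *,
                      p_center: float = 0.64, p_half_range: float = 0.06,
                      trial_jitter: float = 0.01) -> list[UserProfile]:
    """Equally spaced cascade multipliers across users.

    ``separation`` scales the spread: 1 spans p ∈ [0.58, 0.70], the range
    over which cascade segments of 1500 samples keep well-behaved (convex)
    spectra; 0 makes every user statistically identical (only seeds differ).
    """
    if n_users < 2:
        raise ValueError("need at least 2 users")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    offsets = np.linspace(-p_half_range, p_half_range, n_users)
    seeds = np.random.SeedSequence(master_seed).spawn(n_users)
    profiles = []
    for i in range(n_users):
        p = float(np.clip(p_center + separation * offsets[i], 0.505, 0.945))
        profiles.append(UserProfile(
            user_id=f"user{i:03d}", cascade_p=p, trial_jitter=trial_jitter,
            seed=int(seeds[i].generate_state(1)[0] % (2 ** 31))))
    return profiles


def generate_cohort(n_users: int, trials_per_user: int = 10,
                    separation: float = 1.0, master_seed: int = 0,
                    out_dir: str | Path | None = None,
                    duration_s: float = 1.5, fs_hz: float = 10_000.0,
                    ) -> tuple[CohortManifest, list[UserProfile]]:
    """Generate a full synthetic cohort; optionally write it to disk.

    With ``out_dir`` set, one text file per trial plus ``manifest.csv`` and
    ``profiles.json`` are written and the manifest's file column points at
    them; otherwise the manifest carries empty paths and callers should use
    :func:`generate_trial` to materialize signals on demand.
    """
    if n_users * trials_per_user > MAX_COHORT_TRIALS:
        raise ValueError(
            f"cohort of {n_users * trials_per_user} trials exceeds the "
            f"budget of {MAX_COHORT_TRIALS}")
    profiles = generate_profiles(n_users, separation, master_seed)
    entries = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for prof in profiles:
        for k in range(trials_per_user):
            trial = generate_trial(prof, k, duration_s, fs_hz)
            fname = f"{prof.user_id}_{trial.trial_id}.txt"
            if out is not None:
                write_signal(trial, out / fname)
                entries.append((prof.user_id, trial.trial_id,
                                str(out / fname)))
            else:
                entries.append((prof.user_id, trial.trial_id, ""))
    manifest = CohortManifest(entries, {
        "n_users": n_users, "trials_per_user": trials_per_user,
        "separation": separation, "master_seed": master_seed,
    })
    if out is not None:
        save_manifest(manifest, out / "manifest.csv")
        (out / "profiles.json").write_text(json.dumps(
            [{"user_id": pr.user_id, "cascade_p": pr.cascade_p,
              "seed": pr.seed, "trial_jitter": pr.trial_jitter}
             for pr in profiles], indent=2))
    return manifest, profiles


def inject_bad_segments(signal: BreathSignal, kind: str = "regime_switch",
                        at_s: float = 1.0, amplitude: float = 1.0,
                        seed: int = 0) -> BreathSignal:
    """Corrupt a trial so that the MFDFA validity filter has work to do.

    ``regime_switch`` emulates a subject exhaling hard and then trailing
    off: fluctuations around the switch time are replaced by a smooth
    amplitude ramp, so the straddling segments lose their multifractal
    structure (near-zero spectral width or a folded spectrum).
    ``spike_burst`` adds a short burst of spikes of the given amplitude;
    zero amplitude is the identity.
    """
    values = signal.values.copy()
    n = values.size
    fs = signal.sampling_rate_hz
    rng = np.random.default_rng(seed)
    if kind == "regime_switch":
        i0 = int(at_s * fs)
        half = int(0.1 * fs)  # smooth 0.2 s around the switch
        lo, hi = max(i0 - half, 0), min(i0 + half, n)
        ramp = np.linspace(values[lo], values[hi - 1], hi - lo)
        values[lo:hi] = ramp + 1e-6 * rng.standard_normal(hi - lo)
        values[hi:] *= 0.4  # abruptly weaker exhalation after the switch
    elif kind == "spike_burst":
        if amplitude != 0.0:
            width = int(0.05 * fs)
            start = int(at_s * fs)
            idx = start + rng.choice(width, size=max(width // 20, 1),
                                     replace=False)
            idx = idx[idx < n]
            values[idx] += amplitude * np.ptp(values)
    else:
        raise ValueError(f"unknown corruption kind {kind!r}")
    return BreathSignal(values, fs, signal.user_id, signal.trial_id)
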