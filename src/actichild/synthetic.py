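"""Synthetic free-play sessions with known ground truth.

The generator emulates the structure of videotaped free-play sessions of
preschool children wearing hip and wrist accelerometers: ~20 minute
sessions composed of short intermittent activity bouts, a five-class
behavior alphabet, occasional out-of-view intervals, and two correlated
device placements.

The behavior stream is a semi-Markov chain: bout classes follow a
transition-weight matrix (no self-transitions by default) and bout
durations are exponential with class-specific means of a few seconds to
under a minute, reflecting the burst-like activity patterns of this age
group.  Within a bout, movement is intermittent: a two-state moving/quiet
telegraph process gates movement noise (and the ~2 Hz walking / ~3 Hz
running stride sinusoid), so light and vigorous play differ chiefly in
the fraction of time spent moving rather than in instantaneous amplitude.
The wrist channel carries extra broadband noise, occasional fidget bursts
during sedentary/light bouts, per-bout arm-swing attenuation during
locomotion, and arm-stillness episodes during active play — all of which
make single wrist windows ambiguous in ways that neighboring-window
(lag/lead) context can resolve.  Subject-level random effects (amplitude,
noise and stride-frequency multipliers) keep leave-one-subject-out
evaluation honest.

Bouts coded OUT_OF_VIEW keep a hidden true class: the child kept moving,
the observer just lost them, so the signal is synthesized from the hidden
class while the event log shows OUT_OF_VIEW.

All randomness derives from ``SimConfig.seed`` through per-subject,
per-stage ``SeedSequence`` streams, so cohorts are reproducible and hip and
wrist share bout-level attributes (phase, tempo jitter) without sharing
their noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UsageError
from .io_annotation import (
    ACTIVITY_CLASSES,
    OUT_OF_VIEW,
    Event,
    EventLog,
    Recording,
)

SESSION_EPOCH = pd.Timestamp("2019-03-01 09:00:00")


@dataclass(frozen=True)
class ClassSignal:
    """Signal signature of one activity class.

    mean_vm_g: target mean vector magnitude during movement (1.0 = resting
    gravity); noise_sd_g: per-axis white-noise SD at rest / between
    movements; freq_hz/amp_g: optional periodic component (stride frequency
    and amplitude) for locomotor classes; env_sigma: lognormal sigma of the
    slowly varying intensity envelope.

    Non-locomotor movement is intermittent: a two-state (moving/quiet)
    telegraph process with mean dwell times on_s/off_s gates extra noise of
    SD move_sd_g.  The duty cycle — not the instantaneous amplitude — is
    what separates light from vigorous play, and a duty cycle cannot be
    estimated from a 1 s snapshot, which is why longer windows genuinely
    carry more information.  on_s = 0 disables the telegraph.
    """

    mean_vm_g: float
    noise_sd_g: float
    freq_hz: float | None = None
    amp_g: float = 0.0
    env_sigma: float = 0.0
    move_sd_g: float = 0.0
    on_s: float = 0.0
    off_s: float = 0.0


def _default_class_params() -> dict[str, ClassSignal]:
    return {
        # a seated child fidgets briefly every ten seconds or so
        "SED": ClassSignal(1.03, 0.02, env_sigma=0.50,
                           move_sd_g=0.12, on_s=0.5, off_s=12.0),
        # light play: moving ~30% of the time, similar instantaneous
        # intensity to vigorous play; dwell times of 1-2.5 s sit between
        # the 1 s and 10 s window scales, so a 1 s window sees a single
        # ambiguous state while a 10 s window spans several duty cycles
        # quiet-state noise matches SED: a quiet second is uninformative
        # about which activity it belongs to; only the duty cycle tells
        "LIGHT_AG": ClassSignal(1.06, 0.02, env_sigma=0.50,
                                move_sd_g=0.30, on_s=1.0, off_s=2.4),
        # vigorous play: moving ~73% of the time, somewhat harder
        "MV_AG": ClassSignal(1.12, 0.025, env_sigma=0.50,
                             move_sd_g=0.42, on_s=2.4, off_s=0.9),
        # locomotion is steady but not continuous: brief stops/turns pause
        # the stride, so a 1 s window may miss the gait signature entirely
        "WALK": ClassSignal(1.05, 0.06, freq_hz=2.0, amp_g=0.30, env_sigma=0.60,
                            on_s=4.0, off_s=0.8),
        "RUN": ClassSignal(1.15, 0.12, freq_hz=3.0, amp_g=0.70, env_sigma=0.60,
                           on_s=3.0, off_s=0.5),
    }


def _default_bout_means() -> dict[str, float]:
    # sitting/light-play spells last tens of seconds; vigorous bursts seconds
    return {"SED": 40.0, "LIGHT_AG": 20.0, "MV_AG": 8.0, "WALK": 7.0, "RUN": 4.0}


def _default_transitions() -> np.ndarray:
    # rows = from, cols = to, order SED, LIGHT_AG, MV_AG, WALK, RUN
    return np.array(
        [
            [0.0, 4.0, 1.0, 2.0, 0.5],
            [2.0, 0.0, 2.0, 3.0, 1.0],
            [1.0, 3.0, 0.0, 2.0, 2.0],
            [1.5, 3.0, 2.0, 0.0, 1.5],
            [0.5, 2.0, 3.0, 2.0, 0.0],
        ]
    )


@dataclass
class SimConfig:
    n_subjects: int = 15
    session_s: float = 1200.0
    rate_hz: float = 100.0
    class_params: dict[str, ClassSignal] = field(default_factory=_default_class_params)
    bout_mean_s: dict[str, float] = field(default_factory=_default_bout_means)
    transition_weights: np.ndarray = field(default_factory=_default_transitions)
    p_out_of_view: float = 0.05
    wrist_extra_noise: float = 0.08
    wrist_burst_rate: float = 0.04  # bursts per second during SED/LIGHT_AG;
    # rare enough that a corrupted window is an anomaly among clean neighbors
    wrist_burst_amp: float = 0.45  # g
    wrist_burst_s: float = 1.2  # mean burst duration
    wrist_arm_engagement: tuple[float, float] = (0.2, 0.9)  # per-bout periodic
    # attenuation at the wrist (child may hold an object while walking/running)
    wrist_still_rate: float = 0.05  # arm-stillness episodes per second during
    # active (LIGHT_AG/MV_AG) bouts: the wrist goes quiet although the body
    # is active, so single-window wrist features look sedentary
    wrist_still_s: float = 4.0  # mean episode duration
    subject_effect_sd: float = 0.25  # lognormal sigma of per-subject multipliers
    bout_noise_jitter: float = 0.25  # lognormal sigma of per-bout noise level
    env_knot_s: float = 0.45  # correlation time of the intensity envelope
    min_bout_s: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.session_s <= 0 or self.rate_hz <= 0:
            raise UsageError("n_subjects, session_s and rate_hz must be positive")
        self.transition_weights = np.asarray(self.transition_weights, dtype=float)
        if self.transition_weights.shape != (5, 5) or (self.transition_weights < 0).any():
            raise UsageError("transition_weights must be a nonnegative 5x5 matrix")
        if (self.transition_weights.sum(axis=1) == 0).any():
            raise UsageError("every transition row needs at least one positive weight")
        if not 0 <= self.p_out_of_view < 1:
            raise UsageError("p_out_of_view must be in [0, 1)")
        for cls, p in self.class_params.items():
            if p.freq_hz is not None and not 0.25 <= p.freq_hz <= 5.0:
                raise UsageError(f"{cls}: periodic frequency outside [0.25, 5] Hz")


@dataclass
class SimSession:
    hip: Recording
    wrist: Recording
    log: EventLog


def _rng(cfg: SimConfig, subject_id: str, stage: int, extra: int = 0) -> np.random.Generator:
    sid_hash = zlib.crc32(subject_id.encode())
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed % (2**31), sid_hash, stage, extra])
    )


@dataclass(frozen=True)
class _Bout:
    start_s: float
    end_s: float
    true_class: str  # one of the five classes
    code: str  # true class or OUT_OF_VIEW
    phase: float
    tempo_jitter: float
    amp_jitter: float


def _simulate_bout_chain(cfg: SimConfig, subject_id: str) -> list[_Bout]:
    """Semi-Markov bout chain plus per-bout signal attributes.

    Bout structure (stage 1) and per-bout signal attributes (stage 2) come
    from separate streams so both placements can regenerate identical
    attributes.
    """
    rng = _rng(cfg, subject_id, stage=1)
    t = 0.0
    # initial state ~ normalized incoming transition weight, so degenerate
    # one-class chains start (and stay) in their only reachable class
    w0 = cfg.transition_weights.sum(axis=0)
    state = int(rng.choice(5, p=w0 / w0.sum()))
    raw: list[tuple[float, float, str, str]] = []
    while t < cfg.session_s:
        cls = ACTIVITY_CLASSES[state]
        dur = max(cfg.min_bout_s, rng.exponential(cfg.bout_mean_s[cls]))
        end = min(t + dur, cfg.session_s)
        code = OUT_OF_VIEW if rng.random() < cfg.p_out_of_view else cls
        raw.append((t, end, cls, code))
        t = end
        w = cfg.transition_weights[state]
        state = int(rng.choice(5, p=w / w.sum()))
    # merge adjacent bouts with identical true class AND code
    merged: list[tuple[float, float, str, str]] = []
    for b in raw:
        if merged and merged[-1][2] == b[2] and merged[-1][3] == b[3]:
            merged[-1] = (merged[-1][0], b[1], b[2], b[3])
        else:
            merged.append(b)
    attr_rng = _rng(cfg, subject_id, stage=2)
    bouts = []
    for start, end, cls, code in merged:
        bouts.append(
            _Bout(
                start_s=start,
                end_s=end,
                true_class=cls,
                code=code,
                phase=float(attr_rng.uniform(0, 2 * np.pi)),
                tempo_jitter=float(attr_rng.normal(0.0, 0.05)),
                amp_jitter=float(attr_rng.lognormal(0.0, 0.10)),
            )
        )
    return bouts


def simulate_bouts(cfg: SimConfig, subject_id: str) -> EventLog:
    """Ground-truth direct-observation log for one simulated session."""
    events = [
        Event(
            SESSION_EPOCH + pd.Timedelta(seconds=round(b.start_s, 3)),
            SESSION_EPOCH + pd.Timedelta(seconds=round(b.end_s, 3)),
            b.code,
        )
        for b in _simulate_bout_chain(cfg, subject_id)
    ]
    return EventLog(subject_id=subject_id, events=events)


def _subject_effects(cfg: SimConfig, subject_id: str) -> tuple[float, float, float]:
    rng = _rng(cfg, subject_id, stage=0)
    amp_mult = float(rng.lognormal(0.0, cfg.subject_effect_sd))
    noise_mult = float(rng.lognormal(0.0, cfg.subject_effect_sd * 0.7))
    freq_shift = float(rng.normal(0.0, 0.15))  # Hz, stride-tempo idiosyncrasy
    return amp_mult, noise_mult, freq_shift


def synthesize_signal(log: EventLog, cfg: SimConfig, placement: str) -> Recording:
    """Tri-axial signal for one placement consistent with a bout log.

    The log must come from :func:`simulate_bouts` with the same config (the
    bout chain is regenerated to recover hidden classes and shared per-bout
    attributes); determinism per (seed, subject, placement) is guaranteed.
    """
    if placement not in ("hip", "wrist"):
        raise UsageError("placement must be 'hip' or 'wrist'")
    bouts = _simulate_bout_chain(cfg, log.subject_id)
    amp_mult, noise_mult, freq_shift = _subject_effects(cfg, log.subject_id)
    place_idx = 0 if placement == "hip" else 1
    noise_rng = _rng(cfg, log.subject_id, stage=3, extra=place_idx)

    n = int(round(cfg.session_s * cfg.rate_hz))
    t = np.arange(n) / cfg.rate_hz
    sig = np.zeros((n, 3))
    sig[:, 2] = 1.0  # gravity on the vertical axis

    extra_noise = cfg.wrist_extra_noise if placement == "wrist" else 0.0
    for b in bouts:
        i0 = int(np.ceil(b.start_s * cfg.rate_hz - 1e-9))
        i1 = min(n, int(np.ceil(b.end_s * cfg.rate_hz - 1e-9)))
        if i1 <= i0:
            continue
        p = cfg.class_params[b.true_class]
        seg_t = t[i0:i1]
        m = i1 - i0
        env = _smooth_envelope(m, p.env_sigma, cfg, noise_rng)
        state = _telegraph_mask(m, p.on_s, p.off_s, cfg.rate_hz, noise_rng)
        dyn = np.zeros((m, 3))
        # mean-VM elevation accompanies movement, so short windows see an
        # ambiguous snapshot of it rather than a fixed per-class fingerprint
        dc_jitter = noise_rng.lognormal(0.0, 0.3)
        dyn[:, 2] += (p.mean_vm_g - 1.0) * dc_jitter * env * state
        if p.freq_hz is not None and p.amp_g > 0:
            f = max(0.25, p.freq_hz + freq_shift + b.tempo_jitter)
            a = p.amp_g * amp_mult * b.amp_jitter
            if placement == "wrist":
                # arm swing is attenuated when the child carries something
                a *= noise_rng.uniform(*cfg.wrist_arm_engagement)
            phase = 2 * np.pi * f * seg_t + b.phase
            gait = a * env * state  # stride pauses when the child stops
            dyn[:, 2] += 0.80 * gait * np.sin(phase)
            dyn[:, 0] += 0.45 * gait * np.sin(phase + np.pi / 3)
            dyn[:, 1] += 0.30 * gait * np.sin(phase + np.pi / 2)
        jitter = noise_rng.lognormal(0.0, cfg.bout_noise_jitter)
        sd_t = (p.noise_sd_g + extra_noise + p.move_sd_g * state) * noise_mult * jitter
        dyn += noise_rng.normal(0.0, 1.0, size=(m, 3)) * (sd_t * env)[:, None]
        if placement == "wrist" and b.true_class in ("SED", "LIGHT_AG"):
            _add_wrist_bursts(dyn, 0, m, cfg, noise_rng, amp_mult)
        if placement == "wrist" and b.true_class in ("LIGHT_AG", "MV_AG"):
            dyn *= _stillness_mask(m, cfg, noise_rng)[:, None]
        sig[i0:i1] += dyn
    return Recording(
        subject_id=log.subject_id,
        placement=placement,
        sample_rate_hz=cfg.rate_hz,
        start_time=SESSION_EPOCH,
        samples=sig,
    )


def _smooth_envelope(m: int, sigma: float, cfg: SimConfig, rng) -> np.ndarray:
    """Slowly varying lognormal intensity envelope with unit mean power.

    Gaussian knots every ``env_knot_s`` seconds, linearly interpolated, then
    exponentiated; sigma = 0 yields a flat envelope.
    """
    if sigma <= 0 or m < 2:
        return np.ones(m)
    knot_step = max(2, int(round(cfg.env_knot_s * cfg.rate_hz)))
    n_knots = max(2, m // knot_step + 2)
    knots = rng.normal(0.0, 1.0, n_knots)
    x = np.arange(m) / knot_step
    g = np.interp(x, np.arange(n_knots), knots)
    return np.exp(sigma * g - 0.5 * sigma * sigma)


def _telegraph_mask(m: int, on_s: float, off_s: float, rate: float, rng) -> np.ndarray:
    """Two-state moving/quiet process with exponential dwell times.

    Returns a 0/1 array; all ones when on_s <= 0 (no intermittency).
    """
    if on_s <= 0 or off_s <= 0:
        return np.ones(m)
    duty = on_s / (on_s + off_s)
    state = rng.random() < duty
    mask = np.empty(m)
    i = 0
    while i < m:
        dwell = max(1, int(rng.exponential(on_s if state else off_s) * rate))
        mask[i : i + dwell] = 1.0 if state else 0.0
        i += dwell
        state = not state
    return mask


def _stillness_mask(m: int, cfg: SimConfig, rng) -> np.ndarray:
    """Multiplicative gate for arm-stillness episodes inside an active bout.

    The wrist's dynamic content is suppressed to a near-sedentary residual
    during each episode; neighboring windows keep the bout's true intensity,
    which is exactly the ambiguity lag/lead features resolve.
    """
    rate = cfg.rate_hz
    mask = np.ones(m)
    n_eps = rng.poisson(cfg.wrist_still_rate * m / rate)
    for _ in range(n_eps):
        s = int(rng.uniform(0, m))
        e = min(m, s + max(1, int(rng.exponential(cfg.wrist_still_s) * rate)))
        mask[s:e] = 0.15
    return mask


def _add_wrist_bursts(sig, i0, i1, cfg: SimConfig, rng, amp_mult: float) -> None:
    """Short random-phase hand-movement bursts inside a quiet bout."""
    rate = cfg.rate_hz
    dur_s = (i1 - i0) / rate
    n_bursts = rng.poisson(cfg.wrist_burst_rate * dur_s)
    for _ in range(n_bursts):
        b_start = i0 + int(rng.uniform(0, i1 - i0))
        b_len = max(2, int(rng.exponential(cfg.wrist_burst_s) * rate))
        b_end = min(i1, b_start + b_len)
        if b_end <= b_start:
            continue
        k = b_end - b_start
        tt = np.arange(k) / rate
        f_b = rng.uniform(0.5, 4.0)
        phase = rng.uniform(0, 2 * np.pi)
        amp = cfg.wrist_burst_amp * amp_mult * rng.lognormal(0.0, 0.3)
        env = np.hanning(max(k, 2))[:k]
        burst = amp * env * np.sin(2 * np.pi * f_b * tt + phase)
        sig[b_start:b_end, 0] += burst
        sig[b_start:b_end, 1] += 0.7 * burst
        sig[b_start:b_end, 2] += 0.5 * burst


def make_session(cfg: SimConfig, subject_id: str) -> SimSession:
    log = simulate_bouts(cfg, subject_id)
    return SimSession(
        hip=synthesize_signal(log, cfg, "hip"),
        wrist=synthesize_signal(log, cfg, "wrist"),
        log=log,
    )


def make_cohort(cfg: SimConfig) -> list[SimSession]:
    """Independent subjects S01..Snn with subject-level random effects."""
    return [make_session(cfg, f"S{i + 1:02d}") for i in range(cfg.n_subjects)]


def cohort_tables(sessions: list[SimSession]):
    """Recordings dict and logs dict ready for build_feature_table."""
    recordings = {}
    logs = {}
    for s in sessions:
        recordings[(s.hip.subject_id, "hip")] = s.hip
        recordings[(s.wrist.subject_id, "wrist")] = s.wrist
        logs[s.log.subject_id] = s.log
    return recordings, logs
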