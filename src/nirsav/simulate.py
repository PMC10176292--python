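"""Synthetic infant fNIRS cohorts with known ground truth.

The generator emulates the block paradigm of the study this package analyses:
8 s audiovisual stimulation trials of two conditions (synchronous "bimodal"
versus "alternating" unimodal audiovisual speech), separated by baselines
jittered uniformly in 9-12 s, with 3 trials per condition in pseudo-random
order inside every 2-minute block.  Haemodynamic responses are gamma-kernel
convolved boxcars calibrated so the evoked response peaks 9 s after stimulus
onset; HbR is anticorrelated with HbO.  Physiological noise (cardiac,
respiratory, Mayer waves, drift, white), motion artifacts (channel spikes and
global baseline shifts, injected in optical density), missing channels and
per-trial looking-away behaviour reproduce the attrition structure that the
preprocessing rules act on.

Everything is seeded; a cohort is a pure function of its config.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from . import optics
from .montage import Montage, default_montage
from .recording import Event, RawRecording, STIM_CONDITIONS

STIM_DURATION_S = 8.0
BASELINE_JITTER_S = (9.0, 12.0)
BLOCK_S = 120.0
TRIALS_PER_CONDITION_PER_BLOCK = 3
EPOCH_PAD_S = 25.0  # trailing baseline so the last epoch fits the recording


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass
class HrfConfig:
    """Gamma-kernel HRF; tau is derived so the boxcar-convolved response
    peaks at ``peak_time_s`` (must exceed the stimulus duration)."""

    peak_time_s: float = 9.0
    shape: float = 6.0

    @property
    def tau(self) -> float:
        d = STIM_DURATION_S
        if self.peak_time_s <= d:
            raise ValueError("peak_time_s must exceed the 8 s stimulus duration")
        return d / ((self.shape - 1) * np.log(self.peak_time_s / (self.peak_time_s - d)))


@dataclass
class NoiseConfig:
    """Amplitudes in micromolar.  The three oscillatory bands deliberately
    straddle the 0.03-0.50 Hz analysis passband: cardiac (2 Hz, infant heart
    rate) and a slow drift fall outside it, Mayer waves (0.1 Hz) inside it."""

    cardiac_hz: float = 2.0
    cardiac_amp: float = 0.2
    respiratory_hz: float = 0.6
    respiratory_amp: float = 0.3
    mayer_hz: float = 0.1
    mayer_amp: float = 0.3
    drift_amp: float = 0.5
    white_sd: float = 0.3


@dataclass
class ArtifactConfig:
    """Motion artifacts injected in optical density.

    Spikes are channel-specific (a single optode decoupling); baseline shifts
    are global (whole-head movement) and apply to every channel.
    """

    spike_rate_per_min: float = 0.5
    shift_rate_per_min: float = 0.2
    spike_amp_od: float = 0.8
    shift_amp_od: float = 0.3
    spike_duration_s: float = 0.6
    shift_duration_s: float = 2.0


@dataclass
class AttritionConfig:
    p_channel_missing: float = 0.05
    looking_alpha: float = 8.0
    looking_beta: float = 2.0


@dataclass
class EffectSpec:
    """A condition effect planted on a set of channels.

    ``amplitude_um`` is the evoked peak amplitude in the alternating
    condition; the bimodal amplitude is ``amplitude_um`` scaled by the
    additivity gain (super -> larger bimodal response, sub -> smaller,
    linear -> equal, none -> no response at all).  HbO effects drive a
    coupled HbR response through the cohort's hbr_ratio; effects declared on
    HbR add to HbR alone.
    """

    channels: tuple[int, ...]
    amplitude_um: float
    additivity: str = "linear"  # super | sub | linear | none
    chromophore: str = "HbO"


@dataclass
class SimulationConfig:
    seed: int
    n_younger: int = 20
    n_older: int = 22
    n_pandemic_younger: int = 3
    n_pandemic_older: int = 7
    sampling_rate: float = 10.0
    session_length_s: float = 480.0
    hrf: HrfConfig = field(default_factory=HrfConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    attrition: AttritionConfig = field(default_factory=AttritionConfig)
    effects: list[EffectSpec] = field(default_factory=list)
    hbr_ratio: float = -0.3
    hbr_noise_scale: float = 0.5
    super_gain: float = 2.0
    sub_gain: float = 0.5
    dpf: float = optics.DPF_DEFAULT
    i0: float = 1.0

    def validate(self, montage: Montage) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        a = self.artifact
        if min(a.spike_rate_per_min, a.shift_rate_per_min) < 0:
            raise ValueError("artifact rates must be >= 0")
        if not 0 <= self.attrition.p_channel_missing <= 1:
            raise ValueError("p_channel_missing must be in [0, 1]")
        for eff in self.effects:
            if eff.additivity not in ("super", "sub", "linear", "none"):
                raise ValueError(f"bad additivity {eff.additivity!r}")
            if eff.chromophore not in ("HbO", "HbR"):
                raise ValueError(f"bad chromophore {eff.chromophore!r}")
            if not np.isfinite(eff.amplitude_um):
                raise ValueError("effect amplitudes must be finite")
            unknown = set(eff.channels) - set(montage.ids)
            if unknown:
                raise ValueError(f"effect channels {sorted(unknown)} not in montage")


@dataclass
class GroundTruth:
    """Per-participant generating truth, dimensionally consistent with the
    emitted recordings."""

    effect_amplitudes: dict[str, dict]  # pid -> {(channel,chrom,condition): uM}
    artifact_segments: dict[str, list]  # pid -> [(channel|None, t0, t1), ...]
    dropped_channels: dict[str, list[int]]
    looking: dict[str, list[float]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "effect_amplitudes": {
                pid: {f"{c}|{ch}|{cond}": a for (c, ch, cond), a in m.items()}
                for pid, m in self.effect_amplitudes.items()
            },
            "artifact_segments": self.artifact_segments,
            "dropped_channels": self.dropped_channels,
            "looking": self.looking,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# event schedule
# ---------------------------------------------------------------------------
def make_schedule(
    session_length_s: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[Event]:
    """Pseudo-random block schedule.

    Each 120 s block holds 3 trials per condition (8 s each) with no
    condition occurring three times in a row, alternating with baselines
    drawn uniformly from 9-12 s; leftover block time extends the final
    baseline of the block.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_blocks = int(session_length_s // BLOCK_S)
    if n_blocks < 1:
        raise ValueError("session must cover at least one 2-minute block")
    events: list[Event] = []
    tail_conditions: list[str] = []
    for b in range(n_blocks):
        t = b * BLOCK_S
        order = _condition_order(rng, tail_conditions)
        tail_conditions = order[-2:]
        baselines = rng.uniform(*BASELINE_JITTER_S, size=len(order))
        for cond, base in zip(order, baselines):
            events.append(Event("baseline", t, float(base)))
            t += float(base)
            events.append(Event(cond, t, STIM_DURATION_S))
            t += STIM_DURATION_S
        tail = (b + 1) * BLOCK_S - t
        if tail > 1e-9:
            events.append(Event("baseline", t, float(tail)))
    return events


def _condition_order(rng: np.random.Generator,
                     prev_tail: list[str] | None = None) -> list[str]:
    """3 + 3 trials in pseudo-random order, no condition three times in a row
    (including across the block boundary via ``prev_tail``)."""
    k = TRIALS_PER_CONDITION_PER_BLOCK
    pool = list(STIM_CONDITIONS) * k
    prev_tail = prev_tail or []
    while True:
        order = [pool[i] for i in rng.permutation(2 * k)]
        runs = max(sum(1 for _ in g)
                   for _, g in itertools.groupby(prev_tail + order))
        if runs < 3:
            return order


# ---------------------------------------------------------------------------
# haemodynamic response
# ---------------------------------------------------------------------------
def trial_response(t: np.ndarray, hrf: HrfConfig | None = None) -> np.ndarray:
    """Unit-peak evoked response at times ``t`` (s) after stimulus onset.

    Closed form: the gamma-kernel/boxcar convolution equals a difference of
    gamma CDFs, G(t) - G(t - 8), normalised by its value at the peak.
    """
    hrf = hrf or HrfConfig()
    g = stats.gamma(a=hrf.shape, scale=hrf.tau)
    raw = g.cdf(t) - g.cdf(t - STIM_DURATION_S)
    peak = g.cdf(hrf.peak_time_s) - g.cdf(hrf.peak_time_s - STIM_DURATION_S)
    return raw / peak


def _condition_regressors(
    events: list[Event], n_samples: int, fs: float, hrf: HrfConfig
) -> dict[str, np.ndarray]:
    t = np.arange(n_samples) / fs
    out = {}
    for cond in STIM_CONDITIONS:
        sig = np.zeros(n_samples)
        for e in events:
            if e.condition == cond:
                rel = t - e.onset_s
                m = rel > 0
                sig[m] += trial_response(rel[m], hrf)
        out[cond] = sig
    return out


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------
def forward_model(
    conc: np.ndarray,
    montage: Montage | None = None,
    dpf: float = optics.DPF_DEFAULT,
    wavelengths=optics.WAVELENGTHS_NM,
    i0: float = 1.0,
) -> np.ndarray:
    """Map HbO/HbR series (channels, 2, T) to raw intensities (channels, 2, T).

    The exact algebraic inverse of the pipeline's Beer-Lambert conversion
    followed by OD -> intensity, I = I0 * 10**(-dOD).
    """
    montage = montage or default_montage()
    sep = np.array([montage.channel(c).separation_cm for c in montage.ids])
    od = optics.concentration_to_od(conc, sep, dpf, wavelengths)
    return optics.od_to_intensity(od, np.full(od.shape[:-1], i0))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------
def _effect_amplitudes(
    cfg: SimulationConfig, montage: Montage
) -> dict[tuple[int, str, str], float]:
    gains = {"super": cfg.super_gain, "sub": cfg.sub_gain, "linear": 1.0, "none": 0.0}
    amps: dict[tuple[int, str, str], float] = {}
    for eff in cfg.effects:
        g = gains[eff.additivity]
        alt = eff.amplitude_um if eff.additivity != "none" else 0.0
        for c in eff.channels:
            amps[(c, eff.chromophore, "alternating")] = (
                amps.get((c, eff.chromophore, "alternating"), 0.0) + alt
            )
            amps[(c, eff.chromophore, "bimodal")] = (
                amps.get((c, eff.chromophore, "bimodal"), 0.0) + alt * g
            )
    return amps


def _physio_noise(
    rng: np.random.Generator, n_ch: int, n: int, fs: float, nz: NoiseConfig, scale: float
) -> np.ndarray:
    t = np.arange(n) / fs
    out = rng.normal(0.0, nz.white_sd * scale, size=(n_ch, n))
    for hz, amp in (
        (nz.cardiac_hz, nz.cardiac_amp),
        (nz.respiratory_hz, nz.respiratory_amp),
        (nz.mayer_hz, nz.mayer_amp),
        (0.01, nz.drift_amp),  # slow drift
    ):
        phase = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
        out += amp * scale * np.sin(2 * np.pi * hz * t[None, :] + phase)
    out += (nz.drift_amp * scale) * rng.normal(size=(n_ch, 1)) * (t[None, :] / t[-1])
    return out


def _artifact_od(
    rng: np.random.Generator,
    cfg: ArtifactConfig,
    n_ch: int,
    n: int,
    fs: float,
) -> tuple[np.ndarray, list]:
    """Additive OD artifact waveform (n_ch, n) and the true segment list."""
    dur_min = n / fs / 60.0
    wave = np.zeros((n_ch, n))
    segments: list[tuple[int | None, float, float]] = []
    t = np.arange(n) / fs
    n_spikes = rng.poisson(cfg.spike_rate_per_min * dur_min)
    for _ in range(n_spikes):
        ch = int(rng.integers(n_ch))
        t0 = rng.uniform(0, n / fs - cfg.spike_duration_s)
        width = cfg.spike_duration_s / 4.0
        amp = cfg.spike_amp_od * rng.choice([-1.0, 1.0])
        wave[ch] += amp * np.exp(-0.5 * ((t - t0 - 2 * width) / width) ** 2)
        segments.append((ch, float(t0), float(t0 + cfg.spike_duration_s)))
    n_shifts = rng.poisson(cfg.shift_rate_per_min * dur_min)
    for _ in range(n_shifts):
        t0 = rng.uniform(0, n / fs - cfg.shift_duration_s)
        t1 = t0 + cfg.shift_duration_s
        amp = cfg.shift_amp_od * rng.choice([-1.0, 1.0])
        wave[:, (t >= t0) & (t < t1)] += amp
        segments.append((None, float(t0), float(t1)))
    segments.sort(key=lambda s: s[1])
    return wave, segments


def simulate_recording(
    cfg: SimulationConfig,
    participant_id: str,
    age_group: str,
    rng: np.random.Generator,
    montage: Montage | None = None,
    tested_during_pandemic: bool = False,
):
    """One participant: returns (RawRecording, truth dict)."""
    montage = montage or default_montage()
    cfg.validate(montage)
    fs = cfg.sampling_rate
    n_ch = len(montage.ids)
    events = make_schedule(cfg.session_length_s, rng=rng)
    n = int(round((cfg.session_length_s + EPOCH_PAD_S) * fs))

    regressors = _condition_regressors(events, n, fs, cfg.hrf)
    amps = _effect_amplitudes(cfg, montage)
    hbo = np.zeros((n_ch, n))
    hbr = np.zeros((n_ch, n))
    for ci, cid in enumerate(montage.ids):
        for cond in STIM_CONDITIONS:
            a_o = amps.get((cid, "HbO", cond), 0.0)
            a_r = amps.get((cid, "HbR", cond), 0.0)
            if a_o:
                hbo[ci] += a_o * regressors[cond]
                hbr[ci] += cfg.hbr_ratio * a_o * regressors[cond]
            if a_r:
                hbr[ci] += a_r * regressors[cond]
    hbo += _physio_noise(rng, n_ch, n, fs, cfg.noise, 1.0)
    hbr += _physio_noise(rng, n_ch, n, fs, cfg.noise, cfg.hbr_noise_scale)
    conc = np.stack([hbo, hbr], axis=1)  # (n_ch, 2, n)

    intensity = forward_model(conc, montage, cfg.dpf, optics.WAVELENGTHS_NM, cfg.i0)
    art_wave, art_segments = _artifact_od(rng, cfg.artifact, n_ch, n, fs)
    intensity = intensity * 10.0 ** (-art_wave[:, None, :])

    dropped = np.flatnonzero(
        rng.random(n_ch) < cfg.attrition.p_channel_missing
    )
    intensity[dropped] *= 1e-4  # dead optode: intensity falls below the prune floor

    n_stim = len([e for e in events if e.condition in STIM_CONDITIONS])
    looking = rng.beta(cfg.attrition.looking_alpha, cfg.attrition.looking_beta, n_stim)

    rec = RawRecording(
        participant_id=participant_id,
        age_group=age_group,
        sampling_rate=fs,
        intensity=intensity,
        events=events,
        looking=looking,
        tested_during_pandemic=tested_during_pandemic,
    )
    truth = {
        "effects": {
            (cid, ch, cond): a for (cid, ch, cond), a in amps.items()
        },
        "artifact_segments": art_segments,
        "dropped_channels": [montage.ids[i] for i in dropped],
        "looking": looking.tolist(),
    }
    return rec, truth


def simulate_cohort(
    cfg: SimulationConfig, montage: Montage | None = None
) -> tuple[list[RawRecording], GroundTruth]:
    """Simulate both age groups of a cohort; deterministic in cfg.seed."""
    montage = montage or default_montage()
    cfg.validate(montage)
    groups = [("younger", cfg.n_younger, cfg.n_pandemic_younger),
              ("older", cfg.n_older, cfg.n_pandemic_older)]
    n_total = cfg.n_younger + cfg.n_older
    streams = np.random.SeedSequence(cfg.seed).spawn(n_total)
    recs: list[RawRecording] = []
    gt = GroundTruth({}, {}, {}, {})
    k = 0
    for age_group, n_grp, n_pand in groups:
        for i in range(n_grp):
            pid = f"{age_group[0]}{i + 1:03d}"
            rng = np.random.default_rng(streams[k])
            k += 1
            rec, truth = simulate_recording(
                cfg, pid, age_group, rng, montage,
                tested_during_pandemic=(i >= n_grp - n_pand),
            )
            recs.append(rec)
            gt.effect_amplitudes[pid] = truth["effects"]
            gt.artifact_segments[pid] = truth["artifact_segments"]
            gt.dropped_channels[pid] = truth["dropped_channels"]
            gt.looking[pid] = truth["looking"]
    return recs, gt


# ---------------------------------------------------------------------------
# window-mean level nulls (for large calibration studies)
# ---------------------------------------------------------------------------
def simulate_null_window_means(
    n_participants: int,
    seed: int | np.random.Generator,
    montage: Montage | None = None,
    age_group: str = "younger",
    noise_sd: float = 1.0,
    n_trials: int = 6,
):
    """A null cohort expressed directly as a window-means table.

    Under the no-effect null the participant-level window means are
    exchangeable noise across conditions; this generator draws them i.i.d.
    normal, which lets large replicate counts (hundreds of cohorts) feed the
    statistical stages without paying for signal-level synthesis each time.
    """
    import pandas as pd

    from .preprocess import WINDOWS

    montage = montage or default_montage()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        pid = f"{age_group[0]}{i + 1:03d}"
        for cond in STIM_CONDITIONS:
            for ch in montage.ids:
                for chrom in ("HbO", "HbR"):
                    for win in WINDOWS:
                        rows.append(
                            (pid, age_group, cond, ch, chrom, win,
                             rng.normal(0.0, noise_sd), n_trials)
                        )
    return pd.DataFrame(
        rows,
        columns=["participant", "age_group", "condition", "channel",
                 "chromophore", "window", "mean", "n_trials"],
    )


def config_to_json(cfg: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(cfg), indent=1, default=list))


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key, cls in (("hrf", HrfConfig), ("noise", NoiseConfig),
                     ("artifact", ArtifactConfig), ("attrition", AttritionConfig)):
        if key in d and isinstance(d[key], dict):
            d[key] = cls(**d[key])
    if "effects" in d:
        d["effects"] = [
            EffectSpec(**{**e, "channels": tuple(e["channels"])})
            if isinstance(e, dict) else e
            for e in d["effects"]
        ]
    return SimulationConfig(**d)
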