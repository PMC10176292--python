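"""Signal-level preprocessing: pruning, motion correction, filtering,
Beer-Lambert conversion, epoching and trial/channel/participant exclusion.

Stage order is fixed: channel pruning -> optical density -> motion artifact
correction (detect, wavelet, spline) -> exclusion bookkeeping -> band-pass
filtering -> haemoglobin conversion -> epoching -> window means.  The
exclusion rules implement the study's inclusion criteria:

* channels with mean raw intensity outside [0.001, 10] are pruned;
* channels with motion artifacts on more than 3 trials are excluded;
* trials containing, or preceded by less than 5 s, a motion artifact are
  rejected; trials where the infant looked at the screen less than 40% of
  the time are rejected;
* participants need at least 31 of 46 usable channels and at least 3
  surviving trials per condition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import interpolate, signal

from . import optics
from .montage import Montage, default_montage
from .recording import RawRecording, STIM_CONDITIONS

log = logging.getLogger(__name__)

CHROMOPHORES = ("HbO", "HbR")
WINDOWS = ("baseline", "W1", "W2")
#: Analysis windows in seconds relative to stimulus onset, half-open.
WINDOW_BOUNDS = {"baseline": (-5.0, 0.0), "W1": (5.0, 10.0), "W2": (10.0, 15.0)}
WM_COLUMNS = ["participant", "age_group", "condition", "channel", "chromophore",
              "window", "mean", "n_trials"]


@dataclass
class PreprocessParams:
    intensity_lo: float = 0.001
    intensity_hi: float = 10.0
    wavelet_iqr: float = 0.8
    wavelet_name: str = "db2"
    wavelet_max_level: int = 4  # detail bands ~0.3-5 Hz at 10 Hz sampling
    spline_smoothing: float = 0.99
    motion_window_s: float = 1.0
    motion_amp_thresh: float = 0.4  # OD peak-to-peak within a window
    motion_std_thresh: float = 15.0  # x median window SD
    motion_mask_pad_s: float = 1.0
    band_hz: tuple[float, float] = (0.03, 0.50)
    filter_order: int = 3
    dpf: float = optics.DPF_DEFAULT
    epoch_window_s: tuple[float, float] = (-5.0, 20.0)
    max_artifact_trials: int = 3
    min_channels: int = 31
    min_trials_per_condition: int = 3
    max_lookaway: float = 0.60
    pre_trial_guard_s: float = 5.0

    def validate(self, sampling_rate: float) -> None:
        if not 0 < self.intensity_lo < self.intensity_hi:
            raise ValueError("need 0 < intensity_lo < intensity_hi")
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError("band edges must satisfy 0 < low < high")
        if hi >= sampling_rate / 2:
            raise ValueError("band high edge must lie below Nyquist")
        if self.dpf <= 0:
            raise ValueError("dpf must be positive")
        e0, e1 = self.epoch_window_s
        for w0, w1 in WINDOW_BOUNDS.values():
            if w0 < e0 or w1 > e1:
                raise ValueError("analysis windows must lie within the epoch")


@dataclass
class EpochSet:
    """Per-trial concentration segments with rejection flags.

    values: (n_trials, n_channels, 2 chromophores, n_samples) in micromolar;
    time axis spans the epoch window around onset.  Rejection is monotone:
    flagged trials/channels contribute to nothing downstream.
    """

    participant: str
    age_group: str
    times: np.ndarray
    conditions: list[str]
    values: np.ndarray
    channel_ids: list[int]
    looking_rejected: np.ndarray  # (n_trials,)
    motion_rejected: np.ndarray  # (n_trials, n_channels)
    channel_excluded: np.ndarray  # (n_channels,) incl. pruned channels
    tested_during_pandemic: bool = False

    def trial_ok(self) -> np.ndarray:
        """Participant-level trial survival: not looking-rejected and free of
        motion artifacts on every retained channel."""
        keep = ~self.channel_excluded
        motion_any = self.motion_rejected[:, keep].any(axis=1)
        return ~self.looking_rejected & ~motion_any

    def surviving_per_condition(self) -> dict[str, int]:
        ok = self.trial_ok()
        conds = np.asarray(self.conditions)
        return {c: int(np.sum(ok & (conds == c))) for c in STIM_CONDITIONS}


@dataclass
class ParticipantVerdict:
    participant: str
    included: bool
    n_usable_channels: int
    surviving_trials: dict[str, int]
    reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# stage 1: channel pruning
# ---------------------------------------------------------------------------
def prune_channels(raw: RawRecording, params: PreprocessParams) -> np.ndarray:
    """Usability mask: True where the channel-mean raw intensity lies inside
    [intensity_lo, intensity_hi] at both wavelengths."""
    means = raw.intensity.mean(axis=2)  # (n_channels, 2)
    ok = (means >= params.intensity_lo) & (means <= params.intensity_hi)
    mask = ok.all(axis=1)
    raw.channel_usable = mask
    return mask


# ---------------------------------------------------------------------------
# stage 2: optical density
# ---------------------------------------------------------------------------
def intensity_to_od(raw: RawRecording, usable: np.ndarray | None = None) -> np.ndarray:
    """dOD(t) = -log10(I/I_mean) per channel x wavelength.

    Unusable channels are carried through as zeros so array shapes stay
    aligned with the montage; they are excluded downstream anyway.
    """
    usable = np.ones(raw.n_channels, bool) if usable is None else usable
    od = np.zeros_like(raw.intensity)
    if usable.any():
        od[usable] = optics.intensity_to_od(raw.intensity[usable])
    return od


# ---------------------------------------------------------------------------
# stage 3: motion artifact correction
# ---------------------------------------------------------------------------
def detect_motion(
    od: np.ndarray, fs: float, params: PreprocessParams
) -> list[tuple[int | None, float, float]]:
    """Sliding-window artifact detection on OD.

    A window is flagged when its peak-to-peak amplitude exceeds
    ``motion_amp_thresh`` or its SD exceeds ``motion_std_thresh`` times the
    channel's median window SD.  Flagged windows are padded by
    ``motion_mask_pad_s`` and merged into per-channel segments.
    """
    n_ch, _, n = od.shape
    win = max(2, int(round(params.motion_window_s * fs)))
    n_win = n // win
    if n_win < 2:
        return []
    segments: list[tuple[int | None, float, float]] = []
    for ci in range(n_ch):
        x = od[ci, :, : n_win * win].reshape(2, n_win, win)
        ptp = x.max(axis=2) - x.min(axis=2)  # (2, n_win)
        sd = x.std(axis=2)
        med_sd = np.median(sd, axis=1, keepdims=True)
        bad = (ptp > params.motion_amp_thresh) | (
            sd > params.motion_std_thresh * np.maximum(med_sd, 1e-12)
        )
        bad = bad.any(axis=0)
        if not bad.any():
            continue
        idx = np.flatnonzero(bad)
        pad = params.motion_mask_pad_s
        t0s = idx * win / fs - pad
        t1s = (idx + 1) * win / fs + pad
        start, end = t0s[0], t1s[0]
        for t0, t1 in zip(t0s[1:], t1s[1:]):
            if t0 <= end:
                end = max(end, t1)
            else:
                segments.append((ci, max(0.0, start), min(n / fs, end)))
                start, end = t0, t1
        segments.append((ci, max(0.0, start), min(n / fs, end)))
    return segments


def _wavelet_despike(x: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Zero detail coefficients far from their level median (IQR criterion).

    The decomposition depth is capped so that the despiked detail bands stay
    above the evoked-response band: motion spikes are sub-second events,
    while zeroing outlier coefficients in the slow levels would clip the
    haemodynamic response itself (amplitude-dependently, i.e. it would bias
    condition differences).
    """
    wav = pywt.Wavelet(params.wavelet_name)
    max_level = min(pywt.dwt_max_level(len(x), wav.dec_len),
                    params.wavelet_max_level)
    if max_level < 1:
        return x.copy()
    coeffs = pywt.wavedec(x, wav, level=max_level)
    for j in range(1, len(coeffs)):
        c = coeffs[j]
        med = np.median(c)
        q75, q25 = np.percentile(c, [75, 25])
        iqr = q75 - q25
        if iqr <= 0:
            continue
        out = np.abs(c - med) > params.wavelet_iqr * iqr
        coeffs[j] = np.where(out, 0.0, c)
    rec = pywt.waverec(coeffs, wav)
    return rec[: len(x)]


def _spline_correct(
    x: np.ndarray, fs: float, segments: list[tuple[float, float]],
    params: PreprocessParams,
) -> np.ndarray:
    """Within detected segments, replace the smoothing-spline trend by the
    straight line joining the trend values at the segment boundaries."""
    y = x.copy()
    n = len(y)
    p = params.spline_smoothing
    lam = (1.0 - p) / max(p, 1e-9)
    for t0, t1 in segments:
        i0, i1 = max(0, int(t0 * fs)), min(n, int(np.ceil(t1 * fs)))
        if i1 - i0 < 8:
            continue
        idx = np.arange(i0, i1)
        try:
            sp = interpolate.make_smoothing_spline(idx.astype(float), y[idx], lam=lam)
            trend = sp(idx.astype(float))
        except Exception:  # degenerate segment
            trend = np.full(i1 - i0, y[idx].mean())
        level = np.linspace(trend[0], trend[-1], i1 - i0)
        y[idx] = y[idx] - trend + level
    return y


def correct_motion(
    od: np.ndarray, fs: float, params: PreprocessParams,
    usable: np.ndarray | None = None,
) -> tuple[np.ndarray, list[tuple[int | None, float, float]]]:
    """Three-stage motion correction on OD: detect, wavelet, spline.

    Returns the corrected OD and the detected artifact segment list
    (channel index, t0, t1) for downstream trial rejection.
    """
    n_ch = od.shape[0]
    usable = np.ones(n_ch, bool) if usable is None else usable
    segments = detect_motion(od, fs, params)
    out = od.copy()
    min_len = pywt.Wavelet(params.wavelet_name).dec_len
    for ci in range(n_ch):
        if not usable[ci]:
            continue
        segs_c = [(t0, t1) for ch, t0, t1 in segments if ch in (ci, None)]
        for wi in range(2):
            x = out[ci, wi]
            if len(x) >= 2 * min_len:
                x = _wavelet_despike(x, params)
            else:
                log.warning("channel %d: series too short for wavelet stage; "
                            "spline-only correction", ci)
            out[ci, wi] = _spline_correct(x, fs, segs_c, params)
    return out, segments


# ---------------------------------------------------------------------------
# stage 4: band-pass filter
# ---------------------------------------------------------------------------
def bandpass(series: np.ndarray, fs: float, params: PreprocessParams) -> np.ndarray:
    """Zero-phase Butterworth band-pass applied forward-backward along the
    last axis."""
    lo, hi = params.band_hz
    if hi >= fs / 2:
        raise ValueError("band high edge must lie below Nyquist")
    if fs <= 2 * hi:
        raise ValueError("sampling rate too low for the requested band")
    sos = signal.butter(params.filter_order, [lo, hi], btype="bandpass",
                        fs=fs, output="sos")
    return signal.sosfiltfilt(sos, series, axis=-1)


# ---------------------------------------------------------------------------
# stage 5: haemoglobin conversion
# ---------------------------------------------------------------------------
def od_to_concentration(
    od: np.ndarray, montage: Montage, params: PreprocessParams
) -> np.ndarray:
    """Modified Beer-Lambert per channel; (n_ch, 2 wl, T) -> (n_ch, 2 chrom, T)."""
    sep = np.array([montage.channel(c).separation_cm for c in montage.ids])
    return optics.od_to_concentration(od, sep, params.dpf)


# ---------------------------------------------------------------------------
# stage 6: epoching and exclusion rules
# ---------------------------------------------------------------------------
def _intersects(t0: float, t1: float, a: float, b: float) -> bool:
    return t0 < b and t1 > a


def epoch_and_reject(
    conc: np.ndarray,
    raw: RawRecording,
    artifacts: list[tuple[int | None, float, float]],
    usable: np.ndarray,
    params: PreprocessParams,
    montage: Montage | None = None,
) -> tuple[EpochSet, ParticipantVerdict]:
    """Cut [-5, 20) s epochs and apply the exclusion rules.

    ``artifacts`` is a list of (channel index or None for global, t0, t1)
    segments - either detected by :func:`correct_motion` or supplied
    externally (e.g. the simulator's ground truth, or manual coding).
    """
    montage = montage or default_montage()
    fs = raw.sampling_rate
    e0, e1 = params.epoch_window_s
    n_ep = int(round((e1 - e0) * fs))
    times = e0 + np.arange(n_ep) / fs
    stim = raw.stim_events()

    trials, conds, kept_looking, onsets = [], [], [], []
    for k, ev in enumerate(stim):
        i0 = int(round((ev.onset_s + e0) * fs))
        if i0 < 0 or i0 + n_ep > conc.shape[-1]:
            warnings.warn(
                f"{raw.participant_id}: trial at {ev.onset_s:.1f}s extends past "
                "the recording and was dropped"
            )
            continue
        trials.append(conc[:, :, i0:i0 + n_ep])
        conds.append(ev.condition)
        kept_looking.append(raw.looking[k])
        onsets.append(ev.onset_s)
    values = (np.stack(trials) if trials
              else np.empty((0, conc.shape[0], 2, n_ep)))
    n_trials, n_ch = values.shape[0], conc.shape[0]

    # looking rule: reject when on-screen time is strictly below 40%
    looking_rej = np.array(
        [lk < 1.0 - params.max_lookaway for lk in kept_looking], dtype=bool
    )

    # motion rule: artifact intersecting [onset - guard, onset + e1)
    motion_rej = np.zeros((n_trials, n_ch), dtype=bool)
    for ch, t0, t1 in artifacts:
        for ti, onset in enumerate(onsets):
            if _intersects(t0, t1, onset - params.pre_trial_guard_s, onset + e1):
                if ch is None:
                    motion_rej[ti, :] = True
                else:
                    motion_rej[ti, ch] = True

    # channel rule: > max_artifact_trials motion-hit trials excludes the channel
    excluded = ~usable | (motion_rej.sum(axis=0) > params.max_artifact_trials)

    epochs = EpochSet(
        participant=raw.participant_id,
        age_group=raw.age_group,
        times=times,
        conditions=conds,
        values=values,
        channel_ids=list(montage.ids),
        looking_rejected=looking_rej,
        motion_rejected=motion_rej,
        channel_excluded=excluded,
        tested_during_pandemic=raw.tested_during_pandemic,
    )

    n_usable = int(np.sum(~excluded))
    surviving = epochs.surviving_per_condition()
    reasons = []
    if n_usable < params.min_channels:
        reasons.append(f"usable channels {n_usable} < {params.min_channels}")
    lacking = {c: n for c, n in surviving.items()
               if n < params.min_trials_per_condition}
    if lacking:
        reasons.append(
            "surviving trials below minimum: "
            + ", ".join(f"{c}={n}" for c, n in sorted(lacking.items()))
        )
    verdict = ParticipantVerdict(
        participant=raw.participant_id,
        included=not reasons,
        n_usable_channels=n_usable,
        surviving_trials=surviving,
        reasons=reasons,
    )
    return epochs, verdict


# ---------------------------------------------------------------------------
# stage 7: window means
# ---------------------------------------------------------------------------
def window_means(epochs: EpochSet, params: PreprocessParams) -> pd.DataFrame:
    """Participant x condition x channel x chromophore x window means.

    Per trial, the temporal mean inside the window; then the mean over
    surviving trials.  Keys with no surviving trials yield no row.
    """
    rows = []
    ok_trial = ~epochs.looking_rejected
    conds = np.asarray(epochs.conditions)
    for win in WINDOWS:
        w0, w1 = WINDOW_BOUNDS[win]
        m = (epochs.times >= w0) & (epochs.times < w1)
        per_trial = epochs.values[:, :, :, m].mean(axis=3)  # (trial, ch, chrom)
        for ci, cid in enumerate(epochs.channel_ids):
            if epochs.channel_excluded[ci]:
                continue
            keep = ok_trial & ~epochs.motion_rejected[:, ci]
            for cond in STIM_CONDITIONS:
                sel = keep & (conds == cond)
                if not sel.any():
                    continue
                for hi, chrom in enumerate(CHROMOPHORES):
                    rows.append((
                        epochs.participant, epochs.age_group, cond, cid, chrom,
                        win, float(per_trial[sel, ci, hi].mean()), int(sel.sum()),
                    ))
    return pd.DataFrame(rows, columns=WM_COLUMNS)


# ---------------------------------------------------------------------------
# QC metric
# ---------------------------------------------------------------------------
def peak_latency(epochs: EpochSet) -> float:
    """Latency (s) of the peak |response| in 0-20 s post-onset, averaged over
    channels, chromophores and surviving trials.  QC only."""
    ok = epochs.trial_ok()
    if not ok.any():
        return float("nan")
    keep = ~epochs.channel_excluded
    mean_resp = np.abs(epochs.values[ok][:, keep].mean(axis=(0, 1, 2)))
    post = epochs.times >= 0
    return float(epochs.times[post][np.argmax(mean_resp[post])])


# ---------------------------------------------------------------------------
# full per-participant pipeline
# ---------------------------------------------------------------------------
def preprocess_recording(
    raw: RawRecording,
    params: PreprocessParams | None = None,
    montage: Montage | None = None,
    artifacts: list[tuple[int | None, float, float]] | None = None,
) -> tuple[EpochSet, ParticipantVerdict, pd.DataFrame]:
    """Run the full stage order on one recording.

    If ``artifacts`` is given (e.g. ground truth or manual coding) it
    replaces the detected segment list for the exclusion rules; the signal
    correction stages still run.
    """
    params = params or PreprocessParams()
    params.validate(raw.sampling_rate)
    montage = montage or default_montage()
    usable = prune_channels(raw, params)
    od = intensity_to_od(raw, usable)
    od, detected = correct_motion(od, raw.sampling_rate, params, usable)
    segments = detected if artifacts is None else artifacts
    od = bandpass(od, raw.sampling_rate, params)
    conc = od_to_concentration(od, montage, params)
    epochs, verdict = epoch_and_reject(conc, raw, segments, usable, params, montage)
    table = window_means(epochs, params) if verdict.included else pd.DataFrame(
        columns=WM_COLUMNS
    )
    return epochs, verdict, table


def preprocess_cohort(
    recordings: list[RawRecording],
    params: PreprocessParams | None = None,
    montage: Montage | None = None,
    artifact_lists: dict[str, list] | None = None,
) -> tuple[pd.DataFrame, list[ParticipantVerdict]]:
    """Preprocess every recording; concatenated window means of included
    participants plus all verdicts."""
    tables, verdicts = [], []
    for rec in recordings:
        arts = None if artifact_lists is None else artifact_lists.get(
            rec.participant_id)
        _, verdict, table = preprocess_recording(rec, params, montage, arts)
        verdicts.append(verdict)
        if verdict.included:
            tables.append(table)
    table = (pd.concat(tables, ignore_index=True) if tables
             else pd.DataFrame(columns=WM_COLUMNS))
    return table, verdicts
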