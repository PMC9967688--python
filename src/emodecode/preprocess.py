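"""Turn trial recordings into per-band windowed observation tensors.

The pipeline stages implemented here: re-referencing to the temporal
electrodes, averaging channels into ten regions of interest (ROIs),
broadband and sub-band zero-phase FIR filtering, extraction of eight 3 s
analysis windows per 30 s segment, and trial-level exclusion bookkeeping
for segments with missing ROIs.

All filters are windowed-sinc (Hamming) linear-phase FIR applied with the
group delay compensated (single-pass zero phase), the standard approach in
M/EEG analysis.  Using the same transition width for all five sub-band
filters makes adjacent filters complementary at shared band edges, so the
five sub-band signals sum back to the broadband content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "BROADBAND",
    "MontageMap",
    "DEFAULT_MONTAGE",
    "ObservationSet",
    "average_channels_to_rois",
    "rereference",
    "design_fir",
    "bandpass",
    "extract_windows",
    "build_observation_set",
    "WINDOW_START_S",
    "N_WINDOWS",
    "WINDOW_DURATION_S",
]

# Analysis windows: eight non-overlapping 3 s windows covering [3, 27) s.
WINDOW_START_S = 3.0
N_WINDOWS = 8
WINDOW_DURATION_S = 3.0


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with half-open range [low, high) Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges {self.low}-{self.high} Hz")


#: The five canonical EEG sub-bands.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)

#: Broadband analysis range applied before any sub-band work.
BROADBAND = BandDefinition("broadband", 0.5, 45.0)


@dataclass(frozen=True)
class MontageMap:
    """Assignment of 10-20 electrodes to the ten scalp ROIs.

    ROI ids are 1-based.  The reference electrodes are excluded from ROI
    membership.
    """

    rois: dict[int, tuple[str, ...]]
    reference: tuple[str, ...] = ("T7", "T8")

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for roi, members in self.rois.items():
            if len(members) == 0:
                raise ValueError(f"ROI {roi} has no member electrodes")
            for ch in members:
                if ch in seen:
                    raise ValueError(f"electrode {ch} assigned to two ROIs")
                if ch in self.reference:
                    raise ValueError(f"reference electrode {ch} inside ROI {roi}")
                seen.add(ch)

    @property
    def n_rois(self) -> int:
        return len(self.rois)


# 32-channel cap grouped into the ten ROIs: mid-frontal left/right (1, 2),
# left/right frontal (3, 4), centro-parietal left/right (5, 6),
# parieto-occipital left/right (7, 8), fronto-central (9) and central
# parieto-occipital (10).  T7/T8 serve as the reference pair.
DEFAULT_MONTAGE = MontageMap(
    rois={
        1: ("Fp1", "AF3"),
        2: ("Fp2", "AF4"),
        3: ("F7", "F3", "FC5"),
        4: ("F8", "F4", "FC6"),
        5: ("C3", "CP5", "CP1"),
        6: ("C4", "CP6", "CP2"),
        7: ("P7", "P3", "PO3", "O1"),
        8: ("P8", "P4", "PO4", "O2"),
        9: ("Fz", "FC1", "FC2"),
        10: ("Cz", "Pz", "Oz"),
    }
)


def rereference(
    channel_signals: np.ndarray,
    channel_names: list[str],
    reference_names: tuple[str, str] = ("T7", "T8"),
) -> np.ndarray:
    """Subtract the instantaneous mean of the reference channels.

    Parameters
    ----------
    channel_signals : (n_channels, n_samples) array
    channel_names : channel name per row
    reference_names : names of the two reference electrodes
    """
    x = np.asarray(channel_signals, dtype=float)
    idx = []
    for name in reference_names:
        if name not in channel_names:
            raise ValueError(f"reference channel {name!r} not present")
        idx.append(channel_names.index(name))
    ref = x[idx].mean(axis=0, keepdims=True)
    return x - ref


def average_channels_to_rois(
    channel_signals: np.ndarray,
    channel_names: list[str],
    montage: MontageMap = DEFAULT_MONTAGE,
    available: set[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average member channels into ROI signals.

    Returns ``(roi_signals, missing)`` where ``roi_signals`` is
    (n_rois, n_samples) — rows in ascending ROI id order — and ``missing``
    is a boolean vector flagging ROIs with zero available members (their
    rows are NaN).
    """
    x = np.asarray(channel_signals, dtype=float)
    if x.ndim != 2 or x.shape[0] != len(channel_names):
        raise ValueError("channel_signals rows must match channel_names")
    usable = set(channel_names) if available is None else (set(channel_names) & set(available))
    roi_ids = sorted(montage.rois)
    if not any(ch in usable for rid in roi_ids for ch in montage.rois[rid]):
        raise ValueError("no montage channel resolvable in the recording")
    out = np.full((len(roi_ids), x.shape[1]), np.nan)
    missing = np.zeros(len(roi_ids), dtype=bool)
    for k, rid in enumerate(roi_ids):
        rows = [channel_names.index(ch) for ch in montage.rois[rid] if ch in usable]
        if rows:
            out[k] = x[rows].mean(axis=0)
        else:
            missing[k] = True
    return out, missing


def design_fir(
    low: float, high: float, rate: float, transition: float | None = None
) -> np.ndarray:
    """Design a linear-phase windowed-sinc (Hamming) bandpass FIR filter.

    ``transition`` is the transition bandwidth in Hz; by default
    ``min(2, low)`` so that narrow low edges keep their selectivity.
    """
    if not 0 < low < high < rate / 2:
        raise ValueError(f"invalid band edges {low}-{high} Hz at rate {rate} Hz")
    if transition is None:
        transition = min(2.0, low)
    # Hamming main-lobe width: numtaps ~ 3.3 * fs / transition, forced odd.
    numtaps = int(np.ceil(3.3 * rate / transition)) // 2 * 2 + 1
    return sps.firwin(numtaps, [low, high], pass_zero=False, window="hamming", fs=rate)


def _zero_phase_apply(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR filter with zero phase (centered convolution).

    Edges are padded by odd reflection to suppress filter transients;
    output length equals input length.
    """
    n = x.shape[-1]
    pad = min(n - 1, len(taps) // 2)
    left = 2 * x[..., :1] - x[..., 1 : pad + 1][..., ::-1]
    right = 2 * x[..., -1:] - x[..., -pad - 1 : -1][..., ::-1]
    xp = np.concatenate([left, x, right], axis=-1)
    h = taps.reshape((1,) * (x.ndim - 1) + (-1,))
    y = sps.oaconvolve(xp, h, mode="same", axes=-1)
    return y[..., pad : pad + n]


def bandpass(
    signal: np.ndarray,
    low: float,
    high: float,
    rate: float,
    transition: float | None = None,
) -> np.ndarray:
    """Zero-phase FIR bandpass over the last axis; length preserving."""
    taps = design_fir(low, high, rate, transition)
    return _zero_phase_apply(np.asarray(signal, dtype=float), taps)


def extract_windows(segment: np.ndarray, rate: float) -> np.ndarray:
    """Cut eight 3 s non-overlapping windows covering [3, 27) s.

    Window ``k`` covers samples ``[(3 + 3k) * rate, (6 + 3k) * rate)`` for
    ``k = 0..7``.  Accepts arrays with any leading dimensions; the windowed
    axis must hold at least 27 s of samples.
    """
    x = np.asarray(segment)
    start = int(round(WINDOW_START_S * rate))
    wlen = int(round(WINDOW_DURATION_S * rate))
    stop = start + N_WINDOWS * wlen
    if x.shape[-1] < stop:
        raise ValueError(
            f"segment too short: {x.shape[-1]} samples < {stop} required "
            f"({(WINDOW_START_S + N_WINDOWS * WINDOW_DURATION_S):g} s at {rate:g} Hz)"
        )
    block = x[..., start:stop]
    return block.reshape(x.shape[:-1] + (N_WINDOWS, wlen))


@dataclass
class ObservationSet:
    """Per-band windowed tensors for emotional and baseline segments.

    ``emotional[band]`` and ``baseline[band]`` are
    (n_obs, n_rois, n_windows, window_samples) arrays with identical row
    order; the key ``"broadband"`` holds the 0.5–45 Hz filtered windows
    used for relative power and spectral estimation.  ``metadata`` has one
    row per observation (participant, session, trial, condition).
    """

    emotional: dict[str, np.ndarray]
    baseline: dict[str, np.ndarray]
    metadata: pd.DataFrame
    sampling_rate: float
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["participant", "session", "trial", "reason"])
    )

    @property
    def n_obs(self) -> int:
        return len(self.metadata)

    @property
    def band_names(self) -> list[str]:
        return [b for b in self.emotional if b != "broadband"]

    def validate(self) -> None:
        for key, emo in self.emotional.items():
            base = self.baseline[key]
            if emo.shape != base.shape:
                raise ValueError(f"band {key}: emotional/baseline shape mismatch")
            if emo.shape[0] != self.n_obs:
                raise ValueError(f"band {key}: rows do not match metadata")


def _trial_missing_rois(trial) -> list[int]:
    """1-based ids of ROIs that are not finite in either segment."""
    bad = ~(
        np.isfinite(trial.baseline_signal).all(axis=1)
        & np.isfinite(trial.emotional_signal).all(axis=1)
    )
    return [i + 1 for i in np.nonzero(bad)[0]]


def build_observation_set(
    trials: list,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    rate: float | None = None,
    include_band_tensors: bool = True,
    chunk_size: int = 32,
    dtype=np.float32,
) -> ObservationSet:
    """Filter, window and stack a list of trial recordings.

    Trials with any ROI missing (non-finite) in either segment are
    excluded and logged.  Signals are broadband filtered (0.5–45 Hz),
    then each sub-band is filtered from the broadband signal; both are
    windowed into the eight 3 s analysis windows.  Set
    ``include_band_tensors=False`` to keep only the broadband tensors
    (sufficient for power denominators and coherence features).
    """
    if not trials:
        raise ValueError("no trials supplied")
    rate = float(rate if rate is not None else trials[0].sampling_rate)

    kept, excl = [], []
    for t in trials:
        missing = _trial_missing_rois(t)
        if missing:
            excl.append(
                {
                    "participant": t.participant,
                    "session": t.session,
                    "trial": t.trial_index,
                    "reason": "missing ROI(s) " + ",".join(map(str, missing)),
                }
            )
        else:
            kept.append(t)
    if not kept:
        raise ValueError("all trials excluded (every trial has a missing ROI)")

    meta = pd.DataFrame(
        {
            "participant": [t.participant for t in kept],
            "session": [t.session for t in kept],
            "trial": [t.trial_index for t in kept],
            "condition": [t.condition for t in kept],
        }
    )

    # Uniform transition width across sub-band filters keeps adjacent
    # filters complementary at shared edges (band-partition property).
    sub_transition = min(2.0, min(b.low for b in bands))
    bb_taps = design_fir(BROADBAND.low, BROADBAND.high, rate)
    band_taps = {b.name: design_fir(b.low, b.high, rate, sub_transition) for b in bands}

    keys = ["broadband"] + ([b.name for b in bands] if include_band_tensors else [])
    n_kept = len(kept)
    n_rois = kept[0].emotional_signal.shape[0]
    wlen = int(round(WINDOW_DURATION_S * rate))
    shape = (n_kept, n_rois, N_WINDOWS, wlen)
    # preallocated outputs, filled chunk-wise to bound peak memory
    emotional = {k: np.empty(shape, dtype=dtype) for k in keys}
    baseline = {k: np.empty(shape, dtype=dtype) for k in keys}

    for lo in range(0, n_kept, chunk_size):
        batch = kept[lo : lo + chunk_size]
        sl = slice(lo, lo + len(batch))
        for side, store in (("emotional_signal", emotional), ("baseline_signal", baseline)):
            raw = np.stack([np.asarray(getattr(t, side), dtype=float) for t in batch])
            broad = _zero_phase_apply(raw, bb_taps)
            store["broadband"][sl] = extract_windows(broad, rate)
            if include_band_tensors:
                for name, taps in band_taps.items():
                    store[name][sl] = extract_windows(_zero_phase_apply(broad, taps), rate)

    obs = ObservationSet(
        emotional=emotional,
        baseline=baseline,
        metadata=meta,
        sampling_rate=rate,
        exclusions=pd.DataFrame(excl, columns=["participant", "session", "trial", "reason"]),
    )
    obs.validate()
    return obs


def read_edf_channels(path) -> tuple[np.ndarray, list[str], float]:
    """Read an EDF recording into (channels x samples, names, rate).

    Thin wrapper over :mod:`mne`'s EDF reader for the real-data path.
    """
    import mne  # deferred: only needed for EDF input

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data(), list(raw.ch_names), float(raw.info["sfreq"])
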