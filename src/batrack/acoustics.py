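"""Microphone-array geometry, multichannel recordings, call detection and
time-of-arrival-difference (TOAD) estimation.

The array is an overdetermined 8-microphone T-frame with a designated
reference microphone (the top one).  A source position in 3D is recoverable
from four arrival times; the four extra channels provide the redundancy used
for residual-based error assessment downstream.

TOAD sign convention, used everywhere in this package:

    toad_i = t_arrival(mic_i) - t_arrival(reference)

so a microphone closer to the source than the reference has a negative TOAD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import butter, correlate, sosfiltfilt

__all__ = [
    "MicArray",
    "MultiChannelRecording",
    "CallDetection",
    "ToadSet",
    "build_default_array",
    "detect_calls",
    "estimate_toads",
    "read_wav",
    "write_wav",
    "load_array_geometry",
    "save_array_geometry",
]

#: default field sampling rate, Hz
DEFAULT_SAMPLE_RATE = 300_000
#: default cross-correlation band, Hz (covers the FM sweeps of European bats)
DEFAULT_BAND = (15_000.0, 120_000.0)


@dataclass(frozen=True)
class MicArray:
    """Fixed 3D microphone geometry in the array frame (centre origin, z up).

    Parameters
    ----------
    mic_positions
        (8, 3) array, metres.
    reference_index
        Index of the reference (top) microphone.
    reference_points
        (5, 3) array of frame reference points used for co-registration with
        the LiDAR cloud: the four ends of the frame and its centre.
    reference_labels
        Labels for the reference points.
    """

    mic_positions: np.ndarray
    reference_index: int
    reference_points: np.ndarray
    reference_labels: tuple[str, ...] = ("end+x", "end-x", "end+y", "top", "centre")

    def __post_init__(self) -> None:
        pos = np.asarray(self.mic_positions, dtype=float)
        if pos.shape != (8, 3):
            raise ValueError(f"expected 8 microphones with xyz, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("microphone positions must be finite")
        if not 0 <= self.reference_index < 8:
            raise ValueError("reference_index out of range")
        ref = np.asarray(self.reference_points, dtype=float)
        if ref.shape != (5, 3):
            raise ValueError("expected 5 frame reference points")
        # a unique 3D solution needs non-coplanar mics
        centred = pos - pos.mean(axis=0)
        if np.linalg.matrix_rank(centred, tol=1e-9) < 3:
            raise ValueError("microphone positions are coplanar")
        object.__setattr__(self, "mic_positions", pos)
        object.__setattr__(self, "reference_points", ref)

    @property
    def n_mics(self) -> int:
        return self.mic_positions.shape[0]

    @property
    def aperture(self) -> float:
        """Maximum pairwise microphone distance, metres."""
        d = self.mic_positions[:, None, :] - self.mic_positions[None, :, :]
        return float(np.sqrt((d**2).sum(-1)).max())

    @property
    def centre(self) -> np.ndarray:
        return self.mic_positions.mean(axis=0)

    @property
    def non_reference_indices(self) -> np.ndarray:
        return np.array([i for i in range(self.n_mics) if i != self.reference_index])

    def baselines_to_reference(self) -> np.ndarray:
        """Distances (m) from each non-reference mic to the reference mic."""
        ref = self.mic_positions[self.reference_index]
        return np.linalg.norm(
            self.mic_positions[self.non_reference_indices] - ref, axis=1
        )


def build_default_array() -> MicArray:
    """The package's default 2 m-aperture T-frame array.

    Mics at (±1,0,0), (0,±1,0), (0,0,1) [reference, top], (0,0,0.5),
    (0.5,0,0.5), (0,0.5,0.5) metres.  Reference points are the four frame
    ends and the frame centre.
    """
    mics = np.array(
        [
            [1.0, 0.0, 0.0],
            [-1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, -1.0, 0.0],
            [0.0, 0.0, 1.0],
            [0.0, 0.0, 0.5],
            [0.5, 0.0, 0.5],
            [0.0, 0.5, 0.5],
        ]
    )
    ref_points = np.array(
        [
            [1.0, 0.0, 0.0],
            [-1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
            [0.0, 0.0, 0.0],
        ]
    )
    return MicArray(mic_positions=mics, reference_index=4, reference_points=ref_points)


@dataclass
class MultiChannelRecording:
    """8-channel recording; samples are float, unit-scaled from 16-bit PCM."""

    sample_rate: float
    samples: np.ndarray  # (n_channels, n_samples)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class CallDetection:
    """A time window believed to contain one echolocation call."""

    window_start: float
    window_end: float
    trigger_channel: int
    peak_amplitude: float

    def __post_init__(self) -> None:
        if self.window_end <= self.window_start:
            raise ValueError("window_end must exceed window_start")


@dataclass
class ToadSet:
    """Estimated TOADs for one call: one value per non-reference microphone.

    ``toads[k]`` corresponds to ``array.non_reference_indices[k]`` and is
    ``t_mic - t_reference`` in seconds; NaN marks an invalid channel.
    ``peak_correlations`` are the normalised cross-correlation peak heights.
    """

    toads: np.ndarray
    peak_correlations: np.ndarray
    detection_time: float

    def __post_init__(self) -> None:
        self.toads = np.asarray(self.toads, dtype=float)
        self.peak_correlations = np.asarray(self.peak_correlations, dtype=float)
        if self.toads.shape != (7,) or self.peak_correlations.shape != (7,):
            raise ValueError("ToadSet holds exactly 7 channels")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.toads)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


# ----------------------------------------------------------------------------
# WAV + geometry I/O


def write_wav(path: str | Path, rec: MultiChannelRecording) -> None:
    """Write a recording as 16-bit PCM WAV (channels interleaved)."""
    peak = np.abs(rec.samples).max()
    scale = 0.95 * 32767 / peak if peak > 0 else 1.0
    data = np.round(rec.samples.T * scale).astype(np.int16)
    wavfile.write(str(path), int(rec.sample_rate), data)


def read_wav(path: str | Path, start_time: float = 0.0) -> MultiChannelRecording:
    """Read a PCM WAV into a unit-scaled recording; channel k maps to mic k."""
    rate, data = wavfile.read(str(path))
    if data.ndim == 1:
        data = data[:, None]
    samples = data.T.astype(float)
    if np.issubdtype(data.dtype, np.integer):
        samples /= float(np.iinfo(data.dtype).max)
    return MultiChannelRecording(sample_rate=float(rate), samples=samples, start_time=start_time)


def save_array_geometry(path: str | Path, array: MicArray) -> None:
    """CSV with mic rows and reference-point rows (kind,label,x,y,z)."""
    rows = []
    for i, p in enumerate(array.mic_positions):
        label = f"mic{i}" + ("*" if i == array.reference_index else "")
        rows.append(("mic", label, *p))
    for lbl, p in zip(array.reference_labels, array.reference_points):
        rows.append(("ref_point", lbl, *p))
    pd.DataFrame(rows, columns=["kind", "label", "x", "y", "z"]).to_csv(path, index=False)


def load_array_geometry(path: str | Path) -> MicArray:
    df = pd.read_csv(path)
    mics = df[df["kind"] == "mic"]
    refs = df[df["kind"] == "ref_point"]
    ref_index = int(np.flatnonzero(mics["label"].str.endswith("*"))[0])
    return MicArray(
        mic_positions=mics[["x", "y", "z"]].to_numpy(),
        reference_index=ref_index,
        reference_points=refs[["x", "y", "z"]].to_numpy(),
        reference_labels=tuple(refs["label"]),
    )


def write_channel_map(path: str | Path, array: MicArray) -> None:
    """JSON sidecar declaring the WAV channel → microphone mapping."""
    Path(path).write_text(
        json.dumps(
            {
                "channel_to_mic": list(range(array.n_mics)),
                "reference_index": array.reference_index,
                "toad_convention": "t_mic - t_reference",
            },
            indent=2,
        )
    )


# ----------------------------------------------------------------------------
# Detection


def _bandpass_sos(band: tuple[float, float], fs: float):
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} outside (0, {fs / 2}) Hz")
    return butter(4, [lo, hi], btype="band", fs=fs, output="sos")


def detect_calls(
    rec: MultiChannelRecording,
    band: tuple[float, float] = DEFAULT_BAND,
    threshold: float = 8.0,
    holdoff: float = 0.020,
    frame: float = 0.001,
    noise_window: float = 0.100,
    window_pre: float = 0.008,
    window_post: float = 0.017,
) -> list[CallDetection]:
    """Detect candidate calls by band-limited short-time energy.

    Energy in ``frame``-long frames is compared against ``threshold`` times a
    rolling-median noise floor (``noise_window`` long) on every channel; a
    trigger on any channel opens a detection window, and further triggers
    within ``holdoff`` seconds are absorbed into the same event.  Windows are
    sized (``window_pre`` before, ``window_post`` after the trigger) to cover
    the full inter-microphone delay spread of a 2 m array.
    """
    if rec.n_samples == 0:
        return []
    sos = _bandpass_sos(band, rec.sample_rate)
    frame_len = max(1, int(round(frame * rec.sample_rate)))
    n_frames = rec.n_samples // frame_len
    if n_frames == 0:
        return []

    filtered = sosfiltfilt(sos, rec.samples, axis=1)
    trimmed = filtered[:, : n_frames * frame_len]
    energy = (trimmed.reshape(rec.n_channels, n_frames, frame_len) ** 2).sum(axis=2)

    half = max(1, int(round(noise_window / frame / 2)))
    floor = np.empty_like(energy)
    med = pd.DataFrame(energy.T).rolling(2 * half + 1, center=True, min_periods=1).median()
    floor = med.to_numpy().T
    floor = np.maximum(floor, np.finfo(float).tiny)

    above = energy > threshold * floor
    triggered = above.any(axis=0)

    detections: list[CallDetection] = []
    holdoff_frames = int(np.ceil(holdoff / frame))
    i = 0
    while i < n_frames:
        if triggered[i]:
            ch = int(np.argmax(energy[:, i] / floor[:, i]))
            t_trig = (i * frame_len) / rec.sample_rate
            start = max(0.0, t_trig - window_pre)
            end = min(rec.duration, t_trig + window_post)
            peak = float(
                np.abs(
                    filtered[
                        :,
                        int(start * rec.sample_rate) : int(end * rec.sample_rate),
                    ]
                ).max()
            )
            detections.append(
                CallDetection(
                    window_start=start, window_end=end, trigger_channel=ch, peak_amplitude=peak
                )
            )
            i += holdoff_frames
        else:
            i += 1
    return detections


# ----------------------------------------------------------------------------
# TOAD estimation


def _parabolic_refine(corr: np.ndarray, peak: int) -> float:
    """Sub-sample peak offset from a 3-point parabola around ``peak``."""
    if peak <= 0 or peak >= len(corr) - 1:
        return 0.0
    y0, y1, y2 = corr[peak - 1], corr[peak], corr[peak + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return 0.0
    delta = 0.5 * (y0 - y2) / denom
    return float(np.clip(delta, -0.5, 0.5))


def estimate_toads(
    rec: MultiChannelRecording,
    det: CallDetection,
    array: MicArray,
    band: tuple[float, float] = DEFAULT_BAND,
    c: float = 343.0,
) -> ToadSet:
    """Cross-correlation TOADs of one detected call against the reference.

    The lag search is restricted to the physically valid range
    |lag| <= baseline/c (+1 sample), and the peak is refined to sub-sample
    precision by parabolic interpolation.  All-zero (dead) channels get NaN.
    """
    fs = rec.sample_rate
    i0 = int(round(det.window_start * fs))
    i1 = int(round(det.window_end * fs))
    i0 = max(0, i0)
    i1 = min(rec.n_samples, i1)
    seg = rec.samples[:, i0:i1]
    max_baseline = array.baselines_to_reference().max()
    if (i1 - i0) / fs < 2 * max_baseline / c:
        raise ValueError("detection window shorter than twice the maximum possible TOAD")

    sos = _bandpass_sos(band, fs)
    seg = sosfiltfilt(sos, seg, axis=1)

    ref_sig = seg[array.reference_index]
    ref_energy = float((ref_sig**2).sum())
    n = seg.shape[1]

    toads = np.full(7, np.nan)
    peaks = np.zeros(7)
    baselines = array.baselines_to_reference()
    for k, ch in enumerate(array.non_reference_indices):
        sig = seg[ch]
        energy = float((sig**2).sum())
        if energy <= 0 or ref_energy <= 0:
            continue
        corr = correlate(sig, ref_sig, mode="full", method="fft")
        lags = np.arange(-n + 1, n)
        max_lag = int(np.ceil(baselines[k] / c * fs)) + 1
        mask = np.abs(lags) <= max_lag
        corr_w = corr[mask]
        lags_w = lags[mask]
        ipk = int(np.argmax(corr_w))
        delta = _parabolic_refine(corr_w, ipk)
        toads[k] = (lags_w[ipk] + delta) / fs
        peaks[k] = float(corr_w[ipk] / np.sqrt(ref_energy * energy))
    return ToadSet(toads=toads, peak_correlations=peaks, detection_time=det.window_start)
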