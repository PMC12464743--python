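"""Frame-aligned physiological feature extraction and quality control.

Two low-frequency physiological signals drive slow BOLD fluctuations and are
the targets of the reconstruction model:

* **RV (respiration variation)** — the standard deviation of the raw
  respiration-belt waveform in a sliding window (default 6 s) centred at each
  fMRI frame.  RV tracks slow changes in breathing depth/volume.
* **HR (heart rate)** — 60 divided by the mean inter-beat interval of the
  pulse-oximetry (PPG) waveform within the same sliding window, in beats per
  minute.

Both series are then band-pass filtered to the 0.01-0.15 Hz band where their
BOLD correlates live, resampled onto the (possibly downsampled) fMRI frame
grid, and z-normalised.

The QC rules reproduce common automated screening of scanner physiology
recordings: ADC clipping, physiologically implausible mean heart rate
(< 30 or > 97 bpm), a heart rate pinned at exactly 48 bpm (a known failure
mode of some pulse-oximetry units), and missing channels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps


__all__ = [
    "RawPhysio",
    "BeatSeries",
    "FramePhysio",
    "QCReport",
    "detect_beats",
    "extract_hr",
    "extract_rv",
    "bandpass_resample",
    "znormalize",
    "qc_physio",
    "read_physio_text",
    "write_frame_physio",
    "read_frame_physio",
]


@dataclass
class RawPhysio:
    """Raw physiological recording at the scanner's native sampling rate.

    Either channel may be ``None``: a missing waveform is a QC-detectable
    state, not an error.  ``adc_min``/``adc_max`` are the saturation bounds of
    the recording hardware (HCP dialect: 12-bit ADC, 0 and 4095).
    """

    resp: np.ndarray | None
    ppg: np.ndarray | None
    fs: float
    adc_min: float = 0.0
    adc_max: float = 4095.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be positive")
        if self.resp is not None:
            self.resp = np.asarray(self.resp, dtype=float)
        if self.ppg is not None:
            self.ppg = np.asarray(self.ppg, dtype=float)
        if (
            self.resp is not None
            and self.ppg is not None
            and len(self.resp) != len(self.ppg)
        ):
            raise ValueError("resp and ppg must have equal length when both present")


@dataclass
class BeatSeries:
    """Strictly increasing times (s) of detected cardiac beats."""

    beat_times: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if len(self.beat_times) > 1 and not np.all(np.diff(self.beat_times) > 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.beat_times)

    @property
    def ibis(self) -> np.ndarray:
        """Inter-beat intervals (s)."""
        return np.diff(self.beat_times)


@dataclass
class FramePhysio:
    """RV/HR series aligned to the fMRI frame grid."""

    rv: np.ndarray
    hr: np.ndarray
    frame_times: np.ndarray
    dt: float
    window: float = 6.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.rv = np.asarray(self.rv, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if not (len(self.rv) == len(self.hr) == len(self.frame_times)):
            raise ValueError("rv, hr and frame_times must have equal length")
        if self.dt <= 0:
            raise ValueError("frame spacing dt must be positive")


@dataclass
class QCReport:
    """Outcome of the automated physiological quality screen.

    ``verdict`` is "fail" iff any flag is set.
    """

    clipped: bool = False
    n_clipped_samples: int = 0
    hr_out_of_range: bool = False
    hr_constant_48: bool = False
    missing_resp: bool = False
    missing_ppg: bool = False
    mean_hr_bpm: float | None = None

    @property
    def flags(self) -> dict[str, bool]:
        return {
            "clipped": self.clipped,
            "hr_out_of_range": self.hr_out_of_range,
            "hr_constant_48": self.hr_constant_48,
            "missing_resp": self.missing_resp,
            "missing_ppg": self.missing_ppg,
        }

    @property
    def verdict(self) -> str:
        return "fail" if any(self.flags.values()) else "pass"

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dict(
            self.flags,
            n_clipped_samples=int(self.n_clipped_samples),
            mean_hr_bpm=self.mean_hr_bpm,
            verdict=self.verdict,
        )
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def detect_beats(
    ppg: np.ndarray,
    fs: float,
    refractory: float = 0.25,
    smooth_s: float = 0.05,
    height_percentile: float = 60.0,
    prominence_fraction: float = 0.25,
) -> BeatSeries:
    """Detect cardiac beats in a pulse-oximetry waveform.

    Local-maxima detection on a lightly smoothed waveform with an adaptive
    amplitude threshold (``height_percentile`` of the smoothed signal), a
    minimum peak prominence relative to the waveform's range, and a
    refractory period excluding physiologically impossible double-counts.
    The prominence requirement keeps baseline ripples from being counted on
    low-duty-cycle pulse shapes, where a percentile threshold alone sits
    near the baseline.

    Parameters
    ----------
    ppg : waveform samples (arbitrary units).
    fs : sampling rate in Hz.
    refractory : minimum separation between beats (s); 0.25 s corresponds to
        a 240 bpm ceiling.
    smooth_s : moving-average width (s) applied before peak picking.
    height_percentile : percentile of the smoothed waveform used as the
        amplitude threshold.
    prominence_fraction : minimum peak prominence as a fraction of the
        smoothed waveform's peak-to-peak range.

    Returns an empty ``BeatSeries`` for a constant waveform (the caller's QC
    is expected to flag it).
    """
    ppg = np.asarray(ppg, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if len(ppg) < 2 * fs:
        raise ValueError("insufficient waveform: need at least 2 s of samples")
    if np.ptp(ppg) == 0:
        return BeatSeries(np.empty(0))

    width = max(1, int(round(smooth_s * fs)))
    if width % 2 == 0:
        width += 1  # symmetric kernel: no half-sample peak shift
    if width > 1:
        kernel = np.ones(width) / width
        smoothed = np.convolve(ppg, kernel, mode="same")
    else:
        smoothed = ppg

    height = np.percentile(smoothed, height_percentile)
    distance = max(1, int(round(refractory * fs)))
    prominence = prominence_fraction * np.ptp(smoothed)
    peaks, _ = sps.find_peaks(
        smoothed, height=height, distance=distance, prominence=prominence
    )
    return BeatSeries(peaks / fs)


def extract_hr(
    beats: BeatSeries,
    frame_times: np.ndarray,
    window: float = 6.0,
) -> np.ndarray:
    """Per-frame heart rate (bpm) from detected beats.

    HR at frame time ``t`` is ``60 / mean(IBI)`` over inter-beat intervals
    whose midpoint falls in ``[t - window/2, t + window/2]``.  Frames whose
    window contains no interval are filled by linear interpolation from the
    nearest valid frames (nearest-value extrapolation at the edges).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if len(beats) < 2:
        raise ValueError("cannot form inter-beat interval: need at least 2 beats")
    frame_times = np.asarray(frame_times, dtype=float)

    ibis = beats.ibis
    midpoints = beats.beat_times[:-1] + ibis / 2.0
    half = window / 2.0

    hr = np.full(len(frame_times), np.nan)
    for k, t in enumerate(frame_times):
        in_win = (midpoints >= t - half) & (midpoints <= t + half)
        if np.any(in_win):
            hr[k] = 60.0 / np.mean(ibis[in_win])

    valid = np.isfinite(hr)
    if not np.any(valid):
        raise ValueError("no frame window contains an inter-beat interval")
    if not np.all(valid):
        hr = np.interp(frame_times, frame_times[valid], hr[valid])
    return hr


def extract_rv(
    resp: np.ndarray,
    fs: float,
    frame_times: np.ndarray,
    window: float = 6.0,
) -> np.ndarray:
    """Per-frame respiration variation: windowed standard deviation.

    RV at frame time ``t`` is the population standard deviation (divisor
    ``n``) of the raw respiration samples in ``[t - window/2, t + window/2]``.
    Edge windows are truncated to the available samples.
    """
    resp = np.asarray(resp, dtype=float)
    if window * fs < 2:
        raise ValueError("window too short: needs at least 2 samples")
    frame_times = np.asarray(frame_times, dtype=float)
    sample_times = np.arange(len(resp)) / fs
    half = window / 2.0

    rv = np.empty(len(frame_times))
    for k, t in enumerate(frame_times):
        lo = np.searchsorted(sample_times, t - half, side="left")
        hi = np.searchsorted(sample_times, t + half, side="right")
        if hi <= lo:
            raise ValueError(f"empty window at frame time {t:.3f} s")
        rv[k] = np.std(resp[lo:hi])  # population convention (ddof=0)
    return rv


def _butter_bandpass(band: tuple[float, float], fs: float, order: int = 2):
    nyq = fs / 2.0
    lo, hi = band
    if not (0 < lo < hi < nyq):
        raise ValueError(
            f"band {band} must satisfy 0 < f_lo < f_hi < Nyquist ({nyq:.4g} Hz)"
        )
    return sps.butter(order, [lo / nyq, hi / nyq], btype="bandpass")


def bandpass_filter(
    series: np.ndarray,
    dt: float,
    band: tuple[float, float] = (0.01, 0.15),
    order: int = 2,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    series = np.asarray(series, dtype=float)
    b, a = _butter_bandpass(band, 1.0 / dt, order=order)
    padlen = 3 * max(len(a), len(b))
    if series.shape[axis] <= padlen:
        raise ValueError("series too short to filter")
    return sps.filtfilt(b, a, series, axis=axis)


def bandpass_resample(
    series: np.ndarray,
    dt_in: float,
    band: tuple[float, float] = (0.01, 0.15),
    dt_out: float | None = None,
) -> np.ndarray:
    """Zero-phase band-pass then resample a per-frame series.

    When ``dt_out`` is an integer multiple of ``dt_in`` the series is
    decimated by keeping frames ``0, f, 2f, ...`` (length ``ceil(T/f)``);
    otherwise it is linearly interpolated onto the new grid.  ``dt_out=None``
    keeps the input grid.
    """
    filtered = bandpass_filter(series, dt_in, band=band)
    if dt_out is None or np.isclose(dt_out, dt_in):
        return filtered
    ratio = dt_out / dt_in
    if np.isclose(ratio, round(ratio)):
        return filtered[:: int(round(ratio))]
    t_in = np.arange(len(filtered)) * dt_in
    t_out = np.arange(0.0, t_in[-1] + 1e-9, dt_out)
    return np.interp(t_out, t_in, filtered)


def znormalize(series: np.ndarray, axis: int = -1) -> np.ndarray:
    """Rescale to zero mean and unit (population) variance.

    A constant input maps to all-zeros with a warning rather than raising.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("cannot normalize an empty series")
    mean = series.mean(axis=axis, keepdims=True)
    sd = series.std(axis=axis, keepdims=True)
    if np.any(sd == 0):
        warnings.warn("constant series z-normalized to all zeros", RuntimeWarning)
    out = np.where(sd == 0, 0.0, (series - mean) / np.where(sd == 0, 1.0, sd))
    return out


def qc_physio(
    raw: RawPhysio,
    hr: np.ndarray | None,
    clip_fraction: float = 0.01,
    hr_range: tuple[float, float] = (30.0, 97.0),
    constant_hr: float = 48.0,
    constant_tol: float = 0.5,
) -> QCReport:
    """Automated quality screen of a raw recording and its derived HR.

    ``hr`` must be in physical units (bpm), not z-scored.  Each criterion is
    evaluated independently; the verdict is the disjunction of the flags.
    """
    report = QCReport()
    report.missing_resp = raw.resp is None
    report.missing_ppg = raw.ppg is None

    n_clipped = 0
    n_total = 0
    for chan in (raw.resp, raw.ppg):
        if chan is None:
            continue
        n_clipped += int(np.sum((chan <= raw.adc_min) | (chan >= raw.adc_max)))
        n_total += len(chan)
    report.n_clipped_samples = n_clipped
    if n_total > 0 and n_clipped / n_total > clip_fraction:
        report.clipped = True

    if hr is not None and len(hr) > 0:
        hr = np.asarray(hr, dtype=float)
        mean_hr = float(np.mean(hr))
        report.mean_hr_bpm = mean_hr
        if mean_hr < hr_range[0] or mean_hr > hr_range[1]:
            report.hr_out_of_range = True
        if np.all(np.abs(hr - constant_hr) <= constant_tol):
            report.hr_constant_48 = True
    return report


# ---------------------------------------------------------------------------
# I/O: columnar waveform text and frame-aligned TSV + JSON sidecar
# ---------------------------------------------------------------------------

HCP_COLUMNS = {"resp": 1, "ppg": 2}  # 0-based; column 0 is the scanner trigger


def read_physio_text(
    path: str | Path,
    fs: float,
    columns: dict[str, int] | None = None,
    adc_min: float = 0.0,
    adc_max: float = 4095.0,
) -> RawPhysio:
    """Read a whitespace/tab-separated waveform recording.

    ``columns`` maps channel name ("resp", "ppg") to 0-based column index;
    the default is the HCP layout (trigger, respiration, PPG at 400 Hz).
    A mapped column index outside the file is treated as a missing channel.
    """
    columns = dict(HCP_COLUMNS if columns is None else columns)
    data = np.loadtxt(path, ndmin=2)

    def _col(name: str) -> np.ndarray | None:
        idx = columns.get(name)
        if idx is None or idx >= data.shape[1]:
            return None
        return data[:, idx]

    return RawPhysio(
        resp=_col("resp"), ppg=_col("ppg"), fs=fs, adc_min=adc_min, adc_max=adc_max
    )


def write_frame_physio(fp: FramePhysio, path: str | Path,
                       band: tuple[float, float] | None = None) -> None:
    """Write RV/HR as a 2-column TSV plus a JSON sidecar with the metadata."""
    path = Path(path)
    df = pd.DataFrame({"rv": fp.rv, "hr": fp.hr})
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "dt": fp.dt,
        "window": fp.window,
        "normalized": fp.normalized,
        "band": list(band) if band is not None else None,
        "t0": float(fp.frame_times[0]) if len(fp.frame_times) else 0.0,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_frame_physio(path: str | Path) -> FramePhysio:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    n = len(df)
    t0 = sidecar.get("t0", 0.0)
    return FramePhysio(
        rv=df["rv"].to_numpy(),
        hr=df["hr"].to_numpy(),
        frame_times=t0 + np.arange(n) * sidecar["dt"],
        dt=sidecar["dt"],
        window=sidecar.get("window", 6.0),
        normalized=sidecar.get("normalized", False),
    )
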