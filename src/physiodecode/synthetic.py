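"""Brain-body forward simulator with known ground truth.

Generates, from a single seed:

1. coupled low-frequency **latent** RV and HR series, band-limited to
   0.01-0.15 Hz with a 1/f-like in-band tilt (real respiratory and cardiac
   variability concentrates at the slow end of the band) and an exact
   in-sample correlation of ``rho`` (default 0.275, the typical measured
   RV-HR coupling at rest);
2. **raw waveforms** consistent with those latents: a respiration-belt-like
   sinusoid whose instantaneous amplitude follows RV, and a PPG-like pulse
   train whose instantaneous beat rate follows HR, both sampled at a
   scanner-class 400 Hz and quantised to a 12-bit ADC range;
3. **ROI BOLD matrices** built by the same linear forward model the
   variance-explained analysis assumes: each region is a weighted sum of the
   RRF-convolved RV and the CRF-convolved HR plus AR(1) Gaussian noise,
   z-scored.

Because the generative model matches the analysis model, every downstream
module (extraction, reconstruction, variance explained, connectivity) can be
validated against known ground truth without any data download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .physio import RawPhysio, znormalize
from .response import build_physio_regressors

__all__ = [
    "SimConfig",
    "SimScan",
    "simulate_latent_physio",
    "simulate_raw_waveforms",
    "simulate_roi_scan",
    "simulate_dataset",
    "build_manifest",
    "make_synthetic_atlas_parts",
    "make_fixture_bold_image",
]


@dataclass
class SimConfig:
    """Conditions of a simulated study.

    Defaults mirror a downsampled HCP-style resting-state acquisition:
    frame spacing 1.44 s, latents band-limited to 0.01-0.15 Hz with RV-HR
    coupling 0.275, four scans per synthetic subject.

    ``noise_sd`` is the marginal standard deviation of the AR(1) ROI noise
    relative to unit-variance signal components; ``varexp_target`` instead
    prescribes the expected fraction of ROI variance explained by the true
    regressors (noise is then scaled per ROI), e.g. 0.25 for the 20-30%
    regime typical of physiology-rich regions.
    """

    n_scans: int = 8
    n_rois: int = 50
    n_frames: int = 300
    dt: float = 1.44
    band: tuple[float, float] = (0.01, 0.15)
    rho: float = 0.275
    loading_rv: tuple[float, float] = (0.3, 1.0)
    loading_hr: tuple[float, float] = (0.3, 1.0)
    zero_loading_fraction: float = 0.1
    noise_sd: float = 1.7
    varexp_target: float | None = None
    ar_coeff: float = 0.3
    latent_tilt: float = 0.7       # AR(1) pole shaping the in-band spectrum
    scans_per_subject: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.ar_coeff < 1):
            raise ValueError("ar_coeff must be in [0, 1)")


@dataclass
class SimScan:
    """One simulated scan with its generating ground truth."""

    roi_data: np.ndarray            # R x T, z-scored rows
    rv_true: np.ndarray
    hr_true: np.ndarray
    loadings: np.ndarray            # R x 2 (RV, HR) coefficients
    dt: float
    subject: str | None = None
    scan_id: str | None = None
    raw: RawPhysio | None = None


def _band_filter(x: np.ndarray, dt: float, band, order: int = 4) -> np.ndarray:
    nyq = 0.5 / dt
    b, a = sps.butter(order, [band[0] / nyq, band[1] / nyq], btype="bandpass")
    return sps.filtfilt(b, a, x, axis=-1)


def simulate_latent_physio(
    T: int,
    dt: float = 1.44,
    rho: float = 0.275,
    seed: int | np.random.Generator = 0,
    band: tuple[float, float] = (0.01, 0.15),
    latent_tilt: float = 0.7,
) -> tuple[np.ndarray, np.ndarray]:
    """Coupled band-limited latent RV and HR series (both z-scored).

    Two independent Gaussian noises are AR(1)-tilted (pole ``latent_tilt``)
    to weight the slow end of the band, band-pass filtered, z-scored, and
    mixed after sample-orthogonalisation so the sample correlation equals
    ``rho`` exactly for every realisation.
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if T * dt < 3.0 / band[0]:
        # too short to resolve the low edge of the band; still works but warn
        import warnings

        warnings.warn(
            f"series of {T * dt:.0f} s is short for {band[0]} Hz content",
            RuntimeWarning,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    burn = 200
    white = rng.standard_normal((2, T + 2 * burn))
    tilted = sps.lfilter([1.0], [1.0, -latent_tilt], white, axis=1)[:, burn:-burn]
    filtered = _band_filter(tilted, dt, band)
    u = znormalize(filtered[0])
    w = znormalize(filtered[1])
    # exact in-sample coupling: Gram-Schmidt then mix
    w_perp = w - np.dot(w, u) / np.dot(u, u) * u
    w_perp = znormalize(w_perp)
    v = rho * u + np.sqrt(1.0 - rho**2) * w_perp
    return u, znormalize(v)


def simulate_raw_waveforms(
    rv: np.ndarray,
    hr: np.ndarray,
    dt: float,
    fs: float = 400.0,
    seed: int | np.random.Generator = 0,
    hr_mean_bpm: float = 70.0,
    hr_sd_bpm: float = 5.0,
    breathing_rate_hz: float = 1.0 / 3.0,
    rv_offset: float = 1.0,
    rv_scale: float = 0.2,
    pulse_sharpness: float = 25.0,
    noise_sd: float = 0.01,
) -> RawPhysio:
    """Raw respiration/PPG waveforms whose derived RV/HR equal the latents.

    ``rv`` and ``hr`` are z-scored per-frame latents; HR is rescaled to bpm
    via ``hr_mean_bpm + hr_sd_bpm * hr``.  Respiration is a sinusoid at the
    breathing rate with instantaneous amplitude ``rv_offset + rv_scale*rv``
    (must stay positive); PPG is a periodic sharp pulse whose instantaneous
    rate tracks the bpm series.  Both channels are scaled into a 12-bit ADC
    range and rounded to integers, clipping-free by construction.

    The default breathing rate of 1/3 Hz (20 breaths/min, a normal resting
    rate) makes the standard 6-s RV window span exactly two respiratory
    cycles, so the windowed standard deviation tracks the amplitude envelope
    without breathing-phase ripple.
    """
    rv = np.asarray(rv, float)
    hr = np.asarray(hr, float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = len(rv)
    frame_times = np.arange(T) * dt
    t = np.arange(0.0, frame_times[-1] + dt, 1.0 / fs)

    amp = rv_offset + rv_scale * np.interp(t, frame_times, rv)
    if np.any(amp <= 0):
        raise ValueError("respiration amplitude non-positive after shift")
    resp = amp * np.sin(2.0 * np.pi * breathing_rate_hz * t)
    resp = resp + noise_sd * rng.standard_normal(len(t))
    resp_adc = np.rint(2048.0 + 600.0 * resp)

    bpm = hr_mean_bpm + hr_sd_bpm * np.interp(t, frame_times, hr)
    if np.any(bpm <= 0):
        raise ValueError("instantaneous heart rate non-positive")
    phase = np.cumsum(bpm / 60.0) / fs  # beats elapsed
    pulse = np.exp(pulse_sharpness * (np.cos(2.0 * np.pi * phase) - 1.0))
    pulse = pulse + noise_sd * rng.standard_normal(len(t))
    ppg_adc = np.rint(1200.0 + 1600.0 * pulse)

    return RawPhysio(resp=resp_adc, ppg=ppg_adc, fs=fs)


def simulate_roi_scan(
    rv: np.ndarray,
    hr: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimScan:
    """ROI BOLD matrix from the linear physiological forward model.

    Row r = loading_rv[r] * z(rv * RRF) + loading_hr[r] * z(hr * CRF) +
    AR(1) noise, then z-scored.  A configurable fraction of ROIs has zero
    loading on both signals (pure-noise regions).  With ``noise_sd = 0``
    every loaded row is an exact affine combination of the canonical
    regressor columns.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    R, T = config.n_rois, len(rv)

    conv_rv = build_physio_regressors(rv, config.dt, "RRF").columns[:, 0]
    conv_hr = build_physio_regressors(hr, config.dt, "CRF").columns[:, 0]
    conv_rv = znormalize(conv_rv)
    conv_hr = znormalize(conv_hr)

    l_rv = rng.uniform(*config.loading_rv, size=R)
    l_hr = rng.uniform(*config.loading_hr, size=R)
    zero = rng.random(R) < config.zero_loading_fraction
    l_rv[zero] = 0.0
    l_hr[zero] = 0.0

    signal = l_rv[:, None] * conv_rv + l_hr[:, None] * conv_hr

    if config.varexp_target is not None:
        f = config.varexp_target
        sd_signal = signal.std(axis=1)
        noise_scale = np.where(
            sd_signal > 0, sd_signal * np.sqrt((1.0 - f) / f), 1.0
        )
    else:
        noise_scale = np.full(R, config.noise_sd)

    if np.any(noise_scale > 0):
        a = config.ar_coeff
        innov = rng.standard_normal((R, T))
        ar = sps.lfilter([1.0], [1.0, -a], innov, axis=1)
        ar = ar * np.sqrt(1.0 - a**2)  # unit marginal variance
        noise = noise_scale[:, None] * ar
    else:
        noise = 0.0

    data = signal + noise
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        data = znormalize(data, axis=-1)
    return SimScan(
        roi_data=data,
        rv_true=np.asarray(rv, float),
        hr_true=np.asarray(hr, float),
        loadings=np.column_stack([l_rv, l_hr]),
        dt=config.dt,
    )


def build_manifest(n_scans: int, scans_per_subject: int = 4) -> list[dict]:
    """Assign synthetic subject ids, ``scans_per_subject`` scans each."""
    manifest = []
    for i in range(n_scans):
        subject = f"sub-{i // scans_per_subject + 1:04d}"
        manifest.append(
            {"subject": subject, "scan_id": f"{subject}_scan-{i % scans_per_subject + 1}"}
        )
    return manifest


def simulate_dataset(
    config: SimConfig, with_raw: bool = False
) -> tuple[list[SimScan], list[dict]]:
    """Independent scans sharing the loading distribution; seeded manifest.

    Latents and noise are independent across scans; all randomness flows
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    manifest = build_manifest(config.n_scans, config.scans_per_subject)
    scans = []
    for entry in manifest:
        rv, hr = simulate_latent_physio(
            config.n_frames,
            dt=config.dt,
            rho=config.rho,
            seed=rng,
            band=config.band,
            latent_tilt=config.latent_tilt,
        )
        scan = simulate_roi_scan(rv, hr, config, rng=rng)
        scan.subject = entry["subject"]
        scan.scan_id = entry["scan_id"]
        if with_raw:
            scan.raw = simulate_raw_waveforms(rv, hr, config.dt, seed=rng)
        scans.append(scan)
    return scans, manifest


# ---------------------------------------------------------------------------
# Tiny volumetric fixtures (synthetic stand-ins for atlas/NIfTI inputs)
# ---------------------------------------------------------------------------

def make_synthetic_atlas_parts(
    sizes: tuple[int, ...] = (400, 72, 16, 9),
    names: tuple[str, ...] = ("cortical", "white_matter", "subcortical", "aan"),
    prob_parts: tuple[str, ...] = ("white_matter",),
    shape: tuple[int, int, int] = (12, 12, 12),
    seed: int = 0,
):
    """Synthetic four-part atlas on a small shared grid.

    Voxels are dealt contiguously to the parts in order, one or more voxels
    per region, mimicking the cortical / white-matter / subcortical /
    arousal-network composition (400 + 72 + 16 + 9 regions by default).
    Parts named in ``prob_parts`` are emitted as 4-D probability maps (with
    in-region probability 0.99) rather than integer label volumes.

    Returns a list of :class:`physiodecode.atlas.AtlasPart`.
    """
    import nibabel as nib

    from .atlas import AtlasPart

    n_vox = int(np.prod(shape))
    if sum(sizes) > n_vox:
        raise ValueError("grid too small for the requested region counts")
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    parts = []
    cursor = 0
    for name, n_regions in zip(names, sizes):
        labels = np.zeros(n_vox, dtype=np.int16)
        for local in range(1, n_regions + 1):
            labels[cursor] = local
            cursor += 1
        vol = labels.reshape(shape)
        if name in prob_parts:
            prob = np.zeros(shape + (n_regions,), dtype=np.float32)
            for local in range(1, n_regions + 1):
                prob[..., local - 1][vol == local] = 0.99
            img = nib.Nifti1Image(prob, affine)
            parts.append(AtlasPart(name=name, image=img, kind="probability"))
        else:
            img = nib.Nifti1Image(vol, affine)
            parts.append(AtlasPart(name=name, image=img, kind="labels"))
    return parts


def make_fixture_bold_image(
    shape: tuple[int, int, int] = (10, 10, 10),
    n_frames: int = 120,
    dt: float = 1.44,
    seed: int = 0,
):
    """Small random 4-D NIfTI for seed-map and extraction tests."""
    import nibabel as nib

    rng = np.random.default_rng(seed)
    data = rng.standard_normal(shape + (n_frames,)).astype(np.float32)
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((2.0, 2.0, 2.0, dt))
    return img
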