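"""Physiology-to-BOLD forward model and variance-explained analysis.

Slow respiration-volume and heart-rate fluctuations reach the BOLD signal
through approximately linear, delayed hemodynamic couplings described by two
canonical impulse responses from the physiological-noise literature:

* the respiration response function (RRF), a slow positive lobe peaking near
  3 s followed by a broad negative undershoot around 15-20 s::

      RRF(t) = 0.6 t^2.1 e^(-t/1.6) - 0.0023 t^3.54 e^(-t/4.25)

* the cardiac response function (CRF), an early positive lobe followed by a
  Gaussian-shaped negative lobe centred near 12 s::

      CRF(t) = 0.6 t^2.7 e^(-t/1.6) - 16/sqrt(18*pi) e^(-(t-12)^2/18)

Each physiological signal contributes three regressors: the canonical
convolution, its temporal derivative, and a dispersion derivative obtained by
finite-differencing the convolution over a stretch of the kernel's time axis.
Percent variance explained in a BOLD series is the fractional reduction in
temporal variance after projecting out these regressors by ordinary least
squares, times 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


__all__ = [
    "ResponseFunction",
    "RegressorSet",
    "response_function_eval",
    "build_physio_regressors",
    "percent_variance_explained",
    "variance_explained_map",
]


def _rrf(t: np.ndarray) -> np.ndarray:
    return 0.6 * t**2.1 * np.exp(-t / 1.6) - 0.0023 * t**3.54 * np.exp(-t / 4.25)


def _crf(t: np.ndarray) -> np.ndarray:
    gauss = 16.0 / np.sqrt(2.0 * np.pi * 9.0) * np.exp(-((t - 12.0) ** 2) / 18.0)
    return 0.6 * t**2.7 * np.exp(-t / 1.6) - gauss


_KERNELS = {"RRF": _rrf, "CRF": _crf}


def response_function_eval(kind: str, t: float | np.ndarray) -> np.ndarray:
    """Evaluate the RRF or CRF at time ``t`` (seconds, causal: t >= 0)."""
    kind = kind.upper()
    if kind not in _KERNELS:
        raise ValueError(f"unknown response function kind {kind!r}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("response functions are causal: t must be >= 0")
    return _KERNELS[kind](t)


@dataclass
class ResponseFunction:
    """A sampled causal hemodynamic kernel.

    Parameters
    ----------
    kind : "RRF" or "CRF".
    support : duration (s) over which the kernel is sampled.  Both kernels
        are negligible past ~50 s, so the default of 60 s captures them.
    dt : sampling step (s), normally the fMRI frame spacing.
    time_scale : stretch factor applied to the kernel time axis (used by the
        dispersion derivative); 1.0 is canonical.
    """

    kind: str
    support: float = 60.0
    dt: float = 1.44
    time_scale: float = 1.0
    t: np.ndarray = field(init=False)
    values: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.t = np.arange(0.0, self.support + 1e-9, self.dt)
        self.values = response_function_eval(self.kind, self.t / self.time_scale)


@dataclass
class RegressorSet:
    """Design matrix of convolved physiological regressors.

    ``columns`` is T x (3 S) for S signals: canonical convolution, temporal
    derivative and dispersion derivative per signal, all mean-centred.
    """

    columns: np.ndarray
    dt: float
    labels: list[str]

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2:
            raise ValueError("columns must be 2-D (T x K)")
        if self.columns.shape[1] != len(self.labels):
            raise ValueError("labels must match column count")

    @staticmethod
    def concat(sets: list["RegressorSet"]) -> "RegressorSet":
        dts = {s.dt for s in sets}
        if len(dts) != 1:
            raise ValueError("cannot concatenate RegressorSets with different dt")
        return RegressorSet(
            columns=np.hstack([s.columns for s in sets]),
            dt=sets[0].dt,
            labels=[lab for s in sets for lab in s.labels],
        )


def build_physio_regressors(
    signal: np.ndarray,
    dt: float,
    kind: str,
    label: str | None = None,
    support: float = 60.0,
    dispersion_eps: float = 0.1,
) -> RegressorSet:
    """Canonical + temporal-derivative + dispersion-derivative columns.

    canonical   : causal discrete convolution of ``signal`` with the kernel
                  sampled at ``dt``, truncated to the signal length (scaled
                  by ``dt`` so it approximates the continuous convolution).
    temporal    : first difference of the canonical column (leading 0).
    dispersion  : (convolution with the kernel stretched by 1+eps minus the
                  canonical) / eps — a finite-difference sensitivity to the
                  kernel's time scale.

    All columns are mean-centred.  A constant input signal produces (near-)
    constant columns; this degenerate case is flagged with a warning.
    """
    signal = np.asarray(signal, dtype=float)
    T = len(signal)
    if np.ptp(signal) == 0:
        warnings.warn(
            "constant input signal: regressor columns are degenerate",
            RuntimeWarning,
        )
    kern = ResponseFunction(kind, support=support, dt=dt)
    if T < 3 * len(kern.values):
        warnings.warn(
            "signal shorter than 3 kernel supports; regressors may be unstable",
            RuntimeWarning,
        )

    def _conv(values: np.ndarray) -> np.ndarray:
        return np.convolve(signal, values * dt, mode="full")[:T]

    canonical = _conv(kern.values)
    temporal = np.concatenate([[0.0], np.diff(canonical)])
    stretched = ResponseFunction(
        kind, support=support, dt=dt, time_scale=1.0 + dispersion_eps
    )
    dispersion = (_conv(stretched.values) - canonical) / dispersion_eps

    columns = np.column_stack([canonical, temporal, dispersion])
    if np.any(np.ptp(columns, axis=0) == 0):
        warnings.warn("degenerate (constant) regressor column", RuntimeWarning)
    columns = columns - columns.mean(axis=0, keepdims=True)
    base = label if label is not None else kind.lower()
    labels = [f"{base}_canonical", f"{base}_temporal_deriv", f"{base}_dispersion_deriv"]
    return RegressorSet(columns=columns, dt=dt, labels=labels)


def _design_matrix(X: RegressorSet | np.ndarray) -> np.ndarray:
    cols = X.columns if isinstance(X, RegressorSet) else np.asarray(X, dtype=float)
    if cols.ndim != 2:
        raise ValueError("regressors must be 2-D (T x K)")
    return cols


def percent_variance_explained(y: np.ndarray, X: RegressorSet | np.ndarray) -> float:
    """Percent of temporal variance of ``y`` removed by OLS projection on X.

    Fits ``y ~ [1, X]`` and returns ``100 * (1 - var(residual)/var(y))``,
    clipped below at 0.  Rank-deficient designs are handled by the
    least-squares solver (dependent columns contribute nothing) with a
    warning.
    """
    y = np.asarray(y, dtype=float)
    cols = _design_matrix(X)
    T = len(y)
    if cols.shape[0] != T:
        raise ValueError("y and regressors must share the time axis")
    if np.ptp(y) == 0:
        raise ValueError("y is constant: variance explained undefined")
    if T <= cols.shape[1] + 1:
        raise ValueError("need more frames than regressor columns")

    design = np.column_stack([np.ones(T), cols])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            "rank-deficient regressor matrix; dependent columns dropped",
            RuntimeWarning,
        )
    resid = y - design @ beta
    return float(np.clip(100.0 * (1.0 - resid.var() / y.var()), 0.0, None))


def physio_regressor_set(
    rv: np.ndarray, hr: np.ndarray, dt: float, support: float = 60.0,
    dispersion_eps: float = 0.1,
) -> RegressorSet:
    """The joint 6-column set: RV through the RRF, HR through the CRF."""
    return RegressorSet.concat(
        [
            build_physio_regressors(rv, dt, "RRF", label="rv",
                                    support=support, dispersion_eps=dispersion_eps),
            build_physio_regressors(hr, dt, "CRF", label="hr",
                                    support=support, dispersion_eps=dispersion_eps),
        ]
    )


def variance_explained_map(
    data: np.ndarray,
    rv: np.ndarray,
    hr: np.ndarray,
    dt: float,
    support: float = 60.0,
) -> np.ndarray:
    """Per-row percent variance explained by the joint RV/HR regressor set.

    ``data`` is R x T (ROI-by-time; a flattened voxel-by-time matrix works
    identically).  Group-level maps are simple arithmetic means of per-scan
    maps.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    X = physio_regressor_set(rv, hr, dt, support=support)
    return np.array([percent_variance_explained(row, X) for row in data])
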