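"""Voxel-wise mono-exponential T2 mapping.

The signal model is S(TE) = S0 * exp(-TE/T2). Two estimators are provided:

``loglinear_wls``
    Weighted least squares of log S on TE with weights S^2. The weights
    undo the variance distortion of the log transform, so for additive
    noise this is a first-order approximation to the nonlinear fit. Fast,
    deterministic, fully vectorised; the default.

``nls``
    Nonlinear least squares of the exponential model itself
    (Levenberg-style, ``scipy.optimize.least_squares``), initialised from
    the log-linear solution. More accurate in the low-SNR/Rician regime.

A voxel's fit is accepted only if the estimated T2 falls inside a
physiological window (default 1-500 ms, extraocular-muscle range with
margin); rejected voxels are flagged invalid rather than propagated into
the histograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .phantom import MultiEchoVolume, VOIMask

__all__ = ["T2_WINDOW_MS", "VoxelFit", "T2Map", "fit_t2_voxel", "fit_t2_map"]

#: Acceptance window for fitted T2 (ms).
T2_WINDOW_MS = (1.0, 500.0)


class VoxelFit(NamedTuple):
    t2_ms: float
    s0: float
    r_squared: float
    valid: bool


@dataclass
class T2Map:
    """Voxel-wise T2 estimates with fit diagnostics."""

    t2_ms: np.ndarray
    s0: np.ndarray
    r_squared: np.ndarray
    valid: np.ndarray  # boolean: fit accepted

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.t2_ms, self.s0, self.r_squared, self.valid)}
        if len(shapes) != 1:
            raise ValueError("T2Map component volumes must share a shape")


def _r_squared(signals: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((signals - pred) ** 2))
    ss_tot = float(np.sum((signals - signals.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-12 else 0.0
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def _loglinear(signals: np.ndarray, te: np.ndarray) -> tuple[float, float]:
    """Weighted log-linear solution; returns (t2, s0). t2 may be inf/negative
    for non-decaying data; the caller applies the acceptance window."""
    w = signals ** 2
    y = np.log(signals)
    sw = w.sum()
    xb = (w * te).sum() / sw
    yb = (w * y).sum() / sw
    sxx = (w * (te - xb) ** 2).sum()
    slope = (w * (te - xb) * (y - yb)).sum() / sxx
    s0 = float(np.exp(yb - slope * xb))
    t2 = np.inf if slope == 0 else -1.0 / slope
    return float(t2), s0


def fit_t2_voxel(signals: Sequence[float], echo_times_ms: Sequence[float],
                 method: str = "loglinear_wls",
                 t2_window_ms: tuple[float, float] = T2_WINDOW_MS) -> VoxelFit:
    """Fit the mono-exponential decay for a single voxel.

    Non-positive signals (possible on magnitude images after subtraction or
    at the noise floor) are handled by rule: a single non-positive echo is
    dropped if at least three points remain; two or more make the voxel
    invalid. Returns NaN outputs with ``valid=False`` for rejected voxels.
    """
    s = np.asarray(signals, dtype=float)
    te = np.asarray(echo_times_ms, dtype=float)
    if s.shape != te.shape:
        raise ValueError(f"signals {s.shape} and echo_times_ms {te.shape} differ")
    if s.size < 3:
        raise ValueError("need at least 3 echoes to fit S0 and T2")

    keep = s > 0
    n_bad = int((~keep).sum())
    invalid = VoxelFit(np.nan, np.nan, np.nan, False)
    if n_bad >= 2 or keep.sum() < 3:
        return invalid
    s, te = s[keep], te[keep]

    t2, s0 = _loglinear(s, te)
    if method == "nls":
        x0 = [s0, t2] if (np.isfinite(t2) and t2 > 0) else [float(s.max()), 50.0]
        sol = least_squares(
            lambda p: p[0] * np.exp(-te / p[1]) - s, x0=x0,
            bounds=([0.0, 1e-3], [np.inf, 1e4]), method="trf")
        s0, t2 = float(sol.x[0]), float(sol.x[1])
    elif method != "loglinear_wls":
        raise ValueError(f"unknown method {method!r}")

    if not (np.isfinite(t2) and t2_window_ms[0] <= t2 <= t2_window_ms[1]):
        return invalid
    r2 = _r_squared(s, s0 * np.exp(-te / t2))
    return VoxelFit(t2, s0, r2, True)


def _fit_map_loglinear(sig: np.ndarray, te: np.ndarray,
                       window: tuple[float, float]
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised log-linear WLS over an (n_vox, n_echo) signal matrix."""
    pos = sig > 0
    n_bad = (~pos).sum(axis=1)
    usable = (n_bad <= 1) & (pos.sum(axis=1) >= 3)

    w = np.where(pos, sig, 0.0) ** 2
    y = np.log(np.where(pos, sig, 1.0))  # weight 0 where padded
    sw = w.sum(axis=1)
    sw = np.where(sw > 0, sw, 1.0)
    xb = (w * te).sum(axis=1) / sw
    yb = (w * y).sum(axis=1) / sw
    dx = te[None, :] - xb[:, None]
    sxx = (w * dx ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (w * dx * (y - yb[:, None])).sum(axis=1) / sxx
        t2 = -1.0 / slope
    s0 = np.exp(yb - slope * xb)

    valid = usable & np.isfinite(t2) & (t2 >= window[0]) & (t2 <= window[1])
    pred = s0[:, None] * np.exp(-te[None, :] / np.where(valid, t2, 1.0)[:, None])
    resid = np.where(pos, sig - pred, 0.0)
    ss_res = (resid ** 2).sum(axis=1)
    m = (np.where(pos, sig, 0.0)).sum(axis=1) / np.maximum(pos.sum(axis=1), 1)
    ss_tot = (np.where(pos, sig - m[:, None], 0.0) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot,
                      np.where(ss_res < 1e-12, 1.0, 0.0))
    r2 = np.clip(r2, 0.0, 1.0)

    t2 = np.where(valid, t2, np.nan)
    s0 = np.where(valid, s0, np.nan)
    r2 = np.where(valid, r2, np.nan)
    return t2, s0, r2, valid


def fit_t2_map(volume: MultiEchoVolume,
               mask: VOIMask | np.ndarray | None = None,
               method: str = "loglinear_wls",
               t2_window_ms: tuple[float, float] = T2_WINDOW_MS) -> T2Map:
    """Voxel-wise T2 fit over a multi-echo stack.

    Equivalent to applying :func:`fit_t2_voxel` at every voxel; voxels
    outside ``mask`` (a :class:`VOIMask` or boolean volume) are marked
    invalid without being fitted.
    """
    data = volume.data
    te = volume.echo_times_ms
    if data.shape[3] != len(te):
        raise ValueError("echo axis does not match echo_times_ms")
    spatial = data.shape[:3]

    if mask is None:
        sel = np.ones(spatial, dtype=bool)
    elif isinstance(mask, VOIMask):
        if mask.labels.shape != spatial:
            raise ValueError("mask shape does not match volume")
        sel = mask.labels > 0
    else:
        sel = np.asarray(mask, dtype=bool)
        if sel.shape != spatial:
            raise ValueError("mask shape does not match volume")

    t2 = np.full(spatial, np.nan)
    s0 = np.full(spatial, np.nan)
    r2 = np.full(spatial, np.nan)
    valid = np.zeros(spatial, dtype=bool)

    sig = data[sel]
    if sig.size:
        if method == "loglinear_wls":
            vt2, vs0, vr2, vvalid = _fit_map_loglinear(sig, te, t2_window_ms)
        elif method == "nls":
            fits = [fit_t2_voxel(row, te, method="nls", t2_window_ms=t2_window_ms)
                    for row in sig]
            vt2 = np.array([f.t2_ms for f in fits])
            vs0 = np.array([f.s0 for f in fits])
            vr2 = np.array([f.r_squared for f in fits])
            vvalid = np.array([f.valid for f in fits])
        else:
            raise ValueError(f"unknown method {method!r}")
        t2[sel], s0[sel], r2[sel], valid[sel] = vt2, vs0, vr2, vvalid
    return T2Map(t2_ms=t2, s0=s0, r_squared=r2, valid=valid)
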