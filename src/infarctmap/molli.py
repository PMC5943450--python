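"""Per-pixel MOLLI T1 fitting with Look-Locker correction.

The inversion-recovery signal after an adiabatic inversion with
Look-Locker readout is modeled with the canonical three parameters,

    S(TI) = A - B * exp(-TI / T1*),

where ``T1*`` is the apparent (readout-shortened) relaxation time. The
true longitudinal relaxation time follows from the Look-Locker
correction ``T1 = T1* * (B/A - 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .core import ParametricMap
from .phantom import MolliSeries

__all__ = ["MolliFit", "fit_t1_pixel", "fit_t1_map"]


@dataclass(frozen=True)
class MolliFit:
    """Result of one pixel's three-parameter inversion-recovery fit.

    ``t1`` is the Look-Locker-corrected relaxation time (ms); ``t1_star``
    the apparent one. Non-converged or degenerate fits carry
    ``converged=False`` and NaN times, never a silent value.
    """

    a: float
    b: float
    t1_star: float
    t1: float
    residual_rms: float
    converged: bool
    message: str = ""


def _model(params: np.ndarray, tis: np.ndarray) -> np.ndarray:
    a, b, t1s = params
    return a - b * np.exp(-tis / t1s)


def _fit_once(signals: np.ndarray, tis: np.ndarray) -> tuple[np.ndarray, float, bool, str]:
    a0 = float(np.max(signals))
    b0 = 2.0 * a0 if a0 > 0 else 1.0
    t1s0 = float(tis[np.argmin(np.abs(signals))]) / math.log(2.0)
    t1s0 = max(t1s0, float(tis[0]) / 10.0, 1.0)
    res = least_squares(
        lambda p: _model(p, tis) - signals,
        x0=np.array([a0, b0, t1s0]),
        bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
        ftol=1e-10,
        xtol=1e-10,
        gtol=1e-10,
        max_nfev=200,
    )
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return res.x, rms, bool(res.success), res.message


def fit_t1_pixel(
    signals: Sequence[float],
    inversion_times: Sequence[float],
    restore_polarity: bool = False,
) -> MolliFit:
    """Fit one pixel's inversion-recovery curve.

    Parameters
    ----------
    signals
        Signal samples, one per inversion time (signed by default).
    inversion_times
        Strictly increasing TIs in ms; at least 3 samples.
    restore_polarity
        For magnitude data: refit with the first ``j`` samples negated
        for every split ``j`` and keep the lowest-residual solution.

    Deterministic given its inputs.
    """
    s = np.asarray(signals, dtype=float)
    tis = np.asarray(inversion_times, dtype=float)
    if s.ndim != 1 or tis.ndim != 1 or s.size != tis.size:
        raise ValueError("signals and inversion_times must be 1-D and equal-length")
    if s.size < 3:
        raise ValueError(f"need at least 3 samples, got {s.size}")
    if np.any(np.diff(tis) <= 0):
        raise ValueError("inversion times must be strictly increasing")
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(tis))):
        return MolliFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, "non-finite input")
    if np.ptp(s) == 0.0:
        return MolliFit(float(s[0]), np.nan, np.nan, np.nan, 0.0, False, "degenerate: constant signal")

    candidates = [s]
    if restore_polarity:
        for j in range(1, s.size):
            flipped = s.copy()
            flipped[:j] = -flipped[:j]
            candidates.append(flipped)

    best = None
    for cand in candidates:
        params, rms, ok, msg = _fit_once(cand, tis)
        if best is None or rms < best[1]:
            best = (params, rms, ok, msg)
    params, rms, ok, msg = best
    a, b, t1s = (float(v) for v in params)
    if a > 0:
        t1 = t1s * (b / a - 1.0)
    else:
        t1 = np.nan
        ok = False
        msg = f"non-physical fit (A={a:.3g}); {msg}"
    if not np.isfinite(t1) or t1 <= 0:
        ok = False
    return MolliFit(a=a, b=b, t1_star=t1s, t1=t1, residual_rms=rms, converged=ok, message=msg)


def fit_t1_map(
    series: Union[MolliSeries, np.ndarray],
    inversion_times: Optional[Sequence[float]] = None,
    myo_mask: Optional[np.ndarray] = None,
    pixel_spacing: Optional[float] = None,
    restore_polarity: Optional[bool] = None,
) -> ParametricMap:
    """Fit every pixel of a TI series and assemble a native T1 map.

    ``series`` may be a :class:`~infarctmap.phantom.MolliSeries` (which
    carries its TIs, spacing and signal mode) or a raw ``(n_ti, rows,
    cols)`` stack with the remaining arguments supplied. Pixels outside
    ``myo_mask`` and pixels whose fit does not converge are set to NaN.
    """
    if isinstance(series, MolliSeries):
        frames = series.frames
        if inversion_times is None:
            inversion_times = series.inversion_times
        if pixel_spacing is None:
            pixel_spacing = series.pixel_spacing
        if restore_polarity is None:
            restore_polarity = series.magnitude
    else:
        frames = np.asarray(series, dtype=float)
        if inversion_times is None:
            raise ValueError("inversion_times required for a raw frame stack")
        if pixel_spacing is None:
            pixel_spacing = 1.0
        if restore_polarity is None:
            restore_polarity = False
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError(f"series must be (n_ti, rows, cols), got shape {frames.shape}")
    tis = np.asarray(inversion_times, dtype=float)
    if tis.size != frames.shape[0]:
        raise ValueError(
            f"{tis.size} inversion times for {frames.shape[0]} frames"
        )
    shape = frames.shape[1:]
    if myo_mask is not None:
        myo_mask = np.asarray(myo_mask, dtype=bool)
        if myo_mask.shape != shape:
            raise ValueError(f"mask shape {myo_mask.shape} != frame shape {shape}")

    out = np.full(shape, np.nan)
    rows, cols = np.nonzero(myo_mask) if myo_mask is not None else np.nonzero(
        np.ones(shape, dtype=bool)
    )
    for r, c in zip(rows, cols):
        fit = fit_t1_pixel(frames[:, r, c], tis, restore_polarity=restore_polarity)
        if fit.converged:
            out[r, c] = fit.t1
    return ParametricMap(out, float(pixel_spacing), "T1", "molli-fit")
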