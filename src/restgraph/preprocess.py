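"""Signal-side preprocessing: nuisance regression, band-pass, motion screening.

Operates on region-averaged series (voxel-level spatial preprocessing is out
of scope); the standard resting-state order is nuisance regression first,
then temporal band-pass filtering.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import signal

from .errors import DegenerateDesignError, InsufficientVolumesError, InvalidBandError
from .types import MotionSummary, MotionTrace, RoiTimeSeries

__all__ = [
    "regress_nuisance",
    "bandpass",
    "summarize_motion",
    "screen_subjects",
    "DEFAULT_MAX_TRANSLATION_MM",
    "DEFAULT_MAX_ROTATION_DEG",
]

#: Motion screening thresholds: subjects are kept only when every per-axis
#: maximum is strictly below these values.
DEFAULT_MAX_TRANSLATION_MM = 3.0
DEFAULT_MAX_ROTATION_DEG = 3.0


def regress_nuisance(ts: RoiTimeSeries, regressors: np.ndarray | None) -> RoiTimeSeries:
    """Remove nuisance variance by ordinary least squares.

    Each region's series is regressed on ``[intercept | regressors]`` and the
    residuals returned; residual columns are orthogonal to every design
    column.  ``regressors`` is a T x K matrix (e.g. motion parameters, linear
    drift, tissue mean signals) or None for intercept-only (mean centring).
    """
    t = ts.n_timepoints
    if regressors is None:
        design = np.ones((t, 1))
    else:
        regressors = np.asarray(regressors, dtype=float)
        if regressors.ndim == 1:
            regressors = regressors[:, None]
        if regressors.shape[0] != t:
            raise DegenerateDesignError(
                f"regressor rows ({regressors.shape[0]}) != timepoints ({t})"
            )
        design = np.column_stack([np.ones(t), regressors])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        r = 0
        for j in range(design.shape[1]):
            rj = np.linalg.matrix_rank(design[:, : j + 1])
            if rj == r:
                bad.append(j - 1)  # column index within `regressors`
            r = rj
        raise DegenerateDesignError(
            f"rank-deficient nuisance design (rank {rank} < {design.shape[1]}); "
            f"collinear regressor columns: {bad}"
        )
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    residuals = ts.data - design @ beta
    return replace(ts, data=residuals)


def bandpass(ts: RoiTimeSeries, low_hz: float = 0.01, high_hz: float = 0.08,
             method: str = "butterworth") -> RoiTimeSeries:
    """Zero-phase temporal band-pass filter.

    ``method='butterworth'`` (default) applies a second-order Butterworth
    band-pass forward and backward (`scipy.signal.filtfilt`), giving zero
    phase shift; ``method='fft'`` applies an ideal brick-wall filter in the
    frequency domain, for sensitivity checks.
    """
    nyquist = 1.0 / (2.0 * ts.sampling_interval_s)
    if not 0.0 < low_hz < high_hz < nyquist:
        raise InvalidBandError(
            f"band [{low_hz}, {high_hz}] Hz outside (0, Nyquist={nyquist:.4g}) Hz"
        )
    if method == "butterworth":
        b, a = signal.butter(2, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.sampling_interval_s)
        filtered = signal.filtfilt(b, a, ts.data, axis=0)
    elif method == "fft":
        freqs = np.fft.rfftfreq(ts.n_timepoints, d=ts.sampling_interval_s)
        spectrum = np.fft.rfft(ts.data, axis=0)
        keep = (freqs >= low_hz) & (freqs <= high_hz)
        spectrum[~keep, :] = 0.0
        filtered = np.fft.irfft(spectrum, n=ts.n_timepoints, axis=0)
    else:
        raise ValueError(f"unknown band-pass method {method!r}")
    return replace(ts, data=filtered)


def summarize_motion(
    trace: MotionTrace,
    max_translation_mm: float = DEFAULT_MAX_TRANSLATION_MM,
    max_rotation_deg: float = DEFAULT_MAX_ROTATION_DEG,
) -> MotionSummary:
    """Summarize a motion trace Van Dijk-style.

    Relative displacement is the mean over consecutive volume pairs of the
    Euclidean norm of the translation difference; relative rotation is the
    analogue on the (degree-valued) rotation parameters.  The ``excluded``
    flag applies the strict less-than screening rule to the per-axis maxima.
    """
    t = trace.translations.shape[0]
    if t < 2:
        raise InsufficientVolumesError(f"{trace.subject_id}: need >= 2 volumes, got {t}")
    dt = np.diff(trace.translations, axis=0)
    dr = np.diff(trace.rotations, axis=0)
    max_abs_t = np.max(np.abs(trace.translations), axis=0)
    max_abs_r = np.max(np.abs(trace.rotations), axis=0)
    excluded = bool(
        np.any(max_abs_t >= max_translation_mm) or np.any(max_abs_r >= max_rotation_deg)
    )
    return MotionSummary(
        subject_id=trace.subject_id,
        max_abs_translation_mm=max_abs_t,
        max_abs_rotation_deg=max_abs_r,
        mean_relative_displacement_mm=float(np.mean(np.linalg.norm(dt, axis=1))),
        mean_relative_rotation_deg=float(np.mean(np.linalg.norm(dr, axis=1))),
        excluded=excluded,
    )


def screen_subjects(
    summaries: list[MotionSummary],
    max_translation_mm: float = DEFAULT_MAX_TRANSLATION_MM,
    max_rotation_deg: float = DEFAULT_MAX_ROTATION_DEG,
) -> pd.DataFrame:
    """Apply the motion screening rule to a cohort.

    A subject is included only when every per-axis translation maximum is
    strictly below ``max_translation_mm`` and every per-axis rotation maximum
    strictly below ``max_rotation_deg``; boundary values fail.  Returns a
    table (subject_id, included, reason).
    """
    if max_translation_mm <= 0 or max_rotation_deg <= 0:
        raise ValueError("screening thresholds must be positive")
    rows = []
    for s in summaries:
        reasons = []
        for axis, v in zip("xyz", s.max_abs_translation_mm):
            if v >= max_translation_mm:
                reasons.append(f"translation {axis}={v:.3g} mm >= {max_translation_mm} mm")
        for axis, v in zip("xyz", s.max_abs_rotation_deg):
            if v >= max_rotation_deg:
                reasons.append(f"rotation {axis}={v:.3g} deg >= {max_rotation_deg} deg")
        rows.append(
            {
                "subject_id": s.subject_id,
                "included": not reasons,
                "reason": "; ".join(reasons),
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "included", "reason"])
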