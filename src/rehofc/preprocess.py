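"""Temporal preprocessing and head-motion quality assurance.

The fixed preprocessing order for a resting-state series is
discard -> linear detrend -> band-pass (0.01-0.08 Hz) -> nuisance
regression; motion scrubbing is then applied on the connectivity branch
only.  All operations respect the brain mask: out-of-mask voxels pass
through untouched and never enter any statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.fft
from scipy import stats as sps

from .core import BoldSeries, MotionTrace

log = logging.getLogger(__name__)

DEFAULT_BAND_HZ = (0.01, 0.08)
DEFAULT_DRMS_THRESHOLD_MM = 0.5
DEFAULT_SPHERE_RADIUS_MM = 50.0
DEFAULT_MAX_TRANSLATION_MM = 2.0
DEFAULT_MAX_ROTATION_DEG = 2.0
DEFAULT_N_DISCARD = 10


@dataclass
class ScrubReport:
    """Outcome of motion scrubbing for one subject."""

    drms_per_transition: np.ndarray
    flagged_volumes: np.ndarray  # sorted indices
    retained_volumes: np.ndarray  # sorted indices, original order
    excluded_subject: bool

    def to_dict(self) -> dict:
        return {
            "n_flagged": int(self.flagged_volumes.size),
            "n_retained": int(self.retained_volumes.size),
            "flagged_volumes": [int(v) for v in self.flagged_volumes],
            "excluded_subject": bool(self.excluded_subject),
            "max_drms_mm": float(self.drms_per_transition.max())
            if self.drms_per_transition.size else 0.0,
        }


def discard_initial(series: BoldSeries, n_discard: int = DEFAULT_N_DISCARD) -> BoldSeries:
    """Drop the first ``n_discard`` volumes (T1-equilibration period)."""
    if n_discard < 0:
        raise ValueError("n_discard must be nonnegative")
    if n_discard >= series.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {series.n_volumes} volumes")
    return series.with_data(series.data[..., n_discard:])


def detrend_linear(series: BoldSeries) -> BoldSeries:
    """Remove each in-mask voxel's least-squares line (mean and slope)."""
    t = series.n_volumes
    if t < 3:
        raise ValueError("need at least 3 volumes to detrend")
    x = np.arange(t, dtype=float)
    design = np.column_stack([np.ones(t), x - x.mean()])
    y = series.masked().T  # (t, nvox)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return series.put_masked((y - design @ beta).T)


def bandpass(series: BoldSeries,
             low_hz: float = DEFAULT_BAND_HZ[0],
             high_hz: float = DEFAULT_BAND_HZ[1]) -> BoldSeries:
    """Ideal (rectangular) frequency-domain band-pass on in-mask voxels.

    Each voxel series is zero-padded to a fast FFT length, transformed,
    bins strictly outside [low_hz, high_hz] are zeroed, and the series is
    transformed back and truncated.  The rectangular response mirrors the
    REST-toolkit family of filters.
    """
    t = series.n_volumes
    nyquist = 0.5 / series.tr_s
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high cutoff {high_hz} Hz not below Nyquist {nyquist:.4f} Hz")
    y = series.masked()  # (nvox, t)
    # padding a demeaned signal limits spectral leakage from the edge step
    mean = y.mean(axis=1, keepdims=True)
    n_pad = scipy.fft.next_fast_len(2 * t)
    spec = scipy.fft.rfft(y - mean, n=n_pad, axis=1)
    freqs = scipy.fft.rfftfreq(n_pad, d=series.tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec[:, ~keep] = 0.0
    filtered = scipy.fft.irfft(spec, n=n_pad, axis=1)[:, :t]
    return series.put_masked(filtered)


def extract_tissue_signal(series: BoldSeries, tissue_mask: np.ndarray) -> np.ndarray:
    """Per-volume mean signal over a tissue mask (global/WM/CSF regressors)."""
    if not np.asarray(tissue_mask).any():
        raise ValueError("tissue mask is empty")
    return series.data[np.asarray(tissue_mask, dtype=bool)].mean(axis=0)


def regress_nuisance(series: BoldSeries, regressors: np.ndarray) -> BoldSeries:
    """OLS-residualize every in-mask voxel against [intercept | regressors].

    Collinear regressor columns are dropped with a warning rather than
    failing the subject.
    """
    t = series.n_volumes
    regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
    if regressors.size == 0:
        regressors = np.empty((t, 0))
    if regressors.shape[0] != t:
        raise ValueError("regressor rows must match volume count")
    if regressors.shape[1] >= t:
        raise ValueError("more regressors than time points")
    if not np.isfinite(regressors).all():
        raise ValueError("regressors must be finite")

    design = np.column_stack([np.ones(t), regressors])
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    keep = diag > (diag.max() * 1e-10)
    if not keep.all():
        dropped = [int(i) - 1 for i in np.where(~keep)[0]]
        log.warning("dropping %d collinear nuisance column(s): %s",
                    len(dropped), dropped)
        design = design[:, keep]
        q, _ = np.linalg.qr(design)
    y = series.masked().T  # (t, nvox)
    resid = y - q @ (q.T @ y)
    return series.put_masked(resid.T)


def framewise_drms(motion: MotionTrace,
                   sphere_radius_mm: float = DEFAULT_SPHERE_RADIUS_MM) -> np.ndarray:
    """Framewise RMS displacement between neighboring volumes.

    Rotations (degrees) are converted to arc length on a sphere of
    ``sphere_radius_mm`` so that all six parameters are in mm; element i
    is the RMS over the six backward-differenced parameters between
    volumes i and i+1.
    """
    if motion.n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    p = motion.params.copy()
    p[:, 3:] = np.deg2rad(p[:, 3:]) * sphere_radius_mm
    d = np.diff(p, axis=0)
    return np.sqrt(np.mean(d ** 2, axis=1))


def scrub(series: BoldSeries, drms: np.ndarray,
          threshold_mm: float = DEFAULT_DRMS_THRESHOLD_MM,
          ) -> tuple[BoldSeries, ScrubReport]:
    """Delete motion-contaminated volumes before connectivity analysis.

    A transition i -> i+1 with dRMS above threshold is attributed to the
    later volume i+1; that volume, the one back (i) and the two forward
    (i+2, i+3) are flagged, clipped to the scan range.  Flagged volumes
    are removed; the survivors keep their original temporal order.
    """
    t = series.n_volumes
    drms = np.asarray(drms, dtype=float)
    if drms.shape != (t - 1,):
        raise ValueError("drms must have length t-1")
    flagged = np.zeros(t, dtype=bool)
    for i in np.where(drms > threshold_mm)[0]:
        lo, hi = max(i, 0), min(i + 3, t - 1)  # volumes i .. i+3
        flagged[lo:hi + 1] = True
    retained = np.where(~flagged)[0]
    report = ScrubReport(
        drms_per_transition=drms,
        flagged_volumes=np.where(flagged)[0],
        retained_volumes=retained,
        excluded_subject=retained.size == 0,
    )
    if retained.size == 0:
        raise ValueError("all volumes flagged by scrubbing; subject unusable")
    return series.with_data(series.data[..., retained]), report


def exclusion_check(motion: MotionTrace,
                    max_mm: float = DEFAULT_MAX_TRANSLATION_MM,
                    max_deg: float = DEFAULT_MAX_ROTATION_DEG) -> bool:
    """True (exclude subject) iff any cumulative translation exceeds
    ``max_mm`` or any cumulative rotation exceeds ``max_deg``."""
    return bool(
        (np.abs(motion.translations_mm) > max_mm).any()
        or (np.abs(motion.rotations_deg) > max_deg).any()
    )


def preprocess_series(series: BoldSeries, motion: MotionTrace,
                      nuisance_masks: dict[str, np.ndarray] | None = None,
                      n_discard: int = DEFAULT_N_DISCARD,
                      band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
                      global_signal: bool = True,
                      ) -> tuple[BoldSeries, MotionTrace]:
    """Run the fixed preprocessing chain on one subject.

    Returns the preprocessed (unscrubbed) series and the motion trace
    truncated in lockstep with the volume discard.  ``nuisance_masks``
    may provide "global", "wm", and "csf" masks; their mean signals plus
    the six motion parameters are regressed out.  Global-signal
    regression defaults on and is controlled by ``global_signal``.
    """
    if motion.n_volumes != series.n_volumes:
        raise ValueError("motion trace length must match volume count")
    out = discard_initial(series, n_discard)
    motion_kept = MotionTrace(motion.params[n_discard:])
    out = detrend_linear(out)
    out = bandpass(out, *band_hz)
    columns = [motion_kept.params]
    if nuisance_masks:
        if global_signal and "global" in nuisance_masks:
            columns.append(extract_tissue_signal(out, nuisance_masks["global"])[:, None])
        for key in ("wm", "csf"):
            if key in nuisance_masks:
                columns.append(extract_tissue_signal(out, nuisance_masks[key])[:, None])
    out = regress_nuisance(out, np.column_stack(columns))
    return out, motion_kept


def motion_group_comparison(mean_drms: np.ndarray, groups: np.ndarray,
                            patient_label="patient", control_label="control") -> dict:
    """QA report: two-sample t-test of per-subject mean dRMS between groups."""
    groups = np.asarray(groups)
    a = np.asarray(mean_drms)[groups == patient_label]
    b = np.asarray(mean_drms)[groups == control_label]
    t, p = sps.ttest_ind(a, b)
    return {
        "patient_mean_drms_mm": float(np.mean(a)),
        "control_mean_drms_mm": float(np.mean(b)),
        "t": float(t),
        "p": float(p),
        "significant_at_0.05": bool(p < 0.05),
    }
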