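"""Spectral quality control and preprocessing.

The chain applied to raw plasma absorbance spectra:

1. quality test (signal amplitude, signal-to-noise, water-vapour residuals),
2. truncation to the 800-4000 cm^-1 processing range,
3. rubberband (lower convex hull) baseline subtraction,
4. Savitzky-Golay second derivative (multivariate branch only),
5. vector normalisation,

yielding two representations: the baseline-corrected, vector-normalised
absorbance spectra (used for mean and difference spectra) and the
second-derivative, vector-normalised spectra restricted to 3500-1000 cm^-1
(used for PCA and PLS-DA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .cohort import Spectrum, SpectralDataset

__all__ = [
    "QualityThresholds",
    "QualityReport",
    "PreprocessConfig",
    "quality_test",
    "truncate",
    "rubberband_baseline",
    "second_derivative",
    "vector_normalize",
    "preprocess_dataset",
]


@dataclass
class QualityThresholds:
    """Acceptance window for raw spectra.

    ``min_signal``/``max_signal`` bound the absorbance maximum in the amide I
    region; ``min_snr`` bounds the ratio of that maximum to the noise SD
    estimated in a band-free window; ``max_water_vapor`` bounds the
    peak-to-peak detrended residual in the 1837-1847 cm^-1 water-vapour
    window.  Defaults reflect typical high-throughput transmission FTIR
    acceptance windows for dried biofluid films.
    """

    min_signal: float = 0.35
    max_signal: float = 1.25
    min_snr: float = 10.0
    max_water_vapor: float = 0.05
    signal_region: tuple[float, float] = (1600.0, 1700.0)
    noise_region: tuple[float, float] = (1800.0, 1900.0)
    water_vapor_region: tuple[float, float] = (1837.0, 1847.0)

    def __post_init__(self) -> None:
        if self.min_signal >= self.max_signal:
            raise ValueError("min_signal must be < max_signal")
        if self.min_snr <= 0:
            raise ValueError("min_snr must be positive")


@dataclass
class QualityReport:
    """Per-spectrum quality metrics and pass/fail flags."""

    metrics: dict[str, float]
    checks: dict[str, bool]
    passed: bool

    @property
    def failed_criteria(self) -> list[str]:
        return [k for k, ok in self.checks.items() if not ok]


@dataclass
class PreprocessConfig:
    truncate_lo: float = 800.0
    truncate_hi: float = 4000.0
    analysis_lo: float = 1000.0
    analysis_hi: float = 3500.0
    sg_window: int = 9
    sg_polyorder: int = 3
    normalisation: str = "center_unit_norm"  # or "unit_norm"
    derivative_for_multivariate: bool = True

    def __post_init__(self) -> None:
        if not self.truncate_lo < self.analysis_lo < self.analysis_hi < self.truncate_hi:
            raise ValueError("require truncate_lo < analysis_lo < analysis_hi < truncate_hi")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and greater than sg_polyorder")
        if self.normalisation not in ("center_unit_norm", "unit_norm"):
            raise ValueError(f"unknown normalisation {self.normalisation!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def _region_slice(w: np.ndarray, lo: float, hi: float) -> np.ndarray:
    mask = (w >= lo) & (w <= hi)
    if not mask.any():
        raise ValueError(f"grid does not cover region [{lo}, {hi}] cm^-1")
    return mask


def _detrended(values: np.ndarray) -> np.ndarray:
    """Residual after removing a least-squares line (index as abscissa)."""
    x = np.arange(len(values), dtype=float)
    coef = np.polyfit(x, values, 1)
    return values - np.polyval(coef, x)


def quality_test(s: Spectrum, t: QualityThresholds) -> QualityReport:
    """Evaluate a raw spectrum against the quality thresholds.

    The overall verdict is the conjunction of the per-criterion checks.
    """
    w, a = s.wavenumbers, s.absorbance
    signal = float(a[_region_slice(w, *t.signal_region)].max())
    noise_vals = a[_region_slice(w, *t.noise_region)]
    noise_sd = float(np.std(_detrended(noise_vals), ddof=1))
    if noise_sd > 0:
        snr = signal / noise_sd
    else:
        snr = math.inf if signal > 0 else 0.0
    wv_vals = a[_region_slice(w, *t.water_vapor_region)]
    water_vapor = float(np.ptp(_detrended(wv_vals)))

    checks = {
        "signal_min": signal >= t.min_signal,
        "signal_max": signal <= t.max_signal,
        "snr": snr >= t.min_snr,
        "water_vapor": water_vapor <= t.max_water_vapor,
    }
    metrics = {"signal": signal, "noise_sd": noise_sd, "snr": snr, "water_vapor": water_vapor}
    return QualityReport(metrics, checks, all(checks.values()))


def truncate(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep exactly the grid points with lo <= w <= hi; metadata preserved."""
    if lo >= hi:
        raise ValueError("require lo < hi")
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(f"truncation window [{lo}, {hi}] does not overlap the grid")
    return s.replace(wavenumbers=s.wavenumbers[mask], absorbance=s.absorbance[mask])


def _lower_hull_baseline(w_asc: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Lower convex hull of the points (w, a), linearly interpolated.

    Andrew's monotone chain restricted to the lower boundary; ``w_asc`` must
    be strictly increasing.
    """
    n = len(w_asc)
    hull: list[int] = []
    for i in range(n):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # pop k if it lies on or above the chord j->i
            cross = (w_asc[k] - w_asc[j]) * (a[i] - a[j]) - (a[k] - a[j]) * (w_asc[i] - w_asc[j])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(w_asc, w_asc[hull], a[hull])


def rubberband_baseline(s: Spectrum) -> tuple[Spectrum, Spectrum]:
    """Rubberband baseline correction.

    The baseline is the lower convex hull boundary of the (wavenumber,
    absorbance) points; the corrected spectrum is the input minus that
    baseline, hence non-negative and exactly zero at every hull vertex
    (including both endpoints).
    """
    if len(s.wavenumbers) < 2:
        raise ValueError("need at least two points")
    if not np.all(np.isfinite(s.absorbance)):
        raise ValueError("absorbance must be finite")
    ascending = s.wavenumbers[0] < s.wavenumbers[-1]
    w = s.wavenumbers if ascending else s.wavenumbers[::-1]
    a = s.absorbance if ascending else s.absorbance[::-1]
    base = _lower_hull_baseline(w, a)
    if not ascending:
        base = base[::-1]
    return s.replace(absorbance=s.absorbance - base), s.replace(absorbance=base)


def second_derivative(s: Spectrum, window: int = 9, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay second derivative with respect to wavenumber.

    Each point gets the second derivative of a local least-squares
    polynomial fit over ``window`` points; within the terminal half-windows
    the edge polynomial is evaluated directly (polynomial extrapolation).
    Units: absorbance x cm^2.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder < 2 or window <= polyorder:
        raise ValueError("require window > polyorder >= 2")
    if len(s.wavenumbers) < window:
        raise ValueError("spectrum shorter than the filter window")
    step = abs(float(s.wavenumbers[1] - s.wavenumbers[0]))
    d2 = savgol_filter(s.absorbance, window, polyorder, deriv=2, delta=step, mode="interp")
    return s.replace(absorbance=d2)


def vector_normalize(s: Spectrum, mode: str = "center_unit_norm") -> Spectrum:
    """Scale a spectrum to unit Euclidean norm.

    ``center_unit_norm`` first subtracts the mean (the OPUS-style dialect);
    ``unit_norm`` only rescales.
    """
    a = s.absorbance
    if mode == "center_unit_norm":
        a = a - a.mean()
        if np.allclose(a, 0):
            raise ValueError("constant spectrum cannot be centre-normalised")
    elif mode == "unit_norm":
        if np.allclose(a, 0):
            raise ValueError("zero spectrum cannot be normalised")
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    return s.replace(absorbance=a / np.linalg.norm(a))


# ---------------------------------------------------------------------------
# dataset-level pipeline


def _matrix_rubberband(w: np.ndarray, data: np.ndarray) -> np.ndarray:
    ascending = w[0] < w[-1]
    w_asc = w if ascending else w[::-1]
    out = np.empty_like(data)
    for i in range(data.shape[0]):
        a = data[i] if ascending else data[i, ::-1]
        corrected = a - _lower_hull_baseline(w_asc, a)
        out[i] = corrected if ascending else corrected[::-1]
    return out


def _matrix_normalize(data: np.ndarray, mode: str) -> np.ndarray:
    if mode == "center_unit_norm":
        data = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(data, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm spectrum encountered during normalisation")
    return data / norms


def preprocess_dataset(
    d: SpectralDataset,
    config: PreprocessConfig | None = None,
    thresholds: QualityThresholds | None = None,
) -> tuple[SpectralDataset, SpectralDataset, pd.DataFrame]:
    """Run QC and the full preprocessing chain over a dataset.

    Returns ``(multivariate_set, absorbance_set, qc_log)``:

    * ``absorbance_set`` — truncate to the processing range, rubberband
      baseline correction, vector normalisation (the representation used
      for mean and difference spectra);
    * ``multivariate_set`` — additionally the Savitzky-Golay second
      derivative, restricted to the analysis range before the final vector
      normalisation so every retained spectrum has unit norm;
    * ``qc_log`` — one row per *rejected* spectrum with its metric values
      and the failed criteria.

    Raises if every spectrum fails QC.
    """
    config = config or PreprocessConfig()
    thresholds = thresholds or QualityThresholds()

    keep, log_rows = [], []
    for i in range(len(d)):
        rep = quality_test(d[i], thresholds)
        if rep.passed:
            keep.append(i)
        else:
            log_rows.append(
                {
                    "spectrum_id": d.metadata.iloc[i]["spectrum_id"],
                    **rep.metrics,
                    "failed_criteria": ";".join(rep.failed_criteria),
                }
            )
    if not keep:
        raise ValueError("all spectra failed the quality test")
    qc_log = pd.DataFrame(
        log_rows, columns=["spectrum_id", "signal", "noise_sd", "snr", "water_vapor",
                           "failed_criteria"]
    )
    passed = d.select(np.asarray(keep, dtype=int))

    # shared front of the chain: truncate + rubberband
    tmask = (passed.wavenumbers >= config.truncate_lo) & (passed.wavenumbers <= config.truncate_hi)
    if not tmask.any():
        raise ValueError("truncation window does not overlap the grid")
    w_t = passed.wavenumbers[tmask]
    corrected = _matrix_rubberband(w_t, passed.data[:, tmask])

    absorbance_set = passed.with_data(
        w_t, _matrix_normalize(corrected, config.normalisation)
    )

    mv = corrected
    if config.derivative_for_multivariate:
        step = abs(float(w_t[1] - w_t[0]))
        mv = savgol_filter(mv, config.sg_window, config.sg_polyorder, deriv=2,
                           delta=step, axis=1, mode="interp")
    amask = (w_t >= config.analysis_lo) & (w_t <= config.analysis_hi)
    multivariate_set = passed.with_data(
        w_t[amask], _matrix_normalize(mv[:, amask], config.normalisation)
    )
    return multivariate_set, absorbance_set, qc_log
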