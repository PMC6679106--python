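"""Mean spectra, difference spectra and pointwise significance maps.

Group comparisons are made on patient-mean spectra (one spectrum per
patient, averaging the instrumental replicates) to avoid pseudo-replication:
replicate spots of one sample are not independent observations of the
cohort.  At every grid point an independent two-sample two-tailed t-test
(Welch by default) is computed across the patient means, and points with
p below the significance level form the significant mask.  No
multiple-testing correction is applied by default, matching the shaded
p < 0.001 convention of difference-spectrum figures; Benjamini-Hochberg
is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BandDefinition, Spectrum, SpectralDataset, nearest_band

__all__ = [
    "DifferenceResult",
    "patient_mean_spectra",
    "group_mean",
    "difference_spectrum",
    "significant_regions",
]


@dataclass
class DifferenceResult:
    """Difference of group-mean spectra with a pointwise significance map.

    ``difference = mean_b - mean_a``; the subtraction direction is recorded
    in ``group_a``/``group_b``.  ``significant_mask`` is ``p_value < alpha``.
    """

    grid: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    difference: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    significant_mask: np.ndarray
    alpha: float
    n_a: int
    n_b: int
    group_a: str = ""
    group_b: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavenumber": self.grid,
                "mean_a": self.mean_a,
                "mean_b": self.mean_b,
                "difference": self.difference,
                "t_stat": self.t_stat,
                "p_value": self.p_value,
                "significant": self.significant_mask,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def patient_mean_spectra(d: SpectralDataset) -> SpectralDataset:
    """Average replicates into one spectrum per (patient, group)."""
    frames = []
    data_rows = []
    for (pid, grp), idx in d.metadata.groupby(["patient_id", "group"], sort=False).groups.items():
        idx = np.asarray(idx)
        data_rows.append(d.data[idx].mean(axis=0))
        row = d.metadata.iloc[idx[0]].copy()
        row["replicate"] = 0
        row["spectrum_id"] = f"{pid}:{grp}:mean"
        frames.append(row)
    meta = pd.DataFrame(frames).reset_index(drop=True)
    return SpectralDataset(d.wavenumbers, np.vstack(data_rows), meta)


def group_mean(d: SpectralDataset, group: str) -> Spectrum:
    """Pointwise mean over a group's patient-mean spectra."""
    means = patient_mean_spectra(d)
    mask = (means.metadata["group"] == group).to_numpy()
    if not mask.any():
        raise ValueError(f"group {group!r} is empty")
    return Spectrum(means.wavenumbers, means.data[mask].mean(axis=0), group_label=group,
                    patient_id=f"mean({group})")


def difference_spectrum(
    d: SpectralDataset,
    group_a: str,
    group_b: str,
    alpha: float = 0.001,
    equal_var: bool = False,
    correction: str | None = None,
) -> DifferenceResult:
    """Difference of group means with a pointwise t-test mask.

    Parameters
    ----------
    d : SpectralDataset
        Preprocessed spectra; replicates are averaged per patient first.
    group_a, group_b : str
        Reference and comparison groups; ``difference = mean_b - mean_a``.
    alpha : float
        Pointwise significance level (default 0.001).
    equal_var : bool
        Pooled-variance Student's t instead of Welch's t.
    correction : {None, "bh"}
        Optional Benjamini-Hochberg adjustment of the p-values before
        thresholding.
    """
    means = patient_mean_spectra(d)
    A = means.data[(means.metadata["group"] == group_a).to_numpy()]
    B = means.data[(means.metadata["group"] == group_b).to_numpy()]
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each group needs at least two patient-mean spectra")

    t_stat, p = stats.ttest_ind(B, A, axis=0, equal_var=equal_var)
    if correction == "bh":
        p = stats.false_discovery_control(p, method="bh")
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    return DifferenceResult(
        grid=means.wavenumbers,
        mean_a=mean_a,
        mean_b=mean_b,
        difference=mean_b - mean_a,
        t_stat=np.asarray(t_stat),
        p_value=np.asarray(p),
        significant_mask=np.asarray(p) < alpha,
        alpha=alpha,
        n_a=len(A),
        n_b=len(B),
        group_a=group_a,
        group_b=group_b,
    )


def significant_regions(
    r: DifferenceResult, band_library: list[BandDefinition] | None = None
) -> list[dict]:
    """Contiguous significant wavenumber intervals, optionally annotated
    with the nearest band assignment.

    Returns a list of dicts with keys ``lo``, ``hi`` (cm^-1, lo <= hi) and,
    if a band library is given, ``assignment``.
    """
    mask = np.asarray(r.significant_mask, dtype=bool)
    regions = []
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j + 1 < len(mask) and mask[j + 1]:
                j += 1
            w_lo = float(min(r.grid[i], r.grid[j]))
            w_hi = float(max(r.grid[i], r.grid[j]))
            entry = {"lo": w_lo, "hi": w_hi}
            if band_library:
                entry["assignment"] = nearest_band((w_lo + w_hi) / 2.0, band_library).label
            regions.append(entry)
            i = j + 1
        else:
            i += 1
    return regions
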