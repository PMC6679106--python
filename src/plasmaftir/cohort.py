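"""Synthetic plasma-like FTIR spectral cohorts.

Generates absorbance spectra with the hierarchical structure the downstream
analysis assumes: a group-level effect on band intensities, a patient-level
multiplicative random effect, and replicate-level (spot) jitter plus additive
white noise, all on top of a smooth polynomial background.  The default
configuration emulates a prostate-cancer radiotherapy-monitoring cohort:
five treatment time points (baseline, post hormone therapy, post
radiotherapy, two and eight months after radiotherapy) with 10 instrumental
replicates per patient sample, on a descending 4000-400 cm^-1 grid.

Band intensities scale multiplicatively (log-normal effects), consistent with
Beer-Lambert concentration scaling, which keeps absorbance positive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BandDefinition",
    "GroupEffect",
    "CohortConfig",
    "Spectrum",
    "SpectralDataset",
    "generate_cohort",
    "reference_trace",
    "default_band_library",
    "treatment_monitoring_config",
    "toxicity_config",
    "nearest_band",
]

_GAUSS_K = 4.0 * np.log(2.0)  # exp(-4 ln2 x^2 / fwhm^2) has FWHM = fwhm


@dataclass(frozen=True)
class BandDefinition:
    """One vibrational absorption band.

    Parameters
    ----------
    center : float
        Band centre in cm^-1, within [400, 4000].
    width : float
        Full width at half maximum in cm^-1.
    base_amplitude : float
        Peak absorbance of the band in the reference (effect-free) spectrum.
    shape : {"gaussian", "lorentzian"}
        Line shape.
    label : str
        Assignment label, e.g. ``"amide I"``; used to address the band from
        group effects and to annotate significant regions in reports.
    """

    center: float
    width: float
    base_amplitude: float
    shape: str = "gaussian"
    label: str = ""

    def __post_init__(self) -> None:
        if not 400.0 <= self.center <= 4000.0:
            raise ValueError(f"band center {self.center} outside [400, 4000] cm^-1")
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.base_amplitude < 0:
            raise ValueError("base_amplitude must be non-negative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Unit-amplitude line profile evaluated on a wavenumber grid."""
        x = np.asarray(wavenumbers, dtype=float) - self.center
        if self.shape == "gaussian":
            return np.exp(-_GAUSS_K * x**2 / self.width**2)
        # Lorentzian with matching FWHM
        hwhm = self.width / 2.0
        return hwhm**2 / (x**2 + hwhm**2)


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative band-intensity shifts that define one cohort group.

    ``amplitude_multipliers`` maps band labels to positive scale factors;
    bands not mentioned keep their base amplitude, so an empty mapping (or
    all-ones) reproduces the reference group in distribution.
    """

    group_label: str
    amplitude_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, m in self.amplitude_multipliers.items():
            if m <= 0:
                raise ValueError(
                    f"multiplier for band {label!r} must be positive, got {m}"
                )


@dataclass
class CohortConfig:
    """Full parameterisation of a synthetic cohort.

    The patient and replicate effects are log-normal multiplicative factors
    on band amplitudes with the given relative SDs; ``noise_sd`` is additive
    white noise in absorbance units.  ``baseline_coeffs`` are polynomial
    coefficients (ascending powers) in the reduced coordinate
    ``x = (w - 2200) / 1800`` which maps 400..4000 cm^-1 onto [-1, 1].
    """

    band_library: list[BandDefinition] = field(default_factory=lambda: default_band_library())
    group_effects: list[GroupEffect] = field(default_factory=list)
    n_patients_per_group: dict[str, int] = field(default_factory=dict)
    replicates_per_sample: int = 10
    patient_sd: float = 0.08
    replicate_sd: float = 0.03
    noise_sd: float = 0.002
    baseline_coeffs: list[float] = field(default_factory=lambda: [0.05, 0.02, 0.01])
    grid_start: float = 4000.0
    grid_end: float = 400.0
    grid_step: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.patient_sd, self.replicate_sd, self.noise_sd) < 0:
            raise ValueError("all SDs must be non-negative")
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")
        if self.grid_start <= self.grid_end:
            raise ValueError("grid must run downward (grid_start > grid_end)")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        labels = {b.label for b in self.band_library}
        for eff in self.group_effects:
            unknown = set(eff.amplitude_multipliers) - labels
            if unknown:
                raise ValueError(
                    f"group {eff.group_label!r} references unknown bands: {sorted(unknown)}"
                )

    @property
    def wavenumbers(self) -> np.ndarray:
        """The descending wavenumber grid in cm^-1."""
        n = int(round((self.grid_start - self.grid_end) / self.grid_step)) + 1
        return self.grid_start - self.grid_step * np.arange(n)

    @property
    def group_labels(self) -> list[str]:
        return [e.group_label for e in self.group_effects]

    def baseline(self, wavenumbers: np.ndarray) -> np.ndarray:
        x = (np.asarray(wavenumbers, dtype=float) - 2200.0) / 1800.0
        return np.polynomial.polynomial.polyval(x, np.asarray(self.baseline_coeffs, dtype=float))

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["band_library"] = [BandDefinition(**b) for b in d.get("band_library", [])]
        d["group_effects"] = [GroupEffect(**g) for g in d.get("group_effects", [])]
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class Spectrum:
    """One absorbance trace on a wavenumber grid plus sample metadata."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    patient_id: str = ""
    group_label: str = ""
    replicate_id: int = 0
    acute_grade: int | None = None
    late_grade: int | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.shape != self.absorbance.shape:
            raise ValueError("wavenumbers and absorbance must have equal length")
        d = np.diff(self.wavenumbers)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumbers must be strictly monotone")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")

    @property
    def spectrum_id(self) -> str:
        return f"{self.patient_id}:{self.group_label}:{self.replicate_id}"

    def replace(self, **kw) -> "Spectrum":
        return dataclasses.replace(self, **kw)


_META_COLS = ["spectrum_id", "patient_id", "group", "replicate", "acute_grade", "late_grade"]


class SpectralDataset:
    """A collection of spectra on one shared wavenumber grid.

    Stores the absorbances as an ``(n_spectra, n_points)`` matrix together
    with a metadata table (patient id, group, replicate, toxicity grades).
    """

    def __init__(self, wavenumbers: np.ndarray, data: np.ndarray, metadata: pd.DataFrame):
        self.wavenumbers = np.asarray(wavenumbers, dtype=float)
        self.data = np.asarray(data, dtype=float)
        self.metadata = metadata.reset_index(drop=True)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.wavenumbers):
            raise ValueError("data must be (n_spectra, n_points) matching the grid")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata rows must match spectra")
        key = self.metadata[["patient_id", "group", "replicate"]]
        if key.duplicated().any():
            raise ValueError("(patient_id, group, replicate) must be unique")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_spectra(cls, spectra: list[Spectrum]) -> "SpectralDataset":
        if not spectra:
            raise ValueError("empty spectrum list")
        grid = spectra[0].wavenumbers
        for s in spectra[1:]:
            if not np.array_equal(s.wavenumbers, grid):
                raise ValueError("all spectra must share one identical grid")
        data = np.vstack([s.absorbance for s in spectra])
        meta = pd.DataFrame(
            {
                "spectrum_id": [s.spectrum_id for s in spectra],
                "patient_id": [s.patient_id for s in spectra],
                "group": [s.group_label for s in spectra],
                "replicate": [s.replicate_id for s in spectra],
                "acute_grade": [s.acute_grade for s in spectra],
                "late_grade": [s.late_grade for s in spectra],
            }
        )
        return cls(grid, data, meta)

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return self.data.shape[0]

    def __getitem__(self, i: int) -> Spectrum:
        row = self.metadata.iloc[i]
        ag, lg = row["acute_grade"], row["late_grade"]
        return Spectrum(
            self.wavenumbers,
            self.data[i],
            patient_id=row["patient_id"],
            group_label=row["group"],
            replicate_id=int(row["replicate"]),
            acute_grade=None if pd.isna(ag) else int(ag),
            late_grade=None if pd.isna(lg) else int(lg),
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.metadata["group"]))

    def select(self, mask) -> "SpectralDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.nonzero(mask)[0]
        else:
            idx = mask
        return SpectralDataset(self.wavenumbers, self.data[idx], self.metadata.iloc[idx])

    def subset_groups(self, groups: list[str]) -> "SpectralDataset":
        return self.select(self.metadata["group"].isin(groups).to_numpy())

    def with_data(self, wavenumbers: np.ndarray, data: np.ndarray) -> "SpectralDataset":
        return SpectralDataset(wavenumbers, data, self.metadata.copy())

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, data_path: str | Path, metadata_path: str | Path) -> None:
        """Write a wide data CSV (wavenumber column + one column per
        spectrum) and a metadata CSV."""
        wide = pd.DataFrame(
            self.data.T, columns=self.metadata["spectrum_id"], index=self.wavenumbers
        )
        wide.index.name = "wavenumber"
        wide.to_csv(data_path)
        self.metadata[_META_COLS].to_csv(metadata_path, index=False)

    @classmethod
    def read_csv(cls, data_path: str | Path, metadata_path: str | Path) -> "SpectralDataset":
        wide = pd.read_csv(data_path, index_col=0)
        meta = pd.read_csv(metadata_path)
        meta = (
            meta.set_index("spectrum_id")
            .loc[list(wide.columns)]
            .rename_axis("spectrum_id")
            .reset_index()
        )
        return cls(wide.index.to_numpy(float), wide.to_numpy(float).T, meta)


# ---------------------------------------------------------------------------
# generation


def reference_trace(config: CohortConfig) -> Spectrum:
    """The noiseless, effect-free spectrum: background polynomial plus all
    bands at their base amplitudes."""
    w = config.wavenumbers
    a = config.baseline(w)
    for band in config.band_library:
        a = a + band.base_amplitude * band.profile(w)
    return Spectrum(w, a, patient_id="reference", group_label="reference")


def generate_cohort(config: CohortConfig) -> SpectralDataset:
    """Draw a full synthetic cohort.

    For every group listed in ``config.group_effects`` and every patient,
    band amplitudes are ``base x group multiplier x exp(patient_sd * z)``;
    each of the ``replicates_per_sample`` spot spectra further multiplies
    each band by ``exp(replicate_sd * z)`` and adds white noise of SD
    ``noise_sd``.  Bit-reproducible for a given seed.
    """
    if not config.group_effects:
        raise ValueError("config defines no groups")
    for eff in config.group_effects:
        if config.n_patients_per_group.get(eff.group_label, 0) < 1:
            raise ValueError(f"no patient count for group {eff.group_label!r}")

    rng = np.random.default_rng(config.seed)
    w = config.wavenumbers
    background = config.baseline(w)
    profiles = np.vstack([b.profile(w) for b in config.band_library])  # bands x points
    base_amps = np.array([b.base_amplitude for b in config.band_library])
    labels = [b.label for b in config.band_library]

    rows, meta = [], []
    for eff in config.group_effects:
        mult = np.array([eff.amplitude_multipliers.get(lab, 1.0) for lab in labels])
        n_pat = config.n_patients_per_group[eff.group_label]
        for p in range(n_pat):
            pid = f"{eff.group_label}_P{p:03d}"
            patient_factor = np.exp(config.patient_sd * rng.standard_normal(len(labels)))
            amps_patient = base_amps * mult * patient_factor
            for r in range(config.replicates_per_sample):
                spot = np.exp(config.replicate_sd * rng.standard_normal(len(labels)))
                trace = background + (amps_patient * spot) @ profiles
                trace = trace + config.noise_sd * rng.standard_normal(len(w))
                rows.append(trace)
                meta.append(
                    {
                        "spectrum_id": f"{pid}:{eff.group_label}:{r}",
                        "patient_id": pid,
                        "group": eff.group_label,
                        "replicate": r,
                        "acute_grade": None,
                        "late_grade": None,
                    }
                )
    return SpectralDataset(w, np.vstack(rows), pd.DataFrame(meta))


# ---------------------------------------------------------------------------
# default band library and cohort presets

def default_band_library() -> list[BandDefinition]:
    """Plasma mid-IR bands: glycogen/saccharide C-O, nucleic-acid phosphate,
    amide III/II/I/A protein bands, lipid ester carbonyl, CH stretches and
    the broad OH stretch."""
    B = BandDefinition
    return [
        B(1024, 20, 0.18, label="glycogen 1024"),
        B(1050, 20, 0.20, label="glycogen 1050"),
        B(1080, 25, 0.22, label="nucleic acids / phospholipids 1080"),
        B(1125, 25, 0.12, label="carbohydrates 1125"),
        B(1155, 25, 0.14, label="carbohydrates 1155"),
        B(1245, 40, 0.18, label="amide III 1245"),
        B(1310, 40, 0.14, label="amide III 1310"),
        B(1400, 30, 0.22, label="COO- amino acids 1400"),
        B(1450, 30, 0.24, label="CH2 proteins 1450"),
        B(1545, 45, 0.55, label="amide II"),
        B(1656, 50, 0.70, label="amide I"),
        B(1745, 30, 0.10, label="fatty acid esters 1745"),
        B(2852, 30, 0.12, label="CH2 sym lipids 2852"),
        B(2874, 25, 0.08, label="CH3 sym 2874"),
        B(2930, 40, 0.18, label="CH2 asym lipids 2930"),
        B(2960, 30, 0.12, label="CH3 asym 2960"),
        B(3300, 120, 0.45, label="amide A"),
        B(3420, 150, 0.20, label="OH stretch 3420"),
        B(3550, 120, 0.12, label="OH carboxylic 3550"),
    ]


_SACCHARIDE = ["glycogen 1024", "glycogen 1050", "nucleic acids / phospholipids 1080",
               "carbohydrates 1125", "carbohydrates 1155"]
_PROTEIN = ["amide III 1245", "amide III 1310", "amide II", "amide I", "amide A"]
_LIPID = ["fatty acid esters 1745", "CH2 sym lipids 2852", "CH3 sym 2874",
          "CH2 asym lipids 2930", "CH3 asym 2960"]
_OH = ["OH stretch 3420", "OH carboxylic 3550"]


def _mult(groups_of_labels_and_factors: list[tuple[list[str], float]]) -> dict[str, float]:
    out: dict[str, float] = {}
    for labels, f in groups_of_labels_and_factors:
        for lab in labels:
            out[lab] = f
    return out


def treatment_monitoring_config(seed: int = 0) -> CohortConfig:
    """Five-time-point radiotherapy-monitoring cohort.

    Group sizes follow the monitored clinical cohort (baseline 37, post
    hormone 36, post radiotherapy 43, two-month 37, eight-month 35 patients;
    10 replicates each).  Effect directions are qualitative: hormone therapy
    raises protein, lipid and saccharide bands and lowers the OH stretch;
    radiotherapy reverses the protein/lipid rise and raises the 1000-1100
    region; at follow-up lipids recover while protein stays depressed, with
    the shifts growing from two to eight months.  Effect magnitudes are free
    parameters of the simulation, not measured quantities.
    """
    effects = [
        GroupEffect("baseline", {}),
        GroupEffect(
            "post_hormone",
            _mult([(_PROTEIN, 1.06), (_LIPID, 1.10), (_SACCHARIDE, 1.08), (_OH, 0.94)]),
        ),
        GroupEffect(
            "post_radiotherapy",
            _mult([(_PROTEIN, 0.94), (_LIPID, 0.90),
                   (_SACCHARIDE[:3], 1.08), (_OH, 1.05)]),
        ),
        GroupEffect(
            "two_month",
            _mult([(_PROTEIN, 0.94), (_LIPID, 1.05), (_SACCHARIDE[:3], 0.95), (_OH, 1.06)]),
        ),
        GroupEffect(
            "eight_month",
            _mult([(_PROTEIN, 0.91), (_LIPID, 1.09), (_SACCHARIDE[:3], 0.93), (_OH, 1.09)]),
        ),
    ]
    return CohortConfig(
        group_effects=effects,
        n_patients_per_group={
            "baseline": 37,
            "post_hormone": 36,
            "post_radiotherapy": 43,
            "two_month": 37,
            "eight_month": 35,
        },
        seed=seed,
    )


def toxicity_config(seed: int = 0) -> CohortConfig:
    """Acute and late toxicity-grade cohort (grade 0-1 vs grade 2+).

    Sizes follow the monitored cohort: acute 24 vs 19, late 24 vs 11
    patients.  Severe-toxicity groups show raised glycogen/nucleic-acid
    bands and lowered protein bands; late grade 2+ additionally shows raised
    lipid bands.
    """
    effects = [
        GroupEffect("acute_grade_0_1", {}),
        GroupEffect(
            "acute_grade_2plus",
            _mult([(_SACCHARIDE[:3], 1.10), (_PROTEIN, 0.94), (_OH, 1.05)]),
        ),
        GroupEffect("late_grade_0_1", {}),
        GroupEffect(
            "late_grade_2plus",
            _mult([(_SACCHARIDE[:3], 1.08), (_PROTEIN, 0.94), (_LIPID, 1.10), (_OH, 1.05)]),
        ),
    ]
    return CohortConfig(
        group_effects=effects,
        n_patients_per_group={
            "acute_grade_0_1": 24,
            "acute_grade_2plus": 19,
            "late_grade_0_1": 24,
            "late_grade_2plus": 11,
        },
        seed=seed,
    )


def nearest_band(wavenumber: float, band_library: list[BandDefinition]) -> BandDefinition:
    """The library band whose centre is closest to a wavenumber."""
    if not band_library:
        raise ValueError("empty band library")
    return min(band_library, key=lambda b: abs(b.center - wavenumber))
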