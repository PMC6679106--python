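import numpy as np
import pytest

from plasmaftir.cohort import BandDefinition, CohortConfig, GroupEffect, generate_cohort


def brute_force_rubberband(w: np.ndarray, a: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Independent rubberband oracle: the baseline at each point is the
    pointwise maximum over all chords (lines through two spectrum points)
    that lie on or below the whole spectrum."""
    n = len(w)
    base = np.full(n, -np.inf)
    for i in range(n - 1):
        slopes = (a[i + 1:] - a[i]) / (w[i + 1:] - w[i])
        lines = a[i] + slopes[:, None] * (w[None, :] - w[i])
        ok = (lines <= a[None, :] + tol).all(axis=1)
        if ok.any():
            base = np.maximum(base, lines[ok].max(axis=0))
    return base


def two_group_config(
    n_a: int = 6,
    n_b: int = 6,
    replicates: int = 3,
    effect: dict | None = None,
    patient_sd: float = 0.08,
    replicate_sd: float = 0.03,
    noise_sd: float = 0.002,
    seed: int = 0,
    **kw,
) -> CohortConfig:
    """A compact two-group cohort on the full default grid."""
    return CohortConfig(
        group_effects=[GroupEffect("g0", {}), GroupEffect("g1", effect or {})],
        n_patients_per_group={"g0": n_a, "g1": n_b},
        replicates_per_sample=replicates,
        patient_sd=patient_sd,
        replicate_sd=replicate_sd,
        noise_sd=noise_sd,
        seed=seed,
        **kw,
    )


def single_band_config(**kw) -> CohortConfig:
    """One Gaussian amide-I band on a zero background."""
    defaults = dict(
        band_library=[BandDefinition(1656, 40, 1.0, label="amide I")],
        baseline_coeffs=[0.0],
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """Two groups x 6 patients x 3 replicates with a lipid/protein effect."""
    cfg = two_group_config(
        effect={"amide I": 0.92, "CH2 asym lipids 2930": 1.15}, seed=11
    )
    return generate_cohort(cfg)
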