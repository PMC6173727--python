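import numpy as np
import pytest

from nanorodmech import (
    ChainEnsemble,
    FiberContour,
    SawtoothSpec,
    WlcParams,
    bond_correlation_profile,
    generate_contour_ensemble,
    generate_sawtooth_trace,
    ms_end_to_end_profile,
    msmd_profile,
)

RECOVERY_LAMBDA = 200.0  # nm, ground truth of the shared recovery ensemble
RECOVERY_LENGTH = 500.0  # nm
RECOVERY_SEED = 1


@pytest.fixture(scope="session")
def recovery_ensemble():
    """2000 noiseless 2D worm-like chains (lambda=200 nm, L=500 nm,
    step 2 nm) shared by the parameter-recovery tests."""
    params = WlcParams(
        persistence_length=RECOVERY_LAMBDA,
        contour_length=RECOVERY_LENGTH,
        step=2.0,
        seed=RECOVERY_SEED,
    )
    return generate_contour_ensemble(
        params,
        n_fibers=2000,
        length_range=(RECOVERY_LENGTH, RECOVERY_LENGTH),
        noise_sd=0.0,
        seed=RECOVERY_SEED,
    )


@pytest.fixture(scope="session")
def recovery_profiles(recovery_ensemble):
    """All three binned profiles of the shared recovery ensemble."""
    return {
        "msed": ms_end_to_end_profile(recovery_ensemble, n_bins=100),
        "correlation": bond_correlation_profile(recovery_ensemble, n_bins=100),
        "midpoint": msmd_profile(recovery_ensemble, n_bins=100),
    }


@pytest.fixture
def straight_contour():
    """Five collinear points along x, unit spacing."""
    return FiberContour.from_points(
        np.column_stack([np.arange(5.0), np.zeros(5)])
    )


@pytest.fixture
def elbow_contour():
    """The 4-point hand-checked contour (0,0),(1,0),(2,0),(2,1)."""
    return FiberContour.from_points(
        np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [2.0, 1.0]])
    )


def make_sawtooth(n_interfaces, post_drop_fraction=0.5, force_cap=500.0,
                  rise_stiffness=250.0, f_lo_frac=0.55, f_hi_frac=0.90,
                  **kwargs):
    """Convenience builder: evenly spaced rupture forces below the cap."""
    forces = tuple(
        np.linspace(f_lo_frac, f_hi_frac, n_interfaces) * force_cap
    )
    spec = SawtoothSpec(
        n_interfaces=n_interfaces,
        rise_stiffness=rise_stiffness,
        rupture_forces=forces,
        post_drop_fraction=post_drop_fraction,
        force_cap=force_cap,
        **kwargs,
    )
    return generate_sawtooth_trace(spec)


@pytest.fixture
def small_random_contours():
    """Ten random contours of 3-10 points for brute-force equivalence."""
    rng = np.random.default_rng(7)
    contours = []
    for _ in range(10):
        n = int(rng.integers(3, 11))
        pts = np.cumsum(rng.normal(1.0, 0.4, size=(n, 2)), axis=0)
        contours.append(FiberContour.from_points(pts))
    return ChainEnsemble(contours=contours, metadata={"source": "fixture"})
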