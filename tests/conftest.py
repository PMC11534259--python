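"""Shared fixtures: a small noise-free phantom, its reconstructed sodium
image, and a reduced two-patient study report.

Everything is seeded and session-scoped; the expensive acquisition and
study fixtures are built once and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from natsc.phantom import PhantomSpec, TSCEvolutionParams, generate_phantom
from natsc.pipeline import StudyConfig, run_study
from natsc.recon import (
    SequenceParams,
    make_trajectory,
    reconstruct,
    simulate_acquisition,
    steady_state_signal,
)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(
        grid_shape=(64, 64, 64),
        voxel_size_mm=2.5,
        lesion_radii_mm=(4.7,),
        tsc_params=TSCEvolutionParams(noise_sd=0.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def seq_small() -> SequenceParams:
    # full 384-point density-adapted readout, reduced spoke count
    return SequenceParams(n_spokes=1000, n_samples=384)


@pytest.fixture(scope="session")
def sodium_recon(small_phantom, seq_small):
    """Noise-free reconstructed sodium image of the small phantom."""
    sig = steady_state_signal(
        small_phantom.tsc_maps["I"],
        small_phantom.t1_map,
        small_phantom.t2star_map,
        seq_small,
    )
    ks = simulate_acquisition(sig, make_trajectory(seq_small))
    return reconstruct(ks)


@pytest.fixture(scope="session")
def study_report():
    """Reduced noise-free study: two stable patients, known transforms."""
    cfg = StudyConfig.reduced(
        seed=5,
        use_true_transform=True,
        motion_max_mm=0.0,
        motion_max_deg=0.0,
        stable_only=True,
        max_patients=2,
    )
    return run_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def quant_recovery():
    """End-to-end noise-free TSC recovery on a large-compartment phantom.

    Returns per-compartment recovered ROI means alongside the true values
    and tissue T1, for checks of absolute recovery and closed-form bias.
    """
    from natsc.testing import quantification_recovery

    return quantification_recovery(n=64, spacing_mm=2.5, n_spokes=1500)
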