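"""Shared fixtures.

The expensive end-to-end standard synthetic case (32^3, 480 spokes, 248
volumes, calibrated noise, injected motion) is computed once per session
and shared by the acceptance-level tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from dualswift.config import scaled_config
from dualswift.pipeline import run_subject
from dualswift.sequence import SequenceParams, make_dual_schedule, make_spoke_directions


@pytest.fixture(scope="session")
def standard_chain():
    """Full simulate -> acquire -> reconstruct -> preprocess -> GLM run of
    the standard synthetic case (seed 0); both FOVs."""
    cfg = scaled_config(seed=0)
    return cfg, run_subject(cfg, 0)


@pytest.fixture(scope="session")
def small_recon_setup():
    """16^3 noise-free acquisition at 3x angular oversampling, shared by
    reconstruction-fidelity tests."""
    from scipy import ndimage

    from dualswift.acquisition import acquire_dual
    from dualswift.phantom import make_dual_phantom

    n = 16
    n_spokes = 3 * int(np.pi * n**2)
    params = SequenceParams(
        matrix_size=n, n_spokes_per_volume=n_spokes, n_volumes=1,
        samples_per_gap=16, oversampling=2,
    )
    ph = make_dual_phantom(matrix_size=n, seed=1)
    # band-limit the object so NRMSE measures algorithm convergence, not
    # unsampled k-space-corner content
    truth = ndimage.gaussian_filter(ph.volumes[0], 0.7)
    other = ndimage.gaussian_filter(ph.volumes[1], 0.7)
    dirs = make_spoke_directions(n_spokes)
    sched = make_dual_schedule(params, dirs, n_volumes=1)
    s0, _ = acquire_dual(truth[None], other[None], sched, params, noise_sd=0.0, seed=0)
    return truth, s0
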