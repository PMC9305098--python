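import numpy as np
import pytest

from focalsf import synthetic, trajectory, vf_data


@pytest.fixture(scope="session")
def params():
    return trajectory.load_default_params()


@pytest.fixture(scope="session")
def canonical_geometry(params):
    """Eye geometry identical to the canonical model frame, 960-px grid."""
    mm_per_px = 4.11 / 960
    deg_per_px = mm_per_px / 0.274
    disc = (480.0, 480.0)
    dist_px = params.canonical_fd_distance_deg / deg_per_px
    import math

    a = math.radians(params.canonical_fd_angle_deg)
    fovea = (disc[0] - dist_px * math.cos(a), disc[1] + dist_px * math.sin(a))
    return trajectory.EyeGeometry.from_pixels(fovea, disc, mm_per_px=mm_per_px)


@pytest.fixture(scope="session")
def transform(params, canonical_geometry):
    return trajectory.fit_to_eye(params, canonical_geometry)


@pytest.fixture(scope="session")
def grid_right():
    return vf_data.build_grid("right")


@pytest.fixture(scope="session")
def analysis_locs(grid_right):
    return vf_data.analysis_locations(grid_right)


@pytest.fixture(scope="session")
def small_bundle():
    """Small noisy cohort shared by pipeline-level tests."""
    cfg = synthetic.CohortConfig(
        n_subjects=6, seed=1234, image_px=176, normalized_px=160
    )
    return synthetic.simulate_cohort(cfg)


@pytest.fixture
def rng(request):
    # deterministic per-test stream, independent of execution order
    import zlib

    return np.random.default_rng(zlib.crc32(request.node.nodeid.encode()))
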