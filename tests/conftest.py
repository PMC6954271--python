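"""Shared phantom fixtures.

Phantoms are kept small (8–12 mm spheres at 20 µm/px) so the full
reconstruct–stitch–assemble pipeline runs in seconds; session scope
amortizes generation across tests.
"""

import warnings

import pytest

from circumscan import geometry, mosaic, phantom

PHANTOM_MM_PER_PX = 0.02
PHANTOM_C = 0.2
PHANTOM_N_PANELS = 10
PHANTOM_OVERLAP = 0.2


@pytest.fixture(scope="session")
def plain_phantom():
    """Unmarked spherical phantom (d = L = 8 mm) with its acquisition plan."""
    surf = phantom.generate_surface(8.0, 8.0, PHANTOM_MM_PER_PX, seed=1)
    plan = geometry.plan_acquisition(8.0, 8.0, PHANTOM_N_PANELS, 1.0,
                                     PHANTOM_OVERLAP)
    organ = geometry.CompressibleOrgan(4.0, PHANTOM_C, 8.0)
    return surf, plan, organ


@pytest.fixture(scope="session")
def plain_acquisition(plain_phantom):
    surf, plan, organ = plain_phantom
    return phantom.simulate_acquisition(surf, plan, organ)


@pytest.fixture(scope="session")
def plain_panorama(plain_phantom, plain_acquisition):
    """Stitched panels and rolled-out panorama of the unmarked phantom."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        panels, rollout = mosaic.stitch_acquisition(
            plain_acquisition, PHANTOM_OVERLAP
        )
    return panels, rollout


@pytest.fixture(scope="session")
def marked_phantom():
    """Fiducial-marked phantom (d = 12, L = 6 mm): 3 hashes at 10 mm spacing."""
    surf = phantom.generate_surface(12.0, 6.0, PHANTOM_MM_PER_PX, seed=0)
    surf = phantom.apply_fiducials(surf, phantom.FiducialSpec())
    plan = geometry.plan_acquisition(12.0, 6.0, PHANTOM_N_PANELS, 1.0,
                                     PHANTOM_OVERLAP)
    organ = geometry.CompressibleOrgan(6.0, PHANTOM_C, 6.0)
    return surf, plan, organ


@pytest.fixture(scope="session")
def marked_panels(marked_phantom):
    """Reconstructed, stitched panels of the fiducial-marked phantom."""
    surf, plan, organ = marked_phantom
    acq = phantom.simulate_acquisition(surf, plan, organ)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        panels, _ = mosaic.stitch_acquisition(acq, PHANTOM_OVERLAP)
    return panels
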