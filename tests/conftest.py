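"""Shared phantom fixtures.

Session-scoped because the heavier ones run the vesselness filter and both
level-set stages; tests treat them as read-only.
"""

import numpy as np
import pytest

from coroseg.phantom import (PhantomSpec, PlaqueSpec, arc_curve, line_curve, make_phantom)

SPACING = (0.4, 0.4, 0.4)


def dice_pct(a, b) -> float:
    s = int(a.sum()) + int(b.sum())
    return 200.0 * int((a & b).sum()) / s if s else 0.0


@pytest.fixture(scope="session")
def straight_tube():
    """Healthy straight vessel, face-to-face, lumen r=1.5 mm, wall 0.75 mm."""
    curve = line_curve((12.6, 12.6, 0.0), (12.6, 12.6, 59.6))
    return make_phantom(PhantomSpec(curve=curve), (64, 64, 150), SPACING)


@pytest.fixture(scope="session")
def bare_tube():
    """Straight tube without the fat sheath (40 mm, caps inside the volume)."""
    curve = line_curve((9.4, 9.4, 6.0), (9.4, 9.4, 46.0))
    return make_phantom(PhantomSpec(curve=curve, fat_sheath=False), (48, 48, 130), SPACING)


@pytest.fixture(scope="session")
def arc_plaque_phantom():
    """Curved vessel (quarter arc, radius 24 mm) with one 50% soft stenosis."""
    curve = arc_curve(center=(17.8, 4.0, 6.0), radius=24.0, angle_span=np.pi / 2,
                      plane_u=(0, 1, 0), plane_v=(0, 0, 1))
    spec = PhantomSpec(curve=curve,
                       plaques=[PlaqueSpec(start_arc_length=18.0, length=8.0)])
    return make_phantom(spec, (90, 90, 90), SPACING)


@pytest.fixture(scope="session")
def arc_plaque_noisy():
    curve = arc_curve(center=(17.8, 4.0, 6.0), radius=24.0, angle_span=np.pi / 2,
                      plane_u=(0, 1, 0), plane_v=(0, 0, 1))
    spec = PhantomSpec(curve=curve,
                       plaques=[PlaqueSpec(start_arc_length=18.0, length=8.0)],
                       noise_sigma=20.0, seed=7)
    return make_phantom(spec, (90, 90, 90), SPACING)


@pytest.fixture(scope="session")
def motion_gap_phantom():
    """Straight tube with a 5 mm motion-blur gap mid-vessel."""
    curve = line_curve((12.6, 12.6, 0.0), (12.6, 12.6, 59.6))
    spec = PhantomSpec(curve=curve, motion_blur_sigma=(1.0, 1.0),
                       motion_blur_window=(27.0, 32.0))
    return make_phantom(spec, (64, 64, 150), SPACING)


@pytest.fixture(scope="session")
def arc_pipeline_result(arc_plaque_phantom):
    from coroseg.pipeline import run_pipeline

    tr = arc_plaque_phantom
    return run_pipeline(tr.volume, [tr.seed_near_start(2.0), tr.seed_near_end(2.0)])
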