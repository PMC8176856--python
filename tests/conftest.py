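import numpy as np
import pytest

from suvseg import (
    BackgroundModel,
    CohortConfig,
    LogNormalSUV,
    ScalarVolume,
    generate_cohort,
)


def make_volume(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return ScalarVolume(np.asarray(values, dtype=float), spacing, origin)


def clean_model(soft=1.0, noise_sd=0.0, psf_fwhm_mm=0.0):
    """Degenerate background model: constant tissues, configurable degradation."""
    return BackgroundModel(
        tissues={
            "parotis": LogNormalSUV(20.1, 20.1, 20.1),
            "liver": LogNormalSUV(11.3, 11.3, 11.3),
            "spleen": LogNormalSUV(9.9, 9.9, 9.9),
            "soft_tissue": LogNormalSUV(soft, soft, soft),
        },
        noise_sd=noise_sd,
        psf_fwhm_mm=psf_fwhm_mm,
    )


def random_voi_volume(rng, max_side=20):
    """Random grid plus an ellipsoid VOI guaranteed to contain voxel centers."""
    from suvseg import EllipsoidVOI

    shape = tuple(int(s) for s in rng.integers(4, max_side + 1, size=3))
    spacing = tuple(float(s) for s in rng.uniform(0.8, 3.0, size=3))
    origin = tuple(float(o) for o in rng.uniform(-10.0, 10.0, size=3))
    vol = ScalarVolume(rng.uniform(0.0, 20.0, size=shape), spacing, origin)
    idx = tuple(int(i) for i in (rng.integers(0, s) for s in shape))
    center = tuple(origin[a] + idx[a] * spacing[a] for a in range(3))
    semi = tuple(float(s) for s in rng.uniform(1.0, 15.0, size=3) + max(spacing))
    return vol, EllipsoidVOI(center, semi)


@pytest.fixture(scope="session")
def default_cohort():
    """The default-seed, default-condition 50-case phantom cohort."""
    return generate_cohort(CohortConfig())
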