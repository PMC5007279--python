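import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Full-size noise-free phantom: (ct, pet, truth), spacing (3, 1, 1) mm."""
    from spinehough.phantom import default_truth, generate_phantom

    truth = default_truth(noise_suv=0.0)
    ct, pet, truth = generate_phantom(truth)
    return ct, pet, truth


@pytest.fixture(scope="session")
def noise_free_segmentation(noise_free_phantom):
    """Segmentation of the noise-free phantom, shared across tests."""
    from spinehough.segmentation import segment_volume_run

    ct, _, truth = noise_free_phantom
    return segment_volume_run(ct, truth.segments())


@pytest.fixture(scope="session")
def liver_center_mm(noise_free_phantom):
    """Liver ROI center (z, y, x) in mm for the default phantom geometry."""
    _, _, truth = noise_free_phantom
    lx, ly = truth.liver_center_px
    zc = truth.d12_slice - 1
    return (zc * 3.0, ly * 1.0, lx * 1.0)


@pytest.fixture(scope="session")
def small_phantom(tmp_path_factory):
    """A short 16-slice phantom written to disk as NIfTI, for IO/CLI tests."""
    from spinehough import io as shio
    from spinehough.phantom import default_truth, generate_phantom

    truth = default_truth(occiput_slice=2, c7_slice=8, d12_slice=13, seed=7)
    ct, pet, truth = generate_phantom(truth, shape=(16, 64, 64))
    d = tmp_path_factory.mktemp("small_phantom")
    shio.write_volume(ct, d / "ct.nii")
    shio.write_volume(pet, d / "pet.nii")
    return {"dir": d, "ct": ct, "pet": pet, "truth": truth}
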