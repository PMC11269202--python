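import numpy as np
import pytest

from filtomo import scene as S


@pytest.fixture(scope="session")
def voxel_a():
    return 9.52


@pytest.fixture(scope="session")
def small_cluster_sim():
    """10-filament PHF-like parallel cluster (7/3 polarity split), snr 1."""
    spec = S.standard_test_scene(seed=7, n_filaments=10, n_opposite=3,
                                 shape=(128, 128, 128))
    return spec, S.build_scene(spec)


@pytest.fixture(scope="session")
def noiseless_axial_filament():
    """A noiseless PHF-like filament along z, twist 2.5 deg/nm, no wedge."""
    spec = S.FilamentSpec((45.0, 45.0, 5.0), (45.0, 45.0, 171.0),
                          template_id="phf_like", twist_rate=2.5)
    sc = S.SceneSpec(volume_shape=(186, 96, 96), voxel_size=9.52)
    return spec, sc, S.render_filament(spec, sc)
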