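import pytest

from mrforge.sequence_model import Protocol

#: Feasible small protocols per family, used across the suite.
TOY_PROTOCOLS = {
    "flash": Protocol(tr=10, te=5, matrix=(16, 16, 4), fov=(256, 256, 32),
                      slice_thickness=32.0),
    "bssfp": Protocol(tr=6, te=3, matrix=(16, 16, 4), fov=(256, 256, 32),
                      prescans=10, slice_thickness=32.0),
    "mprage": Protocol(tr=300, te=5, ti=100, matrix=(16, 16, 4),
                       fov=(256, 256, 32), slice_thickness=32.0),
    "rare": Protocol(tr=500, te=12, refocus_flip=150, matrix=(16, 16, 4),
                     fov=(256, 256, 32), train_length=(4, 1), slice_thickness=5.0),
    "flair": Protocol(tr=1000, te=12, ti=200, refocus_flip=150, matrix=(16, 16, 4),
                      fov=(256, 256, 32), train_length=(4, 1), slice_thickness=5.0),
    "se_epi_diffusion": Protocol(tr=500, te=60, matrix=(16, 16, 2),
                                 fov=(256, 256, 32), slice_thickness=5.0,
                                 extras={"ref_lines": 0}),
    "grase_pcasl": Protocol(tr=3600, te=12, refocus_flip=120, matrix=(16, 8, 4),
                            fov=(256, 256, 32), partial_fourier=(1.0, 1.0),
                            slice_thickness=32.0, extras={"ref_lines": 0}),
    "radial_ute": Protocol(tr=6, te=0.1, matrix=(16, 16, 16), fov=(256, 256, 256),
                           slice_thickness=256.0,
                           extras={"spokes": 50, "calib_angles": 6}),
    "steam": Protocol(tr=2000, te=20, refocus_flip=90, fov=(25, 25, 25),
                      matrix=(1, 1, 1), averages=2, prescans=1, slice_thickness=25.0),
    "press": Protocol(tr=2000, te=32, fov=(25, 25, 25), matrix=(1, 1, 1),
                      averages=2, prescans=1, slice_thickness=25.0),
}


@pytest.fixture(scope="session")
def toy_protocols():
    return TOY_PROTOCOLS


@pytest.fixture()
def toy_flash():
    from mrforge.sequence_library import build_sequence

    return build_sequence("flash", TOY_PROTOCOLS["flash"])
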