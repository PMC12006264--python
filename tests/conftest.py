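import numpy as np
import pytest

from orthostruct.io_formats import AlignmentFrame
from orthostruct.synthetic_data import default_config, make_comparison_bundle


def make_frame(*rows):
    """AlignmentFrame from gapped strings, ids r1, r2, ... unless given."""
    if rows and isinstance(rows[0], tuple):
        return AlignmentFrame(tuple(rows))
    return AlignmentFrame(tuple((f"r{i + 1}", g) for i, g in enumerate(rows)))


@pytest.fixture(scope="session")
def bundle400(tmp_path_factory):
    """The canonical 4-species end-to-end bundle (400 residues, planted
    displacement and interface), generated once per session."""
    d = tmp_path_factory.mktemp("bundle400")
    path, truth = make_comparison_bundle(default_config(2026), d)
    return path, truth


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A light bundle for structure-side unit tests (no indels)."""
    from orthostruct.synthetic_data import SimConfig

    cfg = SimConfig(
        seed=7, n_species=4, length=120, default_rate=0.05,
        rate_regions=((1, 20, 0.15),), disorder_spans=((1, 20),),
        indel_events_mean=0.0, insertion_events_mean=0.0,
        displacement_plan=(("sp2", 60, 64, 4.0),),
        interface_contacts=(40, 80), hbond_sites=(80,),
    )
    d = tmp_path_factory.mktemp("bundle120")
    path, truth = make_comparison_bundle(cfg, d)
    return path, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
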