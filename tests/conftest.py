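import numpy as np
import pytest

from tracheidzones import (
    BetaZoneParams,
    CellMeasurement,
    GenNormParams,
    MixtureModel,
    species_profile,
)


@pytest.fixture(scope="session")
def obovata_model() -> MixtureModel:
    """Spruce-like mixture reconstructed from published per-zone statistics."""
    return species_profile("picea_obovata").model


@pytest.fixture(scope="session")
def toy_model() -> MixtureModel:
    """Small hand-built mixture with well-separated components."""
    return MixtureModel(
        A_EW=0.5,
        A_LW=0.3,
        ew=BetaZoneParams(alpha=3.0, beta=3.0, a=15.0, b=45.0),
        lw=BetaZoneParams(alpha=3.0, beta=3.0, a=55.0, b=85.0),
        tw=GenNormParams(mu=50.0, alpha_scale=6.0, beta_shape=4.0),
    )


def make_cells(tree="t1", year=2000, row=1, d_seq=(40, 35, 30, 25, 20), cwt_seq=None):
    """Small valid ring row; wall thickness defaults to a rising profile."""
    if cwt_seq is None:
        cwt_seq = [2.0 + 0.5 * i for i in range(len(d_seq))]
    return [
        CellMeasurement(tree_id=tree, year=year, row_id=row, rank=i + 1, D=float(d), CWT=float(w))
        for i, (d, w) in enumerate(zip(d_seq, cwt_seq))
    ]


@pytest.fixture
def small_ring():
    return make_cells()
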