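"""Shared fixtures: small simulated dictionaries built once per session.

Lattice sizes are scaled down from the production default (256) to keep the
suite fast; the scale-invariance property test covers the equivalence.
"""

from __future__ import annotations

import numpy as np
import pytest

from mrvf.dictionary import GridSpec, build_dictionary
from mrvf.physics import Physics
from mrvf.sequence import SequenceParams


@pytest.fixture(scope="session")
def physics() -> Physics:
    return Physics()


@pytest.fixture(scope="session")
def seq() -> SequenceParams:
    return SequenceParams()


@pytest.fixture(scope="session")
def toy_dict():
    """3x3x3 grid with a 2-node ADC axis, 64^2 lattice (fast, on-axis phantoms)."""
    spec = GridSpec(
        bvf_values=[0.02, 0.035, 0.05],
        radius_values=[5.0, 7.5, 15.0],
        delta_chi_values=[0.25, 0.45, 0.65],
        adc_values=[500.0, 800.0],
        lattice_n=64,
        base_seed=7,
    )
    return build_dictionary(spec, workers=1)


@pytest.fixture(scope="session")
def toy555_dict():
    """5x5x5 grid at 128^2 lattice with stored raw trains, for recovery studies."""
    spec = GridSpec(
        bvf_values=list(np.geomspace(0.02, 0.12, 5)),
        radius_values=list(np.geomspace(2.0, 16.0, 5)),
        delta_chi_values=list(np.linspace(0.2, 1.2, 5)),
        adc_values=[800.0],
        lattice_n=128,
        base_seed=11,
    )
    return build_dictionary(spec, workers=1, store_trains=True)
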