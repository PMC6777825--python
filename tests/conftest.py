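import numpy as np
import pytest

from dsfbind.synthetic import LigandSpec, PlateMap, TransitionSpec


@pytest.fixture
def gln_like() -> LigandSpec:
    """Agonist with the affinity/enthalpy regime of a high-affinity amino acid."""
    return LigandSpec("glnlike", "agonist", kd_true_um=30.9, dh0_true=72.1)


@pytest.fixture
def glu_like() -> LigandSpec:
    """Weaker agonist (sub-millimolar Kd)."""
    return LigandSpec("glulike", "agonist", kd_true_um=422.0, dh0_true=72.1)


@pytest.fixture
def destabilizer() -> LigandSpec:
    return LigandSpec("lyslike", "destabilizer")


@pytest.fixture
def inert() -> LigandSpec:
    return LigandSpec("dalalike", "inert")


@pytest.fixture
def buffer_plate_map() -> PlateMap:
    return PlateMap.from_records([(f"B{i}", "buffer", 0.0) for i in range(7)])
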