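import numpy as np
import pytest

from ufscreen.chrom_model import ScreenDesign
from ufscreen.peakproc import CompoundPanel
from ufscreen.simulate import (
    BindingSystem,
    Enzyme,
    Ligand,
    Probe,
    make_grid,
)
from ufscreen.simulate import (
    danshen4_chromatograms,
    danshen4_design,
    danshen4_panel,
)

#: published S/N of the four major Danshen tanshinones
TABLE_SN = {
    "dihydrotanshinone": 1.16,
    "tanshinone_I": 1.88,
    "cryptotanshinone": 1.33,
    "tanshinone_IIA": 2.34,
}

#: published S-S/N per target
TABLE_SSN = {
    "dihydrotanshinone": {"CYP1A2": 0.09, "CYP2C9": -0.07, "CYP3A4": -0.21},
    "tanshinone_I": {"CYP1A2": 0.04, "CYP2C9": 0.16, "CYP3A4": 0.13},
    "cryptotanshinone": {"CYP1A2": 0.51, "CYP2C9": 0.47, "CYP3A4": 0.54},
    "tanshinone_IIA": {"CYP1A2": 0.62, "CYP2C9": 0.62, "CYP3A4": 0.39},
}


@pytest.fixture(scope="session")
def danshen_chroms():
    return danshen4_chromatograms(seed=1)


@pytest.fixture(scope="session")
def danshen_design():
    return danshen4_design()


@pytest.fixture(scope="session")
def danshen_panel():
    return danshen4_panel()


def demo_system(e1_total: float = 1.0, e2_total: float = 1.0) -> BindingSystem:
    """Two enzymes, one orthosteric / one allosteric / one non-binding ligand."""
    return BindingSystem(
        enzymes=(Enzyme("E1", e1_total), Enzyme("E2", e2_total)),
        ligands=(
            Ligand("orth", 5.0, 1.0, 0.1, 8.0),
            Ligand("allo", 5.0, 1.0, 0.1, 14.0),
            Ligand("non", 5.0, 1.0, 0.1, 20.0),
        ),
        kd={("orth", "E1"): 1.0, ("allo", "E2"): 0.5},
        site={("orth", "E1"): "orthosteric", ("allo", "E2"): "allosteric"},
        probes={"E1": Probe("p1", 100.0, 0.1), "E2": Probe("p2", 100.0, 0.1)},
    )


def demo_design() -> ScreenDesign:
    return ScreenDesign(
        targets=("E1", "E2"),
        probe_of={"E1": "p1", "E2": "p2"},
        runs=(
            ("b", "blank", ""),
            ("x", "experimental", ""),
            ("c1", "control", "E1"),
            ("c2", "control", "E2"),
        ),
    )


def demo_panel() -> CompoundPanel:
    return CompoundPanel((("orth", 8.0), ("allo", 14.0), ("non", 20.0)))


def demo_grid() -> np.ndarray:
    return make_grid(26.0, 0.01)
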