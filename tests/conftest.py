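import numpy as np
import pytest

from combiscreen.design import DesignSpec, DrugPanel
from combiscreen.fixtures import FixtureSpec, make_background, plant_objects, ring_template


CASE_DRUGS = ("Apr", "Aur", "Cap", "Cel", "Dis", "Itr", "Min", "Que", "Ser")


@pytest.fixture(scope="session")
def nine_drug_panel() -> DrugPanel:
    """A nine-drug panel shaped like a clinical repurposing cocktail."""
    return DrugPanel(tuple((name, 1.0, "uM") for name in CASE_DRUGS))


@pytest.fixture(scope="session")
def case_spec(nine_drug_panel) -> DesignSpec:
    """Nine drugs screened exhaustively up to order four, in quadruplicate."""
    return DesignSpec(panel=nine_drug_panel, max_order=4, replicates=4, seed=42)


@pytest.fixture(scope="session")
def small_template() -> np.ndarray:
    """A small apoptotic-like ring template that fits many times in a test frame."""
    return ring_template((11, 10), amplitude=60.0, core_depth=25.0)


def planted_frame(template, positions, shape=(64, 64), level=100.0, noise_sd=2.0, seed=0):
    frame = make_background(shape, level, noise_sd, seed)
    return plant_objects(frame, template, positions)
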