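import numpy as np
import pandas as pd
import pytest

from lncstage import ExpressionMatrix, PlantedModule, SimulationDesign
from lncstage.config import STAGE_ORDER
from lncstage.simulate import generate_bundle


def small_design(seed: int = 0) -> SimulationDesign:
    """A reduced design for fast unit tests: 2 planted modules, 180 features."""
    return SimulationDesign(
        n_mrna=120,
        n_lncrna=60,
        planted_modules=(
            PlantedModule("early", "early", size=20, high_stages=("F45", "F65"),
                          n_mrna_members=25),
            PlantedModule("late", "late", size=20, high_stages=("B1", "B90"),
                          n_mrna_members=25),
        ),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(small_design(seed=0))


@pytest.fixture(scope="session")
def default_bundle():
    return generate_bundle(SimulationDesign(seed=0))


def toy_expression(values: np.ndarray, feature_ids=None) -> ExpressionMatrix:
    """Wrap a (features x 21) array as a 7-stage x 3-replicate matrix."""
    n, s = values.shape
    assert s == 21
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n)]
    sample_ids = [f"{st}_r{r}" for st in STAGE_ORDER for r in (1, 2, 3)]
    meta = pd.DataFrame(
        {"stage": np.repeat(list(STAGE_ORDER), 3), "replicate": [1, 2, 3] * 7},
        index=pd.Index(sample_ids, name="sample"),
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                            columns=sample_ids),
        sample_meta=meta,
    )
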