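import numpy as np
import pytest

from foldsea import AnnotationMap, DegTable, RegulationList


@pytest.fixture
def small_deg_table():
    return DegTable(
        gene_id=["a", "b", "c", "d", "e"],
        log_fc=np.array([2.0, -1.5, 0.1, -0.3, 1.2]),
        adj_p=np.array([0.001, 0.01, 0.2, 0.04, 0.03]),
    )


@pytest.fixture
def reg20():
    """20 genes, |logFC| 0.1..2.0, ascending."""
    genes = [f"g{i:02d}" for i in range(1, 21)]
    return RegulationList("up", genes, np.arange(1, 21) / 10.0)


@pytest.fixture
def annotation_top4(reg20):
    """One term containing the four strongest-responding genes."""
    return AnnotationMap({"T": set(reg20.genes[-4:])})
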