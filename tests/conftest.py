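import numpy as np
import pandas as pd
import pytest

from scqpcr.expression import ExpressionMatrix
from scqpcr.qpcr_io import CtTable, PanelSpec


@pytest.fixture
def small_ct() -> CtTable:
    """3 cells x 3 target assays + 18S control; one nondetect."""
    df = pd.DataFrame(
        {
            "ACTB": [12.0, 13.0, 12.5],
            "CD14": [18.0, np.nan, 20.0],
            "TNF": [22.0, 21.0, 23.0],
            "18S": [10.0, 11.0, 12.0],
        },
        index=["c1", "c2", "c3"],
    )
    return CtTable(df)


@pytest.fixture
def small_panel() -> PanelSpec:
    return PanelSpec(["ACTB", "CD14", "TNF"], "ACTB", "18S", 40.0)


@pytest.fixture
def small_meta() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3"],
            "subset": ["classical", "intermediate", "non_classical"],
            "batch": ["b0", "b0", "b0"],
        }
    )


@pytest.fixture
def three_subset_expr() -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Three cells per subset, deterministic values for hand computation."""
    cells = [f"{s}_{i}" for s in ("classical", "intermediate", "non_classical")
             for i in range(3)]
    meta = pd.DataFrame({
        "cell_id": cells,
        "subset": [c.rsplit("_", 1)[0] for c in cells],
        "batch": "b0",
    })
    df = pd.DataFrame(
        {
            "gA": [2.0, 4.0, 6.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
            "gB": [5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
            "gC": [0.0, 0.0, 0.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0],
        },
        index=cells,
    )
    return ExpressionMatrix(df), meta
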