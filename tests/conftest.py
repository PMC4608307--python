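import numpy as np
import pandas as pd
import pytest

from blocknet.io import CONDITIONS, ExpressionStudy


def make_study(
    values: np.ndarray,
    n_donors: int,
    n_replicates: int = 1,
    genes: list[str] | None = None,
) -> ExpressionStudy:
    """Build a study from a (genes, donors*conditions*replicates) array.

    Columns are ordered donor-major, then condition, then replicate,
    matching the simulator's layout.
    """
    values = np.asarray(values, dtype=float)
    samples, rows = [], []
    for d in range(1, n_donors + 1):
        for cond in CONDITIONS:
            for r in range(1, n_replicates + 1):
                sid = f"d{d:02d}_{cond}_r{r}"
                samples.append(sid)
                rows.append(
                    {"sample_id": sid, "donor": f"d{d:02d}", "condition": cond, "replicate": r}
                )
    assert values.shape[1] == len(samples)
    genes = genes or [f"g{i:05d}" for i in range(1, values.shape[0] + 1)]
    return ExpressionStudy(
        genes=genes,
        samples=samples,
        intensities=values,
        design=pd.DataFrame(rows).set_index("sample_id"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_study():
    """3 genes x 1 donor x 4 conditions, single replicate."""
    values = np.array(
        [
            [100.0, 200.0, 150.0, 400.0],
            [50.0, 55.0, 60.0, 52.0],
            [300.0, 310.0, 290.0, 305.0],
        ]
    )
    return make_study(values, n_donors=1)


@pytest.fixture
def random_rcbd_study(rng):
    """50 genes x 8 donors x 4 conditions, collapsed, positive intensities."""
    values = 2.0 ** rng.normal(9.0, 1.0, size=(50, 8 * 4))
    return make_study(values, n_donors=8)
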