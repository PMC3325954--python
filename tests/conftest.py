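import numpy as np
import pandas as pd
import pytest

from senecon.expr_de import ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 probes x 9 samples (3 conditions x 3 replicates), fixed values."""
    rng = np.random.default_rng(42)
    conditions = ["base", "c1", "c2"]
    samples = [f"{c}_r{r}" for c in conditions for r in (1, 2, 3)]
    values = pd.DataFrame(
        rng.normal(8, 1, size=(3, 9)).round(3),
        index=pd.Index(["p1", "p2", "p3"], name="probe_id"),
        columns=samples,
    )
    design = pd.DataFrame(
        {
            "sample_id": samples,
            "condition": [s.rsplit("_", 1)[0] for s in samples],
            "replicate": [int(s[-1]) for s in samples],
        }
    )
    return ExpressionMatrix(values=values, design=design)


def make_signature(members: dict[str, int], universe=None, contrast=("a", "b")):
    from senecon.expr_de import SignificantSet

    return SignificantSet(
        contrast=contrast,
        lfc_cut=0.5,
        p_cut=1e-4,
        members=members,
        universe=frozenset(universe) if universe is not None else frozenset(),
    )
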