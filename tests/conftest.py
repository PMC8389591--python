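import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from survmod import SyntheticDesign, generate_study
from survmod.synthetic import gene_sets_for_truth


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (seed 0) shared by read-only tests."""
    design = SyntheticDesign(seed=0)
    scaffold, expr, classes, surv, truth = generate_study(design)
    gmt = gene_sets_for_truth(truth, list(expr.index), seed=0)
    return {
        "design": design,
        "scaffold": scaffold,
        "expr": expr,
        "classes": classes,
        "surv": surv,
        "truth": truth,
        "gmt": gmt,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr():
    """Tiny deterministic 4-gene expression frame, 3 tumor / 3 normal."""
    rs = np.random.default_rng(7)
    cols = ["t1", "t2", "t3", "n1", "n2", "n3"]
    df = pd.DataFrame(rs.standard_normal((4, 6)), index=["gA", "gB", "gC", "gD"], columns=cols)
    classes = pd.Series(["tumor"] * 3 + ["normal"] * 3, index=cols)
    return df, classes
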