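import numpy as np
import pandas as pd
import pytest

from sclcnet import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleMetadata,
    SimConfig,
    DESpec,
    ModuleSpec,
    simulate_cohort,
)


@pytest.fixture
def tiny_X() -> ExpressionMatrix:
    """3 genes x 2 samples, the quantile-normalization worked example."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 6.0], [2.0, 4.0], [3.0, 8.0]],
            index=["A", "B", "C"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture
def meta_17() -> SampleMetadata:
    """17-patient (5 PR, 12 AR) paired metadata, 34 rows."""
    rows = []
    for i in range(17):
        pat = f"P{i + 1:02d}"
        grp = "PR" if i < 5 else "AR"
        for tp in ("pre", "post"):
            rows.append(
                {"sample_id": f"{pat}_{tp}", "patient_id": pat,
                 "timepoint": tp, "group": grp}
            )
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-gene cohort with planted DE genes and two planted modules."""
    cfg = SimConfig(
        n_genes=300,
        de_spec=tuple(
            DESpec(gene_index=i, delta=d)
            for i, d in zip(range(100, 110), [1.5, -1.5] * 5)
        ),
        module_spec=(
            ModuleSpec(hub_index=0, n_leaves=9, rho=0.9),
            ModuleSpec(hub_index=10, n_leaves=9, rho=0.9),
        ),
        surv_beta=1.0,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def gene_sets() -> GeneSetCollection:
    return GeneSetCollection(
        {"S1": ("A", "B"), "S2": ("C",)},
        {"S1": "first", "S2": "second"},
    )
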