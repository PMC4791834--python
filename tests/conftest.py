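import numpy as np
import pandas as pd
import pytest

from stoichiovar.expression import ExpressionMatrix
from stoichiovar.resource import ComplexDefinition, ComplexResource


def make_design(conditions, replicates):
    rows = []
    for c in conditions:
        for r in range(1, replicates + 1):
            rows.append((f"{c}_r{r}", c, r))
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "replicate"]
    ).set_index("sample_id")


def make_matrix(values, proteins, design):
    frame = pd.DataFrame(values, index=proteins, columns=design.index, dtype=float)
    return ExpressionMatrix(frame, design)


@pytest.fixture
def five_member_resource():
    return ComplexResource(
        [ComplexDefinition("C1", "five members", "user", frozenset(f"P{i}" for i in range(1, 6)))]
    )


@pytest.fixture
def random_resource_factory():
    """Small random resources for property checks (possibly overlapping)."""

    def factory(rng, n_complexes=8, n_proteins=30, size_lo=3, size_hi=8):
        pool = [f"P{i:02d}" for i in range(n_proteins)]
        defs = []
        for i in range(n_complexes):
            size = int(rng.integers(size_lo, size_hi + 1))
            members = frozenset(rng.choice(pool, size=size, replace=False))
            source = ["manual", "compleat", "corum", "user"][int(rng.integers(4))]
            defs.append(ComplexDefinition(f"C{i:02d}", f"C{i:02d}", source, members))
        return ComplexResource(defs)

    return factory
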