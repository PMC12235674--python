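import numpy as np
import pandas as pd
import pytest

from crossnorm.core_io import ExpressionMatrix, SubtypeLabels, clean_and_match
from crossnorm.synthetic import SyntheticDesign, generate


def em(values, genes=None, samples=None, platform="", scale="linear") -> ExpressionMatrix:
    """Build a small ExpressionMatrix from a nested list."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), platform, scale)


def labels_from_counts(counts, class_names=None, prefix="S") -> SubtypeLabels:
    """Labels with the given per-class sample counts."""
    class_names = class_names or [f"C{i}" for i in range(len(counts))]
    mapping, i = {}, 0
    for cls, n in zip(class_names, counts):
        for _ in range(n):
            mapping[f"{prefix}{i:04d}"] = cls
            i += 1
    return SubtypeLabels.from_mapping(mapping, class_order=class_names)


@pytest.fixture(scope="session")
def default_pair():
    """Default synthetic design, generated and cleaned once per session."""
    a, b, labels, truth = generate(SyntheticDesign())
    pair = clean_and_match(a, b, labels)
    return pair, labels, truth
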