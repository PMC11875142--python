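import numpy as np
import pytest

from fermstab import load_paper_dataset


@pytest.fixture(scope="session")
def paper_records():
    return load_paper_dataset()


@pytest.fixture(scope="session")
def paper_design(paper_records):
    """(X, y) for the stability regressions: (D, plasmid size, T) -> hours."""
    from fermstab.regression import design_matrix
    X = design_matrix(paper_records)
    y = np.array([r.stability_duration for r in paper_records], float)
    return X, y
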