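import numpy as np
import pytest

import pparqsar as p


@pytest.fixture(scope="session")
def pfas_panel():
    """A small homologous PFAS-like panel covering all five subgroups."""
    return (
        p.make_pfas_like_series("PFCA", list(range(3, 11)))
        + p.make_pfas_like_series("PFSA", [4, 5, 6, 7, 8])
        + p.make_pfas_like_series("PFECA", [4, 5, 6, 7])
        + p.make_pfas_like_series("PFESA", [4, 5, 6])
        + p.make_pfas_like_series("FTS", [4, 6, 8])
    )


@pytest.fixture(scope="session")
def panel_matrix(pfas_panel):
    """Raw descriptor matrix for the panel (featurized once per session)."""
    matrix, failures = p.featurize(pfas_panel)
    assert not failures
    return matrix


@pytest.fixture(scope="session")
def planted():
    """Planted 2-feature problem at the modelling scale (34 x 141)."""
    spec = p.PlantedMatrixSpec(seed=11)
    X, logy = p.simulate_descriptor_matrix(spec)
    return spec, X, np.exp(logy)


@pytest.fixture(scope="session")
def toy_model(planted):
    """Linear model on the planted features, standardized, with scaler."""
    spec, X, y = planted
    std = p.standardize(X)
    sel = std.subset([X.feature_names[j] for j in spec.planted_mask])
    return p.fit(sel, y)
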