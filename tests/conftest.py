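import numpy as np
import pandas as pd
import pytest

from drpcurves import FeatureMap, OmicsMatrix, SyntheticConfig, build_pairs


@pytest.fixture
def toy_feature_map() -> FeatureMap:
    return FeatureMap(
        landmark_genes=frozenset({"g1", "g2", "g3"}),
        gene_to_protein={
            "g1": frozenset({"p1"}),
            "g2": frozenset({"p2", "p2b"}),
            "g9": frozenset({"p9"}),
        },
        gene_targets={
            "g1": frozenset({"pep1", "pep2"}),
            "g3": frozenset({"pep3"}),
            "g9": frozenset({"pep9"}),
        },
        phosphopeptide_to_protein={
            "pep1": "p1",
            "pep2": "p2",
            "pep3": "p9",
            "pep4": "p1",
            "pep9": "p9",
        },
    )


@pytest.fixture
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_cell_lines=30,
        n_drugs=6,
        n_features_per_modality={"rnaseq": 25, "proteomics": 25},
        seed=7,
    )


def matrix_from(values, cells=None, feats=None, modality="rnaseq", mask=None):
    values = np.asarray(values, dtype=float)
    cells = cells or [f"c{i}" for i in range(values.shape[0])]
    feats = feats or [f"f{j}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=cells, columns=feats)
    mask_frame = None
    if mask is not None:
        mask_frame = pd.DataFrame(np.asarray(mask, bool), index=cells, columns=feats)
    return OmicsMatrix(values=frame, modality=modality, missing_mask=mask_frame)


@pytest.fixture
def tiny_paired():
    """2 cell lines x 3 drugs, fully observed, known profiles."""
    omics = matrix_from([[1.0, 2.0], [3.0, 4.0]], cells=["c1", "c2"], feats=["f1", "f2"])
    responses = pd.DataFrame(
        {
            "cell_line": ["c1", "c1", "c1", "c2", "c2", "c2"],
            "drug": ["dA", "dB", "dC"] * 2,
            "ln_ic50": [2.0, 1.0, 0.5, 4.0, 3.0, 2.5],
        }
    )
    return build_pairs(omics, responses)
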