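"""Omics preprocessing and landmark-gene feature selection.

Implements the preprocessing each modality receives before pairing:
zero-imputation of missing proteomics values, per-cell-line standard scaling
of phosphoproteomics, landmark-panel feature selection (with the
modality-specific mapping rules), random feature subsampling and the
one-site-per-protein collapse.  The operations are exposed both as
scikit-learn transformers (operating on cells x features DataFrames) and as
thin functions over :class:`~drpcurves.datatypes.OmicsMatrix`.

The pipeline order for phosphoproteomics is scale-per-cell-line first, then
feature selection: scaling is applied to the full downloaded matrix, so the
row statistics are computed over all measured peptides, not the selected
subset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import FeatureMap, OmicsMatrix

__all__ = [
    "ZeroImputer",
    "PerCellLineScaler",
    "LandmarkFeatureSelector",
    "RandomFeatureSubsampler",
    "OneSitePerProteinCollapser",
    "impute_missing_zero",
    "scale_per_cell_line",
    "select_landmark_features",
    "subsample_features",
    "collapse_one_site_per_protein",
]


class ZeroImputer(BaseEstimator, TransformerMixin):
    """Replace missing entries with zeros.

    Missing proteomics abundances are assumed to sit below the limit of
    quantitation, so zero is the conventional fill value.
    """

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        return X.fillna(0.0)


class PerCellLineScaler(BaseEstimator, TransformerMixin):
    """Standard-scale each row (cell line) to mean 0, SD 1.

    Uses the population (divide-by-n) SD convention.  Zero-variance rows map
    to all zeros rather than erroring, so degenerate inputs flow through.
    This is a per-sample transform: there is nothing to learn at fit time,
    which also means it cannot leak information across the train/test split.
    """

    def fit(self, X, y=None):
        if np.asarray(X).shape[1] < 2:
            raise ValueError("per-cell-line scaling needs >=2 features")
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        frame = isinstance(X, pd.DataFrame)
        values = np.asarray(X, dtype=float)
        if values.shape[1] < 2:
            raise ValueError("per-cell-line scaling needs >=2 features")
        mean = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)  # ddof=0
        out = np.where(sd > 0, (values - mean) / np.where(sd == 0, 1.0, sd), 0.0)
        if frame:
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


class LandmarkFeatureSelector(BaseEstimator, TransformerMixin):
    """Select the landmark-panel features appropriate to a modality.

    rnaseq     : columns in the landmark gene set.
    proteomics : columns among the proteins coded for by landmark genes.
    phospho    : columns among peptides whose parent protein is coded by a
                 landmark gene AND that are a target of a landmark gene.

    Column order of the input is preserved.
    """

    _MODALITIES = ("rnaseq", "proteomics", "phospho")

    def __init__(self, feature_map: FeatureMap, modality: str = "rnaseq"):
        self.feature_map = feature_map
        self.modality = modality

    def _keep(self, feature_ids: list[str]) -> list[str]:
        fmap = self.feature_map
        if self.modality == "rnaseq":
            allowed = fmap.landmark_genes
        elif self.modality == "proteomics":
            allowed = fmap.landmark_proteins()
        elif self.modality == "phospho":
            proteins = fmap.landmark_proteins()
            targets = fmap.landmark_target_peptides()
            allowed = {
                pep
                for pep in fmap.phosphopeptide_to_protein
                if fmap.phosphopeptide_to_protein[pep] in proteins
                and pep in targets
            }
        else:
            raise ValueError(f"modality must be one of {self._MODALITIES}")
        keep = [f for f in feature_ids if f in allowed]
        if not keep:
            raise ValueError(
                f"no {self.modality} features overlap the landmark panel; "
                "check the landmark list and mapping tables"
            )
        return keep

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("LandmarkFeatureSelector requires a DataFrame with feature ids")
        self.keep_ = self._keep(list(X.columns))
        return self

    def transform(self, X):
        return X.loc[:, self.keep_]


class RandomFeatureSubsampler(BaseEstimator, TransformerMixin):
    """Keep ``k`` columns chosen uniformly without replacement (seeded).

    Used to test whether a modality's advantage is explained by it simply
    having more features; input column order is preserved.
    """

    def __init__(self, k: int = 100, seed: int = 0):
        self.k = k
        self.seed = seed

    def fit(self, X, y=None):
        n = np.asarray(X).shape[1]
        if self.k > n:
            raise ValueError(f"k={self.k} exceeds feature count {n}")
        rng = np.random.default_rng(self.seed)
        chosen = rng.choice(n, size=self.k, replace=False)
        self.keep_idx_ = np.sort(chosen)
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.iloc[:, self.keep_idx_]
        return np.asarray(X)[:, self.keep_idx_]


class OneSitePerProteinCollapser(BaseEstimator, TransformerMixin):
    """Keep one phosphopeptide column per parent protein.

    Retains the site with the highest variance across cell lines (the most
    informative single site under a linear-signal view).  Ties break toward
    the earlier input column.  Input column order is preserved.
    """

    def __init__(self, feature_map: FeatureMap):
        self.feature_map = feature_map

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("OneSitePerProteinCollapser requires a DataFrame")
        pep2prot = self.feature_map.phosphopeptide_to_protein
        unmapped = [f for f in X.columns if f not in pep2prot]
        if unmapped:
            raise ValueError(f"unmapped phosphopeptides: {unmapped}")
        variances = X.var(axis=0, ddof=0)
        best: dict[str, tuple[float, int, str]] = {}
        for pos, pep in enumerate(X.columns):
            prot = pep2prot[pep]
            var = float(variances[pep])
            # higher variance wins; earlier column wins ties
            if prot not in best or var > best[prot][0]:
                best[prot] = (var, pos, pep)
        keep_pos = sorted(pos for _, pos, _ in best.values())
        self.keep_ = [X.columns[p] for p in keep_pos]
        return self

    def transform(self, X):
        return X.loc[:, self.keep_]


# ---------------------------------------------------------------------------
# OmicsMatrix-level wrappers


def impute_missing_zero(m: OmicsMatrix) -> OmicsMatrix:
    """Zero-fill masked entries; unmasked entries unchanged; mask cleared."""
    if m.missing_mask is None:
        return m.with_values(m.values.copy(), missing_mask=None)
    values = m.values.mask(m.missing_mask, 0.0)
    return m.with_values(values, missing_mask=None)


def scale_per_cell_line(m: OmicsMatrix) -> OmicsMatrix:
    """Standard-scale each cell line's profile (population SD)."""
    scaler = PerCellLineScaler().fit(m.values)
    return m.with_values(scaler.transform(m.values), missing_mask=m.missing_mask)


def select_landmark_features(m: OmicsMatrix, fmap: FeatureMap) -> OmicsMatrix:
    """Apply the modality-specific landmark selection rule to ``m``."""
    sel = LandmarkFeatureSelector(fmap, modality=m.modality).fit(m.values)
    mask = None if m.missing_mask is None else m.missing_mask.loc[:, sel.keep_]
    return m.with_values(sel.transform(m.values), missing_mask=mask)


def subsample_features(m: OmicsMatrix, k: int, seed: int) -> OmicsMatrix:
    """Keep ``k`` uniformly chosen columns (seeded, order preserved)."""
    sub = RandomFeatureSubsampler(k=k, seed=seed).fit(m.values)
    mask = None if m.missing_mask is None else m.missing_mask.iloc[:, sub.keep_idx_]
    return m.with_values(sub.transform(m.values), missing_mask=mask)


def collapse_one_site_per_protein(m: OmicsMatrix, fmap: FeatureMap) -> OmicsMatrix:
    """Reduce a phospho matrix to its highest-variance site per protein."""
    col = OneSitePerProteinCollapser(fmap).fit(m.values)
    mask = None if m.missing_mask is None else m.missing_mask.loc[:, col.keep_]
    return m.with_values(col.transform(m.values), missing_mask=mask)


def prepare_modality(
    m: OmicsMatrix, fmap: FeatureMap | None = None
) -> OmicsMatrix:
    """Run the standard preprocessing chain for a modality.

    proteomics: zero-impute missing values.  phospho: per-cell-line standard
    scaling (before selection).  All modalities: landmark feature selection
    when a feature map is supplied.
    """
    out = m
    if out.missing_mask is not None:
        out = impute_missing_zero(out)
    if out.modality == "phospho":
        out = scale_per_cell_line(out)
    if fmap is not None:
        out = select_landmark_features(out, fmap)
    return out
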