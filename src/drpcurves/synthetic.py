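"""Synthetic multi-omics + ln(IC50) data with the structure the analysis assumes.

The generator emulates the statistical shape of GDSC/ProCan-style inputs:
log2-scaled omics profiles (one profile per cell line, reused across all of
that cell line's drug pairs), proteomics-style missingness at a configurable
rate, and a response surface

    y(c, d) = mu_d + e_c + eps,   eps ~ N(0, noise_sd^2)

where ``mu_d`` is a drug-level mean ln(IC50) (some drugs kill most cell
lines, others almost none — the structure the drug-average benchmark
exploits) and ``e_c`` is a latent cell-line sensitivity.  The latent effect
is embedded into every modality through a linear factor model on the
informative features:

    x_{c,m,j} = centre + a_{m,j} * (e_c + eta_{c,m}) + feature noise,
    eta_{c,m} ~ N(0, modality_distortion_sd[m]^2),

with loadings a_{m,j} supported on the informative block only.  Modalities
are therefore correlated read-outs of one cellular state, each
individually predictive of the response — mirroring the empirical situation
where transcriptome, proteome and phosphoproteome reach similar predictive
performance — and a modality advantage can be planted by giving a rival
modality nonzero distortion.  Zero-imputation of masked proteomics entries
degrades that modality's read-out slightly, as it does in real data.
Ground truth (drug means and per-modality weights) is returned for recovery
tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import OmicsMatrix

#: default modality sizing (desk scale)
DEFAULT_FEATURES = {"rnaseq": 200, "proteomics": 200, "phospho": 200}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study conditions.

    Attributes
    ----------
    n_cell_lines, n_drugs : int
        Panel size.
    n_features_per_modality : dict
        Modality name -> feature count.
    drug_mean_sd : float
        Spread of the drug-level mean ln(IC50) mu_d across drugs.
    cell_effect_sd : float
        Standard deviation (across cell lines) of the latent cell-line
        sensitivity e_c carried by the informative features.
    n_informative_features : int
        How many features (per modality) carry the cell-line signal.
    noise_sd : float
        Irreducible measurement noise on ln(IC50).
    missing_rate : float
        Fraction of proteomics-style entries flagged missing (the real
        proteomics matrix carries ~38% missing values).
    sparsity_of_response : float
        Fraction of (cell line, drug) pairs without a measured IC50.
    missing_modalities : tuple
        Which modalities receive missingness (default: proteomics only).
    modality_distortion_sd : dict
        Per-modality SD of the read-out distortion eta (default 0.0: the
        modality reads the latent effect perfectly).  Raising one modality's
        distortion plants an advantage for the others.
    """

    n_cell_lines: int = 200
    n_drugs: int = 50
    n_features_per_modality: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FEATURES)
    )
    drug_mean_sd: float = 1.0
    cell_effect_sd: float = 0.6
    n_informative_features: int = 20
    noise_sd: float = 0.4
    missing_rate: float = 0.38
    sparsity_of_response: float = 0.2
    missing_modalities: tuple[str, ...] = ("proteomics",)
    modality_distortion_sd: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_lines < 1 or self.n_drugs < 1:
            raise ValueError("n_cell_lines and n_drugs must be positive")
        for name, count in self.n_features_per_modality.items():
            if count < 1:
                raise ValueError(f"modality {name!r} must have >=1 feature")
            if self.n_informative_features > count:
                raise ValueError(
                    "n_informative_features exceeds feature count of "
                    f"modality {name!r}"
                )
        for name, value in (
            ("missing_rate", self.missing_rate),
            ("sparsity_of_response", self.sparsity_of_response),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name, value in (
            ("drug_mean_sd", self.drug_mean_sd),
            ("cell_effect_sd", self.cell_effect_sd),
            ("noise_sd", self.noise_sd),
        ):
            if value < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """The planted signal, for recovery tests.

    ``effect_weights[m]`` holds modality m's informative-feature loadings on
    the latent cell effect (nonzero exactly on the informative block);
    ``cell_effects`` is the latent sensitivity e_c itself.
    """

    drug_means: dict[str, float]
    effect_weights: dict[str, np.ndarray]
    cell_effects: dict[str, float]
    noise_sd: float


def _rng_for(config: SyntheticConfig, stream: str) -> np.random.Generator:
    # independent, reproducible substream per purpose (crc32 is process-stable,
    # unlike builtin hash)
    tag = zlib.crc32(stream.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def _cell_ids(config: SyntheticConfig) -> list[str]:
    return [f"CL{i:04d}" for i in range(config.n_cell_lines)]


def _latent_effect(config: SyntheticConfig) -> np.ndarray:
    """The shared cell-line sensitivity e_c, scaled to cell_effect_sd."""
    if config.cell_effect_sd == 0 or config.n_informative_features == 0:
        return np.zeros(config.n_cell_lines)
    raw = _rng_for(config, "latent").normal(size=config.n_cell_lines)
    sd = raw.std()
    return raw * (config.cell_effect_sd / sd) if sd > 0 else raw


#: scale of the informative-feature loadings and of the per-feature noise
_LOADING_SD = 2.0
_FEATURE_NOISE_SD = 2.0


def _modality_loadings(config: SyntheticConfig, modality: str) -> np.ndarray:
    """Factor loadings a_m (support = the informative block)."""
    k = config.n_informative_features
    n_feat = config.n_features_per_modality[modality]
    a = np.zeros(n_feat)
    if k == 0 or config.cell_effect_sd == 0:
        return a
    rng = _rng_for(config, f"loadings:{modality}")
    a[:k] = rng.normal(scale=_LOADING_SD, size=k)
    return a


def generate_omics_profiles(config: SyntheticConfig, modality: str) -> OmicsMatrix:
    """Generate one modality's cell-line x feature matrix.

    Background values are Gaussian on a log2-like scale (centre 5, SD 2 —
    typical of log2 expression/abundance matrices).  Informative columns are
    a factor model on the latent cell effect: centre + loading * (e + eta_m)
    + feature noise, so each informative feature is marginally predictive
    and the block jointly recovers e.  For modalities listed in
    ``config.missing_modalities`` a ``missing_rate`` fraction of entries is
    flagged missing (uniformly at random); masked entries retain their true
    values until imputation.
    """
    if modality not in config.n_features_per_modality:
        raise KeyError(
            f"modality {modality!r} not declared in config "
            f"(declared: {sorted(config.n_features_per_modality)})"
        )
    n_feat = config.n_features_per_modality[modality]
    rng = _rng_for(config, f"omics:{modality}")
    values = rng.normal(loc=5.0, scale=_FEATURE_NOISE_SD, size=(config.n_cell_lines, n_feat))

    k = config.n_informative_features
    loadings = _modality_loadings(config, modality)
    if loadings.any():
        effect = _latent_effect(config)
        distortion = config.modality_distortion_sd.get(modality, 0.0)
        readout = effect
        if distortion > 0:
            readout = effect + rng.normal(scale=distortion, size=config.n_cell_lines)
        values[:, :k] += np.outer(readout, loadings[:k])

    cells = _cell_ids(config)
    feats = [f"{modality}_f{j:04d}" for j in range(n_feat)]
    frame = pd.DataFrame(values, index=cells, columns=feats)
    mask = None
    if modality in config.missing_modalities and config.missing_rate > 0:
        flagged = rng.random(frame.shape) < config.missing_rate
        mask = pd.DataFrame(flagged, index=cells, columns=feats)
    return OmicsMatrix(values=frame, modality=modality, missing_mask=mask)


def generate_ic50_table(
    config: SyntheticConfig, profiles: dict[str, OmicsMatrix]
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the long-format ln(IC50) table for the generated profiles.

    y(c,d) = mu_d + e_c + eps with the same latent effect the profiles
    embed, so every modality's informative block predicts the cell-line part
    of the response (up to that modality's distortion).  A
    ``sparsity_of_response`` fraction of pairs is dropped at random.
    """
    if not profiles:
        raise ValueError("profiles must contain at least one modality")
    missing = set(config.n_features_per_modality) - set(profiles)
    if missing:
        raise ValueError(f"profiles missing declared modalities: {sorted(missing)}")

    rng = _rng_for(config, "responses")
    cells = next(iter(profiles.values())).cell_line_ids
    drugs = [f"D{j:03d}" for j in range(config.n_drugs)]
    drug_means = dict(
        zip(drugs, rng.normal(0.0, config.drug_mean_sd, size=config.n_drugs))
    )
    effect = _latent_effect(config)[: len(cells)]

    rows = []
    for i, cell in enumerate(cells):
        eps = rng.normal(0.0, config.noise_sd, size=config.n_drugs)
        for j, drug in enumerate(drugs):
            rows.append((cell, drug, drug_means[drug] + effect[i] + eps[j]))
    table = pd.DataFrame(rows, columns=["cell_line", "drug", "ln_ic50"])
    if config.sparsity_of_response > 0:
        keep = rng.random(len(table)) >= config.sparsity_of_response
        table = table.loc[keep].reset_index(drop=True)
    truth = GroundTruth(
        drug_means=drug_means,
        effect_weights={m: _modality_loadings(config, m) for m in sorted(profiles)},
        cell_effects=dict(zip(cells, effect)),
        noise_sd=config.noise_sd,
    )
    return table, truth


def simulate_dataset(
    config: SyntheticConfig,
) -> tuple[dict[str, OmicsMatrix], pd.DataFrame, GroundTruth]:
    """Generate all declared modalities plus the response table."""
    profiles = {
        m: generate_omics_profiles(config, m)
        for m in sorted(config.n_features_per_modality)
    }
    table, truth = generate_ic50_table(config, profiles)
    return profiles, table, truth
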