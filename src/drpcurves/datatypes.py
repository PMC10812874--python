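"""Core in-memory containers for the drug-response-prediction pipeline.

The pipeline moves three kinds of data around: per-modality omics matrices
(cell lines x features), a long-format table of ln(IC50) drug responses, and
the paired (cell profile, one-hot drug, target) arrays that the learners
consume.  Matrices are held as pandas DataFrames indexed by cell-line id with
feature ids as columns; the paired arrays are plain numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

RESPONSE_COLUMNS = ("cell_line", "drug", "ln_ic50")


@dataclass
class OmicsMatrix:
    """A cell-line x feature real matrix for one omics modality.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are cell lines, columns are features (genes, proteins or
        phosphopeptides depending on the modality).
    modality : str
        Modality name, conventionally one of ``rnaseq``, ``proteomics``,
        ``phospho``.
    missing_mask : pandas.DataFrame of bool, optional
        True where the measurement is missing (e.g. proteomics values below
        the limit of quantitation).  Missing entries are carried explicitly
        rather than silently zeroed; see
        :func:`drpcurves.preprocess.impute_missing_zero`.
    """

    values: pd.DataFrame
    modality: str
    missing_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate cell-line ids: {dupes}")
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique())
            raise ValueError(f"duplicate feature ids: {dupes}")
        if self.missing_mask is not None:
            if self.missing_mask.shape != self.values.shape:
                raise ValueError(
                    "missing_mask shape "
                    f"{self.missing_mask.shape} != values shape {self.values.shape}"
                )
            self.missing_mask = self.missing_mask.set_axis(idx, axis=0).set_axis(
                cols, axis=1
            )

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cell_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def with_values(
        self,
        values: pd.DataFrame,
        missing_mask: pd.DataFrame | None = None,
    ) -> "OmicsMatrix":
        """Return a copy carrying new values (and optionally a new mask)."""
        return replace(self, values=values, missing_mask=missing_mask)

    def restrict_cell_lines(self, cell_lines: Sequence[str]) -> "OmicsMatrix":
        """Row-subset to ``cell_lines`` in the given order."""
        values = self.values.loc[list(cell_lines)]
        mask = None
        if self.missing_mask is not None:
            mask = self.missing_mask.loc[list(cell_lines)]
        return replace(self, values=values, missing_mask=mask)


@dataclass
class FeatureMap:
    """Static landmark-gene panel and gene/protein/peptide mapping tables.

    ``landmark_genes`` is the dimensionality-reduction panel (a ~1,000-gene
    set whose expression recovers most of the transcriptome).
    ``gene_to_protein`` maps genes to the protein ids they code for;
    ``gene_targets`` maps genes to the phosphopeptides they (as kinases)
    target; ``phosphopeptide_to_protein`` maps each measured peptide to its
    parent protein.
    """

    landmark_genes: frozenset[str]
    gene_to_protein: dict[str, frozenset[str]] = field(default_factory=dict)
    gene_targets: dict[str, frozenset[str]] = field(default_factory=dict)
    phosphopeptide_to_protein: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, ids in (
            ("landmark_genes", self.landmark_genes),
            ("gene_to_protein", self.gene_to_protein),
            ("gene_targets", self.gene_targets),
            ("phosphopeptide_to_protein", self.phosphopeptide_to_protein),
        ):
            if any(not str(i) for i in ids):
                raise ValueError(f"{name} contains an empty identifier")
        self.landmark_genes = frozenset(self.landmark_genes)
        self.gene_to_protein = {
            g: frozenset(p) for g, p in self.gene_to_protein.items()
        }
        self.gene_targets = {g: frozenset(p) for g, p in self.gene_targets.items()}

    def landmark_proteins(self) -> frozenset[str]:
        """Proteins coded for by a landmark gene."""
        out: set[str] = set()
        for gene in self.landmark_genes:
            out |= self.gene_to_protein.get(gene, frozenset())
        return frozenset(out)

    def landmark_target_peptides(self) -> frozenset[str]:
        """Phosphopeptides that are a target of a landmark gene."""
        out: set[str] = set()
        for gene in self.landmark_genes:
            out |= self.gene_targets.get(gene, frozenset())
        return frozenset(out)


def validate_response_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format (cell_line, drug, ln_ic50) response table.

    Enforces the column contract, uniqueness of (cell_line, drug) pairs and
    finiteness of the ln(IC50) targets; returns the table with canonical
    column order.
    """
    missing = [c for c in RESPONSE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"response table missing columns: {missing}")
    table = table.loc[:, list(RESPONSE_COLUMNS)]
    dup = table.duplicated(subset=["cell_line", "drug"])
    if dup.any():
        pairs = table.loc[dup, ["cell_line", "drug"]].values.tolist()[:5]
        raise ValueError(f"duplicate (cell_line, drug) pairs, e.g. {pairs}")
    if not np.isfinite(table["ln_ic50"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite ln_ic50 values in response table")
    return table


@dataclass
class PairedDataset:
    """Aligned (x_c, x_d, y) triples: the training unit of the pipeline.

    ``cell_inputs`` repeats each cell line's omics profile once per measured
    drug; ``drug_inputs`` is the one-hot drug encoding over
    ``drug_vocabulary``; ``targets`` holds ln(IC50).  ``pair_index`` records
    the (cell_line, drug) identity of every row.
    """

    cell_inputs: np.ndarray
    drug_inputs: np.ndarray
    targets: np.ndarray
    pair_index: list[tuple[str, str]]
    drug_vocabulary: list[str]

    def __post_init__(self) -> None:
        n = len(self.targets)
        if not (self.cell_inputs.shape[0] == self.drug_inputs.shape[0] == n == len(self.pair_index)):
            raise ValueError("cell_inputs, drug_inputs, targets and pair_index lengths differ")
        if self.drug_inputs.shape[1] != len(self.drug_vocabulary):
            raise ValueError("drug one-hot width != vocabulary size")
        sums = self.drug_inputs.sum(axis=1)
        if n and not np.array_equal(sums, np.ones(n)):
            raise ValueError("each drug one-hot row must sum to exactly 1")

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def n_pairs(self) -> int:
        return len(self.targets)

    @property
    def cell_lines(self) -> list[str]:
        return [c for c, _ in self.pair_index]

    @property
    def drugs(self) -> list[str]:
        return [d for _, d in self.pair_index]

    def features(self) -> np.ndarray:
        """Concatenated (x_c || x_d) design matrix for tabular learners."""
        return np.hstack([self.cell_inputs, self.drug_inputs])

    def subset(self, rows: Sequence[int]) -> "PairedDataset":
        """Row-subset keeping the drug vocabulary (encoding is stable)."""
        rows = list(rows)
        return PairedDataset(
            cell_inputs=self.cell_inputs[rows],
            drug_inputs=self.drug_inputs[rows],
            targets=self.targets[rows],
            pair_index=[self.pair_index[i] for i in rows],
            drug_vocabulary=list(self.drug_vocabulary),
        )
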