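"""Delimited-file readers and writers.

All matrices travel as TSV/CSV with one header row of feature ids and one id
column of cell lines (orientation configurable), so synthetic and real data
flow through one code path.  Empty cells are recorded in the missing mask,
never silently zeroed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .datatypes import FeatureMap, OmicsMatrix, validate_response_table

logger = logging.getLogger(__name__)

_ORIENTATIONS = ("cells-by-features", "features-by-cells")


def _infer_delimiter(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _check_rectangular(path: str | Path, delimiter: str) -> None:
    # header may legitimately carry one fewer field (R-style matrix dump)
    with open(path) as fh:
        header_width = fh.readline().count(delimiter)
        width: int | None = None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            w = line.count(delimiter)
            if width is None:
                width = w
                if header_width not in (w, w - 1):
                    raise ValueError(
                        f"{path}: header has {header_width + 1} fields, "
                        f"data rows have {w + 1}"
                    )
            elif w != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({w + 1} fields, expected {width + 1})"
                )


def read_omics_matrix(
    path: str | Path,
    modality: str,
    delimiter: str | None = None,
    orientation: str = "cells-by-features",
) -> OmicsMatrix:
    """Read a delimited omics matrix into an :class:`OmicsMatrix`.

    Parameters
    ----------
    orientation : str
        ``"cells-by-features"`` (rows are cell lines) or
        ``"features-by-cells"`` (file is transposed; it is transposed back on
        read so both orientations yield the identical matrix).
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    delimiter = delimiter or _infer_delimiter(path)
    _check_rectangular(path, delimiter)
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if orientation == "features-by-cells":
        frame = frame.T
    mask = frame.isna()
    values = frame.astype(float).fillna(0.0).where(~mask, 0.0)
    logger.info(
        "read %s matrix %s: %d cell lines x %d features (%d missing)",
        modality, path, frame.shape[0], frame.shape[1], int(mask.to_numpy().sum()),
    )
    return OmicsMatrix(
        values=values,
        modality=modality,
        missing_mask=mask if mask.to_numpy().any() else None,
    )


def write_omics_matrix(
    m: OmicsMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    """Write a matrix; masked entries are emitted as empty cells."""
    delimiter = delimiter or _infer_delimiter(path)
    frame = m.values
    if m.missing_mask is not None:
        frame = frame.mask(m.missing_mask)
    frame.to_csv(path, sep=delimiter)


def read_response_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read the long-format ``cell_line,drug,ln_ic50`` response table.

    ln_ic50 is the natural-log-transformed IC50 (the GDSC convention).
    """
    delimiter = delimiter or _infer_delimiter(path)
    table = pd.read_csv(path, sep=delimiter, dtype={"cell_line": str, "drug": str})
    table = validate_response_table(table)
    logger.info(
        "read response table %s: %d rows, %d cell lines, %d drugs",
        path, len(table), table["cell_line"].nunique(), table["drug"].nunique(),
    )
    return table


def write_response_table(
    table: pd.DataFrame, path: str | Path, delimiter: str | None = None
) -> None:
    delimiter = delimiter or _infer_delimiter(path)
    validate_response_table(table).to_csv(path, sep=delimiter, index=False)


def read_feature_map(
    landmark_path: str | Path,
    gene_to_protein_path: str | Path | None = None,
    gene_targets_path: str | Path | None = None,
    peptide_to_protein_path: str | Path | None = None,
) -> FeatureMap:
    """Assemble a :class:`FeatureMap` from static TSV mapping tables.

    ``landmark_path`` holds one gene per line (no header).  The optional
    two-column TSVs are headered ``gene<TAB>protein``, ``gene<TAB>peptide``
    and ``peptide<TAB>protein`` respectively.
    """
    landmarks = frozenset(
        line.strip() for line in open(landmark_path) if line.strip()
    )

    def _pairs(path: str | Path | None) -> list[tuple[str, str]]:
        if path is None:
            return []
        frame = pd.read_csv(path, sep="\t", dtype=str)
        return [tuple(row) for row in frame.itertuples(index=False)]

    gene_to_protein: dict[str, set[str]] = {}
    for gene, protein in _pairs(gene_to_protein_path):
        gene_to_protein.setdefault(gene, set()).add(protein)
    gene_targets: dict[str, set[str]] = {}
    for gene, peptide in _pairs(gene_targets_path):
        gene_targets.setdefault(gene, set()).add(peptide)
    peptide_to_protein = dict(_pairs(peptide_to_protein_path))
    return FeatureMap(
        landmark_genes=landmarks,
        gene_to_protein={g: frozenset(v) for g, v in gene_to_protein.items()},
        gene_targets={g: frozenset(v) for g, v in gene_targets.items()},
        phosphopeptide_to_protein=peptide_to_protein,
    )
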