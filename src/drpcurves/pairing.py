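"""Paired-dataset construction: (x_c, x_d, y) triples with one-hot drugs.

A cell line's omics profile is measured once but predicts many drug
responses, so the same x_c row is repeated across that cell line's drugs;
each (x_c, x_d) pair corresponds to a unique target y.  Drugs carry no
molecular descriptors — the one-hot encoding deliberately contains no
chemistry, so modality comparisons are not confounded by drug features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import OmicsMatrix, PairedDataset, validate_response_table


def one_hot_encode_drugs(
    drug_ids: list[str], vocabulary: list[str]
) -> np.ndarray:
    """One-hot encode ``drug_ids`` against an ordered drug vocabulary.

    The vocabulary is fixed from the full response table before any
    splitting, so train and test share one encoding and drugs absent from a
    training subset still have a defined column.
    """
    position = {d: j for j, d in enumerate(vocabulary)}
    unknown = [d for d in drug_ids if d not in position]
    if unknown:
        raise KeyError(f"drugs not in vocabulary: {sorted(set(unknown))}")
    out = np.zeros((len(drug_ids), len(vocabulary)))
    for i, d in enumerate(drug_ids):
        out[i, position[d]] = 1.0
    return out


def drop_cell_lines_without_targets(
    omics: dict[str, OmicsMatrix], responses: pd.DataFrame
) -> dict[str, OmicsMatrix]:
    """Remove cell lines that have no measured response from every modality."""
    responses = validate_response_table(responses)
    with_targets = set(responses["cell_line"])
    out: dict[str, OmicsMatrix] = {}
    for modality, matrix in omics.items():
        keep = [c for c in matrix.cell_line_ids if c in with_targets]
        if not keep:
            import warnings

            warnings.warn(
                f"all cell lines of modality {modality!r} lack targets",
                stacklevel=2,
            )
        out[modality] = matrix.restrict_cell_lines(keep)
    return out


def intersect_cell_line_sets(matrices: list[OmicsMatrix]) -> list[str]:
    """Sorted intersection of the matrices' cell-line sets.

    This realises the cell-line-set (CLS) construction: analyses run on the
    cell lines profiled in every modality under comparison.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    common = set(matrices[0].cell_line_ids)
    for m in matrices[1:]:
        common &= set(m.cell_line_ids)
    return sorted(common)


def build_pairs(
    omics: OmicsMatrix,
    responses: pd.DataFrame,
    cell_lines: list[str] | None = None,
    drug_vocabulary: list[str] | None = None,
) -> PairedDataset:
    """Assemble the aligned (x_c, x_d, y) triples for one modality.

    One triple per response row; rows ordered by (cell line, drug)
    lexicographically so re-running is byte-identical.  The drug vocabulary
    defaults to the sorted distinct drugs of ``responses``.
    """
    responses = validate_response_table(responses)
    if cell_lines is None:
        cell_lines = [c for c in omics.cell_line_ids if c in set(responses["cell_line"])]
    cell_set = set(cell_lines)
    missing = cell_set - set(omics.cell_line_ids)
    if missing:
        raise KeyError(f"cell lines absent from omics matrix: {sorted(missing)[:5]}")
    responses = responses[responses["cell_line"].isin(cell_set)]
    orphan = set(responses["cell_line"]) - set(omics.cell_line_ids)
    if orphan:
        raise KeyError(f"responses reference unknown cell lines: {sorted(orphan)[:5]}")
    responses = responses.sort_values(["cell_line", "drug"], kind="mergesort")

    if drug_vocabulary is None:
        drug_vocabulary = sorted(responses["drug"].unique())
    row_of = {c: i for i, c in enumerate(omics.cell_line_ids)}
    values = omics.values.to_numpy()
    cell_rows = [row_of[c] for c in responses["cell_line"]]
    cell_inputs = values[cell_rows]
    drug_inputs = one_hot_encode_drugs(list(responses["drug"]), drug_vocabulary)
    return PairedDataset(
        cell_inputs=cell_inputs,
        drug_inputs=drug_inputs,
        targets=responses["ln_ic50"].to_numpy(dtype=float),
        pair_index=list(zip(responses["cell_line"], responses["drug"])),
        drug_vocabulary=list(drug_vocabulary),
    )
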