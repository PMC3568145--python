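"""Reading, validation and alignment of the three input tables.

All matrices are tab-separated UTF-8 text: first row holds sample ids, first
column holds gene ids.  Expression values are real numbers (log2 scale);
copy-number status codes are the discrete GISTIC/RAE-style values
{-2, -1, 0, +1, +2}.  The annotation table has two columns
(sample_id, class) with class in {TUMOR, NORMAL}, case-insensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR = "TUMOR"
NORMAL = "NORMAL"
VALID_CNA_CODES = frozenset({-2, -1, 0, 1, 2})

#: column layout of the ranked per-gene output files
RESULT_COLUMNS = [
    "gene",
    "n_altered",
    "eis_normal",
    "eis_tumor",
    "z_normal",
    "z_tumor",
    "z_comb",
    "p_value",
    "corrected_p",
]


@dataclass
class AlterationDataset:
    """Aligned expression, copy-number status and sample annotation.

    ``expression``: genes x samples (tumors and normals), float, NaN = missing.
    ``cna``: genes x tumor samples, int codes in {-2..2}.
    ``annotation``: sample_id -> TUMOR | NORMAL, covering every expression column.
    """

    expression: pd.DataFrame
    cna: pd.DataFrame
    annotation: pd.Series

    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s in self.expression.columns if self.annotation[s] == TUMOR]

    @property
    def normal_samples(self) -> list[str]:
        return [s for s in self.expression.columns if self.annotation[s] == NORMAL]


def _check_unique(ids, kind: str, path) -> None:
    seen: set = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {kind} id {x!r} in {path}")
        seen.add(x)


def _read_table(path) -> tuple[list[str], list[str], list[list[str]]]:
    """Parse the TSV dialect, returning (sample_ids, gene_ids, raw cells)."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValueError(f"empty matrix file: {path}")
    header = lines[0].split("\t")
    samples = header[1:]
    _check_unique(samples, "sample", path)
    genes: list[str] = []
    rows: list[list[str]] = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        genes.append(parts[0])
        if len(parts) - 1 != len(samples):
            raise ValueError(
                f"row {parts[0]!r} in {path} has {len(parts) - 1} values, "
                f"expected {len(samples)}"
            )
        rows.append(parts[1:])
    _check_unique(genes, "gene", path)
    return samples, genes, rows


def read_expression_matrix(path, missing_token: str = "NA") -> pd.DataFrame:
    """Read a gene x sample expression matrix (log2 intensities).

    Cells equal to ``missing_token`` become NaN.  Duplicate ids and
    non-numeric cells raise ``ValueError`` naming the offender.
    """
    samples, genes, rows = _read_table(path)
    values = np.empty((len(genes), len(samples)), dtype=float)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            if cell == missing_token:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric expression value {cell!r} at gene "
                        f"{genes[i]!r}, sample {samples[j]!r} in {path}"
                    ) from None
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)


def read_cna_matrix(path) -> pd.DataFrame:
    """Read a gene x sample copy-number status matrix (codes -2..+2)."""
    samples, genes, rows = _read_table(path)
    values = np.empty((len(genes), len(samples)), dtype=np.int8)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            try:
                code = int(cell)
            except ValueError:
                raise ValueError(
                    f"non-integer copy-number code {cell!r} at gene "
                    f"{genes[i]!r}, sample {samples[j]!r} in {path}"
                ) from None
            if code not in VALID_CNA_CODES:
                raise ValueError(
                    f"copy-number code {code} out of range [-2, 2] at gene "
                    f"{genes[i]!r}, sample {samples[j]!r} in {path}"
                )
            values[i, j] = code
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)


def read_annotation(path) -> pd.Series:
    """Read the two-column sample annotation table (sample_id, TUMOR|NORMAL)."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for ln in fh:
            if not ln.strip():
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"annotation line without class: {ln!r} in {path}")
            sample, cls = parts[0], parts[1].strip().upper()
            if sample in ("sample", "sample_id") and cls in ("CLASS", "TYPE"):
                continue  # optional header
            if cls not in (TUMOR, NORMAL):
                raise ValueError(
                    f"annotation class {parts[1]!r} for sample {sample!r} "
                    f"is not TUMOR/NORMAL in {path}"
                )
            if sample in mapping and mapping[sample] != cls:
                raise ValueError(f"sample {sample!r} annotated twice with different classes")
            mapping[sample] = cls
    if not mapping:
        raise ValueError(f"empty annotation file: {path}")
    ann = pd.Series(mapping, name="class")
    if not (ann == TUMOR).any():
        raise ValueError("annotation contains no TUMOR samples")
    return ann


def align_dataset(
    expr: pd.DataFrame, cna: pd.DataFrame, annot: pd.Series
) -> AlterationDataset:
    """Restrict the three inputs to their shared genes and usable samples.

    Genes are reduced to the expression/CNA intersection (expression order).
    Tumor samples must be present in expression, CNA and annotation; normal
    samples only need expression and annotation, since copy-number calls for
    normal tissue are frequently absent and normals are used purely as an
    expression reference.  Dropped counts are logged as warnings.
    """
    annot = annot.str.upper()
    genes = [g for g in expr.index if g in set(cna.index)]
    if not genes:
        raise ValueError("expression and copy-number matrices share no genes")
    annotated = set(annot.index)
    cna_samples = set(cna.columns)
    keep: list[str] = []
    for s in expr.columns:
        if s not in annotated:
            continue
        if annot[s] == TUMOR and s not in cna_samples:
            continue
        keep.append(s)
    if not any(annot[s] == TUMOR for s in keep):
        raise ValueError("no tumor sample is shared by expression, CNA and annotation")

    dropped_expr = len(expr.columns) - len(keep)
    if dropped_expr:
        logger.warning("align_dataset: dropped %d expression sample(s)", dropped_expr)
    tumors = [s for s in keep if annot[s] == TUMOR]
    dropped_cna = len(cna.columns) - len(tumors)
    if dropped_cna:
        logger.warning("align_dataset: dropped %d CNA sample(s)", dropped_cna)
    dropped_genes = len(expr.index) - len(genes)
    if dropped_genes:
        logger.warning("align_dataset: dropped %d expression gene(s)", dropped_genes)

    return AlterationDataset(
        expression=expr.loc[genes, keep],
        cna=cna.loc[genes, tumors],
        annotation=annot.loc[keep],
    )


def write_results(results: pd.DataFrame, direction: str, path) -> None:
    """Write one ranked output file (AMP or DEL analysis).

    ``results`` must already be ranked: Z_COMB decreasing for amplifications,
    increasing for deletions (most negative first).  Columns follow
    ``RESULT_COLUMNS``; absent normal-reference fields are written as NA.
    """
    out = results.reindex(columns=RESULT_COLUMNS)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    """Read back a ranked output file written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a gene x sample matrix in the package's TSV dialect."""
    df.to_csv(path, sep="\t", index_label="gene")


def write_annotation(annot: pd.Series, path) -> None:
    annot.to_csv(path, sep="\t", header=False)
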