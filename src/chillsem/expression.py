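"""Expression-matrix container and TSV interfaces.

The pipeline's central data structure is a genes × samples table together
with a per-sample design (timepoint, replicate).  Values may be raw counts,
FPKM, log-scale continuous expression, or row Z-scores; the ``kind`` tag
records which, and count matrices are validated as nonnegative integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_KINDS = ("counts", "fpkm", "log", "zscore")

#: float format used by every numeric TSV writer; pinned so that repeated
#: runs with the same seed produce byte-identical files.
FLOAT_FORMAT = "%.10g"


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with sample design metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample IDs as columns.
    design
        DataFrame indexed by sample ID with columns ``timepoint`` and
        ``replicate``, aligned to ``values.columns``.
    kind
        One of ``counts``, ``fpkm``, ``log``, ``zscore``.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene IDs")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")
        if not self.design.index.equals(self.values.columns):
            # allow same set in same order under a different index name
            if list(self.design.index) != list(self.values.columns):
                raise ValueError("design samples do not match matrix columns")
        if self.kind == "counts":
            arr = self.values.to_numpy()
            if (arr < 0).any():
                raise ValueError("counts must be nonnegative")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_for_timepoint(self, timepoint: str) -> list[str]:
        mask = self.design["timepoint"] == timepoint
        return list(self.design.index[mask])

    def restrict_genes(self, genes) -> "ExpressionMatrix":
        """Subset to the given genes, preserving the given order."""
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[genes], self.design, self.kind)

    # ------------------------------------------------------------------
    def to_tsv(self, path, design_path=None) -> None:
        df = self.values.copy()
        df.index.name = "gene"
        if self.kind == "counts":
            df.astype(np.int64).to_csv(path, sep="\t")
        else:
            df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
        if design_path is not None:
            d = self.design.copy()
            d.index.name = "sample"
            d.to_csv(design_path, sep="\t")


def read_design_tsv(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"sample": str, "timepoint": str})
    design = design.set_index("sample")
    return design


def read_expression_tsv(path, design_path=None, kind: str = "counts",
                        design: pd.DataFrame | None = None) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    if design is None:
        if design_path is not None:
            design = read_design_tsv(design_path)
        else:
            design = default_design(list(values.columns))
    return ExpressionMatrix(values, design, kind)


def default_design(sample_ids: list[str],
                   timepoints: list[str] | None = None,
                   replicates: int | None = None) -> pd.DataFrame:
    """Build a design table for a list of samples.

    When ``timepoints``/``replicates`` tile the samples exactly, samples are
    assigned in blocks (all replicates of the first timepoint first);
    otherwise every sample falls into a single pseudo-timepoint ``all``.
    """
    n = len(sample_ids)
    if timepoints and replicates and n == len(timepoints) * replicates:
        tp = [timepoints[i // replicates] for i in range(n)]
        rep = [i % replicates + 1 for i in range(n)]
    else:
        tp = ["all"] * n
        rep = list(range(1, n + 1))
    return pd.DataFrame({"timepoint": tp, "replicate": rep},
                        index=pd.Index(sample_ids, name="sample"))
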