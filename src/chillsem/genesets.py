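"""Gene-block assignment, over-representation testing, and Z-scaling.

Chilling-responsive genes are partitioned into functional blocks — hormone
signal-transduction classes (ABA, IAA, CTK, ETH, BR, GA, JA, SA, SL),
transcription-factor families (ICE1, CBF, bZIP), and the antioxidant
system (AO) — from a gene → label annotation table.  A hypergeometric
over-representation test asks whether a block is enriched among a selected
gene set, and row Z-scoring prepares FPKM matrices for heatmaps and for
PLS path modeling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import CRGSet, bh_adjust
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

#: controlled label vocabulary; unknown labels are kept as user-defined terms
CONTROLLED_VOCABULARY = frozenset(
    {"ABA", "IAA", "CTK", "ETH", "BR", "GA", "JA", "SA", "SL",
     "ICE1", "CBF", "bZIP", "AO"})


def read_annotation_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(ann.columns[:2])
    ann = ann.rename(columns={cols[0]: "gene", cols[1]: "block"})
    return ann


@dataclass
class GeneSetPartition:
    """Block label → ordered gene list, restricted to a CRG set; a gene may
    sit in several blocks, genes with no label are ``unassigned``."""

    blocks: dict[str, list[str]]
    unassigned: list[str]

    def covered(self) -> set[str]:
        out = set(self.unassigned)
        for genes in self.blocks.values():
            out.update(genes)
        return out


def assign_blocks(crgs: CRGSet | set[str], annotation: pd.DataFrame) -> GeneSetPartition:
    """Assign each CRG every block label it carries; unlabeled CRGs go to
    the unassigned list.  Block order and within-block gene order follow
    the annotation's input order (deterministic)."""
    genes = crgs.genes if isinstance(crgs, CRGSet) else set(crgs)
    if annotation.duplicated(subset=["gene", "block"]).any():
        raise ValueError("duplicate (gene, label) pairs in annotation")
    unknown = sorted(set(annotation["block"]) - CONTROLLED_VOCABULARY)
    if unknown:
        warnings.warn(f"annotation labels outside the controlled vocabulary "
                      f"kept as user-defined terms: {unknown}", stacklevel=2)
    blocks: dict[str, list[str]] = {}
    labeled: set[str] = set()
    for gene, block in annotation[["gene", "block"]].itertuples(index=False):
        if gene not in genes:
            continue
        blocks.setdefault(block, []).append(gene)
        labeled.add(gene)
    # preserve input order for the unassigned remainder where possible
    unassigned = sorted(genes - labeled)
    return GeneSetPartition(blocks, unassigned)


def ora_hypergeometric(selected: set[str], universe: set[str],
                       annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-label hypergeometric over-representation of ``selected`` within
    ``universe``: p = P(overlap ≥ observed) under sampling |selected| genes
    without replacement; BH-adjusted across labels.  An empty label set has
    p = 1 by convention."""
    selected, universe = set(selected), set(universe)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    m = len(universe)
    n_sel = len(selected)
    rows = []
    for label, sub in annotation.groupby("block", sort=True):
        label_set = set(sub["gene"]) & universe
        overlap = len(label_set & selected)
        if not label_set:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, m, len(label_set), n_sel))
        rows.append((label, len(label_set), overlap, min(1.0, p)))
    out = pd.DataFrame(rows, columns=["label", "label_size", "overlap", "p_value"])
    out["fdr"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out


def zscore_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Row-wise Z-score: (x − mean)/sd with sample sd (n − 1).  Rows with
    zero sd map to all-zero and are logged."""
    if matrix.n_samples < 2:
        raise ValueError("Z-scoring needs at least 2 samples")
    values = matrix.values
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning("constant row(s) mapped to zero in Z-scoring: %s",
                       list(values.index[flat]))
    safe_sd = sd.mask(flat, 1.0)
    z = values.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[flat] = 0.0
    return ExpressionMatrix(z, matrix.design, kind="zscore")
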