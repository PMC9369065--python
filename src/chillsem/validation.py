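"""qRT-PCR relative quantification and RNA-Seq concordance.

Relative expression from Ct values follows the 2^−ΔΔCt convention: the
target gene's Ct is normalized to a reference gene (e.g. Actin) per
sample, then to a calibrator sample, and exponentiated.  Concordance
between platforms is an OLS regression of qPCR log2 fold-changes on the
RNA-Seq ones, with the Pearson correlation and its t-based p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_CT_COLUMNS = ("gene", "sample", "ct_target", "ct_reference")


def read_ct_tsv(path) -> pd.DataFrame:
    ct = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing column(s): {missing}")
    return ct


def ddct(ct: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """2^−ΔΔCt relative expression per (gene, sample).

    ΔCt = Ct_target − Ct_reference; ΔΔCt = ΔCt_sample − ΔCt_calibrator;
    relative expression = 2^−ΔΔCt (the calibrator sample maps to 1 by
    construction).  Technical replicates (repeated (gene, sample) rows)
    are averaged on the Ct scale first.
    """
    missing = [c for c in REQUIRED_CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing column(s): {missing}")
    if not np.isfinite(ct[["ct_target", "ct_reference"]].to_numpy()).all():
        raise ValueError("Ct values must be finite")
    mean_ct = (ct.groupby(["gene", "sample"], sort=False)[["ct_target", "ct_reference"]]
               .mean().reset_index())
    mean_ct["dct"] = mean_ct["ct_target"] - mean_ct["ct_reference"]
    cal = mean_ct[mean_ct["sample"] == calibrator].set_index("gene")["dct"]
    missing_cal = sorted(set(mean_ct["gene"]) - set(cal.index))
    if missing_cal:
        raise ValueError(f"no calibrator row for gene(s): {missing_cal[:5]}")
    mean_ct["ddct"] = mean_ct["dct"] - mean_ct["gene"].map(cal)
    mean_ct["relative_expression"] = 2.0 ** (-mean_ct["ddct"])
    return mean_ct[["gene", "sample", "dct", "ddct", "relative_expression"]]


@dataclass
class ConcordanceResult:
    """OLS fit of qPCR on RNA-Seq log2 fold-changes."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "pearson_r": self.r, "p_value": self.p_value, "n": self.n}


def concordance(log2fc_rnaseq: pd.Series, log2fc_qpcr: pd.Series) -> ConcordanceResult:
    """Regress qPCR log2 fold-changes (y) on RNA-Seq ones (x) over the
    shared genes; Pearson r with a two-sided p from the t distribution
    with n − 2 df."""
    shared = log2fc_rnaseq.index.intersection(log2fc_qpcr.index)
    x = log2fc_rnaseq.loc[shared].to_numpy(dtype=float)
    y = log2fc_qpcr.loc[shared].to_numpy(dtype=float)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("fold-changes must be finite")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in RNA-Seq fold-changes")
    res = stats.linregress(x, y)
    return ConcordanceResult(float(res.slope), float(res.intercept),
                             float(res.rvalue), float(res.pvalue), len(shared))
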