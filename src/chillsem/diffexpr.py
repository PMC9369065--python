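"""Negative-binomial differential-expression screening.

A transparent re-implementation of the classical count-based DE screen:
median-of-ratios library-size normalization, method-of-moments NB
dispersion with a small floor, a Wald test on the log2 fold-change via the
delta method, Benjamini–Hochberg FDR, and the two-threshold screen
(FDR ≤ 0.01 and |fold-change| ≥ 2).  Genes passing the screen in every
chilling-vs-control contrast form the chilling-responsive gene (CRG) set.

The test is deliberately simple and self-contained — no dispersion
shrinkage across genes, no outlier refitting — so every number it produces
can be recomputed by hand from the formulas below.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


# ----------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------

def size_factors(counts: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_s = median over genes g (with positive geometric mean) of
    count_gs / geomean_g.  Requires every sample to have at least one
    usable gene.
    """
    values = counts.values if isinstance(counts, ExpressionMatrix) else counts
    arr = values.to_numpy(dtype=float)
    if (arr.sum(axis=0) == 0).any():
        bad = values.columns[arr.sum(axis=0) == 0].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    with np.errstate(divide="ignore"):
        log_geo = np.log(arr).mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no gene with positive counts in every sample")
    ratios = arr[usable] / np.exp(log_geo[usable])[:, None]
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise ValueError("nonpositive size factor; counts too sparse")
    return pd.Series(factors, index=values.columns, name="size_factor")


def normalize_counts(counts: ExpressionMatrix) -> pd.DataFrame:
    """Counts divided by their median-of-ratios size factors."""
    return counts.values / size_factors(counts)


def fpkm(counts: ExpressionMatrix, gene_lengths_bp: pd.Series) -> ExpressionMatrix:
    """FPKM_gs = count_gs × 10⁹ / (length_g × total_s) from raw counts."""
    lengths = gene_lengths_bp.reindex(counts.values.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise KeyError(f"genes without a length: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.values.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("per-sample totals must be positive")
    vals = counts.values.div(lengths, axis=0).div(totals, axis=1) * 1e9
    return ExpressionMatrix(vals, counts.design, kind="fpkm")


# ----------------------------------------------------------------------
# dispersion and the Wald test
# ----------------------------------------------------------------------

def estimate_dispersion(normalized: np.ndarray, floor: float = DISPERSION_FLOOR) -> float:
    """Method-of-moments NB dispersion α = max(floor, (s² − x̄)/x̄²).

    ``normalized`` is one gene's normalized counts over ≥ 2 samples.
    Raises when the mean is zero (dispersion undefined for that gene).
    """
    x = np.asarray(normalized, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    mean = x.mean()
    if mean == 0:
        raise ValueError("dispersion undefined for an all-zero gene")
    var = x.var(ddof=1)
    return max(floor, (var - mean) / mean ** 2)


def pooled_dispersion(counts: ExpressionMatrix, norm: pd.DataFrame | None = None,
                      floor: float = DISPERSION_FLOOR) -> np.ndarray:
    """Per-gene NB dispersion pooled over every timepoint group.

    Raw MoM estimate (s² − x̄)/x̄² within each group with ≥ 2 replicates,
    df-weighted across groups, floored afterwards.  Pooling over the whole
    design rather than one pair of groups roughly doubles the degrees of
    freedom in a 4 × 3 timecourse, which keeps the normal-reference Wald
    test's type-I error close to nominal at triplicate group sizes.
    """
    if norm is None:
        norm = normalize_counts(counts)
    raw = np.zeros(norm.shape[0])
    df_total = 0
    for tp in counts.design["timepoint"].unique():
        cols = counts.samples_for_timepoint(tp)
        if len(cols) < 2:
            continue
        x = norm[cols].to_numpy()
        m = x.mean(axis=1)
        s2 = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(m > 0, (s2 - m) / m ** 2, 0.0)
        df = len(cols) - 1
        raw += df * r
        df_total += df
    if df_total == 0:
        raise ValueError("no timepoint group with >= 2 replicates")
    return np.maximum(floor, raw / df_total)


@dataclass
class ContrastResult:
    """Per-gene log2 fold-change, Wald p-value, and BH FDR for one
    treatment-vs-control contrast."""

    table: pd.DataFrame          # index gene; log2fc, p_value, fdr
    contrast: str                # e.g. "C0d_vs_L4d"
    dropped_genes: list[str]     # all-zero genes excluded before testing

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df.index.name = "gene"
        df.to_csv(path, sep="\t", float_format="%.10g")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_contrast(counts: ExpressionMatrix, control_timepoint: str,
                  treatment_timepoint: str,
                  pseudocount: float = PSEUDOCOUNT,
                  dispersion_floor: float = DISPERSION_FLOOR) -> ContrastResult:
    """NB Wald test of one treatment timepoint against the control.

    Per gene, on median-of-ratios-normalized counts:
    log2fc = log2((x̄_t + c)/(x̄_c + c)); the Wald SE follows from the delta
    method with NB variance (μ + α μ²)/n per group mean; two-sided p from
    N(0, 1).  The per-gene dispersion α is the df-weighted pool of the raw
    method-of-moments estimates over *every* timepoint group in the design
    (within-group centered, floored afterwards): the whole design informs
    one dispersion per gene, which every contrast then shares.
    """
    ctrl = counts.samples_for_timepoint(control_timepoint)
    trt = counts.samples_for_timepoint(treatment_timepoint)
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("both groups need at least 2 replicates")

    norm = normalize_counts(counts)
    nonzero = counts.values.sum(axis=1) > 0
    dropped = list(counts.values.index[~nonzero])
    if dropped:
        logger.info("dropping %d all-zero gene(s) before testing", len(dropped))
    xc = norm.loc[nonzero, ctrl].to_numpy()
    xt = norm.loc[nonzero, trt].to_numpy()
    nc, nt = xc.shape[1], xt.shape[1]

    mc, mt = xc.mean(axis=1), xt.mean(axis=1)
    log2fc = np.log2((mt + pseudocount) / (mc + pseudocount))

    alpha = pooled_dispersion(counts, norm=norm, floor=dispersion_floor)[
        nonzero.to_numpy()]

    var_mc = (mc + alpha * mc ** 2) / nc
    var_mt = (mt + alpha * mt ** 2) / nt
    ln2 = np.log(2.0)
    se = np.sqrt(var_mt / (mt + pseudocount) ** 2 +
                 var_mc / (mc + pseudocount) ** 2) / ln2

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    # zero-SE genes: identical means -> null; separated means -> certain
    degenerate = (se == 0) & (log2fc != 0)
    p[degenerate] = 0.0
    table = pd.DataFrame({"log2fc": log2fc, "p_value": p, "fdr": bh_adjust(p)},
                         index=counts.values.index[nonzero])
    label = f"{control_timepoint}_vs_{treatment_timepoint}"
    return ContrastResult(table, label, dropped)


# ----------------------------------------------------------------------
# screening and the CRG set
# ----------------------------------------------------------------------

def screen_degs(result: ContrastResult, fdr_max: float = 0.01,
                min_abs_log2fc: float = 1.0) -> pd.DataFrame:
    """Two-threshold DEG screen: fdr ≤ fdr_max and |log2fc| ≥ min_abs_log2fc
    (fold-change ≥ 2 ⟺ |log2fc| ≥ 1), both boundaries inclusive.

    Returns the passing genes with an up/down ``direction`` column.
    """
    if fdr_max <= 0 or min_abs_log2fc <= 0:
        raise ValueError("thresholds must be positive")
    t = result.table
    passing = t[(t["fdr"] <= fdr_max) & (t["log2fc"].abs() >= min_abs_log2fc)].copy()
    passing["direction"] = np.where(passing["log2fc"] >= 0, "up", "down")
    return passing


@dataclass
class CRGSet:
    """Genes surviving the DEG screen in every contrast."""

    genes: frozenset[str]
    provenance: tuple[str, ...]
    venn: dict[str, int]         # membership pattern ('101', ...) → region size

    def __len__(self) -> int:
        return len(self.genes)


def intersect_crgs(deg_sets: list[set[str]],
                   labels: list[str] | None = None) -> CRGSet:
    """Intersect per-contrast DEG sets and report every Venn region size.

    Region keys are membership patterns over the input order, e.g. '110'
    is genes in sets 1 and 2 but not 3; sizes are exclusive and sum to the
    union size.
    """
    if len(deg_sets) < 2:
        raise ValueError("need at least 2 DEG sets")
    sets = [set(s) for s in deg_sets]
    if labels is None:
        labels = [f"set{i + 1}" for i in range(len(sets))]
    venn: dict[str, int] = {}
    for pattern in product((1, 0), repeat=len(sets)):
        if not any(pattern):
            continue
        region = set.intersection(*[s for s, m in zip(sets, pattern) if m]) if any(
            pattern) else set()
        for s, m in zip(sets, pattern):
            if not m:
                region = region - s
        venn["".join(map(str, pattern))] = len(region)
    core = frozenset(set.intersection(*sets))
    return CRGSet(core, tuple(labels), venn)
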