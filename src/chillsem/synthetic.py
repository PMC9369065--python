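"""Synthetic expression data with known ground truth.

Two parallel generators make every downstream stage testable without any
sequencing data:

* a **latent-factor generator** producing continuous, log-scale indicator
  matrices under a reflective measurement model (each indicator gene is
  ``loading × latent + noise``) with a user-chosen directed-acyclic
  structural model among gene-block latents (hormone → transcription
  factor → antioxidant, in the default topology);
* a **negative-binomial count generator** producing a timepoints ×
  replicates count matrix in which a chosen fraction of genes carries a
  fold-change at the non-control timepoints, for differential-expression
  screening.

All latent variables are generated with population variance 1 so the
configured structural coefficients are directly the standardized path
coefficients a PLS path model estimates.  Endogenous residual variances
are solved from the implied covariance of the parents; a configuration
whose explained variance exceeds 1 is inadmissible and raises by default
(``variance_policy="error"``), or can be shrunk to the admissible boundary
(``variance_policy="rescale"``; the realized coefficients are then
reported as the truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix, default_design, read_design_tsv, read_expression_tsv

DEFAULT_TIMEPOINTS = ("0d", "4d", "8d", "12d")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    ``loadings`` maps block name → loading(s): a scalar shared by all of a
    block's indicators or a per-indicator list.  ``indicator_noise_sd`` of
    ``None`` chooses the noise per indicator as ``sqrt(1 − loading²)`` so
    every indicator has unit population variance.
    """

    block_spec: list[tuple[str, int]] = field(
        default_factory=lambda: [("ABA", 10), ("ICE1", 3), ("CBF", 3), ("bZIP", 3), ("AO", 10)])
    structural_edges: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("ABA", "ICE1", 0.5), ("ABA", "CBF", 0.5),
                                 ("ABA", "bZIP", 0.5), ("ICE1", "AO", 0.3),
                                 ("CBF", "AO", 0.3), ("bZIP", "AO", 0.3),
                                 ("ABA", "AO", 0.2)])
    loadings: dict | float = 0.85
    indicator_noise_sd: float | None = None
    n_samples: int = 12
    n_genes: int = 2000
    count_baseline_mean: float = 100.0
    count_dispersion: float = 0.05
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    replicates: int = 3
    seed: int = 0
    variance_policy: str = "error"

    def __post_init__(self) -> None:
        names = [b for b, _ in self.block_spec]
        if len(set(names)) != len(names):
            raise ValueError("duplicate block names")
        for src, tgt, beta in self.structural_edges:
            if abs(beta) > 1:
                raise ValueError(f"path coefficient {beta} outside [-1, 1]")
            if src not in names or tgt not in names:
                raise ValueError(f"edge {src}->{tgt} references unknown block")
        for lam in np.atleast_1d(np.concatenate(
                [np.atleast_1d(self.loading_for(b, k)) for b, k in self.block_spec] or [[0.0]])):
            if abs(lam) > 1:
                raise ValueError(f"loading {lam} outside [-1, 1]")
        if self.indicator_noise_sd is not None and self.indicator_noise_sd < 0:
            raise ValueError("indicator_noise_sd must be nonnegative")
        if self.count_dispersion < 0:
            raise ValueError("count_dispersion must be nonnegative")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.variance_policy not in ("error", "rescale"):
            raise ValueError("variance_policy must be 'error' or 'rescale'")

    def loading_for(self, block: str, n_ind: int) -> np.ndarray:
        if isinstance(self.loadings, dict):
            lam = self.loadings[block]
        else:
            lam = self.loadings
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        if lam.size == 1:
            lam = np.repeat(lam, n_ind)
        if lam.size != n_ind:
            raise ValueError(f"block {block}: {lam.size} loadings for {n_ind} indicators")
        return lam

    def indicator_ids(self) -> tuple[list[str], list[str]]:
        """Gene IDs for every indicator and their block labels, in block order."""
        genes, blocks = [], []
        for block, k in self.block_spec:
            for i in range(k):
                genes.append(f"{block}_{i + 1:02d}")
                blocks.append(block)
        return genes, blocks


@dataclass
class LatentModel:
    """Implied moments of the structural model: topological order, realized
    coefficients, residual SDs, and the latent covariance matrix."""

    order: list[str]
    parents: dict[str, list[str]]
    coefs: dict[str, np.ndarray]
    residual_sd: dict[str, float]
    covariance: pd.DataFrame

    def path_dict(self) -> dict[tuple[str, str], float]:
        out = {}
        for tgt, preds in self.parents.items():
            for p, c in zip(preds, self.coefs[tgt]):
                out[(p, tgt)] = float(c)
        return out


def build_latent_model(config: SimulationConfig) -> LatentModel:
    """Solve residual variances from the implied covariance so every latent
    has population variance 1."""
    names = [b for b, _ in config.block_spec]
    g = nx.DiGraph()
    g.add_nodes_from(names)
    g.add_weighted_edges_from(config.structural_edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("structural_edges must form a directed acyclic graph")
    # stable topological order: Kahn's algorithm breaking ties by block order
    order = list(nx.lexicographical_topological_sort(g, key=names.index))

    cov = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    parents: dict[str, list[str]] = {}
    coefs: dict[str, np.ndarray] = {}
    residual_sd: dict[str, float] = {}
    for node in order:
        preds = sorted(g.predecessors(node), key=names.index)
        if not preds:
            cov.loc[node, node] = 1.0
            residual_sd[node] = 1.0
            continue
        beta = np.array([g[p][node]["weight"] for p in preds], dtype=float)
        sigma_pp = cov.loc[preds, preds].to_numpy()
        explained = float(beta @ sigma_pp @ beta)
        if explained > 1.0 + 1e-12:
            if config.variance_policy == "error":
                raise ValueError(
                    f"latent {node!r}: explained variance {explained:.4g} > 1; "
                    "reduce path coefficients or use variance_policy='rescale'")
            beta = beta / np.sqrt(explained)
            explained = 1.0
        resid_var = max(0.0, 1.0 - explained)
        parents[node] = preds
        coefs[node] = beta
        residual_sd[node] = float(np.sqrt(resid_var))
        # cov(node, earlier) = sum_p beta_p cov(p, earlier)
        for other in order:
            cov.loc[node, other] = cov.loc[other, node] = float(
                beta @ cov.loc[preds, other].to_numpy())
        cov.loc[node, node] = 1.0
    return LatentModel(order, parents, coefs, residual_sd, cov)


def simulate_latents(config: SimulationConfig,
                     rng: np.random.Generator | None = None,
                     model: LatentModel | None = None) -> pd.DataFrame:
    """Draw samples × latents scores: exogenous latents i.i.d. N(0, 1),
    endogenous latents as the structural combination plus a residual whose
    variance brings the total to 1.  Deterministic given ``config.seed``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if model is None:
        model = build_latent_model(config)
    n = config.n_samples
    scores = pd.DataFrame(index=range(n), columns=model.order, dtype=float)
    for node in model.order:
        eps = rng.standard_normal(n) * model.residual_sd[node]
        if node in model.parents:
            base = scores[model.parents[node]].to_numpy() @ model.coefs[node]
        else:
            base = 0.0
        scores[node] = base + eps
    # restore configured block order for the caller
    names = [b for b, _ in config.block_spec]
    return scores[names]


def simulate_indicators(latents: pd.DataFrame, config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[ExpressionMatrix, pd.DataFrame, dict[str, float]]:
    """Reflective measurement model: indicator = loading × latent + noise.

    Returns the continuous (log-scale) expression matrix, the gene → block
    annotation table, and the per-gene true loadings.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(latents)
    genes, blocks = config.indicator_ids()
    true_loadings: dict[str, float] = {}
    cols = {}
    for block, k in config.block_spec:
        lam = config.loading_for(block, k)
        z = latents[block].to_numpy()
        for i in range(k):
            gene = f"{block}_{i + 1:02d}"
            if config.indicator_noise_sd is None:
                sd = float(np.sqrt(max(0.0, 1.0 - lam[i] ** 2)))
            else:
                sd = config.indicator_noise_sd
            cols[gene] = lam[i] * z + rng.standard_normal(n) * sd
            true_loadings[gene] = float(lam[i])
    sample_ids = _sample_ids(config, n)
    values = pd.DataFrame(cols, index=sample_ids).T
    values.index.name = "gene"
    design = default_design(sample_ids, list(config.timepoints), config.replicates)
    annotation = pd.DataFrame({"gene": genes, "block": blocks})
    return ExpressionMatrix(values, design, kind="log"), annotation, true_loadings


def simulate_counts(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[ExpressionMatrix, set[str]]:
    """NB count matrix over the timepoints × replicates design.

    Each gene's count is NB with mean ``baseline × 2^de_log2fc`` at the
    non-control timepoints if the gene was sampled as DE (probability
    ``de_fraction``), and ``baseline`` otherwise; variance = μ + α μ².
    """
    if len(config.timepoints) < 2:
        raise ValueError("need at least 2 timepoints")
    if config.replicates < 2:
        raise ValueError("need at least 2 replicates")
    if config.count_baseline_mean <= 0:
        raise ValueError("count_baseline_mean must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n_tp, reps = len(config.timepoints), config.replicates
    n_samp = n_tp * reps
    genes = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    de_mask = rng.random(config.n_genes) < config.de_fraction
    fold = 2.0 ** config.de_log2fc

    mu = np.full((config.n_genes, n_samp), float(config.count_baseline_mean))
    # non-control samples are all samples past the first timepoint's block
    mu[de_mask, reps:] *= fold
    alpha = config.count_dispersion
    if alpha == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / alpha
        counts = rng.negative_binomial(r, r / (r + mu))
    sample_ids = [f"{tp}_r{j + 1}" for tp in config.timepoints for j in range(reps)]
    values = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=sample_ids)
    design = default_design(sample_ids, list(config.timepoints), reps)
    de_genes = {g for g, m in zip(genes, de_mask) if m}
    return ExpressionMatrix(values, design, kind="counts"), de_genes


def _sample_ids(config: SimulationConfig, n: int) -> list[str]:
    if n == len(config.timepoints) * config.replicates:
        return [f"{tp}_r{j + 1}" for tp in config.timepoints
                for j in range(config.replicates)]
    width = len(str(n))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


@dataclass
class SyntheticDataset:
    """A simulated dataset plus the truth used to generate it."""

    expression: ExpressionMatrix          # continuous log-scale indicators
    counts: ExpressionMatrix              # NB counts
    annotation: pd.DataFrame              # gene, block (indicator genes)
    true_scores: pd.DataFrame             # samples × latents
    true_paths: dict[tuple[str, str], float]
    true_loadings: dict[str, float]
    de_genes: set[str]
    config: SimulationConfig

    def write(self, outdir) -> dict[str, Path]:
        """Write the TSV/YAML interface files; returns path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression.tsv",
            "counts": outdir / "counts.tsv",
            "design": outdir / "design.tsv",
            "expression_design": outdir / "expression_design.tsv",
            "annotation": outdir / "annotation.tsv",
            "truth": outdir / "truth.yaml",
        }
        self.expression.to_tsv(paths["expression"], paths["expression_design"])
        self.counts.to_tsv(paths["counts"], paths["design"])
        self.annotation.to_csv(paths["annotation"], sep="\t", index=False)
        truth = {
            "paths": [{"from": s, "to": t, "coefficient": c}
                      for (s, t), c in sorted(self.true_paths.items())],
            "loadings": {g: float(l) for g, l in sorted(self.true_loadings.items())},
            "de_genes": sorted(self.de_genes),
            "seed": int(self.config.seed),
        }
        with open(paths["truth"], "w") as fh:
            yaml.safe_dump(truth, fh, sort_keys=True)
        return paths


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run both generators under one seed and bundle the ground truth."""
    model = build_latent_model(config)
    rng = np.random.default_rng(config.seed)
    latents = simulate_latents(config, rng=rng, model=model)
    expression, annotation, true_loadings = simulate_indicators(latents, config, rng=rng)
    counts, de_genes = simulate_counts(config, rng=rng)
    return SyntheticDataset(
        expression=expression, counts=counts, annotation=annotation,
        true_scores=latents, true_paths=model.path_dict(),
        true_loadings=true_loadings, de_genes=de_genes, config=config)


def read_dataset(outdir) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, dict]:
    """Read back the files written by :meth:`SyntheticDataset.write`."""
    outdir = Path(outdir)
    expression = read_expression_tsv(outdir / "expression.tsv",
                                     outdir / "expression_design.tsv", kind="log")
    counts = read_expression_tsv(outdir / "counts.tsv", outdir / "design.tsv",
                                 kind="counts")
    annotation = pd.read_csv(outdir / "annotation.tsv", sep="\t")
    with open(outdir / "truth.yaml") as fh:
        truth = yaml.safe_load(fh)
    return expression, counts, annotation, truth
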