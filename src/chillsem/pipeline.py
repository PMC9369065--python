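"""End-to-end pipeline: simulate → screen → partition → PLS-SEM → qPCR.

``run_pipeline`` executes the five stages in order under a single seeded
configuration, writes every stage's tables under one run directory, and
finishes with a manifest (versions, seeds, input digests, per-stage record
counts).  Runs are idempotent: the same config and seed produce
byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .diffexpr import fpkm, intersect_crgs, screen_degs, test_contrast
from .expression import ExpressionMatrix, read_expression_tsv
from .genesets import assign_blocks, ora_hypergeometric, read_annotation_tsv, zscore_rows
from .plssem import PathModel, bootstrap, effects, fit_pls, to_dot, validate_model
from .synthetic import SimulationConfig, simulate_dataset
from .validation import concordance, ddct

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


class InputPaths(BaseModel):
    """Optional external inputs; anything omitted is simulated."""

    counts: Optional[Path] = None
    design: Optional[Path] = None
    annotation: Optional[Path] = None
    expression: Optional[Path] = None
    model: Optional[Path] = None


class RunConfig(BaseModel):
    """Validated pipeline configuration (YAML-loadable)."""

    seed: int
    outdir: Path = Path("chillsem_run")
    # synthetic data
    n_genes: int = Field(2000, ge=10)
    n_samples: int = Field(12, ge=3)
    timepoints: list[str] = ["0d", "4d", "8d", "12d"]
    replicates: int = Field(3, ge=2)
    count_baseline_mean: float = Field(100.0, gt=0)
    count_dispersion: float = Field(0.05, ge=0)
    de_fraction: float = Field(0.1, ge=0, le=1)
    de_log2fc: float = 2.0
    block_spec: list[tuple[str, int]] = [("ABA", 10), ("ICE1", 3), ("CBF", 3),
                                         ("bZIP", 3), ("AO", 10)]
    structural_edges: list[tuple[str, str, float]] = [
        ("ABA", "ICE1", 0.5), ("ABA", "CBF", 0.5), ("ABA", "bZIP", 0.5),
        ("ICE1", "AO", 0.3), ("CBF", "AO", 0.3), ("bZIP", "AO", 0.3),
        ("ABA", "AO", 0.2)]
    loadings: float = 0.85
    variance_policy: Literal["error", "rescale"] = "error"
    # screening
    control: str = "0d"
    treatments: list[str] = ["4d", "8d", "12d"]
    fdr_max: float = Field(0.01, gt=0)
    min_fold_change: float = Field(2.0, gt=1)
    # PLS-SEM
    scheme: Literal["path", "centroid", "factorial"] = "path"
    bootstrap_B: int = Field(5000, ge=2)
    sign_policy: Literal["individual", "construct", "none"] = "individual"
    # qPCR emulation
    n_qpcr_genes: int = Field(10, ge=3)
    qpcr_noise_sd: float = Field(0.25, ge=0)
    figures: bool = True
    inputs: InputPaths = InputPaths()

    @field_validator("treatments")
    @classmethod
    def _at_least_one_treatment(cls, v):
        if not v:
            raise ValueError("need at least one treatment timepoint")
        return v

    @property
    def min_abs_log2fc(self) -> float:
        return float(np.log2(self.min_fold_change))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = RunConfig(**raw)
    for name, p in cfg.inputs.model_dump().items():
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"configured input {name!r} not found: {p}")
    return cfg


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def label_count_genes(gene_ids: list[str], de_genes: set[str],
                      block_spec: list[tuple[str, int]],
                      rng: np.random.Generator) -> pd.DataFrame:
    """Assign block labels to count genes, drawing each block's members
    preferentially from the DE genes (so enrichment among screened genes
    is the expected outcome, as in the real study)."""
    de_pool = sorted(de_genes)
    other_pool = sorted(set(gene_ids) - de_genes)
    rng.shuffle(de_pool)
    rng.shuffle(other_pool)
    pool = de_pool + other_pool
    rows, cursor = [], 0
    for block, k in block_spec:
        for g in pool[cursor:cursor + k]:
            rows.append((g, block))
        cursor += k
    return pd.DataFrame(rows, columns=["gene", "block"])


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package": "chillsem", "version": __version__,
                      "seed": config.seed, "stages": []}
    written: list[Path] = []

    # ---- stage 1: simulate ------------------------------------------
    stage_dir = outdir / "simulate"
    try:
        sim_cfg = SimulationConfig(
            block_spec=[tuple(b) for b in config.block_spec],
            structural_edges=[tuple(e) for e in config.structural_edges],
            loadings=config.loadings, n_samples=config.n_samples,
            n_genes=config.n_genes, count_baseline_mean=config.count_baseline_mean,
            count_dispersion=config.count_dispersion,
            de_fraction=config.de_fraction, de_log2fc=config.de_log2fc,
            timepoints=tuple(config.timepoints), replicates=config.replicates,
            seed=config.seed, variance_policy=config.variance_policy)
        if config.inputs.counts is not None:
            counts = read_expression_tsv(config.inputs.counts,
                                         config.inputs.design, kind="counts")
            dataset = None
            de_genes: set[str] = set()
        else:
            dataset = simulate_dataset(sim_cfg)
            paths = dataset.write(stage_dir)
            written += list(paths.values())
            counts = dataset.counts
            de_genes = dataset.de_genes
        rng_aux = np.random.default_rng(sim_cfg.seed + 3)
        lengths = pd.Series(rng_aux.integers(500, 3000, size=len(counts.gene_ids)),
                            index=pd.Index(counts.gene_ids, name="gene"),
                            name="length_bp")
        stage_dir.mkdir(parents=True, exist_ok=True)
        lengths.to_csv(stage_dir / "gene_lengths.tsv", sep="\t")
        written.append(stage_dir / "gene_lengths.tsv")
        if config.inputs.annotation is not None:
            count_annotation = read_annotation_tsv(config.inputs.annotation)
        else:
            count_annotation = label_count_genes(
                counts.gene_ids, de_genes, [tuple(b) for b in config.block_spec],
                rng_aux)
        count_annotation.to_csv(stage_dir / "count_annotation.tsv", sep="\t",
                                index=False)
        written.append(stage_dir / "count_annotation.tsv")
        manifest["stages"].append({"name": "simulate", "n_genes": len(counts.gene_ids),
                                   "n_samples": counts.n_samples,
                                   "n_true_de": len(de_genes)})
    except (ValueError, FileNotFoundError, KeyError) as exc:
        raise StageError("simulate", "simulation_failed", str(exc)) from exc

    # ---- stage 2: differential expression ---------------------------
    stage_dir = outdir / "deg"
    stage_dir.mkdir(parents=True, exist_ok=True)
    try:
        deg_sets, labels, first_contrast = [], [], None
        for tp in config.treatments:
            res = test_contrast(counts, config.control, tp)
            res.to_tsv(stage_dir / f"contrast_{res.contrast}.tsv")
            written.append(stage_dir / f"contrast_{res.contrast}.tsv")
            degs = screen_degs(res, config.fdr_max, config.min_abs_log2fc)
            degs.index.name = "gene"
            degs.to_csv(stage_dir / f"degs_{res.contrast}.tsv", sep="\t",
                        float_format="%.10g")
            written.append(stage_dir / f"degs_{res.contrast}.tsv")
            deg_sets.append(set(degs.index))
            labels.append(res.contrast)
            if first_contrast is None:
                first_contrast = res
        crgs = intersect_crgs(deg_sets, labels)
        pd.Series(sorted(crgs.genes), name="gene").to_csv(
            stage_dir / "crgs.tsv", sep="\t", index=False)
        _write_json({"labels": list(crgs.provenance), "regions": crgs.venn,
                     "n_crgs": len(crgs)}, stage_dir / "venn.json")
        written += [stage_dir / "crgs.tsv", stage_dir / "venn.json"]
        manifest["stages"].append({"name": "deg", "contrasts": labels,
                                   "deg_counts": [len(s) for s in deg_sets],
                                   "n_crgs": len(crgs)})
    except ValueError as exc:
        raise StageError("deg", "contrast_failed", str(exc)) from exc

    # ---- stage 3: partition + enrichment + Z matrix ------------------
    stage_dir = outdir / "partition"
    stage_dir.mkdir(parents=True, exist_ok=True)
    try:
        partition = assign_blocks(crgs, count_annotation)
        _write_json({"blocks": partition.blocks,
                     "unassigned": partition.unassigned},
                    stage_dir / "partition.json")
        ora = ora_hypergeometric(set(crgs.genes), set(counts.gene_ids),
                                 count_annotation)
        ora.to_csv(stage_dir / "ora.tsv", sep="\t", index=False,
                   float_format="%.10g")
        fpkm_mat = fpkm(counts, lengths)
        block_genes = [g for genes in partition.blocks.values() for g in genes]
        zmat = zscore_rows(fpkm_mat.restrict_genes(sorted(set(block_genes)))
                           if block_genes else fpkm_mat)
        zmat.to_tsv(stage_dir / "zscore_blocks.tsv")
        written += [stage_dir / "partition.json", stage_dir / "ora.tsv",
                    stage_dir / "zscore_blocks.tsv"]
        manifest["stages"].append({
            "name": "partition",
            "block_sizes": {b: len(g) for b, g in partition.blocks.items()},
            "n_unassigned": len(partition.unassigned)})
    except ValueError as exc:
        raise StageError("partition", "partition_failed", str(exc)) from exc

    # ---- stage 4: PLS-SEM --------------------------------------------
    stage_dir = outdir / "plssem"
    stage_dir.mkdir(parents=True, exist_ok=True)
    try:
        if dataset is None and (config.inputs.model is None
                                or config.inputs.expression is None):
            raise StageError("plssem", "missing_input",
                             "external counts require an external model and "
                             "expression matrix for the PLS stage")
        if config.inputs.model is not None:
            model = PathModel.from_yaml(config.inputs.model)
        else:
            blocks: dict[str, list[str]] = {}
            for gene, block in dataset.annotation.itertuples(index=False):
                blocks.setdefault(block, []).append(gene)
            model = PathModel(
                blocks, [(s, t) for s, t, _ in config.structural_edges],
                config.scheme)
        model.to_yaml(stage_dir / "model.yaml")
        if config.inputs.expression is not None:
            expr = read_expression_tsv(config.inputs.expression, kind="log")
        else:
            expr = dataset.expression
        pls_input = zscore_rows(expr.restrict_genes(model.indicator_ids))
        fit = fit_pls(pls_input, model)
        report = validate_model(fit)
        result = {
            "converged": fit.converged, "n_iterations": fit.n_iterations,
            "outer_weights": {k: round(v, 10) for k, v in fit.outer_weights.items()},
            "loadings": {k: round(v, 10) for k, v in fit.loadings.items()},
            "path_coefficients": {f"{s}->{t}": round(c, 10)
                                  for (s, t), c in fit.path_coefficients.items()},
            "r_squared": {k: round(v, 10) for k, v in fit.r_squared.items()},
            "ave": {k: round(v, 10) for k, v in fit.ave.items()},
            "composite_reliability": {k: round(v, 10)
                                      for k, v in fit.composite_reliability.items()},
        }
        _write_json(result, stage_dir / "fit.json")
        effects(fit).to_csv(stage_dir / "effects.tsv", sep="\t", index=False,
                            float_format="%.10g")
        report.to_csv(stage_dir / "validity.tsv", sep="\t", float_format="%.10g")
        boot = bootstrap(pls_input, model, B=config.bootstrap_B,
                         sign_policy=config.sign_policy, seed=config.seed)
        boot.table.to_csv(stage_dir / "bootstrap.tsv", sep="\t", index=False,
                          float_format="%.10g")
        (stage_dir / "model.dot").write_text(to_dot(fit))
        written += [stage_dir / "model.yaml", stage_dir / "fit.json",
                    stage_dir / "effects.tsv", stage_dir / "validity.tsv",
                    stage_dir / "bootstrap.tsv", stage_dir / "model.dot"]
        manifest["stages"].append({
            "name": "plssem", "n_latents": len(model.latents),
            "n_edges": len(model.edges), "converged": fit.converged,
            "bootstrap_B": boot.B, "bootstrap_converged": boot.n_converged,
            "min_ave": min(fit.ave.values())})
    except (ValueError, KeyError, RuntimeError) as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError("plssem", "fit_failed", str(exc)) from exc

    # ---- stage 5: qPCR validation ------------------------------------
    stage_dir = outdir / "validate_qpcr"
    stage_dir.mkdir(parents=True, exist_ok=True)
    try:
        rnaseq_fc = first_contrast.table["log2fc"]
        degs_first = screen_degs(first_contrast, config.fdr_max,
                                 config.min_abs_log2fc)
        # a panel spanning the fold-change range: strongest responders plus
        # unchanged genes, as a qPCR confirmation panel would
        n_de = config.n_qpcr_genes // 2
        strong = list(rnaseq_fc.loc[sorted(degs_first.index)]
                      .abs().sort_values(ascending=False).index[:n_de])
        flat = list(rnaseq_fc.drop(strong).abs().sort_values()
                    .index[:config.n_qpcr_genes - len(strong)])
        chosen = sorted(strong + flat)
        rng_q = np.random.default_rng(config.seed + 4)
        qpcr_fc = rnaseq_fc.loc[chosen] + rng_q.normal(
            0.0, config.qpcr_noise_sd, size=len(chosen))
        # encode the fold-changes as a two-sample Ct table (reference Ct 20)
        cal, trt = "calibrator", "treated"
        rows = []
        for g in chosen:
            rows.append((g, cal, 25.0, 20.0))
            rows.append((g, trt, 25.0 - qpcr_fc.loc[g], 20.0))
        ct = pd.DataFrame(rows, columns=["gene", "sample", "ct_target",
                                         "ct_reference"])
        ct.to_csv(stage_dir / "ct.tsv", sep="\t", index=False,
                  float_format="%.10g")
        rel = ddct(ct, calibrator=cal)
        rel.to_csv(stage_dir / "relative_expression.tsv", sep="\t", index=False,
                   float_format="%.10g")
        qpcr_log2 = (rel[rel["sample"] == trt].set_index("gene")
                     ["relative_expression"].apply(np.log2))
        conc = concordance(rnaseq_fc.loc[chosen], qpcr_log2)
        _write_json(conc.to_dict(), stage_dir / "concordance.json")
        written += [stage_dir / "ct.tsv", stage_dir / "relative_expression.tsv",
                    stage_dir / "concordance.json"]
        manifest["stages"].append({"name": "validate_qpcr", "n_genes": len(chosen),
                                   "pearson_r": conc.r})
    except ValueError as exc:
        raise StageError("validate_qpcr", "qpcr_failed", str(exc)) from exc

    if config.figures:
        render_outputs(outdir, zmat, partition, fit)

    manifest["outputs"] = {str(p.relative_to(outdir)): _sha256(p)
                           for p in sorted(written)}
    _write_json(manifest, outdir / "manifest.json")
    return manifest


def render_outputs(outdir: Path, zmat: ExpressionMatrix, partition, fit) -> list[Path]:
    """Z-score heatmaps per block and nothing else binary; the DOT diagram
    and all tables are written by the stages themselves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = Path(outdir) / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    made = []
    for block, genes in partition.blocks.items():
        genes = [g for g in genes if g in zmat.values.index]
        if not genes:
            logger.info("block %s has no genes in the Z matrix; heatmap skipped",
                        block)
            continue
        sub = zmat.values.loc[genes]
        fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(genes))))
        im = ax.imshow(sub.to_numpy(), aspect="auto", cmap="RdBu_r",
                       vmin=-2.5, vmax=2.5)
        ax.set_yticks(range(len(genes)), genes, fontsize=6)
        ax.set_xticks(range(sub.shape[1]), sub.columns, rotation=90, fontsize=6)
        ax.set_title(f"{block} (row Z-score)")
        fig.colorbar(im, ax=ax, shrink=0.6)
        out = figdir / f"heatmap_{block}.png"
        fig.savefig(out, dpi=120, bbox_inches="tight")
        plt.close(fig)
        made.append(out)
    return made
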