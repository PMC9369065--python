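"""Partial Least Squares path modeling (PLS-SEM) for gene-block networks.

This module is a from-scratch implementation of the Lohmöller PLS
algorithm for path models with reflective (Mode A) measurement, as used to
relate hormone-signaling, transcription-factor, and antioxidant gene
blocks: each block of indicator genes measures one latent variable, and
the latents are connected by a directed acyclic structural model
(hormone → {ICE1, CBF, bZIP} → antioxidant plus a direct
hormone → antioxidant edge in the default topology).

Estimation alternates between an *outer* step, where each latent score is
the standardized weighted sum of its indicators, and an *inner* step,
where each latent's proxy is a weighted sum of its structural neighbors.
Three inner weighting schemes are supported:

``path`` (default)
    weight of a predecessor = its multiple-OLS coefficient when the
    latent is regressed on all its predecessors; weight of a successor =
    its score correlation.
``centroid``
    sign of the score correlation for every neighbor.
``factorial``
    the score correlation for every neighbor.

Mode A updates each outer weight to the correlation between the indicator
and its latent's inner proxy.  After convergence, loadings are
indicator–score correlations, path coefficients are per-endogenous-latent
standardized OLS coefficients on the predecessor scores, and direct,
indirect (sum over all multi-edge directed paths of the product of edge
coefficients), and total effects are decomposed exactly over the DAG.

Inference is by bootstrap over samples with the *individual sign changes*
convention: each resampled outer weight and loading is aligned to the
sign of the original estimate individually, and each construct is
re-oriented by the majority sign agreement of its loadings before the
path coefficients are aggregated.

All quantities are scale-free: indicator columns are standardized
internally, so any per-gene location/scale transform of the input (e.g.
row Z-scored FPKM) leaves the estimates unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .expression import ExpressionMatrix

SCHEMES = ("path", "centroid", "factorial")


class NonConvergenceWarning(UserWarning):
    pass


class LowSampleWarning(UserWarning):
    pass


# ----------------------------------------------------------------------
# model specification
# ----------------------------------------------------------------------

@dataclass
class PathModel:
    """Latent-variable blocks and directed structural edges.

    ``latents`` maps latent name → ordered list of indicator gene IDs
    (reflective mode throughout); ``edges`` is a list of (source, target)
    latent pairs forming a DAG.
    """

    latents: dict[str, list[str]]
    edges: list[tuple[str, str]]
    scheme: str = "path"

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        seen: set[str] = set()
        for name, inds in self.latents.items():
            if not inds:
                raise ValueError(f"latent {name!r} has no indicators")
            overlap = seen & set(inds)
            if overlap:
                raise ValueError(f"indicator(s) shared between latents: {sorted(overlap)}")
            seen.update(inds)
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("structural edges must form a DAG")
        for s, t in self.edges:
            if s not in self.latents or t not in self.latents:
                raise ValueError(f"edge {s}->{t} references unknown latent")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.latents)
        g.add_edges_from(self.edges)
        return g

    @property
    def latent_names(self) -> list[str]:
        return list(self.latents)

    @property
    def indicator_ids(self) -> list[str]:
        return [i for inds in self.latents.values() for i in inds]

    @classmethod
    def from_yaml(cls, path) -> "PathModel":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        latents = {lv["name"]: list(lv["indicators"]) for lv in spec["latents"]}
        edges = [(e["from"], e["to"]) for e in spec["edges"]]
        return cls(latents, edges, spec.get("scheme", "path"))

    def to_yaml(self, path) -> None:
        spec = {
            "latents": [{"name": n, "indicators": list(i), "mode": "reflective"}
                        for n, i in self.latents.items()],
            "edges": [{"from": s, "to": t} for s, t in self.edges],
            "scheme": self.scheme,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(spec, fh, sort_keys=False)


def hormone_mediation_model(hormone: str, hormone_genes: list[str],
                            tf_blocks: dict[str, list[str]],
                            ao_genes: list[str], scheme: str = "path") -> PathModel:
    """The default mediation topology: hormone → each TF family → AO, plus
    the direct hormone → AO edge."""
    latents = {hormone: list(hormone_genes)}
    latents.update({tf: list(g) for tf, g in tf_blocks.items()})
    latents["AO"] = list(ao_genes)
    edges = [(hormone, tf) for tf in tf_blocks]
    edges += [(tf, "AO") for tf in tf_blocks]
    edges.append((hormone, "AO"))
    return PathModel(latents, edges, scheme)


# ----------------------------------------------------------------------
# core estimation
# ----------------------------------------------------------------------

def _standardize(mat: np.ndarray) -> np.ndarray:
    """Column standardization with population (n) denominator."""
    sd = mat.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant indicator column")
    return (mat - mat.mean(axis=0)) / sd


@dataclass
class _Structure:
    """Pre-resolved index structure of a PathModel, for fast refits."""

    latent_names: list[str]
    blocks: list[np.ndarray]            # per latent: indicator column indices
    preds: list[np.ndarray]             # per latent: predecessor latent indices
    succs: list[np.ndarray]
    edge_index: list[tuple[int, int]]   # model.edges as latent indices
    block_of: np.ndarray                # per indicator: its latent index


def _resolve(model: PathModel, columns: list[str]) -> _Structure:
    col_pos = {c: i for i, c in enumerate(columns)}
    names = model.latent_names
    lat_pos = {n: i for i, n in enumerate(names)}
    blocks, block_of = [], np.empty(len(columns), dtype=int)
    for j, name in enumerate(names):
        idx = np.array([col_pos[i] for i in model.latents[name]], dtype=int)
        blocks.append(idx)
        block_of[idx] = j
    preds = [np.array(sorted(lat_pos[s] for s, t in model.edges if t == n), dtype=int)
             for n in names]
    succs = [np.array(sorted(lat_pos[t] for s, t in model.edges if s == n), dtype=int)
             for n in names]
    edge_index = [(lat_pos[s], lat_pos[t]) for s, t in model.edges]
    return _Structure(names, blocks, preds, succs, edge_index, block_of)


def _fit_core(raw: np.ndarray, st: _Structure, scheme: str,
              tol: float, max_iter: int):
    """Lohmöller iteration on a samples × indicators matrix.

    Returns (weights, loadings, scores, path coefficients per edge,
    R² per latent, n_iterations, converged).
    """
    n, p = raw.shape
    X = _standardize(raw)
    L = len(st.blocks)

    w = np.ones(p)
    for idx in st.blocks:                       # unit-norm per block
        w[idx] /= np.linalg.norm(w[idx])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # outer step: standardized weighted sums
        Y = np.empty((n, L))
        for j, idx in enumerate(st.blocks):
            y = X[:, idx] @ w[idx]
            Y[:, j] = (y - y.mean()) / y.std()
        R = (Y.T @ Y) / n                       # score correlations
        # inner step
        E = np.zeros((L, L))
        for j in range(L):
            nb = np.concatenate([st.preds[j], st.succs[j]])
            if nb.size == 0:
                continue
            if scheme == "centroid":
                E[j, nb] = np.sign(R[j, nb])
            elif scheme == "factorial":
                E[j, nb] = R[j, nb]
            else:                               # path weighting scheme
                pr = st.preds[j]
                if pr.size:
                    E[j, pr] = np.linalg.solve(R[np.ix_(pr, pr)], R[pr, j])
                E[j, st.succs[j]] = R[j, st.succs[j]]
        Z = Y @ E.T
        sd = Z.std(axis=0)
        keep = sd > 0
        Z[:, keep] = (Z[:, keep] - Z[:, keep].mean(axis=0)) / sd[keep]
        Z[:, ~keep] = Y[:, ~keep]               # isolated latent: keep own score
        # outer update, Mode A: weight = corr(indicator, inner proxy)
        w_new = np.empty(p)
        for j, idx in enumerate(st.blocks):
            w_new[idx] = X[:, idx].T @ Z[:, j] / n
            nrm = np.linalg.norm(w_new[idx])
            if nrm == 0:
                w_new[idx] = w[idx]
            else:
                w_new[idx] /= nrm
        delta = np.max(np.abs(w_new - w))
        w = w_new
        if delta < tol:
            converged = True
            break

    # final scores and loadings
    Y = np.empty((n, L))
    for j, idx in enumerate(st.blocks):
        y = X[:, idx] @ w[idx]
        Y[:, j] = (y - y.mean()) / y.std()
    loadings = np.empty(p)
    for j, idx in enumerate(st.blocks):
        loadings[idx] = X[:, idx].T @ Y[:, j] / n
    # sign orientation: flip each latent so its loading sum is positive
    for j, idx in enumerate(st.blocks):
        if loadings[idx].sum() < 0:
            Y[:, j] *= -1
            w[idx] *= -1
            loadings[idx] *= -1

    R = (Y.T @ Y) / n
    paths = np.zeros(len(st.edge_index))
    r2 = np.full(L, np.nan)
    for j in range(L):
        pr = st.preds[j]
        if pr.size == 0:
            continue
        beta = np.linalg.solve(R[np.ix_(pr, pr)], R[pr, j])
        r2[j] = float(beta @ R[pr, j])
        for e, (s, t) in enumerate(st.edge_index):
            if t == j:
                paths[e] = beta[list(pr).index(s)]
    return w, loadings, Y, paths, r2, n_iter, converged


@dataclass
class PLSFit:
    """Fitted measurement and structural model."""

    model: PathModel
    outer_weights: pd.Series
    loadings: pd.Series
    scores: pd.DataFrame                       # samples × latents, unit variance
    path_coefficients: dict[tuple[str, str], float]
    r_squared: dict[str, float]                # endogenous latents only
    n_iterations: int
    converged: bool

    @property
    def ave(self) -> dict[str, float]:
        return {name: ave(self, name) for name in self.model.latent_names}

    @property
    def composite_reliability(self) -> dict[str, float]:
        return {name: composite_reliability(self, name)
                for name in self.model.latent_names}


def fit_pls(data: ExpressionMatrix | pd.DataFrame, model: PathModel,
            tol: float = 1e-7, max_iter: int = 300) -> PLSFit:
    """Fit the PLS path model.

    ``data`` is a genes × samples :class:`ExpressionMatrix` (restricted or
    restrictable to the model's indicators) or a samples × indicators
    DataFrame.  Raises on constant indicator columns and when the sample
    size cannot support the largest structural regression; warns (but
    proceeds — PLS needs only correlations) when n is below the indicator
    count.
    """
    if isinstance(data, ExpressionMatrix):
        frame = data.restrict_genes(model.indicator_ids).values.T
    else:
        missing = [i for i in model.indicator_ids if i not in data.columns]
        if missing:
            raise KeyError(f"indicator(s) missing from data: {missing[:5]}")
        frame = data[model.indicator_ids]
    raw = frame.to_numpy(dtype=float)
    n = raw.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    st = _resolve(model, list(frame.columns))
    max_preds = max((len(p) for p in st.preds), default=0)
    if n < max_preds + 1:
        raise ValueError(f"n={n} samples cannot support a latent with "
                         f"{max_preds} predecessors")
    if n < raw.shape[1]:
        warnings.warn(
            f"n={n} samples for {raw.shape[1]} indicators: PLS estimates "
            "remain computable but are low-powered and unstable",
            LowSampleWarning, stacklevel=2)

    w, lam, Y, paths, r2, n_iter, converged = _fit_core(
        raw, st, model.scheme, tol, max_iter)
    if not converged:
        warnings.warn(f"PLS did not converge in {max_iter} iterations; "
                      "returning last iterate", NonConvergenceWarning, stacklevel=2)
    names = st.latent_names
    return PLSFit(
        model=model,
        outer_weights=pd.Series(w, index=model.indicator_ids, name="weight"),
        loadings=pd.Series(lam, index=model.indicator_ids, name="loading"),
        scores=pd.DataFrame(Y, index=frame.index, columns=names),
        path_coefficients={model.edges[e]: float(paths[e])
                           for e in range(len(model.edges))},
        r_squared={names[j]: float(r2[j]) for j in range(len(names))
                   if not np.isnan(r2[j])},
        n_iterations=n_iter,
        converged=converged,
    )


# ----------------------------------------------------------------------
# reliability / validity
# ----------------------------------------------------------------------

def ave(fit: PLSFit, latent: str) -> float:
    """Average variance extracted: mean of squared loadings of the latent's
    indicators (convergent validity; ≥ 0.5 is the conventional bar)."""
    lam = fit.loadings[fit.model.latents[latent]].to_numpy()
    return float(np.mean(lam ** 2))


def composite_reliability(fit: PLSFit, latent: str) -> float:
    """Composite reliability (Σλ)² / ((Σλ)² + Σ(1 − λ²))."""
    lam = fit.loadings[fit.model.latents[latent]].to_numpy()
    num = lam.sum() ** 2
    denom = num + np.sum(1.0 - lam ** 2)
    return float(num / denom) if denom > 0 else 0.0


def validate_model(fit: PLSFit, ave_min: float = 0.5) -> pd.DataFrame:
    """Per-latent reliability report; a latent passes when AVE ≥ ave_min
    (inclusive)."""
    rows = []
    for name in fit.model.latent_names:
        a = ave(fit, name)
        rows.append({
            "latent": name, "ave": a, "composite_reliability":
            composite_reliability(fit, name), "n_indicators":
            len(fit.model.latents[name]), "passes": bool(a >= ave_min),
        })
    return pd.DataFrame(rows).set_index("latent")


# ----------------------------------------------------------------------
# effect decomposition
# ----------------------------------------------------------------------

def effects(fit: PLSFit, model: PathModel | None = None) -> pd.DataFrame:
    """Direct / indirect / total effects for every ordered latent pair.

    direct = the edge coefficient (0 without an edge); indirect = the sum
    over all directed paths of length ≥ 2 of the product of constituent
    coefficients; total = direct + indirect.  Exact on the DAG via matrix
    powers of the coefficient matrix.
    """
    model = model or fit.model
    names = model.latent_names
    L = len(names)
    pos = {n: i for i, n in enumerate(names)}
    B = np.zeros((L, L))
    for (s, t), c in fit.path_coefficients.items():
        B[pos[s], pos[t]] = c
    total = np.zeros_like(B)
    power = B.copy()
    for _ in range(L - 1):
        total += power
        power = power @ B
    indirect = total - B
    rows = []
    for i in range(L):
        for j in range(L):
            if i == j:
                continue
            rows.append({"source": names[i], "target": names[j],
                         "direct": float(B[i, j]),
                         "indirect": float(indirect[i, j]),
                         "total": float(total[i, j])})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# bootstrap inference
# ----------------------------------------------------------------------

@dataclass
class BootstrapSummary:
    """Bootstrap SEs, t statistics (normal reference), and percentile CIs
    for outer weights, loadings, and path coefficients."""

    table: pd.DataFrame
    B: int
    n_converged: int
    n_dropped: int
    sign_policy: str
    seed: int | None


def bootstrap(data: ExpressionMatrix | pd.DataFrame, model: PathModel,
              B: int = 5000, sign_policy: str = "individual",
              seed: int | None = None, tol: float = 1e-7,
              max_iter: int = 300, ci_level: float = 0.95) -> BootstrapSummary:
    """Bootstrap over samples with replacement, refitting each resample.

    ``sign_policy``:

    * ``individual`` — each resampled outer weight and loading is flipped
      individually to the sign of the original estimate; each construct is
      re-oriented by the majority sign agreement of its loadings, and the
      path coefficients inherit the product of the two constructs'
      orientations;
    * ``construct`` — whole constructs are flipped by the loading-majority
      rule only;
    * ``none`` — raw resampled estimates.

    Non-convergent resamples are dropped and counted.  SE is the sd of the
    aligned estimates, t = original / SE with two-sided normal p, and CIs
    are percentile intervals of the aligned estimates.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    if sign_policy not in ("individual", "construct", "none"):
        raise ValueError("sign_policy must be individual, construct, or none")
    original = fit_pls(data, model, tol=tol, max_iter=max_iter)

    if isinstance(data, ExpressionMatrix):
        frame = data.restrict_genes(model.indicator_ids).values.T
    else:
        frame = data[model.indicator_ids]
    raw = frame.to_numpy(dtype=float)
    n = raw.shape[0]
    st = _resolve(model, list(frame.columns))
    L = len(st.latent_names)
    p = raw.shape[1]
    n_edges = len(st.edge_index)

    w0 = original.outer_weights.to_numpy()
    l0 = original.loadings.to_numpy()
    p0 = np.array([original.path_coefficients[e] for e in model.edges])

    rng = np.random.default_rng(seed)
    idx_all = rng.integers(0, n, size=(B, n))
    W = np.empty((B, p))
    Lm = np.empty((B, p))
    P = np.empty((B, n_edges))
    kept = np.zeros(B, dtype=bool)
    for b in range(B):
        sub = raw[idx_all[b]]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                wb, lb, _, pb, _, _, conv = _fit_core(
                    sub, st, model.scheme, tol, max_iter)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not conv:
            continue
        if sign_policy != "none":
            # construct orientation: majority sign agreement of the block's
            # loadings with the original estimate
            flip = np.ones(L)
            for j, bidx in enumerate(st.blocks):
                agree = np.sum(np.sign(lb[bidx]) == np.sign(l0[bidx]))
                if agree < len(bidx) - agree:
                    flip[j] = -1.0
            for e, (s, t) in enumerate(st.edge_index):
                pb[e] *= flip[s] * flip[t]
            if sign_policy == "construct":
                for j, bidx in enumerate(st.blocks):
                    wb[bidx] *= flip[j]
                    lb[bidx] *= flip[j]
            else:  # individual: per-parameter alignment
                wb = np.where(np.sign(w0) * wb < 0, -wb, wb)
                lb = np.where(np.sign(l0) * lb < 0, -lb, lb)
        W[b], Lm[b], P[b] = wb, lb, pb
        kept[b] = True
    n_conv = int(kept.sum())
    if n_conv < 2:
        raise RuntimeError("fewer than 2 bootstrap resamples converged")

    lo = 100 * (1 - ci_level) / 2
    rows = []
    block_name = [st.latent_names[j] for j in st.block_of]
    for kind, orig, boot, names, latents in (
            ("weight", w0, W[kept], model.indicator_ids, block_name),
            ("loading", l0, Lm[kept], model.indicator_ids, block_name),
            ("path", p0, P[kept], [f"{s}->{t}" for s, t in model.edges],
             [None] * n_edges)):
        se = boot.std(axis=0, ddof=1)
        mean = boot.mean(axis=0)
        ci_lo = np.percentile(boot, lo, axis=0)
        ci_hi = np.percentile(boot, 100 - lo, axis=0)
        for k, name in enumerate(names):
            if se[k] > 0:
                t_stat = orig[k] / se[k]
            else:
                t_stat = 0.0 if orig[k] == 0 else np.inf * np.sign(orig[k])
            rows.append({
                "kind": kind, "name": name, "latent": latents[k],
                "original": float(orig[k]), "boot_mean": float(mean[k]),
                "se": float(se[k]), "t": float(t_stat),
                "p_value": float(2 * stats.norm.sf(abs(t_stat))),
                "ci_low": float(ci_lo[k]), "ci_high": float(ci_hi[k]),
            })
    table = pd.DataFrame(rows)
    return BootstrapSummary(table, B, n_conv, B - n_conv, sign_policy, seed)


# ----------------------------------------------------------------------
# export
# ----------------------------------------------------------------------

def to_dot(fit: PLSFit, name: str = "pls_model") -> str:
    """Graphviz DOT text of the fitted structural model: edge width
    proportional to |path coefficient|, red for positive and blue for
    negative effects."""
    lines = [f"digraph {name} {{", "  rankdir=LR;",
             "  node [shape=ellipse, style=filled, fillcolor=lightgrey];"]
    for latent in fit.model.latent_names:
        r2 = fit.r_squared.get(latent)
        label = latent if r2 is None else f"{latent}\\nR2={r2:.3f}"
        lines.append(f'  "{latent}" [label="{label}"];')
    for (s, t), c in fit.path_coefficients.items():
        color = "red" if c >= 0 else "blue"
        width = 1.0 + 4.0 * abs(c)
        lines.append(f'  "{s}" -> "{t}" [label="{c:.3f}", color={color}, '
                     f"penwidth={width:.2f}];")
    lines.append("}")
    return "\n".join(lines) + "\n"
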