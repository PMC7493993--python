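"""Weighted co-expression network analysis over expression profiles.

From-scratch implementation of the standard weighted-network workflow for a
transcription-factor expression matrix: soft-threshold selection by
scale-free topology fit, correlation-power adjacency, topological overlap
matrix (TOM), average-linkage module detection on 1-TOM with a static tree
cut, module eigengenes (first principal component, sign-anchored) and
eigengene-based connectivity (kME), module-trait Pearson statistics, and
hub-gene calling with the kME >= 0.99 and edge weight >= 0.5 rule.

Expression matrices are genes x samples DataFrames; "edge weight" means
adjacency throughout (the regulatory-network reading of the hub criterion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

#: Standard module color sequence, assigned by decreasing module size.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
]
GREY = "grey"


@dataclass
class NetworkConfig:
    min_fpkm: float = 1.0  # TF pre-filter on mean FPKM
    min_kme: float = 0.7  # post-assignment membership filter
    power_candidates: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)
    scale_free_r2_target: float = 0.8
    network_type: str = "unsigned"
    tree_cut_height: float = 0.9
    min_module_size: int = 5
    kme_min_hub: float = 0.99
    weight_min_hub: float = 0.5
    power: Optional[int] = None  # fixed soft power; None = pick automatically


@dataclass
class ModuleResult:
    modules: pd.Series  # gene -> color (grey = unassigned)
    eigengenes: pd.DataFrame  # module x sample
    kme: pd.DataFrame  # gene x module
    module_trait: pd.DataFrame  # long: module, trait, r, r2, p, significant
    hub_genes: dict[str, list[str]] = field(default_factory=dict)
    power: int = 0


def prefilter_genes(
    fpkm: pd.DataFrame,
    tf_table: Optional[pd.DataFrame] = None,
    min_fpkm: float = 1.0,
) -> pd.DataFrame:
    """Keep (optionally TF-annotated) genes with mean FPKM >= min_fpkm."""
    keep = fpkm.mean(axis=1) >= min_fpkm
    sub = fpkm[keep]
    if tf_table is not None:
        sub = sub.loc[sub.index.intersection(tf_table["gene"])]
    return sub


def _adjacency_matrix(expr: np.ndarray, power: float, network_type: str) -> np.ndarray:
    cor = np.corrcoef(expr)
    cor = np.clip(cor, -1.0, 1.0)
    if network_type == "unsigned":
        a = np.abs(cor) ** power
    elif network_type == "signed":
        a = ((1.0 + cor) / 2.0) ** power
    else:
        raise ValueError(f"unknown network type: {network_type}")
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression.

    Connectivities are binned, per-bin frequency regressed on per-bin mean
    connectivity in log10 space; the fit is reported as R^2 when the slope is
    negative (scale-free-like) and 0 otherwise.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() * (1 + 1e-9), n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(k[sel].mean())
        ys.append(sel.mean())
    if len(xs) < 3:
        return 0.0
    lx, ly = np.log10(xs), np.log10(ys)
    slope, _, r, _, _ = stats.linregress(lx, ly)
    return float(r**2) if slope < 0 else 0.0


def pick_soft_power(
    expression: pd.DataFrame,
    power_candidates: Sequence[int] = NetworkConfig.power_candidates,
    scale_free_r2_target: float = 0.8,
    network_type: str = "unsigned",
) -> int:
    """Smallest candidate power with scale-free fit R^2 >= target.

    Falls back to the power of maximal R^2 (with a warning) when no
    candidate reaches the target.
    """
    if expression.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    expr = expression.to_numpy(dtype=float)
    expr = expr[expr.std(axis=1) > 0]
    best_power, best_r2 = int(power_candidates[0]), -1.0
    for p in power_candidates:
        a = _adjacency_matrix(expr, p, network_type)
        r2 = scale_free_fit(a.sum(axis=1))
        if r2 >= scale_free_r2_target:
            return int(p)
        if r2 > best_r2:
            best_power, best_r2 = int(p), r2
    warnings.warn(
        f"no candidate power reached scale-free R^2 {scale_free_r2_target}; "
        f"using power {best_power} (R^2 {best_r2:.3f})"
    )
    return best_power


def build_network(
    expression: pd.DataFrame, power: float, network_type: str = "unsigned"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjacency and topological overlap matrices.

    a_ij = |cor|^power (unsigned) or ((1+cor)/2)^power (signed);
    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with a
    unit diagonal.  Zero-variance genes are excluded with a warning.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    sd = expression.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"excluding {(sd == 0).sum()} constant gene(s)")
        expression = expression[sd > 0]
    genes = expression.index
    a = _adjacency_matrix(expression.to_numpy(dtype=float), power, network_type)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    adj = pd.DataFrame(a, index=genes, columns=genes)
    return adj, pd.DataFrame(tom, index=genes, columns=genes)


def detect_modules(
    tom: pd.DataFrame,
    tree_cut_height: float = 0.9,
    min_module_size: int = 5,
) -> pd.Series:
    """Average-linkage clustering of 1-TOM with a static tree cut.

    Clusters below ``min_module_size`` fall into grey; surviving clusters are
    colored in decreasing size order from the standard color sequence.
    """
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0
    link = average(squareform(diss, checks=False))
    labels = fcluster(link, t=tree_cut_height, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    colors = {}
    next_color = 0
    for lab in sizes.index:  # value_counts sorts by size descending
        if sizes[lab] >= min_module_size and next_color < len(MODULE_COLORS):
            colors[lab] = MODULE_COLORS[next_color]
            next_color += 1
        else:
            colors[lab] = GREY
    return pd.Series([colors[l] for l in labels], index=tom.index, name="module")


def _standardize(expr: np.ndarray) -> np.ndarray:
    mu = expr.mean(axis=1, keepdims=True)
    sd = expr.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (expr - mu) / sd


def module_eigengene_kme(
    expression: pd.DataFrame,
    modules: pd.Series,
    min_kme: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Module eigengenes, gene kME matrix, and the kME-filtered assignment.

    The eigengene is the first principal component of the standardized
    within-module expression (unit-norm sample scores), sign-anchored so the
    average gene-eigengene correlation is non-negative.  Genes whose
    own-module kME falls below ``min_kme`` are dropped to grey and the
    eigengenes recomputed once.  Returns (eigengenes, kme, modules).
    """
    modules = modules.reindex(expression.index)

    def eigengene_of(genes: pd.Index) -> np.ndarray:
        x = _standardize(expression.loc[genes].to_numpy(dtype=float))
        if x.shape[0] == 1:
            v = x[0]
            return v / np.linalg.norm(v)
        # first left-singular vector of samples x genes
        u, _, _ = np.linalg.svd(x.T, full_matrices=False)
        me = u[:, 0]
        cors = np.array([np.corrcoef(row, me)[0, 1] for row in x])
        if cors.mean() < 0:
            me = -me
        return me

    def compute(mods: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
        names = sorted(c for c in mods.unique() if c != GREY)
        if not names:
            raise ValueError("no non-grey module")
        mes = pd.DataFrame(
            {m: eigengene_of(mods.index[mods == m]) for m in names},
            index=expression.columns,
        ).T
        x = _standardize(expression.to_numpy(dtype=float))
        kme = pd.DataFrame(
            np.corrcoef(x, mes.to_numpy())[: x.shape[0], x.shape[0]:],
            index=expression.index,
            columns=names,
        )
        return mes, kme

    mes, kme = compute(modules)
    own = pd.Series(
        [kme.at[g, m] if m != GREY else np.nan for g, m in modules.items()],
        index=modules.index,
    )
    drop = (own < min_kme) & (modules != GREY)
    if drop.any():
        modules = modules.mask(drop, GREY)
        if (modules != GREY).any():
            mes, kme = compute(modules)
    return mes, kme, modules


def module_trait_stats(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    r2_threshold: float = 0.8,
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Pearson eigengene-trait correlations with t-distribution p-values.

    Returns a long DataFrame (module, trait, r, r2, p, significant);
    significance requires r^2 > r2_threshold and p < p_threshold.  Constant
    traits give missing statistics.
    """
    n = eigengenes.shape[1]
    rows = []
    for m in eigengenes.index:
        me = eigengenes.loc[m].to_numpy(dtype=float)
        for trait in traits.columns:
            tv = traits[trait].to_numpy(dtype=float)
            if np.std(tv) == 0 or np.std(me) == 0:
                rows.append((m, trait, np.nan, np.nan, np.nan, False))
                continue
            r = float(np.corrcoef(me, tv)[0, 1])
            df = n - 2
            denom = max(1.0 - r * r, np.finfo(float).tiny)
            t = r * np.sqrt(df / denom)
            p = float(2.0 * stats.t.sf(abs(t), df))
            rows.append((m, trait, r, r * r, p, (r * r > r2_threshold) and (p < p_threshold)))
    return pd.DataFrame(rows, columns=["module", "trait", "r", "r2", "p", "significant"])


def find_hub_genes(
    kme: pd.DataFrame,
    adjacency: pd.DataFrame,
    modules: pd.Series,
    kme_min: float = 0.99,
    weight_min: float = 0.5,
) -> dict[str, list[str]]:
    """Hubs: own-module kME >= kme_min and some within-module edge >= weight_min."""
    hubs: dict[str, list[str]] = {}
    for m in kme.columns:
        members = [g for g in modules.index if modules[g] == m and g in adjacency.index]
        found = []
        for g in members:
            if kme.at[g, m] < kme_min:
                continue
            others = [o for o in members if o != g]
            if others and adjacency.loc[g, others].max() >= weight_min:
                found.append(g)
        if found:
            hubs[m] = sorted(found)
    return hubs


def hub_edge_list(
    adjacency: pd.DataFrame, hubs: Sequence[str], weight_min: float = 0.5
) -> pd.DataFrame:
    """Weighted edges among hub genes with weight >= weight_min."""
    rows = []
    hubs = list(hubs)
    for i, g in enumerate(hubs):
        for h in hubs[i + 1 :]:
            w = float(adjacency.at[g, h])
            if w >= weight_min:
                rows.append((g, h, w))
    return pd.DataFrame(rows, columns=["gene1", "gene2", "weight"])


def run_wgcna(
    fpkm: pd.DataFrame,
    traits: pd.DataFrame,
    config: NetworkConfig = NetworkConfig(),
    tf_table: Optional[pd.DataFrame] = None,
) -> ModuleResult:
    """End-to-end network analysis: filter, power, TOM, modules, traits, hubs."""
    expr = prefilter_genes(fpkm, tf_table, config.min_fpkm)
    if expr.shape[0] < 2:
        raise ValueError("fewer than 2 genes survive the expression filter")
    if config.power is not None:
        power = config.power
    else:
        power = pick_soft_power(
            expr, config.power_candidates, config.scale_free_r2_target, config.network_type
        )
    adjacency, tom = build_network(expr, power, config.network_type)
    expr = expr.loc[tom.index]
    modules = detect_modules(tom, config.tree_cut_height, config.min_module_size)
    mes, kme, modules = module_eigengene_kme(expr, modules, config.min_kme)
    traits = traits.loc[expr.columns]
    mt = module_trait_stats(mes, traits)
    hubs = find_hub_genes(kme, adjacency, modules, config.kme_min_hub, config.weight_min_hub)
    return ModuleResult(modules, mes, kme, mt, hubs, power)
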