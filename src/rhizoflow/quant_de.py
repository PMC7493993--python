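"""Expression quantification and differential-expression statistics.

FPKM conversion of fragment counts, a negative-binomial Wald test between
tissue pairs in the decision structure of classic DESeq (median-of-ratios
size factors, method-of-moments dispersions shrunk toward a fitted 1/mean
trend, Wald test on the log fold change, Benjamini-Hochberg correction,
|fold change| >= 4 and FDR < 0.01 to call a DEG), tissue-specific gene
selection (expressed at FPKM > 0.1 in at least two replicates of exactly one
tissue, top five by mean FPKM), and the 2^-ddCt relative-expression formula
for qPCR concordance checks.

Count matrices are pandas DataFrames (genes x samples) with sample columns
named ``T{tissue}_{replicate}``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def tissue_of(sample: str) -> str:
    return sample.split("_")[0]


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """FPKM[g,s] = counts[g,s] * 1e9 / (length[g] * total_counts[s])."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero library size")
    return counts.mul(1e9, axis=0).div(lengths, axis=0).div(totals, axis=1)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization over genes with all-positive counts."""
    mat = counts.to_numpy(dtype=float)
    pos = (mat > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no gene has positive counts in every sample")
    logs = np.log(mat[pos])
    log_geo = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_geo, axis=0))
    return pd.Series(sf, index=counts.columns)


def _group_mle_q(y: np.ndarray, s: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB MLE of the normalized group mean q with known dispersion.

    Solves sum_j (y_j - s_j q) / (1 + alpha s_j q) = 0 by Newton iteration on
    log q (guarantees positivity).  Rows with all-zero counts return 0.
    """
    q = y.sum(axis=1) / s.sum()
    zero = q <= 0
    q = np.where(zero, 1.0, q)
    lq = np.log(q)
    for _ in range(50):
        q = np.exp(lq)
        mu = s[None, :] * q[:, None]
        denom = 1.0 + alpha[:, None] * mu
        f = ((y - mu) / denom).sum(axis=1)
        # df/dlog q = -q * sum s_j (1 + alpha y_j) / denom^2
        fp = -(mu * (1.0 + alpha[:, None] * y) / denom**2).sum(axis=1)
        step = np.where(fp != 0, f / fp, 0.0)
        step = np.clip(step, -2.0, 2.0)
        lq = lq - step
        if np.max(np.abs(step)) < 1e-12:
            break
    q = np.exp(lq)
    q[zero] = 0.0
    return q


def _dispersion_estimates(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Method-of-moments dispersion shrunk toward an a0 + a1/mu trend."""
    n_g = norm.shape[0]
    num = np.zeros(n_g)
    den = np.zeros(n_g)
    mu_all = np.zeros(n_g)
    for idx in groups:
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += v - m
        den += m**2
        mu_all += m / len(groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / den, np.nan)
    raw = np.clip(np.nan_to_num(raw, nan=1e-8), 1e-8, 10.0)
    # gamma-ish trend fit by least squares on (1/mu, raw) over informative genes
    ok = mu_all > 1.0
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mu_all[ok]])
        coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
        a0, a1 = max(coef[0], 1e-8), max(coef[1], 0.0)
    else:
        a0, a1 = max(np.median(raw), 1e-8), 0.0
    trend = np.clip(a0 + a1 / np.maximum(mu_all, 0.5), 1e-8, 10.0)
    # geometric-mean shrinkage between the per-gene and trended estimates
    return np.exp(0.5 * np.log(raw) + 0.5 * np.log(trend))


def call_degs(
    counts: pd.DataFrame,
    tissue_pair: tuple[str, str],
    fc_threshold: float = 4.0,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """NB Wald differential-expression test between two tissues.

    Returns a DataFrame indexed by gene with columns log2fc, p_value, fdr,
    is_deg; ``is_deg`` applies the |fold change| >= fc_threshold (two-sided,
    i.e. ratio >= fc or <= 1/fc) and fdr < fdr_threshold rule.  log2fc is
    reported as tissue_pair[1] over tissue_pair[0] on the normalized scale.
    """
    t_a, t_b = tissue_pair
    cols_a = [c for c in counts.columns if tissue_of(c) == t_a]
    cols_b = [c for c in counts.columns if tissue_of(c) == t_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each tissue needs at least two replicates")
    sub = counts[cols_a + cols_b]
    sf = size_factors(sub)
    y = sub.to_numpy(dtype=float)
    s = sf.to_numpy()
    norm = y / s[None, :]
    ia = np.arange(len(cols_a))
    ib = np.arange(len(cols_a), len(cols_a) + len(cols_b))
    alpha = _dispersion_estimates(norm, [ia, ib])

    qa = _group_mle_q(y[:, ia], s[ia], alpha)
    qb = _group_mle_q(y[:, ib], s[ib], alpha)

    # half-a-normalized-count floor keeps the Wald statistic defined when a
    # group is all zeros; both-zero genes are reported as null
    floor_a = 0.5 / s[ia].sum()
    floor_b = 0.5 / s[ib].sum()
    qa_t = np.maximum(qa, floor_a)
    qb_t = np.maximum(qb, floor_b)

    def info(q: np.ndarray, idx: np.ndarray) -> np.ndarray:
        mu = s[idx][None, :] * q[:, None]
        return (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(1.0 / info(qa_t, ia) + 1.0 / info(qb_t, ib))
        lfc_nat = np.log(qb_t) - np.log(qa_t)
        z = lfc_nat / se
    both_zero = (qa == 0) & (qb == 0)
    z[both_zero] = 0.0
    p = 2.0 * stats.norm.sf(np.abs(z))
    fdr = multipletests(p, method="fdr_bh")[1]
    log2fc = lfc_nat / np.log(2.0)
    log2fc[both_zero] = 0.0
    is_deg = (np.abs(log2fc) >= np.log2(fc_threshold)) & (fdr < fdr_threshold)
    res = pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "fdr": fdr, "is_deg": is_deg},
        index=counts.index,
    )
    res.attrs["tissue_pair"] = tissue_pair
    return res


def select_specific_genes(
    fpkm: pd.DataFrame,
    top_n: int = 5,
    min_fpkm: float = 0.1,
    min_reps: int = 2,
) -> pd.DataFrame:
    """Tissue-specific genes and the per-tissue top-N ranking.

    A gene is specific to tissue T iff its FPKM exceeds ``min_fpkm`` in at
    least ``min_reps`` replicates of T and in fewer than ``min_reps``
    replicates of every other tissue.  Within each tissue, specific genes are
    ranked by mean FPKM over the expressed replicates and the top ``top_n``
    kept.
    """
    tissues = sorted({tissue_of(c) for c in fpkm.columns})
    expressed_reps = pd.DataFrame(
        {t: (fpkm[[c for c in fpkm.columns if tissue_of(c) == t]] > min_fpkm).sum(axis=1)
         for t in tissues}
    )
    rows = []
    for t in tissues:
        others = [o for o in tissues if o != t]
        mask = (expressed_reps[t] >= min_reps) & (
            expressed_reps[others] < min_reps
        ).all(axis=1)
        cols = [c for c in fpkm.columns if tissue_of(c) == t]
        for gene in fpkm.index[mask]:
            vals = fpkm.loc[gene, cols]
            expressed = vals[vals > min_fpkm]
            rows.append({"gene": gene, "tissue": t, "mean_fpkm": float(expressed.mean())})
    df = pd.DataFrame(rows, columns=["gene", "tissue", "mean_fpkm"])
    if df.empty:
        df["rank"] = pd.Series(dtype=int)
        return df
    df = df.sort_values(["tissue", "mean_fpkm"], ascending=[True, False])
    df["rank"] = df.groupby("tissue").cumcount() + 1
    return df[df["rank"] <= top_n].reset_index(drop=True)


def ddct(
    target_ct: float,
    reference_ct: float,
    calibrator_target_ct: float,
    calibrator_reference_ct: float,
) -> float:
    """Relative expression 2^-ddCt against a reference gene and calibrator."""
    delta_sample = target_ct - reference_ct
    delta_cal = calibrator_target_ct - calibrator_reference_ct
    return float(2.0 ** (-(delta_sample - delta_cal)))
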