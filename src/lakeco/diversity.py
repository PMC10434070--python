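"""Diversity, distance-decay, permutation tests and differential abundance.

Alpha diversity is computed on rarefied counts; beta diversity is
Bray-Curtis. Hypothesis tests are permutation-based throughout (PERMANOVA
pseudo-F, Mantel-style regressions, partial Mantel, group-label permutation
for differential abundance), two-sided where a direction is not implied, with
the standard ``(1 + #extreme) / (1 + n_perm)`` p-value so p never reaches 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .io import AbundanceTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# rarefaction + alpha diversity


def rarefy(table: AbundanceTable, depth=None, seed=0, policy="error") -> AbundanceTable:
    """Subsample every sample to ``depth`` reads without replacement.

    ``depth`` defaults to the minimum sample total. Samples shallower than
    ``depth`` either raise (``policy='error'``) or are dropped
    (``policy='drop'``).
    """
    sums = table.sample_sums()
    if depth is None:
        depth = int(sums.min())
    keep = sums >= depth
    if not keep.all():
        shallow = [s for s, k in zip(table.sample_ids, keep) if not k]
        if policy == "drop":
            logger.warning("dropping %d samples shallower than %d", len(shallow), depth)
            table = table.subset_samples([s for s in table.sample_ids if s not in shallow])
        else:
            raise ValueError(f"samples shallower than depth {depth}: {shallow}")
    rng = np.random.default_rng(seed)
    cols = [
        rng.multivariate_hypergeometric(col, depth)
        for col in table.counts.T
    ]
    return AbundanceTable(table.taxon_ids, table.sample_ids, np.column_stack(cols))


def shannon(counts, base=None) -> float:
    """Shannon entropy −Σ p·log p of one sample (natural log by default)."""
    counts = np.asarray(counts, float)
    if counts.sum() <= 0:
        raise ValueError("sample has no counts")
    p = counts[counts > 0] / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base is not None else h


def alpha_diversity(table: AbundanceTable, base=None) -> pd.DataFrame:
    """Observed richness and Shannon index per sample."""
    rows = {
        s: {"richness": int((col > 0).sum()), "shannon": shannon(col, base)}
        for s, col in zip(table.sample_ids, table.counts.T)
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


# ---------------------------------------------------------------------------
# beta diversity


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if (table.sample_sums() == 0).any():
        raise ValueError("zero-sum sample")
    d = pdist(table.counts.T.astype(float), metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=table.sample_ids)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_perm: int


def _permanova_stats(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray):
    n = len(labels)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_among = ss_total - ss_within
    a = len(uniq)
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return f, ss_among / ss_total


def permanova(dm: DistanceMatrix, groups, n_perm=999, seed=0) -> PermanovaResult:
    """One-way PERMANOVA (Anderson's pseudo-F) with free label permutation.

    ``groups`` maps sample id → group label (mapping or pandas Series), or is
    a sequence aligned with ``dm.ids``.
    """
    if hasattr(groups, "__getitem__") and not isinstance(groups, (list, tuple, np.ndarray)):
        labels = np.asarray([groups[s] for s in dm.ids])
    else:
        labels = np.asarray(list(groups))
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    d2 = dm.data**2
    f_obs, r2 = _permanova_stats(d2, labels, uniq)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm, _ = _permanova_stats(d2, rng.permutation(labels), uniq)
        if f_perm >= f_obs - 1e-12:
            hits += 1
    return PermanovaResult(f_obs, r2, (1 + hits) / (1 + n_perm), n_perm)


# ---------------------------------------------------------------------------
# distance decay + Mantel


@dataclass(frozen=True)
class DecayFit:
    slope: float
    intercept: float
    R2: float
    p: float
    n_perm: int


def _aligned_triangles(dy: DistanceMatrix, dx: DistanceMatrix):
    if set(dy.ids) != set(dx.ids):
        raise ValueError("distance matrices have mismatched ids")
    dx = dx.filter(dy.ids)
    iu = np.triu_indices(dy.shape[0], k=1)
    return dy.data, dx.data, iu


def decay_fit(dy: DistanceMatrix, dx: DistanceMatrix, n_perm=999, seed=0) -> DecayFit:
    """OLS of pairwise ``dy`` on ``dx`` with a Mantel-style permutation p.

    Regression is over the n(n−1)/2 upper-triangle pairs; the p-value
    permutes one matrix's ids jointly (preserving the pair dependence
    structure) and is two-sided on the Pearson correlation.
    """
    y_mat, x_mat, iu = _aligned_triangles(dy, dx)
    x, y = x_mat[iu], y_mat[iu]
    if np.allclose(x, x[0]):
        raise ValueError("constant predictor distances")
    fit = stats.linregress(x, y)
    r_obs = fit.rvalue
    rng = np.random.default_rng(seed)
    n = y_mat.shape[0]
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r_perm = np.corrcoef(x_mat[p][:, p][iu], y)[0, 1]
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    return DecayFit(
        float(fit.slope),
        float(fit.intercept),
        float(r_obs**2),
        (1 + hits) / (1 + n_perm),
        n_perm,
    )


def mantel(da: DistanceMatrix, db: DistanceMatrix, n_perm=999, seed=0):
    """Simple Mantel test (Pearson r of triangles, two-sided permutation p)."""
    a_mat, b_mat, iu = _aligned_triangles(da, db)
    r_obs = float(np.corrcoef(a_mat[iu], b_mat[iu])[0, 1])
    rng = np.random.default_rng(seed)
    n = a_mat.shape[0]
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r_perm = np.corrcoef(a_mat[p][:, p][iu], b_mat[iu])[0, 1]
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    return r_obs, (1 + hits) / (1 + n_perm)


def _partial_r(a, b, c) -> float:
    r_ab = np.corrcoef(a, b)[0, 1]
    r_ac = np.corrcoef(a, c)[0, 1]
    r_bc = np.corrcoef(b, c)[0, 1]
    denom = (1 - r_ac**2) * (1 - r_bc**2)
    if denom <= 1e-12:
        raise ValueError("degenerate partial correlation (|r| = 1 with covariate)")
    return float((r_ab - r_ac * r_bc) / np.sqrt(denom))


def partial_mantel(
    da: DistanceMatrix, db: DistanceMatrix, dc: DistanceMatrix, n_perm=999, seed=0
):
    """Partial Mantel: correlation of A with B controlling for C.

    Permutes A's ids; two-sided p.
    """
    a_mat, b_mat, iu = _aligned_triangles(da, db)
    _, c_mat, _ = _aligned_triangles(da, dc)
    b, c = b_mat[iu], c_mat[iu]
    r_obs = _partial_r(a_mat[iu], b, c)
    rng = np.random.default_rng(seed)
    n = a_mat.shape[0]
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        try:
            r_perm = _partial_r(a_mat[p][:, p][iu], b, c)
        except ValueError:
            continue
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    return r_obs, (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# differential abundance


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def aggregate_counts(
    table: AbundanceTable, annotation: pd.DataFrame, level: str
) -> pd.DataFrame:
    """Sum counts within annotation ``level`` labels (features × samples).

    Taxa lacking a label are pooled under ``unassigned``.
    """
    labels = (
        annotation.reindex(table.taxon_ids)[level]
        .fillna("unassigned")
        .to_numpy()
    )
    frame = table.to_frame()
    frame.index = labels
    return frame.groupby(level=0).sum()


def differential_abundance(
    table: AbundanceTable,
    groups,
    annotation: pd.DataFrame | None = None,
    level: str = "trophic_group",
    reference: str = "freshwater",
    treatment: str = "salt",
    n_perm=999,
    seed=0,
    alpha=0.05,
    pseudo_fraction=None,
) -> pd.DataFrame:
    """Per-feature log2 fold change (treatment vs reference) with BH control.

    Counts are aggregated to ``level`` (set ``annotation=None`` to test raw
    taxa), converted to per-sample relative abundances, and each feature's
    log2FC = log2((mean_treat + c)/(mean_ref + c)) with pseudo-fraction ``c``
    defaulting to half the smallest nonzero relative abundance
    (``pseudo_fraction`` overrides). The p-value permutes
    group labels on the difference of group means (two-sided); features
    absent everywhere are dropped with a log entry.
    """
    if hasattr(groups, "__getitem__") and not isinstance(groups, (list, tuple, np.ndarray)):
        labels = np.asarray([groups[s] for s in table.sample_ids])
    else:
        labels = np.asarray(list(groups))
    in_ref, in_trt = labels == reference, labels == treatment
    if in_ref.sum() == 0 or in_trt.sum() == 0:
        raise ValueError("both groups must be non-empty")
    if annotation is not None:
        agg = aggregate_counts(table, annotation, level)
    else:
        agg = table.to_frame()
    counts = agg.to_numpy(float)
    keep_cols = in_ref | in_trt
    counts = counts[:, keep_cols]
    labels = labels[keep_cols]
    empty = counts.sum(axis=1) == 0
    if empty.any():
        logger.warning("dropping %d features absent everywhere", int(empty.sum()))
        counts, features = counts[~empty], agg.index[~empty]
    else:
        features = agg.index
    rel = counts / counts.sum(axis=0)
    c = rel[rel > 0].min() / 2.0 if pseudo_fraction is None else pseudo_fraction
    is_trt = labels == treatment
    mean_trt = rel[:, is_trt].mean(axis=1)
    mean_ref = rel[:, ~is_trt].mean(axis=1)
    log2fc = np.log2((mean_trt + c) / (mean_ref + c))
    diff_obs = np.abs(mean_trt - mean_ref)
    rng = np.random.default_rng(seed)
    hits = np.zeros(len(features))
    for _ in range(n_perm):
        perm = rng.permutation(is_trt)
        d = np.abs(rel[:, perm].mean(axis=1) - rel[:, ~perm].mean(axis=1))
        hits += d >= diff_obs - 1e-15
    p_raw = (1 + hits) / (1 + n_perm)
    p_adj = bh_adjust(p_raw)
    return pd.DataFrame(
        {
            "log2FC": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        },
        index=pd.Index(features, name="feature_id"),
    )
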