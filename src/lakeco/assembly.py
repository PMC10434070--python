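"""Null-model partitioning of community assembly processes.

Two standardized null-model metrics are computed for every sample pair:

* **βNTI** — the standardized effect size of the between-sample mean nearest
  taxon distance (βMNTD) against a null that shuffles taxa across the tips of
  the phylogeny. |βNTI| > 2 indicates deterministic selection (heterogeneous
  if > 2, homogeneous if < −2).
* **RC_Bray** — the rank of the observed Bray-Curtis dissimilarity within a
  null ensemble that preserves each sample's richness and total abundance
  (taxa drawn by occupancy frequency, individuals filled by metacommunity
  relative abundance), rescaled to [−1, 1].

Pairs not separated by selection (|βNTI| ≤ 2) are then split by RC_Bray into
dispersal limitation (> 0.95), homogenizing dispersal (< −0.95) and
undominated (otherwise). Boundary values fall on the non-extreme side
(strict inequalities). Levins' niche breadth (B, and its per-sample
community mean Bcom) completes the module.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis
from skbio import DistanceMatrix, TreeNode
from skbio.stats.distance import DissimilarityMatrix

from .io import AbundanceTable, patristic_distances

logger = logging.getLogger(__name__)

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


# ---------------------------------------------------------------------------
# βMNTD / βNTI


def _weights(table: AbundanceTable, abundance_weighted: bool) -> np.ndarray:
    """Per-sample taxon weight matrix (taxa × samples, columns sum to 1)."""
    if abundance_weighted:
        return table.relative_abundances()
    presence = table.presence().astype(float)
    richness = presence.sum(axis=0)
    if (richness == 0).any():
        raise ValueError("sample with no taxa")
    return presence / richness


def _beta_mntd_from_distances(dist: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """βMNTD for all sample pairs given a taxa × taxa distance matrix.

    ``nearest[i, m] = min_{j present in m} dist[i, j]`` is computed once per
    sample; βMNTD(k, m) = ½(Σ_i w_ik·nearest[i, m] + Σ_j w_jm·nearest[j, k]).
    """
    present = weights > 0
    n_taxa, n_samples = weights.shape
    nearest = np.empty((n_taxa, n_samples))
    for m in range(n_samples):
        nearest[:, m] = dist[:, present[:, m]].min(axis=1)
    cross = weights.T @ nearest  # cross[k, m] = Σ_i w_ik nearest[i, m]
    out = 0.5 * (cross + cross.T)
    np.fill_diagonal(out, 0.0)
    return out


def beta_mntd(
    table: AbundanceTable, tree: TreeNode, abundance_weighted: bool = True
) -> DistanceMatrix:
    """Between-sample mean nearest taxon distance (patristic)."""
    dm = patristic_distances(tree, table.taxon_ids)
    weights = _weights(table, abundance_weighted)
    return DistanceMatrix(
        _beta_mntd_from_distances(dm.data, weights), ids=table.sample_ids
    )


def bnti(
    table: AbundanceTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> DistanceMatrix:
    """β-nearest taxon index: (βMNTD_obs − mean_null) / sd_null per pair.

    The null shuffles taxa across the tree's tips (one uniform permutation of
    the patristic matrix per null iteration, shared by all pairs — the
    ``comdistnt``-style tip shuffle). Pairs whose null sd is zero are set to
    NaN and logged.
    """
    if n_null < 99:
        raise ValueError("n_null must be ≥ 99")
    dm = patristic_distances(tree, table.taxon_ids)
    dist = dm.data
    weights = _weights(table, abundance_weighted)
    obs = _beta_mntd_from_distances(dist, weights)
    rng = np.random.default_rng(seed)
    n_taxa = dist.shape[0]
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        null = _beta_mntd_from_distances(dist[np.ix_(perm, perm)], weights)
        acc += null
        acc2 += null**2
    mean = acc / n_null
    var = np.maximum(acc2 / n_null - mean**2, 0.0)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    degenerate = (sd == 0) & ~np.eye(len(obs), dtype=bool)
    np.fill_diagonal(z, 0.0)
    if degenerate.any():
        logger.warning("%d pairs with zero null sd excluded", int(degenerate.sum() // 2))
        z[degenerate] = np.nan
        # NaN-bearing matrices cannot be strict DistanceMatrix instances
        return DissimilarityMatrix(z, ids=table.sample_ids)
    return DistanceMatrix(z, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# RC_Bray


def _null_sample(rng, occupancy_p, metacommunity, richness, total) -> np.ndarray:
    """One null community: fix richness, fill abundance by regional pool."""
    n_taxa = len(occupancy_p)
    chosen = rng.choice(n_taxa, size=richness, replace=False, p=occupancy_p)
    counts = np.zeros(n_taxa)
    counts[chosen] = 1.0
    if total > richness:
        pool = metacommunity[chosen]
        counts[chosen] += rng.multinomial(total - richness, pool / pool.sum())
    return counts


def rc_bray(table: AbundanceTable, n_null: int = 999, seed: int = 0) -> DistanceMatrix:
    """Bray-Curtis-based Raup-Crick deviation, in [−1, 1] per sample pair.

    Null communities preserve each sample's observed richness (taxa drawn
    with probability proportional to occupancy frequency across samples) and
    total abundance (individuals filled proportionally to metacommunity
    relative abundance among the drawn taxa). RC_Bray = 2·rank − 1 where rank
    is the fraction of null Bray-Curtis values below the observed one, ties
    counted half.

    Each pair's null stream is seeded from ``(seed, i, j)`` so results do not
    depend on evaluation order.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if n_null < 99:
        raise ValueError("n_null must be ≥ 99")
    counts = table.counts.astype(float)
    occupancy = (counts > 0).sum(axis=1).astype(float)
    if occupancy.sum() == 0:
        raise ValueError("empty table")
    occupancy_p = occupancy / occupancy.sum()
    metacommunity = counts.sum(axis=1)
    richness = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0).astype(int)
    n = table.n_samples
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        obs = braycurtis(counts[:, i], counts[:, j])
        rng = np.random.default_rng(np.random.SeedSequence([seed, i, j]))
        below = ties = 0
        for _ in range(n_null):
            x = _null_sample(rng, occupancy_p, metacommunity, richness[i], totals[i])
            y = _null_sample(rng, occupancy_p, metacommunity, richness[j], totals[j])
            b = braycurtis(x, y)
            if b < obs - 1e-12:
                below += 1
            elif abs(b - obs) <= 1e-12:
                ties += 1
        out[i, j] = out[j, i] = 2.0 * (below + 0.5 * ties) / n_null - 1.0
    return DistanceMatrix(out, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# five-process classification


@dataclass
class AssemblyResult:
    """Per-pair βNTI / RC_Bray values, process calls and process fractions."""

    pairs: pd.DataFrame  # columns: sample_a, sample_b, bnti, rc_bray, process
    fractions: pd.Series  # proportions over PROCESSES, over classified pairs


def classify_pair(bnti_value: float, rc_value: float) -> str | None:
    """Assign one sample pair to an assembly process (None if βNTI missing)."""
    if np.isnan(bnti_value):
        return None
    if bnti_value > 2:
        return "heterogeneous_selection"
    if bnti_value < -2:
        return "homogeneous_selection"
    if rc_value > 0.95:
        return "dispersal_limitation"
    if rc_value < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def classify_assembly(bnti_dm: DistanceMatrix, rc_dm: DistanceMatrix) -> AssemblyResult:
    """Five-process partition over all sample pairs.

    |βNTI| > 2 → selection (heterogeneous / homogeneous by sign); otherwise
    RC_Bray beyond ±0.95 → dispersal limitation / homogenizing dispersal;
    the remainder is undominated. Boundary values (exactly 2 or 0.95) fall to
    the weaker class. Pairs with missing βNTI propagate as missing and are
    excluded from the fractions.
    """
    if list(bnti_dm.ids) != list(rc_dm.ids):
        rc_dm = rc_dm.filter(bnti_dm.ids)
    ids = bnti_dm.ids
    rows = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        rows.append(
            {
                "sample_a": ids[i],
                "sample_b": ids[j],
                "bnti": bnti_dm.data[i, j],
                "rc_bray": rc_dm.data[i, j],
                "process": classify_pair(bnti_dm.data[i, j], rc_dm.data[i, j]),
            }
        )
    pairs = pd.DataFrame(rows)
    classified = pairs["process"].dropna()
    if len(classified) == 0:
        raise ValueError("no classifiable pairs")
    fractions = (
        classified.value_counts(normalize=True)
        .reindex(PROCESSES, fill_value=0.0)
        .rename("fraction")
    )
    return AssemblyResult(pairs, fractions)


def stochastic_fraction(result: AssemblyResult) -> float:
    """Combined weight of the three stochastic processes."""
    return float(
        result.fractions[
            ["dispersal_limitation", "homogenizing_dispersal", "undominated"]
        ].sum()
    )


# ---------------------------------------------------------------------------
# Levins niche breadth


@dataclass
class NicheBreadth:
    """Per-taxon Levins B and its per-sample community mean Bcom."""

    b: pd.Series  # indexed by taxon_id, values in [1, n_samples]
    bcom: pd.Series  # indexed by sample_id


def levins_breadth(table: AbundanceTable) -> NicheBreadth:
    """Levins' niche breadth B_j = 1 / Σ_i P_ij² across samples.

    P_ij is taxon j's count in sample i divided by taxon j's total across
    samples (each taxon's distribution over habitats sums to 1), so B ranges
    from 1 (confined to one sample) to N (evenly spread over all N samples).
    Bcom for a sample is the mean B over the taxa present in it. All-zero
    taxa are dropped with a log entry.
    """
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    present = totals > 0
    if not present.all():
        logger.warning("dropping %d all-zero taxa", int((~present).sum()))
    counts = counts[present]
    p = counts / counts.sum(axis=1, keepdims=True)
    b_values = 1.0 / (p**2).sum(axis=1)
    taxa = [t for t, keep in zip(table.taxon_ids, present) if keep]
    b = pd.Series(b_values, index=pd.Index(taxa, name="taxon_id"), name="B")
    occupancy = counts > 0
    bcom = pd.Series(
        [
            b_values[occupancy[:, s]].mean() if occupancy[:, s].any() else np.nan
            for s in range(table.n_samples)
        ],
        index=pd.Index(table.sample_ids, name="sample_id"),
        name="Bcom",
    )
    return NicheBreadth(b, bcom)
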