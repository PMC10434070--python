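"""Synthetic lake-microeukaryote communities with tunable salinity filtering.

The generator emulates the sampling design the pipeline targets: a handful of
lakes spanning a salinity gradient from fresh (<1 %) to hypersaline (~11 %),
each contributing several surface-water samples, with ~1,000 taxa whose
salinity optima evolved along a shared phylogeny. Species sorting is a
Gaussian niche filter on salinity raised to a filtering-strength exponent
``w``: at ``w = 0`` every sample draws from the same regional pool (the
neutral regime), while large ``w`` makes local communities track their
salinity optimum (the selected regime). Counts are multinomial at a fixed
sequencing depth, i.e. the tables look like post-rarefaction ZOTU tables.

All randomness descends from one master seed through
``numpy.random.SeedSequence`` spawning, so a given configuration is
bit-reproducible and the five outputs (metadata, tree, niche profiles,
abundance table, trophic annotation) are mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import TROPHIC_GROUPS, AbundanceTable, classify_salinity, read_tree

#: Lake-level salinity (%) levels: five freshwater, one brackish, one
#: subsaline, one salt lake.
DEFAULT_SALINITY_LEVELS = (0.3, 0.5, 0.6, 0.7, 0.9, 3.6, 6.2, 11.3)

#: Taxon-level trophic guild proportions. Photosynthetic taxa dominate
#: (algae-rich surface waters); consumers next; the remainder split among
#: saprotrophs, parasites, mixotrophs and unclassifiable lineages.
DEFAULT_TROPHIC_PROPORTIONS = {
    "consumer": 0.20,
    "saprotroph": 0.08,
    "parasite": 0.06,
    "photosynthetic": 0.55,
    "mixotroph": 0.05,
    "unclassified": 0.06,
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic data set.

    Attributes
    ----------
    n_lakes, samples_per_lake, n_taxa, sequencing_depth
        Design sizes. Depth is per-sample total count (post-rarefaction
        scale).
    salinity_levels
        One mean salinity (%) per lake.
    filtering_strength
        Exponent ``w`` on the Gaussian niche kernel; 0 = neutral assembly.
    niche_width
        Gaussian niche breadth σ (salinity % units).
    brownian_rate
        Brownian-motion rate of salinity-optimum evolution per unit branch
        length (trees are ultrametric with height ~1).
    root_optimum
        Ancestral salinity optimum (%). The default (together with the
        Brownian rate) yields a predominantly freshwater-adapted pool in
        which salt tolerance is the derived minority state, as in inland
        lake systems.
    salinity_jitter_sd
        SD of the multiplicative lognormal jitter of sample salinities
        around the lake level (0 → exact levels).
    regional_lognormal_params
        (mean, sd) of log regional abundances.
    """

    n_lakes: int = 8
    samples_per_lake: int = 10
    n_taxa: int = 1000
    salinity_levels: tuple = DEFAULT_SALINITY_LEVELS
    filtering_strength: float = 3.0
    niche_width: float = 1.5
    brownian_rate: float = 3.5
    root_optimum: float = 2.5
    salinity_jitter_sd: float = 0.05
    sequencing_depth: int = 10000
    regional_lognormal_params: tuple = (0.0, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lakes < 1 or self.samples_per_lake < 1 or self.n_taxa < 3:
            raise ValueError("design sizes must be positive (n_taxa ≥ 3)")
        if len(self.salinity_levels) != self.n_lakes:
            raise ValueError("need one salinity level per lake")
        if self.niche_width <= 0:
            raise ValueError("niche_width must be positive")
        if self.filtering_strength < 0:
            raise ValueError("filtering_strength must be ≥ 0")
        if self.sequencing_depth < 100:
            raise ValueError("sequencing_depth must be ≥ 100")


# ---------------------------------------------------------------------------


def simulate_environment(cfg: SimulationConfig, rng=None) -> pd.DataFrame:
    """Sample metadata: lakes at their salinity levels plus covariates.

    Each sample's salinity is its lake's level times a lognormal jitter
    (sd ``cfg.salinity_jitter_sd`` on the log scale). The drought index APDSI
    is generated anti-correlated with salinity (drier basins are saltier);
    water temperature and nutrients are uncorrelated noise; coordinates and
    altitude are lake-level constants.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    rows = []
    lat0 = rng.uniform(40.0, 47.0, size=cfg.n_lakes)
    lon0 = rng.uniform(110.0, 127.0, size=cfg.n_lakes)
    alt0 = rng.uniform(600.0, 2100.0, size=cfg.n_lakes)
    for li, level in enumerate(cfg.salinity_levels):
        lake = f"lake_{li + 1:02d}"
        for si in range(cfg.samples_per_lake):
            salinity = float(
                level * np.exp(rng.normal(0.0, cfg.salinity_jitter_sd))
            )
            rows.append(
                {
                    "sample_id": f"{lake}_s{si + 1:02d}",
                    "lake": lake,
                    "salinity": salinity,
                    "water_class": classify_salinity(salinity),
                    "WT": float(rng.normal(18.0, 3.0)),
                    "TN": float(np.exp(rng.normal(0.5, 0.6))),
                    "TP": float(np.exp(rng.normal(-1.5, 0.8))),
                    "APDSI": float(1.0 - 0.35 * salinity + rng.normal(0.0, 0.6)),
                    "MAT": float(rng.normal(5.0, 2.0)),
                    "MAP": float(rng.normal(250.0, 60.0)),
                    "latitude": float(lat0[li]),
                    "longitude": float(lon0[li]),
                    "altitude": float(alt0[li]),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_phylogeny(n_taxa: int, seed: int) -> TreeNode:
    """Pure-birth (Yule) ultrametric tree with ``n_taxa`` labelled tips.

    Lineages split at unit rate; after the last split all tips are extended
    by one further exponential holding time so pendant edges are strictly
    positive and patristic distance is a metric. The height is rescaled to 1.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be ≥ 3")
    rng = np.random.default_rng(seed)
    # children[i] = (left, right) internal bookkeeping; birth_time per node
    birth = [0.0, 0.0]
    parent = [-1, -1]
    active = [0, 1]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node = active[k]
        left, right = len(birth), len(birth) + 1
        birth.extend([t, t])
        parent.extend([node, node])
        active[k] = left
        active.append(right)
    t += rng.exponential(1.0 / n_taxa)  # final hold keeps pendant edges > 0

    children: dict[int, list[int]] = {}
    for node, par in enumerate(parent):
        if par >= 0:
            children.setdefault(par, []).append(node)

    width = len(str(n_taxa))
    tip_counter = [0]

    def newick(node: int) -> str:
        end = birth[children[node][0]] if node in children else t
        length = (end - birth[node]) / t  # rescale height to 1
        if node in children:
            inner = ",".join(newick(c) for c in children[node])
            return f"({inner}):{length:.10f}"
        tip_counter[0] += 1
        return f"taxon_{tip_counter[0]:0{width}d}:{length:.10f}"

    root = f"({newick(0)},{newick(1)});"
    return read_tree(root)


def evolve_niche_optima(
    tree: TreeNode,
    brownian_rate: float,
    root_optimum: float,
    rng,
    regional_lognormal_params=(0.0, 1.5),
    clip=(0.0, 15.0),
) -> pd.DataFrame:
    """Brownian-motion salinity optima along the tree, plus regional pool.

    Each branch adds a Normal(0, rate²·length) increment; tip optima are
    clipped to ``clip`` (salinity %). Regional (metacommunity) abundances are
    i.i.d. lognormal. Returns a DataFrame indexed by taxon_id with columns
    ``optimum`` and ``regional_abundance``.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    values = {id(tree): float(root_optimum)}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, brownian_rate * np.sqrt(max(node.length, 0.0)))
        values[id(node)] = values[id(node.parent)] + step
    tips = list(tree.tips())
    optima = np.clip([values[id(t)] for t in tips], clip[0], clip[1])
    mu, sd = regional_lognormal_params
    regional = rng.lognormal(mu, sd, size=len(tips))
    return pd.DataFrame(
        {"optimum": optima, "regional_abundance": regional},
        index=pd.Index([t.name for t in tips], name="taxon_id"),
    )


def assemble_communities(
    metadata: pd.DataFrame,
    profiles: pd.DataFrame,
    filtering_strength: float,
    niche_width: float,
    depth: int,
    rng,
) -> AbundanceTable:
    """Multinomial draws from a salinity-filtered regional pool.

    For a sample at salinity *s*, taxon *j* has sampling weight
    ``regional_j · exp(−(s − optimum_j)² / (2σ²))^w``. With ``w = 0`` the
    expected composition is identical across salinities (neutral regime).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    opt = profiles["optimum"].to_numpy(float)
    regional = profiles["regional_abundance"].to_numpy(float)
    columns = []
    for s in metadata["salinity"].to_numpy(float):
        kernel = np.exp(-((s - opt) ** 2) / (2.0 * niche_width**2))
        weights = regional * kernel**filtering_strength
        total = weights.sum()
        if total <= 0 or not np.isfinite(total):
            raise ValueError(
                "all sampling weights vanished — niche_width too small for "
                f"salinity {s}"
            )
        columns.append(rng.multinomial(depth, weights / total))
    return AbundanceTable(
        tuple(profiles.index),
        tuple(metadata.index),
        np.column_stack(columns),
    )


def assign_trophic_groups(
    taxon_ids, proportions=None, rng=None
) -> pd.DataFrame:
    """I.i.d. categorical trophic-guild labels plus a mock taxonomy.

    Each taxon also receives class- and order-level labels (orders nested in
    classes) so rank aggregation is exercisable. Returns a DataFrame indexed
    by taxon_id with ``trophic_group``, ``class`` and ``order`` columns.
    """
    proportions = dict(DEFAULT_TROPHIC_PROPORTIONS if proportions is None else proportions)
    if set(proportions) != set(TROPHIC_GROUPS):
        raise ValueError(f"proportions must cover exactly {TROPHIC_GROUPS}")
    p = np.array([proportions[g] for g in TROPHIC_GROUPS], float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be non-negative and sum to 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    taxon_ids = list(taxon_ids)
    groups = rng.choice(len(TROPHIC_GROUPS), size=len(taxon_ids), p=p)
    n_classes = max(3, min(20, len(taxon_ids) // 10))
    classes = rng.integers(n_classes, size=len(taxon_ids))
    orders = rng.integers(3, size=len(taxon_ids))  # 3 orders per class
    return pd.DataFrame(
        {
            "trophic_group": [TROPHIC_GROUPS[g] for g in groups],
            "class": [f"class_{c + 1:02d}" for c in classes],
            "order": [f"class_{c + 1:02d}_order_{o + 1}" for c, o in zip(classes, orders)],
        },
        index=pd.Index(taxon_ids, name="taxon_id"),
    )


# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """Bundle of one simulated study: table, metadata, tree, profiles, annotation."""

    table: AbundanceTable
    metadata: pd.DataFrame
    tree: TreeNode
    profiles: pd.DataFrame
    annotation: pd.DataFrame
    config: SimulationConfig = field(repr=False)


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Run the full generator under one master seed."""
    ss = np.random.SeedSequence(cfg.seed)
    s_env, s_tree, s_niche, s_comm, s_troph = ss.spawn(5)
    metadata = simulate_environment(cfg, np.random.default_rng(s_env))
    tree = simulate_phylogeny(cfg.n_taxa, s_tree.generate_state(1)[0] % 2**31)
    profiles = evolve_niche_optima(
        tree,
        cfg.brownian_rate,
        cfg.root_optimum,
        np.random.default_rng(s_niche),
        cfg.regional_lognormal_params,
    )
    table = assemble_communities(
        metadata,
        profiles,
        cfg.filtering_strength,
        cfg.niche_width,
        cfg.sequencing_depth,
        np.random.default_rng(s_comm),
    )
    annotation = assign_trophic_groups(
        profiles.index, rng=np.random.default_rng(s_troph)
    )
    return SyntheticDataset(table, metadata, tree, profiles, annotation, cfg)


def provenance(cfg: SimulationConfig) -> dict:
    """JSON-serialisable record of all generator parameters."""
    record = asdict(cfg)
    record["salinity_levels"] = list(cfg.salinity_levels)
    record["regional_lognormal_params"] = list(cfg.regional_lognormal_params)
    return record
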