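"""Shared data model and readers/writers for the pipeline's file formats.

All tables are tab-delimited UTF-8 text with ``.`` as the decimal mark.
Abundance tables are oriented taxa × samples (ZOTU-table convention), so
prevalence filters and niche-breadth computations are row-wise. Trees are
newick with branch lengths. Networks are exchanged as an edge-list TSV plus a
node-attribute TSV. Downstream modules consume only the in-memory types
defined here and never touch files directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

#: The six trophic guild labels a taxon may carry.
TROPHIC_GROUPS = (
    "consumer",
    "saprotroph",
    "parasite",
    "photosynthetic",
    "mixotroph",
    "unclassified",
)

#: Water-class cutoffs on salinity (%): class applies up to (but excluding)
#: the stated upper edge; salinity at or above the last edge is "salt".
DEFAULT_SALINITY_CUTOFFS = (
    ("freshwater", 1.0),
    ("brackish", 5.0),
    ("subsalt", 10.0),
)
WATER_CLASSES = ("freshwater", "brackish", "subsalt", "salt")


class FormatError(ValueError):
    """Raised when an input file violates its structural contract."""


@dataclass(frozen=True)
class AbundanceTable:
    """Integer count table, taxa × samples.

    Parameters
    ----------
    taxon_ids
        Row labels; unique.
    sample_ids
        Column labels; unique.
    counts
        Non-negative integer matrix of shape (n_taxa, n_samples).
    """

    taxon_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        taxa = tuple(str(t) for t in self.taxon_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        object.__setattr__(self, "taxon_ids", taxa)
        object.__setattr__(self, "sample_ids", samples)
        if len(set(taxa)) != len(taxa):
            raise FormatError("duplicate taxon ids")
        if len(set(samples)) != len(samples):
            raise FormatError("duplicate sample ids")
        counts = np.asarray(self.counts)
        if counts.shape != (len(taxa), len(samples)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(taxa)} taxa × {len(samples)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)):
                raise ValueError("counts contain NaN or infinite values")
            rounded = np.rint(counts)
            if not np.array_equal(rounded, counts):
                raise ValueError("counts must be integers")
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64, copy=False))

    # -- convenience views -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def taxon_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def presence(self) -> np.ndarray:
        """Boolean occurrence matrix (taxa × samples)."""
        return self.counts > 0

    def relative_abundances(self) -> np.ndarray:
        """Column-normalised proportions; zero-sum columns raise."""
        sums = self.sample_sums()
        if (sums == 0).any():
            bad = [s for s, t in zip(self.sample_ids, sums) if t == 0]
            raise ValueError(f"zero-total samples: {bad}")
        return self.counts / sums

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.taxon_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AbundanceTable":
        return cls(tuple(frame.index), tuple(frame.columns), frame.to_numpy())

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AbundanceTable(self.taxon_ids, tuple(sample_ids), self.counts[:, idx])

    def subset_taxa(self, keep: np.ndarray) -> "AbundanceTable":
        """Subset rows by a boolean mask or list of taxon ids."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            taxa = tuple(t for t, k in zip(self.taxon_ids, keep) if k)
            return AbundanceTable(taxa, self.sample_ids, self.counts[keep])
        idx = [self.taxon_ids.index(t) for t in keep]
        return AbundanceTable(tuple(keep), self.sample_ids, self.counts[idx])


# ---------------------------------------------------------------------------
# abundance table I/O


def read_abundance_table(path) -> AbundanceTable:
    """Read a taxa × samples count TSV (first column = taxon ids)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicate sample columns")
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.columns = sample_ids  # undo pandas' dedup-mangling, already checked
    if frame.index.duplicated().any():
        raise FormatError(f"{path}: duplicate taxon ids")
    values = frame.to_numpy()
    if values.dtype == object:
        raise ValueError(f"{path}: non-numeric cells")
    return AbundanceTable(tuple(frame.index.astype(str)), tuple(sample_ids), values)


def write_abundance_table(table: AbundanceTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# sample metadata


def classify_salinity(salinity: float, cutoffs=DEFAULT_SALINITY_CUTOFFS) -> str:
    """Map a salinity (%) to its water class using half-open intervals."""
    if salinity < 0:
        raise ValueError("salinity must be non-negative")
    for label, upper in cutoffs:
        if salinity < upper:
            return label
    return "salt"


def read_metadata(path, cutoffs=DEFAULT_SALINITY_CUTOFFS) -> pd.DataFrame:
    """Read the per-sample metadata TSV.

    Requires a ``sample_id`` column; derives ``water_class`` from salinity
    when absent. Optional covariates left empty are kept as missing values
    (NaN), never filled with zero.
    """
    frame = pd.read_csv(path, sep="\t")
    if "sample_id" not in frame.columns:
        raise FormatError(f"{path}: missing sample_id column")
    if frame["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    frame = frame.set_index("sample_id")
    if "salinity" in frame.columns and (frame["salinity"] < 0).any():
        raise ValueError("negative salinity")
    if "water_class" not in frame.columns and "salinity" in frame.columns:
        frame["water_class"] = [
            classify_salinity(s, cutoffs) for s in frame["salinity"]
        ]
    return frame


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# trophic annotation


def read_annotation(path) -> pd.DataFrame:
    """Read the taxon annotation TSV (taxon_id, trophic_group, taxonomy…)."""
    frame = pd.read_csv(path, sep="\t")
    if "taxon_id" not in frame.columns:
        raise FormatError(f"{path}: missing taxon_id column")
    if frame["taxon_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate taxon annotation rows")
    frame = frame.set_index("taxon_id")
    if "trophic_group" in frame.columns:
        bad = set(frame["trophic_group"]) - set(TROPHIC_GROUPS)
        if bad:
            raise ValueError(f"unknown trophic groups: {sorted(bad)}")
    return frame


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="taxon_id")


def check_annotation_covers(annotation: pd.DataFrame, table: AbundanceTable) -> None:
    missing = set(table.taxon_ids) - set(annotation.index)
    if missing:
        raise ValueError(f"{len(missing)} taxa lack annotation rows")


# ---------------------------------------------------------------------------
# phylogenetic tree


def read_tree(source) -> TreeNode:
    """Read a rooted newick tree and validate tips and branch lengths.

    ``source`` may be a path or a newick string.
    """
    text = str(source)
    if "(" in text and ";" in text:
        tree = TreeNode.read(StringIO(text), convert_underscores=False)
    else:
        tree = TreeNode.read(str(source), convert_underscores=False)
    tips = list(tree.tips())
    names = [t.name for t in tips]
    if any(n is None or n == "" for n in names):
        raise FormatError("tree has unlabeled tips")
    if len(set(names)) != len(names):
        raise FormatError("tree has duplicate tip labels")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise FormatError("tree has missing branch lengths")
        if node.length < 0:
            raise FormatError("tree has negative branch lengths")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def patristic_distances(tree: TreeNode, taxon_ids=None) -> DistanceMatrix:
    """Tip-to-tip (patristic) distance matrix, optionally reordered/subset."""
    dm = tree.tip_tip_distances()
    if taxon_ids is not None:
        missing = set(taxon_ids) - set(dm.ids)
        if missing:
            raise ValueError(f"taxa absent from tree: {sorted(missing)[:5]} …")
        dm = dm.filter(taxon_ids)
    return dm


# ---------------------------------------------------------------------------
# network I/O (edge list + node attributes)


def write_network(net: nx.Graph, edge_path, node_path) -> None:
    """Write a signed co-occurrence network as edge and node TSVs.

    The edge file carries (source, target, weight, sign); the node file the
    per-node attributes used downstream (degree, module, Zi, Pi, role,
    trophic_group) when present. Topology round-trips losslessly.
    """
    edges = [
        {
            "source": u,
            "target": v,
            "weight": d.get("weight", 1.0),
            "sign": d.get("sign", 1),
        }
        for u, v, d in net.edges(data=True)
    ]
    pd.DataFrame(edges, columns=["source", "target", "weight", "sign"]).to_csv(
        edge_path, sep="\t", index=False
    )
    attr_cols = ["module", "Zi", "Pi", "role", "trophic_group"]
    rows = []
    for n, d in net.nodes(data=True):
        row = {"node": n, "degree": net.degree(n)}
        for c in attr_cols:
            if c in d:
                row[c] = d[c]
        rows.append(row)
    pd.DataFrame(rows).to_csv(node_path, sep="\t", index=False)


def read_network(edge_path, node_path=None) -> nx.Graph:
    """Read back a network written by :func:`write_network`."""
    net = nx.Graph()
    edges = pd.read_csv(edge_path, sep="\t")
    for _, row in edges.iterrows():
        net.add_edge(
            str(row["source"]),
            str(row["target"]),
            weight=float(row["weight"]),
            sign=int(row["sign"]),
        )
    if node_path is not None:
        nodes = pd.read_csv(node_path, sep="\t")
        for _, row in nodes.iterrows():
            name = str(row["node"])
            if name not in net:
                net.add_node(name)
            for c in nodes.columns:
                if c not in ("node", "degree") and not pd.isna(row[c]):
                    net.nodes[name][c] = row[c]
    return net
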