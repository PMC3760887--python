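"""Input/output and preprocessing for networks, expression matrices and gene sets.

Networks are undirected simple graphs over feature identifiers (genes and
optionally miRNAs).  Node ordering is always lexicographic so that every
matrix derived from a network (adjacency, Laplacian, kernel) is reproducible
bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MRNA = "mRNA"
MIRNA = "miRNA"


def _norm_edge(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class Network:
    """Undirected simple graph with a fixed lexicographic node order.

    Parameters
    ----------
    nodes
        Ordered (lexicographic) tuple of node identifiers.
    edges
        Frozenset of lexicographically ordered node pairs; no self-loops.
    node_type
        Mapping node -> "mRNA" | "miRNA".  Nodes absent from the mapping
        are mRNA.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    node_type: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        if tuple(sorted(self.nodes)) != self.nodes:
            raise ValueError("nodes must be in lexicographic order")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if u > v:
                raise ValueError(f"edge ({u!r}, {v!r}) not normalized")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint not in node set: ({u!r}, {v!r})")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
        node_type: Mapping[str, str] | None = None,
    ) -> "Network":
        """Build a network from an edge iterable, dropping self-loops and
        collapsing duplicate edges."""
        edge_set: set[tuple[str, str]] = set()
        nodes: set[str] = set(extra_nodes)
        for u, v in edges:
            nodes.add(u)
            nodes.add(v)
            if u != v:
                edge_set.add(_norm_edge(u, v))
        return cls(tuple(sorted(nodes)), frozenset(edge_set), dict(node_type or {}))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def type_of(self, node: str) -> str:
        return self.node_type.get(node, MRNA)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix in node order."""
        idx = self.index()
        a = np.zeros((self.n_nodes, self.n_nodes))
        for u, v in self.edges:
            i, j = idx[u], idx[v]
            a[i, j] = a[j, i] = 1.0
        return a

    def degrees(self) -> np.ndarray:
        idx = self.index()
        d = np.zeros(self.n_nodes)
        for u, v in self.edges:
            d[idx[u]] += 1.0
            d[idx[v]] += 1.0
        return d


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def read_edge_list(path: str, format: str = "sif") -> Network:
    """Read an undirected network from a SIF or two-column edge-list file.

    SIF rows are ``source<TAB>relation<TAB>target``; relation labels are
    accepted but not distinguished.  Two-column rows are
    ``source<TAB>target``.  Self-loops are dropped and duplicate edges
    collapsed.
    """
    if format not in ("sif", "two-column"):
        raise ValueError(f"unknown format {format!r}")
    edges: list[tuple[str, str]] = []
    nodes: set[str] = set()
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if format == "sif":
                if len(fields) != 3:
                    raise ParseError(
                        f"{path}:{lineno}: expected 3 tab-separated fields "
                        f"(source, relation, target), got {len(fields)}"
                    )
                u, _, v = fields
            else:
                if len(fields) != 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected 2 tab-separated fields, "
                        f"got {len(fields)}"
                    )
                u, v = fields
            n_rows += 1
            nodes.update((u, v))
            edges.append((u, v))
    if n_rows == 0:
        raise ParseError(f"{path}: no edges found")
    return Network.from_edges(edges, extra_nodes=nodes)


def write_edge_list(net: Network, path: str) -> None:
    """Write a network as a two-column tab-delimited edge list.

    Isolated nodes are written as a single-field row so the round trip
    preserves the node set.
    """
    connected = {u for e in net.edges for u in e}
    with open(path, "w") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")
        for n in net.nodes:
            if n not in connected:
                fh.write(f"{n}\n")


def read_edge_list_with_isolated(path: str) -> Network:
    """Read the two-column dialect written by :func:`write_edge_list`,
    where single-field rows are isolated nodes."""
    edges: list[tuple[str, str]] = []
    nodes: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                nodes.add(fields[0])
            elif len(fields) == 2:
                nodes.update(fields)
                edges.append((fields[0], fields[1]))
            else:
                raise ParseError(f"{path}:{lineno}: expected 1 or 2 fields")
    return Network.from_edges(edges, extra_nodes=nodes)


@dataclass
class ExpressionDataset:
    """Feature x sample expression matrix with binary class labels.

    ``labels`` take values +1 (positive / early-relapse class) and -1.
    ``feature_type`` maps feature -> "mRNA" | "miRNA"; missing means mRNA.
    """

    features: list[str]
    samples: list[str]
    values: np.ndarray
    labels: np.ndarray
    feature_type: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != (len(self.features), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if len(self.labels) != len(self.samples):
            raise ValueError("one label per sample required")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1 or -1")
        if len(set(self.features)) != len(self.features):
            raise ValueError("feature identifiers must be unique")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def feature_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.features)}

    def subset_features(self, keep: Sequence[str]) -> "ExpressionDataset":
        idx = self.feature_index()
        rows = [idx[f] for f in keep]
        return ExpressionDataset(
            list(keep),
            list(self.samples),
            self.values[rows],
            self.labels.copy(),
            {f: self.feature_type[f] for f in keep if f in self.feature_type},
        )

    def subset_samples(self, cols: Sequence[int]) -> "ExpressionDataset":
        cols = list(cols)
        return ExpressionDataset(
            list(self.features),
            [self.samples[c] for c in cols],
            self.values[:, cols],
            self.labels[cols],
            dict(self.feature_type),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features, columns=self.samples)


def read_expression(expr_path: str, labels_path: str) -> ExpressionDataset:
    """Read a tab-delimited expression matrix (rows = features, header row of
    sample IDs) and a two-column ``sample<TAB>{+1|-1}`` label file."""
    df = pd.read_csv(expr_path, sep="\t", index_col=0)
    labels = {}
    with open(labels_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{labels_path}:{lineno}: expected sample<TAB>label")
            try:
                labels[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ParseError(
                    f"{labels_path}:{lineno}: label must be +1 or -1"
                ) from exc
    missing = [s for s in df.columns if s not in labels]
    if missing:
        raise ParseError(f"no label for samples: {missing[:5]}")
    y = np.array([labels[s] for s in df.columns])
    return ExpressionDataset(list(df.index.astype(str)), list(df.columns), df.to_numpy(), y)


def write_expression(data: ExpressionDataset, expr_path: str, labels_path: str) -> None:
    data.to_frame().to_csv(expr_path, sep="\t")
    with open(labels_path, "w") as fh:
        for s, y in zip(data.samples, data.labels):
            fh.write(f"{s}\t{y:+d}\n")


def aggregate_probesets(
    values: pd.DataFrame, mapping: Mapping[str, str], labels: np.ndarray | None = None
) -> ExpressionDataset | pd.DataFrame:
    """Collapse a probeset x sample matrix to genes by averaging the rows of
    all probesets mapped to the same gene.

    Probesets absent from the mapping are dropped (their count is logged).
    Returns an :class:`ExpressionDataset` when labels are given, otherwise
    the aggregated gene x sample DataFrame.
    """
    if not mapping:
        raise ValueError("empty probeset-to-gene mapping")
    mapped = values.index.to_series().map(dict(mapping))
    n_unmapped = int(mapped.isna().sum())
    if n_unmapped:
        logger.info("dropping %d probesets without a gene mapping", n_unmapped)
    kept = values.loc[mapped.notna()]
    genes = mapped.dropna()
    agg = kept.groupby(genes.values).mean()
    agg = agg.sort_index()
    if labels is None:
        return agg
    return ExpressionDataset(
        list(agg.index.astype(str)), list(agg.columns), agg.to_numpy(), labels
    )


def build_analysis_network(
    ppi: Network,
    features: Sequence[str],
    mirna_targets: Network | None = None,
    feature_type: Mapping[str, str] | None = None,
) -> Network:
    """Assemble the analysis graph over exactly the measured features.

    The node set equals the feature set: network nodes without expression
    data are dropped (and their edges with them), while measured features
    missing from the network are added as isolated nodes so they stay in
    the ranking.  Optional miRNA-target edges are merged in the same way
    and treated as undirected.
    """
    if not features:
        raise ValueError("features must be non-empty")
    fset = set(features)
    edges = [(u, v) for u, v in ppi.edges if u in fset and v in fset]
    if mirna_targets is not None:
        edges.extend(
            (u, v) for u, v in mirna_targets.edges if u in fset and v in fset
        )
    ntype = dict(feature_type or {})
    if mirna_targets is not None:
        for n, t in mirna_targets.node_type.items():
            if n in fset and n not in ntype:
                ntype[n] = t
    return Network.from_edges(edges, extra_nodes=fset, node_type=ntype)


class SurvivalRecord(NamedTuple):
    sample: str
    time: float   # follow-up time, years
    event: bool   # relapse/metastasis observed


EXCLUDED = "excluded"


def dichotomize_survival(
    records: Iterable[SurvivalRecord], cutoff_years: float
) -> dict[str, object]:
    """Turn survival records into binary relapse classes.

    A sample whose event occurs within the cutoff is an early relapse (+1);
    an event-free sample followed at least to the cutoff (or an event after
    it) is a late/no relapse (-1); an event-free sample censored before the
    cutoff is excluded: it can be placed in neither class reliably.
    """
    if cutoff_years <= 0:
        raise ValueError("cutoff_years must be positive")
    out: dict[str, object] = {}
    for rec in records:
        if rec.time < 0:
            raise ValueError(f"negative follow-up time for sample {rec.sample!r}")
        if rec.event and rec.time <= cutoff_years:
            out[rec.sample] = 1
        elif rec.time >= cutoff_years:
            out[rec.sample] = -1
        else:
            out[rec.sample] = EXCLUDED
    return out


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = set(fields[2:])
    return sets
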