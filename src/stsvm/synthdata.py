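"""Synthetic networks and expression data with network-localized signal.

The generator emulates the statistical structure the smoothing method
assumes: a sparse scale-free interaction graph, two-class Gaussian
expression in which a *connected* module of genes is differentially
expressed, an optional bipartite miRNA->gene layer whose miRNAs targeting
the module are anti-correlated with it, and class imbalance of the kind
seen in relapse cohorts (defaults: 30% positives).

Everything is reproducible: a configuration plus a seed determines the
network, the planted module and the expression matrix exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .netio import MIRNA, MRNA, ExpressionDataset, Network


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    effect_size is the class mean shift in units of the within-class sd
    (noise_sd); mirna_effect likewise, applied with opposite sign to
    miRNAs targeting the planted module.
    """

    n_genes: int = 1000
    n_mirnas: int = 0
    n_pos: int = 30
    n_neg: int = 70
    network_model: str = "scale-free"  # or "erdos-renyi"
    attachment: int = 2                # preferential-attachment edges per node
    er_edge_prob: float = 0.004
    targets_per_mirna: int = 10
    module_size: int = 20
    effect_size: float = 0.8
    mirna_effect: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.module_size > self.n_genes:
            raise ValueError("module_size cannot exceed n_genes")
        if self.effect_size < 0 or self.mirna_effect < 0:
            raise ValueError("effect sizes must be non-negative")
        if self.network_model not in ("scale-free", "erdos-renyi"):
            raise ValueError(f"unknown network model {self.network_model!r}")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _mirna_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"mir-{i:0{width}d}" for i in range(n)]


def gen_network(config: SimulationConfig, seed: int = 0) -> Network:
    """Generate the simulation graph.

    Scale-free graphs use preferential attachment seeded with a single
    connected pair, so with attachment m the edge count is
    1 + m*(n_genes - 2) and the gene layer is connected.  The optional
    miRNA layer wires each miRNA to ``targets_per_mirna`` distinct random
    genes.
    """
    rng = np.random.default_rng(seed)
    genes = _gene_names(config.n_genes)
    if config.network_model == "scale-free":
        seed_size = max(2, config.attachment)
        g = nx.barabasi_albert_graph(
            config.n_genes,
            config.attachment,
            seed=int(rng.integers(2**31 - 1)),
            initial_graph=nx.complete_graph(seed_size),
        )
    else:
        g = nx.erdos_renyi_graph(
            config.n_genes, config.er_edge_prob, seed=int(rng.integers(2**31 - 1))
        )
    edges = [(genes[u], genes[v]) for u, v in g.edges() if u != v]
    node_type = {name: MRNA for name in genes}
    mirnas = _mirna_names(config.n_mirnas)
    for m in mirnas:
        node_type[m] = MIRNA
        n_targets = min(config.targets_per_mirna, config.n_genes)
        targets = rng.choice(config.n_genes, size=n_targets, replace=False)
        edges.extend((m, genes[t]) for t in targets)
    return Network.from_edges(
        edges, extra_nodes=genes + mirnas, node_type=node_type
    )


def plant_module(net: Network, module_size: int, seed: int = 0) -> list[str]:
    """Pick a connected gene module by breadth-first growth from a random
    seed gene (connectivity is the premise of network-localized signal)."""
    rng = np.random.default_rng(seed)
    genes = [n for n in net.nodes if net.type_of(n) == MRNA]
    adj: dict[str, list[str]] = {g: [] for g in genes}
    for u, v in net.edges:
        if net.type_of(u) == MRNA and net.type_of(v) == MRNA:
            adj[u].append(v)
            adj[v].append(u)
    for g in adj:
        adj[g].sort()
    start_candidates = [g for g in genes if adj[g]] or genes
    start = start_candidates[int(rng.integers(len(start_candidates)))]
    module = [start]
    in_module = {start}
    frontier = list(adj[start])
    while len(module) < module_size:
        frontier = [g for g in frontier if g not in in_module]
        if not frontier:
            # graph component exhausted; top up with random remaining genes
            rest = [g for g in genes if g not in in_module]
            if not rest:
                break
            pick = rest[int(rng.integers(len(rest)))]
            module.append(pick)
            in_module.add(pick)
            frontier = list(adj[pick])
            continue
        pick = frontier[int(rng.integers(len(frontier)))]
        module.append(pick)
        in_module.add(pick)
        frontier.extend(adj[pick])
    return sorted(module)


def gen_expression(
    net: Network, config: SimulationConfig, seed: int = 0
) -> tuple[ExpressionDataset, dict[str, list[str]]]:
    """Two-class Gaussian expression with a planted differential module.

    All features are Normal(0, noise_sd); in the positive class the planted
    module genes are shifted by +effect_size*noise_sd and (when
    mirna_effect > 0) the miRNAs targeting at least one module gene are
    shifted by -mirna_effect*noise_sd, mimicking repressive regulation.

    Returns the dataset and a truth dict with keys ``module_genes`` and
    ``shifted_mirnas``.
    """
    rng = np.random.default_rng(seed)
    module = plant_module(net, config.module_size, seed=int(rng.integers(2**31 - 1)))
    features = list(net.nodes)
    n_samples = config.n_pos + config.n_neg
    values = rng.normal(0.0, config.noise_sd, size=(len(features), n_samples))
    labels = np.array([1] * config.n_pos + [-1] * config.n_neg)
    pos = labels == 1
    idx = {f: i for i, f in enumerate(features)}
    for g in module:
        values[idx[g], pos] += config.effect_size * config.noise_sd
    shifted_mirnas: list[str] = []
    if config.mirna_effect > 0:
        module_set = set(module)
        for u, v in sorted(net.edges):
            m, g = None, None
            if net.type_of(u) == MIRNA and net.type_of(v) == MRNA:
                m, g = u, v
            elif net.type_of(v) == MIRNA and net.type_of(u) == MRNA:
                m, g = v, u
            if m is not None and g in module_set and m not in shifted_mirnas:
                shifted_mirnas.append(m)
        for m in shifted_mirnas:
            values[idx[m], pos] -= config.mirna_effect * config.noise_sd
    width = max(3, len(str(n_samples)))
    samples = [f"S{i:0{width}d}" for i in range(n_samples)]
    data = ExpressionDataset(
        features,
        samples,
        values,
        labels,
        {f: net.type_of(f) for f in features},
    )
    return data, {"module_genes": module, "shifted_mirnas": sorted(shifted_mirnas)}


def simulate(
    config: SimulationConfig, seed: int = 0
) -> tuple[Network, ExpressionDataset, dict[str, list[str]]]:
    """Generate a network and matching expression dataset in one call.

    The network and expression seeds are derived from ``seed`` so the pair
    is reproducible as a unit.
    """
    rng = np.random.default_rng(seed)
    net_seed = int(rng.integers(2**31 - 1))
    expr_seed = int(rng.integers(2**31 - 1))
    net = gen_network(config, seed=net_seed)
    data, truth = gen_expression(net, config, seed=expr_seed)
    return net, data, truth
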