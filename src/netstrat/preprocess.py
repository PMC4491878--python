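"""Event-to-gene expansion and network alignment.

Turns the binary event x sample profile into a samples x genes 0/1 matrix
whose columns line up with the interaction-network node set, ready for
propagation smoothing.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .data_io import EventMatrix

log = logging.getLogger(__name__)


def expand_events(events: EventMatrix) -> pd.DataFrame:
    """Expand events to member genes and merge per-gene indicators.

    Gene ``g`` is altered in sample ``s`` iff some event containing ``g`` is
    1 in ``s`` — genes in a recurrent copy-number region are treated equally
    as altered, and multiple alteration classes hitting the same gene (e.g.
    both gain and mutation) merge into a single indicator.  Returns a
    samples x genes int8 matrix.
    """
    events.validate()
    gene_to_events: dict[str, list[str]] = {}
    for event_id, genes in events.member_genes.items():
        for gene in genes:
            gene_to_events.setdefault(gene, []).append(event_id)

    columns = {}
    for gene in sorted(gene_to_events):
        columns[gene] = (
            events.values.loc[gene_to_events[gene]].max(axis=0).astype("int8")
        )
    matrix = pd.DataFrame(columns, index=events.sample_ids, dtype="int8")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate gene columns after expansion")

    zero_samples = matrix.index[matrix.sum(axis=1) == 0].tolist()
    if zero_samples:
        log.info("%d samples carry no alteration after expansion", len(zero_samples))
    return matrix


def align_to_network(
    genes: pd.DataFrame, net: nx.Graph, keep_all: bool = False
) -> tuple[pd.DataFrame, nx.Graph, pd.DataFrame]:
    """Project the gene matrix onto the interaction network.

    The network is restricted to its largest connected component containing
    at least one altered gene (``keep_all=True`` retains every node,
    isolated ones included); matrix columns become exactly the retained
    network genes — network genes never altered in any sample stay as
    all-zero columns, serving as propagation targets.

    Returns ``(aligned matrix, aligned network, coverage report)`` where the
    report lists every input gene with its total alteration count and
    whether/why it was dropped.
    """
    altered_genes = set(genes.columns[(genes != 0).any(axis=0)])
    net_nodes = set(net.nodes)
    in_net = [g for g in genes.columns if g in net_nodes]
    if not set(in_net) & altered_genes:
        raise ValueError("no altered gene maps onto the network")

    if keep_all:
        kept_nodes = set(net_nodes)
        subnet = net.copy()
    else:
        components = sorted(nx.connected_components(net), key=len, reverse=True)
        kept_nodes = None
        for comp in components:
            if comp & altered_genes:
                kept_nodes = comp
                break
        if kept_nodes is None:
            raise ValueError("no connected component contains an altered gene")
        subnet = net.subgraph(kept_nodes).copy()

    node_order = sorted(kept_nodes)
    aligned = genes.reindex(columns=node_order, fill_value=0).astype("int8")

    counts = genes.sum(axis=0)
    status = []
    for gene in genes.columns:
        if gene not in net_nodes:
            status.append("dropped:not_in_network")
        elif gene not in kept_nodes:
            status.append("dropped:outside_component")
        else:
            status.append("kept")
    report = pd.DataFrame(
        {"alteration_count": counts.astype(int), "status": status}, index=genes.columns
    )
    report.index.name = "gene"

    dropped = report[report["status"] != "kept"]
    log.info(
        "aligned to network: %d/%d genes kept (%d network nodes); "
        "%d genes dropped carrying %d alterations",
        len(genes.columns) - len(dropped), len(genes.columns), len(node_order),
        len(dropped), int(dropped["alteration_count"].sum()),
    )
    return aligned, subnet, report
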