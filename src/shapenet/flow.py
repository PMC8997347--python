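"""Maximum-flow extraction of the subnetwork linking a module to a TF.

Edge capacities are the unsigned semantic similarities (negative regulation
still carries capacity; supernode and feedback edges carry capacity 1).
The max-flow value equals the min-cut capacity; the reported subnetwork
keeps the top flow-carrying edges at a percentile threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class FlowResult:
    value: float
    edge_flow: pd.DataFrame  # columns source, target, flow, capacity
    source: str
    sink: str


def max_flow(
    net: nx.DiGraph,
    source: str,
    sink: str,
    capacities: dict[tuple[str, str], float] | None = None,
    undirected: bool = False,
) -> FlowResult:
    """Maximum flow from source to sink with similarity capacities.

    ``capacities`` overrides per-edge capacities; otherwise each edge uses
    its ``similarity`` attribute (falling back to |weight|).  With
    ``undirected=True`` every edge may carry flow both ways.
    """
    if source not in net or sink not in net:
        raise ValueError("source or sink absent from network")
    if source == sink:
        raise ValueError("source equals sink")
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes())
    for a, b, d in net.edges(data=True):
        cap = (capacities.get((a, b)) if capacities is not None
               else d.get("similarity", abs(d.get("weight", 1.0))))
        if cap is None:
            cap = 0.0
        if cap < 0:
            raise ValueError("capacities must be >= 0")
        g.add_edge(a, b, capacity=float(cap))
        if undirected and not g.has_edge(b, a):
            g.add_edge(b, a, capacity=float(cap))
    value, flow = nx.maximum_flow(g, source, sink)
    rows = [
        (a, b, f, g[a][b]["capacity"])
        for a, targets in flow.items()
        for b, f in targets.items()
        if f > 0
    ]
    edge_flow = pd.DataFrame(rows,
                             columns=["source", "target", "flow", "capacity"])
    return FlowResult(float(value), edge_flow, source, sink)


def top_flow_subnetwork(
    result: FlowResult, percentile: float = 99.0
) -> pd.DataFrame:
    """Edges at or above the given percentile of positive flows.

    The percentile (linear interpolation) is computed over flow-carrying
    edges only; ties at the threshold are included.
    """
    flows = result.edge_flow["flow"].to_numpy()
    positive = flows > 0
    if not positive.any():
        log.warning("no positive flow; empty subnetwork")
        return result.edge_flow.iloc[0:0]
    thresh = np.percentile(flows[positive], percentile)
    return result.edge_flow[positive & (flows >= thresh)].reset_index(drop=True)
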