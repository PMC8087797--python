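"""Stream-order computation on forest topologies."""

from __future__ import annotations

from typing import Optional

from .types import StreamNetwork


def strahler_orders(topology: dict[str, Optional[str]]) -> dict[str, int]:
    """Compute Strahler orders for every node of a stream forest.

    ``topology`` maps child segment id to parent segment id (roots map to
    ``None``). Leaves are order 1; a node whose maximum child order m is
    attained by two or more children gets order m + 1, otherwise m.

    Raises ``ValueError`` on cyclic topologies.
    """
    children: dict[Optional[str], list[str]] = {}
    nodes = set(topology)
    for child, parent in topology.items():
        children.setdefault(parent, []).append(child)
        if parent is not None and parent not in topology:
            raise ValueError(f"parent {parent!r} missing from topology")

    orders: dict[str, int] = {}
    # iterative postorder so deep trees do not hit the recursion limit
    roots = [n for n in nodes if topology[n] is None]
    if not roots and nodes:
        raise ValueError("topology has no root (cycle?)")
    stack: list[tuple[str, bool]] = [(r, False) for r in roots]
    visited = 0
    while stack:
        node, expanded = stack.pop()
        kids = children.get(node, [])
        if not expanded:
            stack.append((node, True))
            stack.extend((k, False) for k in kids)
            continue
        visited += 1
        if not kids:
            orders[node] = 1
        else:
            kid_orders = [orders[k] for k in kids]
            m = max(kid_orders)
            orders[node] = m + 1 if kid_orders.count(m) >= 2 else m
    if visited != len(nodes):
        raise ValueError("topology is not a forest (unreachable nodes or cycle)")
    return orders


def recompute_orders(network: StreamNetwork) -> dict[str, int]:
    """Strahler orders for a network's segments from its topology alone."""
    return strahler_orders(network.topology)
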