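"""Waller–Kraft gate evaluation and the upstream/downstream drive terms.

The Waller–Kraft operator blends the fuzzy-logic AND (minimum) and OR
(maximum) of a weight set through a single parameter ``r``::

    B(w; r) = r * min(w) + (1 - r) * max(w),   0 <= r <= 1

``r`` close to 1 behaves like AND, close to 0 like OR; the conventional
AND regime is r in [0.5, 1] and the default throughout the package is
r = 0.75.

Each node ``k`` with at least one outgoing edge carries a single gate
value ``B_k`` computed over its *own* outgoing weight set.  A target
protein ``i`` is then driven by

* upstream:   sum over immediate upstream nodes k of  B_k * x_k
* downstream: B_i * x_i

which are the activation and inactivation drive terms of the activity
equation (see :mod:`boolsde.engine`).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .network import SignalingNetwork

__all__ = [
    "waller_kraft",
    "gate_values",
    "upstream_drive",
    "downstream_drive",
]

AND_REGIME = (0.5, 1.0)  # r range conventionally read as AND logic


def waller_kraft(weights: Sequence[float], r: float) -> float:
    """Evaluate the Waller–Kraft operator on a non-empty weight set.

    Returns ``r*min(weights) + (1-r)*max(weights)``, which always lies
    between the minimum and maximum of the weights.  ``r=1`` reduces to
    the fuzzy AND (min), ``r=0`` to the fuzzy OR (max).
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("waller_kraft requires a non-empty weight list")
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"operator parameter r={r} outside [0, 1]")
    if np.any(w < 0.0) or np.any(w > 1.0):
        raise ValueError("weights must lie in [0, 1]")
    return float(r * w.min() + (1.0 - r) * w.max())


def gate_values(net: SignalingNetwork, r: float) -> np.ndarray:
    """Per-node gate vector B over each node's outgoing weights.

    Nodes with no outgoing edges (terminals) get 0.0 by convention:
    their downstream drive vanishes and they never appear as an upstream
    neighbor of anything.
    """
    values = np.zeros(len(net.nodes))
    for i, node_id in enumerate(net.node_ids):
        weights = net.outgoing_weights(node_id)
        if weights:
            values[i] = waller_kraft(weights, r)
    return values


def _activity_vector(
    net: SignalingNetwork,
    activities: Mapping[str, float] | Sequence[float] | np.ndarray,
) -> np.ndarray:
    if isinstance(activities, Mapping):
        return np.array([activities[node_id] for node_id in net.node_ids])
    x = np.asarray(activities, dtype=float)
    if x.shape != (len(net.nodes),):
        raise ValueError(
            f"activity vector has shape {x.shape}, expected ({len(net.nodes)},)"
        )
    return x


def upstream_drive(
    net: SignalingNetwork,
    target: str,
    activities: Mapping[str, float] | Sequence[float] | np.ndarray,
    r: float,
) -> float:
    """Activation drive on ``target``: sum of B_k * x_k over upstream k.

    B_k is the Waller–Kraft gate over upstream node k's full outgoing
    weight set.  Receptors (no upstream) get 0.
    """
    x = _activity_vector(net, activities)
    total = 0.0
    for k in net.in_nodes(target):
        b_k = waller_kraft(net.outgoing_weights(k), r)
        total += b_k * x[net.node_index(k)]
    return total


def downstream_drive(
    net: SignalingNetwork,
    target: str,
    activities: Mapping[str, float] | Sequence[float] | np.ndarray,
    r: float,
) -> float:
    """Inactivation drive on ``target``: B_i * x_i over its own outgoing
    weights; 0 for terminal nodes (no outgoing edges)."""
    x = _activity_vector(net, activities)
    weights = net.outgoing_weights(target)
    if not weights:
        return 0.0
    return waller_kraft(weights, r) * x[net.node_index(target)]
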