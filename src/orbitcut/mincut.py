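"""Minimum s-t cut on a capacitated directed graph.

The cut is obtained from a maximum flow (strong duality): scipy's Dinic
solver computes the flow, and the source side of the minimum cut is the set
of nodes reachable from the source in the residual graph.

scipy's solver works on integer capacities. Float capacities are quantised
by a fixed scale factor of 2**16 (rounding to ~1.5e-5 of a unit); inputs
that are already integral are solved exactly at scale 1. Hard constraints
must be encoded as large *finite* capacities by the caller, never infinity.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

__all__ = ["solve_min_cut"]

_FLOAT_SCALE = 2 ** 16
_CAP_LIMIT = 2 ** 30


def solve_min_cut(capacity, source: int, sink: int) -> tuple[float, np.ndarray]:
    """Solve the minimum s-t cut of a directed capacitated graph.

    Parameters
    ----------
    capacity
        Square dense or sparse matrix; entry (i, j) is the capacity of the
        directed edge i -> j. All capacities must be finite and >= 0.
    source, sink
        Node indices of s and t.

    Returns
    -------
    cut_value : float
        The minimum cut value (equals the maximum flow value).
    source_side : ndarray of int
        Sorted node indices on the source side of the cut; contains
        ``source`` and never ``sink``.
    """
    cap = sparse.csr_matrix(capacity)
    if cap.shape[0] != cap.shape[1]:
        raise ValueError(f"capacity matrix must be square, got {cap.shape}")
    n = cap.shape[0]
    if not (0 <= source < n and 0 <= sink < n) or source == sink:
        raise ValueError(f"invalid source/sink ({source}, {sink}) for {n} nodes")
    data = np.asarray(cap.data, dtype=np.float64)
    if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
        raise ValueError("capacities must be finite and non-negative")

    # scipy's solver needs every capacity within int32; pick the largest
    # scale (up to 2**16) keeping the maximum capacity below 2**30
    max_cap = float(data.max()) if data.size else 0.0
    integral = data.size == 0 or np.all(data == np.round(data))
    if integral and max_cap <= _CAP_LIMIT:
        scale = 1.0
    else:
        scale = min(float(_FLOAT_SCALE), _CAP_LIMIT / max(max_cap, 1.0))
    icap = cap.copy()
    icap.data = np.round(data * scale).astype(np.int32)
    icap.eliminate_zeros()
    icap = sparse.csr_matrix(icap)
    if icap.nnz == 0:
        # no edges at all: zero flow, source side is just the source
        return 0.0, np.array([source])

    res = maximum_flow(icap, source, sink)
    residual = (icap - res.flow).tocsr()
    residual.data = (residual.data > 0).astype(np.int8)
    residual.eliminate_zeros()
    order = breadth_first_order(residual, source, directed=True, return_predecessors=False)
    source_side = np.sort(np.asarray(order))
    if sink in source_side:
        raise RuntimeError("sink reachable in residual graph; max-flow did not converge")
    return float(res.flow_value) / scale, source_side
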