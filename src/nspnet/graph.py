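"""Classical weighted graph measures used as the comparison baseline."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import AtlasMap
from .fc import FCMatrix, FCWindowSeries
from .dynamics import strength_and_variability


def node_strength(C: FCMatrix | np.ndarray) -> np.ndarray:
    """Weighted degree: row sum excluding the self-connection."""
    A = C.C if isinstance(C, FCMatrix) else np.asarray(C, dtype=float)
    return A.sum(axis=1) - np.diag(A)


def participation_coefficient(C: FCMatrix | np.ndarray, atlas: AtlasMap) -> np.ndarray:
    """Weighted participation coefficient over the system partition.

    P_j = 1 - sum_s (k_js / k_j)^2 with k_js the strength of node j into
    system s; P = 0 for an isolated node by convention.
    """
    A = C.C if isinstance(C, FCMatrix) else np.asarray(C, dtype=float)
    n = A.shape[0]
    if atlas.n_regions != n:
        raise KeyError("atlas does not cover all regions")
    W = A - np.diag(np.diag(A))
    k = W.sum(axis=1)
    p = np.zeros(n)
    nz = k > 0
    frac_sq = np.zeros(n)
    for system in atlas.system_names:
        idx = atlas.indices(system)
        ks = W[:, idx].sum(axis=1)
        frac_sq[nz] += (ks[nz] / k[nz]) ** 2
    p[nz] = 1.0 - frac_sq[nz]
    return p


def windowed_metrics(
    windows: FCWindowSeries, atlas: AtlasMap
) -> tuple[np.ndarray, np.ndarray]:
    """(n_windows x n_regions) strength and participation trajectories."""
    s = np.stack([node_strength(w) for w in windows])
    p = np.stack([participation_coefficient(w, atlas) for w in windows])
    return s, p


def metric_variability(windowed: np.ndarray) -> np.ndarray:
    """Sample SD over windows (axis 0)."""
    _, sd = strength_and_variability(windowed)
    return sd


def graph_metric_table(
    subject_id: str,
    group: str,
    static_fc: FCMatrix,
    windows: FCWindowSeries,
    atlas: AtlasMap,
) -> pd.DataFrame:
    """Tidy per-region table: graph_degree, graph_pc and their variabilities."""
    deg = node_strength(static_fc)
    pc = participation_coefficient(static_fc, atlas)
    s_t, p_t = windowed_metrics(windows, atlas)
    rows = []
    for j, rid in enumerate(static_fc.region_ids):
        rows.append((subject_id, group, "region", rid, "graph_degree", deg[j]))
        rows.append((subject_id, group, "region", rid, "graph_pc", pc[j]))
        rows.append(
            (subject_id, group, "region", rid, "graph_degree_var",
             metric_variability(s_t[:, [j]])[0])
        )
        rows.append(
            (subject_id, group, "region", rid, "graph_pc_var",
             metric_variability(p_t[:, [j]])[0])
        )
    return pd.DataFrame(
        rows, columns=["subject", "group", "scope", "unit", "measure", "value"]
    )
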