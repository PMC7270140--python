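"""Location-specific cell-cytokine correlation networks.

For each tumour location, every (immune cell type, cytokine gene) pair is
scored by the Pearson correlation between deconvolved cell fractions and
cytokine expression across that location's samples.  Three summaries follow:

* a thresholded bipartite network (edge kept iff rho > 0.6 and p < 0.05)
  mirroring the published network figures, exportable to GraphML;
* per-cell **connectivity**: the sum of all significant (p < 0.05)
  correlations between that cell and the cytokine panel -- a scalar measure
  of how transcriptionally "active" the cell type is (signed sum by default,
  absolute-value sum available);
* **unweighted eigenvector centrality** over the binary significance graph
  (adjacency = 1 iff p < 0.05), computed by power iteration and normalized
  to unit Euclidean norm; nodes outside the principal connected component
  score 0.

Between-location contrasts (convexity minus skull base) of connectivity and
centrality rank the cell types whose cytokine engagement differs by tumour
location.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .deconvolve import CellFractions
from .errors import DegenerateInputError, ValidationError
from .stats import pearson_with_p
from .types import ExpressionMatrix

EDGE_COLUMNS = ("cell_type", "cytokine", "rho", "p", "n", "location", "degenerate")


def cell_cytokine_edges(fractions: CellFractions, expression: ExpressionMatrix,
                        panel, metadata: pd.DataFrame, location: str
                        ) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation table for every (cell type, cytokine) pair within
    one location group.

    Returns (edge table, panel genes missing from the expression matrix).
    Cell fractions with zero variance across the location's samples produce
    degenerate-flagged rows (rho 0, p 1) rather than NaNs or errors.
    """
    meta = metadata.set_index("sample_id")
    in_expr = set(expression.sample_ids)
    samples = [s for s in fractions.sample_ids
               if s in in_expr and meta.loc[s, "location"] == location]
    if len(samples) < 3:
        raise DegenerateInputError(
            f"location {location!r} has {len(samples)} usable samples (need >= 3)")
    gidx = expression.gene_index()
    missing = [g for g in panel if g not in gidx]
    present = [g for g in panel if g in gidx]
    frac = fractions.to_frame().loc[samples]
    expr_cols = [expression.sample_ids.index(s) for s in samples]
    rows = []
    n = len(samples)
    for cell in fractions.cell_type_names:
        f = frac[cell].to_numpy()
        f_degenerate = np.ptp(f) == 0
        for g in present:
            e = expression.values[gidx[g], expr_cols]
            if f_degenerate or np.ptp(e) == 0:
                rows.append((cell, g, 0.0, 1.0, n, location, True))
                continue
            res = pearson_with_p(f, e)
            rows.append((cell, g, res.rho, res.p, n, location, False))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS), missing


def build_network(edges: pd.DataFrame, rho_min: float = 0.6, alpha: float = 0.05,
                  two_sided: bool = False) -> nx.Graph:
    """Bipartite cell-cytokine graph after effect-size and significance
    thresholding.

    Nodes are all cell types and all panel cytokines in the edge table; an
    edge is kept iff ``rho > rho_min`` (or ``|rho| > rho_min`` with
    ``two_sided``) and ``p < alpha``, weighted by rho.
    """
    g = nx.Graph()
    for cell in pd.unique(edges["cell_type"]):
        g.add_node(cell, kind="cell", bipartite=0)
    for cyt in pd.unique(edges["cytokine"]):
        g.add_node(cyt, kind="cytokine", bipartite=1)
    for row in edges.itertuples(index=False):
        effect = abs(row.rho) if two_sided else row.rho
        if effect > rho_min and row.p < alpha:
            g.add_edge(row.cell_type, row.cytokine, weight=float(row.rho))
    return g


def connectivity(edges: pd.DataFrame, alpha: float = 0.05,
                 mode: str = "signed") -> pd.Series:
    """Per-cell connectivity: sum of significant correlations with the panel.

    ``signed`` (default) sums raw rho over rows with ``p < alpha`` (no
    effect-size threshold); ``absolute`` sums ``|rho|``.
    """
    if mode not in ("signed", "absolute"):
        raise ValidationError(f"unknown connectivity mode {mode!r}")
    sig = edges[edges["p"] < alpha]
    vals = sig["rho"] if mode == "signed" else sig["rho"].abs()
    out = vals.groupby(sig["cell_type"]).sum()
    return out.reindex(pd.unique(edges["cell_type"]), fill_value=0.0).rename("connectivity")


def eigenvector_centrality(edges: pd.DataFrame, alpha: float = 0.05,
                           tol: float = 1e-12, max_iter: int = 100000) -> pd.Series:
    """Unweighted eigenvector centrality of the binary significance graph.

    Adjacency is 1 iff ``p < alpha``; the principal eigenvector is found by
    power iteration (on ``A + I`` to avoid bipartite oscillation) restricted
    to the connected component with the largest principal eigenvalue, and
    normalized to unit Euclidean norm.  All other nodes -- including
    isolated ones -- score 0; an edgeless graph returns all zeros.
    """
    cells = list(pd.unique(edges["cell_type"]))
    cyts = list(pd.unique(edges["cytokine"]))
    nodes = cells + cyts
    index = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for row in edges.itertuples(index=False):
        if row.p < alpha:
            i, j = index[row.cell_type], index[row.cytokine]
            A[i, j] = A[j, i] = 1.0
    cent = np.zeros(len(nodes))
    g = nx.from_numpy_array(A)
    components = [sorted(c) for c in nx.connected_components(g) if len(c) > 1]
    if components:
        best = None
        for comp in components:
            sub = A[np.ix_(comp, comp)]
            lam, vec = _power_iteration(sub, tol=tol, max_iter=max_iter)
            # ties between components broken by smallest member index so the
            # "principal component" is well defined
            if best is None or lam > best[0] + 1e-9 or \
                    (abs(lam - best[0]) <= 1e-9 and comp[0] < best[1][0]):
                best = (lam, comp, vec)
        _, comp, vec = best
        cent[comp] = vec
    return pd.Series(cent, index=nodes, name="centrality")


def _power_iteration(A: np.ndarray, tol: float, max_iter: int) -> tuple[float, np.ndarray]:
    n = A.shape[0]
    v = np.full(n, 1.0 / np.sqrt(n))
    shifted = A + np.eye(n)  # same eigenvectors, strictly dominant top eigenvalue
    for _ in range(max_iter):
        w = shifted @ v
        w /= np.linalg.norm(w)
        if np.abs(w - v).max() < tol:
            v = w
            break
        v = w
    v = np.abs(v)  # Perron vector of a connected non-negative matrix
    lam = float(v @ A @ v)
    return lam, v / np.linalg.norm(v)


@dataclass
class NetworkSummary:
    """Per-location network statistics."""

    location: str
    connectivity: pd.Series        # per cell type
    centrality: pd.Series          # per node (cells and cytokines)
    mode: str                      # connectivity mode used
    alpha: float


def summarize_location(edges: pd.DataFrame, alpha: float = 0.05,
                       mode: str = "signed") -> NetworkSummary:
    """Connectivity + centrality for one location's edge table."""
    locs = pd.unique(edges["location"])
    if len(locs) != 1:
        raise ValidationError("edge table must cover exactly one location")
    return NetworkSummary(
        location=str(locs[0]),
        connectivity=connectivity(edges, alpha=alpha, mode=mode),
        centrality=eigenvector_centrality(edges, alpha=alpha),
        mode=mode, alpha=alpha)


def compare_locations(convexity: NetworkSummary, skull_base: NetworkSummary
                      ) -> pd.DataFrame:
    """Convexity-minus-skull-base contrasts of connectivity and centrality.

    Positive values mean greater connectivity/centrality in convexity
    tumours; the table is sorted by the connectivity contrast, descending.
    """
    cells_c = set(convexity.connectivity.index)
    cells_s = set(skull_base.connectivity.index)
    if cells_c != cells_s:
        raise ValidationError(
            f"cell-type sets differ between locations: {sorted(cells_c ^ cells_s)}")
    cells = list(convexity.connectivity.index)
    dconn = convexity.connectivity[cells] - skull_base.connectivity[cells]
    dcent = (convexity.centrality.reindex(cells, fill_value=0.0)
             - skull_base.centrality.reindex(cells, fill_value=0.0))
    out = pd.DataFrame({
        "delta_connectivity": dconn,
        "delta_centrality": dcent,
    })
    out["connectivity_rank"] = out["delta_connectivity"].rank(ascending=False, method="min").astype(int)
    out["centrality_rank"] = out["delta_centrality"].rank(ascending=False, method="min").astype(int)
    return out.sort_values("delta_connectivity", ascending=False)


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
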