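"""Gaussian graphical model over the metabolite panel.

Edges of a GGM are *full-order partial correlations*: the correlation
between two metabolites after conditioning on every other metabolite and
on the covariates (age, sex, FFMI, and batch where present).  Covariates
are removed first by residualisation; on the residual covariance S the
partial correlations come from the precision matrix Ω = S⁻¹,

    ρ_ij = −ω_ij / sqrt(ω_ii ω_jj) .

Each coefficient is tested with the Fisher z transform,
z = atanh(r)·sqrt(n − k − 3) with k the number of conditioned variables
(covariates plus the M−2 other metabolites), under Bonferroni control at
α = 0.01 over all M(M−1)/2 pairs.  An edge enters the network only if it
is significant AND |ρ| is at or above a magnitude cut-off (default 0.3).
Nodes carry the association colouring: red for a significant positive
FFMI association, blue for negative, white otherwise.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_CONTROLS = ("age", "sex", "ffmi")


@dataclass
class PartialCorrelationMatrix:
    """Symmetric matrix of full-order partial correlations.

    ``n_controls`` counts every conditioned variable for one pair:
    the covariates plus the other M−2 metabolites.
    """

    values: pd.DataFrame
    n_samples: int
    n_controls: int
    regularised: bool = False

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GgmNetwork:
    """Association-coloured metabolite network (wraps ``networkx.Graph``)."""

    graph: nx.Graph
    r_cutoff: float
    alpha: float


def partial_correlations(
    transformed: pd.DataFrame,
    pheno: pd.DataFrame,
    controls: tuple[str, ...] = DEFAULT_CONTROLS,
    ridge: float = 0.0,
) -> PartialCorrelationMatrix:
    """Full-order partial correlations, covariates residualised out first.

    ``transformed`` is the QC'd, transformed metabolite matrix.  A ridge
    λ > 0 is added to the residual covariance diagonal for near-singular
    panels and marks the result ``regularised``.
    """
    Y = transformed.loc[pheno.index].to_numpy(dtype=float)
    n, m = Y.shape
    k = len(controls) + m - 2
    if n <= m + len(controls) + 3:
        raise ValueError(
            "need n_subjects > n_metabolites + n_covariates + 3; "
            "consider the ridge option"
        )
    cols = [np.ones(n)]
    for c in controls:
        col = pheno[c]
        if c == "batch":
            d = pd.get_dummies(col, drop_first=True, dtype=float)
            cols.extend(d[cc].to_numpy() for cc in d.columns)
            k += d.shape[1] - 1
            continue
        cols.append(col.to_numpy(dtype=float))
    X = np.column_stack(cols)
    resid = Y - X @ np.linalg.lstsq(X, Y, rcond=None)[0]
    S = np.cov(resid, rowvar=False, ddof=1)
    if ridge > 0:
        S = S + ridge * np.eye(m)
    try:
        omega = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "residual covariance is singular; pass ridge > 0 to regularise"
        ) from exc
    d = np.sqrt(np.diag(omega))
    pc = -omega / np.outer(d, d)
    pc = np.clip((pc + pc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(pc, 1.0)
    values = pd.DataFrame(pc, index=transformed.columns,
                          columns=transformed.columns)
    return PartialCorrelationMatrix(values, n_samples=n, n_controls=k,
                                    regularised=ridge > 0)


def test_edges(pcm: PartialCorrelationMatrix, alpha: float = 0.01) -> pd.DataFrame:
    """Fisher-z test of every pair; Bonferroni significance over C(M,2).

    Returns one row per unordered pair with columns
    (m1, m2, r_partial, p, significant).
    """
    m = len(pcm.metabolites)
    dof = pcm.n_samples - pcm.n_controls - 3
    if dof <= 0:
        raise ValueError("n - k - 3 <= 0: partial correlations under-determined")
    n_pairs = m * (m - 1) // 2
    bound = alpha / n_pairs
    rows = []
    vals = pcm.values.to_numpy()
    names = pcm.metabolites
    for i in range(m):
        for j in range(i + 1, m):
            r = float(vals[i, j])
            z = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15)) * math.sqrt(dof)
            p = float(2.0 * stats.norm.sf(abs(z)))
            rows.append((names[i], names[j], r, p, p < bound))
    return pd.DataFrame(rows,
                        columns=["m1", "m2", "r_partial", "p", "significant"])


def build_network(
    pcm: PartialCorrelationMatrix,
    edge_tests: pd.DataFrame,
    assoc_results: pd.DataFrame | None = None,
    r_cutoff: float = 0.3,
    alpha: float = 0.01,
) -> GgmNetwork:
    """Network with edges that are significant AND |r| ≥ cutoff (inclusive).

    Node colours follow the association results: red = significant
    positive FFMI estimate, blue = significant negative, white otherwise
    (or when the metabolite has no association row, with a warning).
    """
    g = nx.Graph()
    assoc = (assoc_results.set_index("trait")
             if assoc_results is not None else None)
    for met in pcm.metabolites:
        colour, beta, p = "white", float("nan"), float("nan")
        if assoc is not None and met in assoc.index:
            row = assoc.loc[met]
            beta, p = float(row["beta"]), float(row["p"])
            if bool(row["significant"]):
                colour = "red" if beta > 0 else "blue"
        elif assoc is not None:
            warnings.warn(f"no association result for {met!r}; node white",
                          stacklevel=2)
        g.add_node(met, colour=colour, beta=beta, p=p)
    for row in edge_tests.itertuples(index=False):
        if row.significant and abs(row.r_partial) >= r_cutoff:
            g.add_edge(row.m1, row.m2, r_partial=float(row.r_partial),
                       p_partial=float(row.p))
    return GgmNetwork(graph=g, r_cutoff=r_cutoff, alpha=alpha)


def export_network(net: GgmNetwork, path, format: str = "graphml") -> None:
    """Write the network with node/edge attributes.

    ``graphml`` and ``gml`` round-trip through :func:`import_network`;
    ``tsv_edgelist`` is a plain mirror of the edge table.
    """
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "gml":
        nx.write_gml(net.graph, path)
    elif format == "tsv_edgelist":
        rows = [
            {"m1": a, "m2": b, **attrs}
            for a, b, attrs in net.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["m1", "m2", "r_partial", "p_partial"]
                     ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def import_network(path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "gml":
        return nx.read_gml(path)
    raise ValueError(f"unknown format {format!r}")
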