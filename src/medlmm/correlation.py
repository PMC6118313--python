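"""Expression-phenotype correlation screening and network construction.

The screen computes, per gene, Spearman's rho (with a two-sided, tie-
corrected p-value) and the squared Pearson correlation against the
phenotype, keeps genes detectable in more than a minimum fraction of
lines, and selects correlated genes by Benjamini-Hochberg FDR control.
The selected genes plus the phenotype then form a correlation network in
which an edge is drawn whenever the pairwise Spearman p-value survives a
Bonferroni threshold ``alpha_fwer / C(n_nodes, 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "CorrelationNetwork",
    "detectability_filter",
    "phenotype_correlations",
    "bh_fdr",
    "build_network",
]

EXACT_PERMUTATION_N = 10  # below this, Spearman p by exact permutation


@dataclass
class CorrelationResult:
    gene: str
    rho: float
    rho_p: float
    r2: float
    defined: bool = True


@dataclass
class CorrelationNetwork:
    nodes: list[str]
    edges: pd.DataFrame  # columns: node_a, node_b, coefficient, p_value, sign
    alpha_fwer: float
    n_tests: int

    @property
    def threshold(self) -> float:
        return self.alpha_fwer / self.n_tests

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for rec in self.edges.itertuples(index=False):
            g.add_edge(
                rec.node_a, rec.node_b, coefficient=rec.coefficient,
                p_value=rec.p_value, sign=rec.sign,
            )
        return g


def detectability_filter(expr: pd.DataFrame, min_fraction: float = 0.1) -> list[str]:
    """Genes whose fraction of lines with expression > 0 strictly exceeds
    ``min_fraction`` ("detectable" means a value above the zero floor)."""
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    frac = (expr.to_numpy(dtype=float) > 0).mean(axis=0)
    return [g for g, f in zip(expr.columns, frac) if f > min_fraction]


def _spearman(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    n = a.shape[0]
    if n < EXACT_PERMUTATION_N:
        res = stats.permutation_test(
            (a,),
            lambda x: stats.spearmanr(x, b).statistic,
            permutation_type="pairings",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        rho = stats.spearmanr(a, b).statistic
        return float(rho), float(res.pvalue)
    res = stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def phenotype_correlations(expr: pd.DataFrame, y: np.ndarray) -> list[CorrelationResult]:
    """Per-gene Spearman rho/p and squared Pearson r against the phenotype.

    Constant expression columns yield an undefined result (``defined=False``)
    and are excluded from downstream testing.
    """
    y = np.asarray(y, dtype=float)
    if expr.shape[0] != y.shape[0]:
        raise ValueError("expression and phenotype line counts differ")
    if y.shape[0] < 4:
        raise ValueError("need at least 4 lines")
    out = []
    for gene in expr.columns:
        e = expr[gene].to_numpy(dtype=float)
        if np.ptp(e) == 0:
            out.append(CorrelationResult(str(gene), np.nan, np.nan, np.nan, defined=False))
            continue
        rho, rho_p = _spearman(e, y)
        r = stats.pearsonr(e, y).statistic
        out.append(CorrelationResult(str(gene), rho, rho_p, float(r**2)))
    return out


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up discoveries at FDR level ``q``.

    Returns a boolean mask: ranks up to the largest k with
    ``p_(k) <= k q / m`` are discoveries.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def build_network(
    expr_sub: pd.DataFrame,
    y: np.ndarray,
    alpha_fwer: float = 0.01,
    phenotype_name: str = "phenotype",
) -> CorrelationNetwork:
    """Bonferroni-thresholded pairwise Spearman network over genes + phenotype.

    All ``C(g + 1, 2)`` pairs among the gene columns and the phenotype are
    tested; an edge is kept iff its p-value is at most
    ``alpha_fwer / n_tests``, with the correlation sign recorded.
    """
    cols = list(expr_sub.columns)
    nodes = cols + [phenotype_name]
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes")
    data = {c: expr_sub[c].to_numpy(dtype=float) for c in cols}
    data[phenotype_name] = np.asarray(y, dtype=float)
    n_tests = comb(len(nodes), 2)
    threshold = alpha_fwer / n_tests
    rows = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            rho, p = _spearman(data[a], data[b])
            if p <= threshold:
                rows.append(
                    {
                        "node_a": a,
                        "node_b": b,
                        "coefficient": rho,
                        "p_value": p,
                        "sign": "+" if rho >= 0 else "-",
                    }
                )
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "coefficient", "p_value", "sign"])
    return CorrelationNetwork(nodes=nodes, edges=edges, alpha_fwer=alpha_fwer, n_tests=n_tests)
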