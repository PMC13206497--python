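"""Rank correlations, FDR control, and co-occurrence / taxon-volatile networks.

The statistical primitives are implemented here rather than delegated:
Spearman's rho is the Pearson correlation of mid-rank vectors, with a
two-sided p-value computed by exhaustive permutation for n <= 9 samples
and by the t approximation (n - 2 degrees of freedom) otherwise, and
Benjamini-Hochberg q-values follow the step-up definition
q_(i) = min_{j >= i} m p_(j) / j capped at 1. Both are cross-checked
against scipy/statsmodels in the test suite.

Two co-occurrence networks are distinguished: the *analysis* network
(|rho| > 0.6, q < 0.05) from which hub taxa are read off (degree strictly
greater than 9 by default), and the sparser *display* network
(|rho| > 0.8, p < 0.01) used only for visualization. Taxon-volatile
association networks use their own threshold family (|rho| > 0.5,
p < 0.05, q < 0.05) and a taxon qualifies as flavor-associated when it is
significantly correlated with at least five volatile compounds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datamodel_io import AbundanceTable, AnalysisConfig, VolatileTable

logger = logging.getLogger("syncom_core")

EXACT_PERMUTATION_MAX_N = 9

NetworkKind = Literal["analysis", "display", "taxon_volatile"]


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4)
def _permutation_indices(n: int) -> np.ndarray:
    """All n! permutations of range(n), cached per n (n <= 9)."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-rank vectors (ties receive
    average ranks). For n <= 9 the p-value is exact: the proportion of
    all n! permutations of one rank vector with |rho| at least the
    observed |rho| (within 1e-12). For larger n the usual t
    approximation with n - 2 degrees of freedom is used.

    Constant input yields (nan, nan); callers building networks exclude
    such flagged pairs rather than erroring.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))

    rx = _midranks(x)
    ry = _midranks(y)
    rho = _pearson(rx, ry)

    if n <= EXACT_PERMUTATION_MAX_N:
        perms = _permutation_indices(n)
        cx = rx - rx.mean()
        cy = ry - ry.mean()
        denom = np.sqrt((cx @ cx) * (cy @ cy))
        rho_perm = (cy[perms] @ cx) / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        p = _t_pvalue(np.array([rho]), n)[0]
    return float(rho), float(p)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))


def _t_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation, df = n - 2."""
    r = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(t)] = 0.0  # |rho| == 1 exactly
    return np.minimum(p, 1.0)


def _pairwise_spearman(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """rho and p matrices for all row pairs of ``values`` (rows x samples).

    Vectorized rank correlation; p-values dispatch on sample count the
    same way :func:`spearman` does.
    """
    n = values.shape[1]
    ranks = stats.rankdata(values, axis=1, method="average")
    if n <= EXACT_PERMUTATION_MAX_N:
        m = values.shape[0]
        rho = np.eye(m)
        p = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                rho[i, j], p[i, j] = spearman(values[i], values[j])
                rho[j, i], p[j, i] = rho[i, j], p[i, j]
        return rho, p
    z = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((z * z).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (z @ z.T) / np.outer(norms, norms)
    p = _t_pvalue(rho, n)
    return rho, p


def _cross_spearman(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """rho and p for every (row of a, row of b) pair; shared sample axis."""
    n = a.shape[1]
    if n <= EXACT_PERMUTATION_MAX_N:
        rho = np.zeros((a.shape[0], b.shape[0]))
        p = np.zeros_like(rho)
        for i in range(a.shape[0]):
            for j in range(b.shape[0]):
                rho[i, j], p[i, j] = spearman(a[i], b[j])
        return rho, p
    ra = stats.rankdata(a, axis=1, method="average")
    rb = stats.rankdata(b, axis=1, method="average")
    za = ra - ra.mean(axis=1, keepdims=True)
    zb = rb - rb.mean(axis=1, keepdims=True)
    na = np.sqrt((za * za).sum(axis=1))
    nb = np.sqrt((zb * zb).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (za @ zb.T) / np.outer(na, nb)
    p = _t_pvalue(rho, n)
    return rho, p


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR
# ---------------------------------------------------------------------------


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j: p_(j) >= p_(i)} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    """One tested pair: names, rho, raw p, and BH-adjusted q."""

    item_a: str
    item_b: str
    rho: float
    p: float
    q: float


@dataclass
class CorrelationNetwork:
    """Undirected correlation network with per-edge rho/p/q."""

    kind: NetworkKind
    nodes: list[str]
    edges: list[CorrelationResult] = field(default_factory=list)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for e in self.edges:
            if e.item_a == e.item_b:
                raise ValueError(f"self-loop on {e.item_a!r}")
            if e.item_a not in node_set or e.item_b not in node_set:
                raise ValueError(f"edge ({e.item_a!r}, {e.item_b!r}) references unknown node")

    @property
    def degree(self) -> dict[str, int]:
        d = {n: 0 for n in self.nodes}
        for e in self.edges:
            d[e.item_a] += 1
            d[e.item_b] += 1
        return d

    def has_edge(self, a: str, b: str) -> bool:
        return any({e.item_a, e.item_b} == {a, b} for e in self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(kind=self.kind)
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.item_a, e.item_b, rho=e.rho, p=e.p, q=e.q)
        return g

    def to_edge_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.item_a, e.item_b, e.rho, e.p, e.q) for e in self.edges],
            columns=["source", "target", "rho", "p", "q"],
        )

    def write_edgelist(self, path: str | Path) -> None:
        self.to_edge_dataframe().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_degree_table(self, path: str | Path) -> None:
        deg = self.degree
        pd.DataFrame(
            sorted(deg.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["node", "degree"],
        ).to_csv(path, sep="\t", index=False)


def _drop_constant_rows(values: np.ndarray, names: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    keep = np.ptp(values, axis=1) > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        logger.warning(
            "dropping %d constant row(s) from correlation testing: %s",
            len(dropped), ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    return values[keep], [n for n, k in zip(names, keep) if k]


def build_cooccurrence(
    table: AbundanceTable,
    config: AnalysisConfig | None = None,
    kind: Literal["analysis", "display"] = "analysis",
    clr: bool = False,
) -> CorrelationNetwork:
    """Taxon co-occurrence network from all pairwise Spearman tests.

    BH correction is applied over the full family of taxon-pair tests.
    Analysis edges require |rho| > ``edge_r_threshold`` and
    q < ``edge_q_threshold``; display edges require
    |rho| > ``display_r_threshold`` and p < ``display_p_threshold``.
    Constant taxa (e.g., always absent) are dropped with a warning.
    ``clr=True`` correlates centered log-ratio values instead of relative
    abundances (opt-in compositionality correction).
    """
    config = config or AnalysisConfig()
    if not table.normalized:
        raise ValueError("co-occurrence network requires a normalized abundance table")
    if len(table.samples) < 4:
        raise ValueError(f"need at least 4 samples, got {len(table.samples)}")
    if len(table.taxa) < 2:
        raise ValueError("need at least 2 taxa")

    source = clr_transform(table) if clr else table
    values, names = _drop_constant_rows(source.values, source.taxa)
    if len(names) < 2:
        return CorrelationNetwork(kind=kind, nodes=list(table.taxa))

    rho, p = _pairwise_spearman(values)
    iu = np.triu_indices(len(names), k=1)
    q_flat = bh_fdr(p[iu])

    if kind == "analysis":
        def passes(r, pv, qv):
            return abs(r) > config.edge_r_threshold and qv < config.edge_q_threshold
    elif kind == "display":
        def passes(r, pv, qv):
            return abs(r) > config.display_r_threshold and pv < config.display_p_threshold
    else:
        raise ValueError(f"unknown co-occurrence kind {kind!r}")

    edges = []
    for (i, j), qv in zip(zip(*iu), q_flat):
        r, pv = rho[i, j], p[i, j]
        if np.isfinite(r) and passes(r, pv, qv):
            edges.append(CorrelationResult(names[i], names[j], float(r), float(pv), float(qv)))
    return CorrelationNetwork(kind=kind, nodes=list(table.taxa), edges=edges)


def hub_taxa(network: CorrelationNetwork, config: AnalysisConfig | None = None) -> set[str]:
    """Taxa whose degree strictly exceeds the connectivity threshold."""
    config = config or AnalysisConfig()
    if network.kind != "analysis":
        raise ValueError("hub detection is defined on the analysis-kind network")
    thr = config.hub_degree_threshold
    return {n for n, d in network.degree.items() if d > thr}


def flavor_associated_taxa(
    abundance: AbundanceTable,
    volatiles: VolatileTable,
    config: AnalysisConfig | None = None,
) -> tuple[CorrelationNetwork, set[str]]:
    """Taxon-volatile association network and the flavor-associated taxon set.

    Every taxon x compound pair is tested; BH runs over this family
    separately from the co-occurrence family. A taxon qualifies when at
    least ``flavor_min_volatiles`` compounds pass
    |rho| > flavor_r_threshold, p < flavor_p_threshold and
    q < flavor_q_threshold.
    """
    config = config or AnalysisConfig()
    a_ids = abundance.sample_ids
    v_ids = volatiles.sample_ids
    if a_ids != v_ids:
        if set(a_ids) == set(v_ids):
            # same samples, different order: align volatiles to abundance order
            idx = [v_ids.index(s) for s in a_ids]
            volatiles = VolatileTable(
                compounds=list(volatiles.compounds),
                samples=[volatiles.samples[i] for i in idx],
                values=volatiles.values[:, idx],
            )
        else:
            missing = sorted(set(a_ids) ^ set(v_ids))
            raise ValueError(f"abundance/volatile sample mismatch: {missing}")

    t_vals, t_names = _drop_constant_rows(abundance.values, abundance.taxa)
    c_vals, c_names = _drop_constant_rows(volatiles.values, volatiles.names)

    nodes = list(t_names) + [c for c in c_names]
    network = CorrelationNetwork(kind="taxon_volatile", nodes=nodes)
    if not t_names or not c_names:
        return network, set()

    rho, p = _cross_spearman(t_vals, c_vals)
    q = bh_fdr(p.ravel()).reshape(p.shape)

    counts: dict[str, int] = {t: 0 for t in t_names}
    edges = []
    for i, t in enumerate(t_names):
        for j, c in enumerate(c_names):
            r, pv, qv = rho[i, j], p[i, j], q[i, j]
            if (
                np.isfinite(r)
                and abs(r) > config.flavor_r_threshold
                and pv < config.flavor_p_threshold
                and qv < config.flavor_q_threshold
            ):
                edges.append(CorrelationResult(t, c, float(r), float(pv), float(qv)))
                counts[t] += 1
    network.edges = edges
    qualifying = {t for t, k in counts.items() if k >= config.flavor_min_volatiles}
    return network, qualifying


def clr_transform(table: AbundanceTable, pseudocount: float = 1e-6) -> AbundanceTable:
    """Centered log-ratio pre-transform (opt-in compositionality correction).

    Not applied by default; the standard pipeline correlates relative
    abundances directly. Output values are shifted to be non-negative
    (a per-table constant) so the container invariants hold; rank-based
    statistics are unaffected by the shift.
    """
    x = table.values + pseudocount
    logx = np.log(x)
    clr = logx - logx.mean(axis=0, keepdims=True)
    return AbundanceTable(
        taxa=list(table.taxa),
        samples=list(table.samples),
        values=clr - clr.min(),
        level=table.level,
        normalized=False,
    )
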