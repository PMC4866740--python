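"""Partition-agreement and partition-quality metrics.

Agreement between two partitions of the same node set is measured by the
variation of information (VI, normalised to NVI by log n) and by the
confusion-matrix normalised mutual information (NMI, Danon form).  Quality
of a single partition against the graph is measured by Newman-Girvan
modularity Q and by modularity density Q_ds, which weighs each community's
contribution by its internal edge density and subtracts a pairwise
split penalty, countering both the resolution limit and the tendency to
shatter large communities.

All entropies use natural logarithms; NVI and NMI are ratios, so the base
cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import Graph, Partition


def _contingency(X: Partition, Y: Partition) -> tuple[np.ndarray, int]:
    nodes = sorted(X.assignment)
    if set(nodes) != set(Y.assignment):
        raise ValueError("partitions cover different node sets")
    xs = np.array([X.assignment[v] for v in nodes])
    ys = np.array([Y.assignment[v] for v in nodes])
    kx = xs.max() + 1
    ky = ys.max() + 1
    counts = np.zeros((kx, ky), dtype=np.int64)
    np.add.at(counts, (xs, ys), 1)
    return counts, len(nodes)


def variation_of_information(X: Partition, Y: Partition) -> tuple[float, float]:
    """(VI, NVI): VI = H(X) + H(Y) - 2 I(X,Y), NVI = VI / log n.

    Zero iff the partitions are identical; NVI reaches 1 between the
    all-singletons partition and the single-community partition.
    """
    counts, n = _contingency(X, Y)
    p = counts / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0

    def h(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    mi = float((p[nz] * np.log(p[nz] / np.outer(px, py)[nz])).sum())
    vi = h(px) + h(py) - 2 * mi
    vi = max(vi, 0.0)
    nvi = vi / np.log(n) if n > 1 else 0.0
    return vi, float(nvi)


def normalized_mutual_information(X: Partition, Y: Partition) -> float:
    """Confusion-matrix NMI: 2 I(X,Y) / (H(X) + H(Y)).

    1 for identical partitions, 0 for independent ones.  When both
    partitions are trivial (single community) the ratio is 0/0 and the
    value is defined as 1, since the partitions are identical.
    """
    counts, n = _contingency(X, Y)
    ni = counts.sum(axis=1)
    nj = counts.sum(axis=0)
    nz = counts > 0
    num = -2.0 * float(
        (counts[nz] * np.log(counts[nz] * n / np.outer(ni, nj)[nz])).sum()
    )
    den = float((ni * np.log(ni / n)).sum() + (nj * np.log(nj / n)).sum())
    if den == 0.0:
        return 1.0 if counts.shape == (1, 1) else 0.0
    return num / den


def modularity(graph: Graph, P: Partition) -> float:
    """Newman-Girvan modularity of a total partition.

    Q = sum_c [ m_c/m - (D_c / 2m)^2 ] with m_c the community's internal
    edge count and D_c its total degree.  Zero for the single-community
    partition; can be negative for adversarial partitions.
    """
    m = graph.m
    if m == 0:
        return 0.0
    intra: dict[int, int] = {}
    deg: dict[int, int] = {}
    for v in graph.nodes:
        c = P.assignment[v]
        deg[c] = deg.get(c, 0) + graph.degree(v)
    for u, v in graph.edges():
        if P.assignment[u] == P.assignment[v]:
            c = P.assignment[u]
            intra[c] = intra.get(c, 0) + 1
    q = 0.0
    for c, d in deg.items():
        q += intra.get(c, 0) / m - (d / (2 * m)) ** 2
    return q


def modularity_density(graph: Graph, P: Partition) -> float:
    """Density-weighted modularity Q_ds.

    Per community c with n_c nodes, m_in internal and m_out boundary
    edges, internal density d_c = 2 m_in / (n_c (n_c - 1)) (0 for
    singletons), and pairwise density d_cc' = m_cc' / (n_c n_c'):

        Q_ds = sum_c [ (m_in/m) d_c - ((2 m_in + m_out) d_c / 2m)^2
                       - sum_{c' != c} (m_cc' / 2m) d_cc' ]
    """
    m = graph.m
    if m == 0:
        return 0.0
    comms = P.communities()
    size = {c: len(ms) for c, ms in comms.items()}
    m_in: dict[int, int] = {c: 0 for c in comms}
    m_pair: dict[tuple[int, int], int] = {}
    for u, v in graph.edges():
        cu, cv = P.assignment[u], P.assignment[v]
        if cu == cv:
            m_in[cu] += 1
        else:
            key = (cu, cv) if cu < cv else (cv, cu)
            m_pair[key] = m_pair.get(key, 0) + 1
    m_out = {c: 0 for c in comms}
    for (cu, cv), k in m_pair.items():
        m_out[cu] += k
        m_out[cv] += k
    q = 0.0
    for c in comms:
        n_c = size[c]
        d_c = 2 * m_in[c] / (n_c * (n_c - 1)) if n_c > 1 else 0.0
        q += (m_in[c] / m) * d_c
        q -= ((2 * m_in[c] + m_out[c]) / (2 * m) * d_c) ** 2
    for (cu, cv), k in m_pair.items():
        d_pair = k / (size[cu] * size[cv])
        # both ordered pairs (c, c') and (c', c) contribute the penalty
        q -= 2 * (k / (2 * m)) * d_pair
    return q


@dataclass(frozen=True)
class MetricReport:
    """All metrics for one (graph, partition[, reference]) triple."""

    n: int
    m: int
    q: float
    q_ds: float
    nvi: float | None = None
    nmi: float | None = None

    def as_dict(self) -> dict:
        out = {"n": self.n, "m": self.m, "q": self.q, "q_ds": self.q_ds}
        if self.nvi is not None:
            out["nvi"] = self.nvi
        if self.nmi is not None:
            out["nmi"] = self.nmi
        return out


def evaluate(graph: Graph, P: Partition, truth: Partition | None = None) -> MetricReport:
    nvi = nmi = None
    if truth is not None:
        _, nvi = variation_of_information(P, truth)
        nmi = normalized_mutual_information(P, truth)
    return MetricReport(
        n=graph.n,
        m=graph.m,
        q=modularity(graph, P),
        q_ds=modularity_density(graph, P),
        nvi=nvi,
        nmi=nmi,
    )
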