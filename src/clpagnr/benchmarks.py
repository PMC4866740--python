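"""Synthetic benchmark graphs with planted community structure.

Three families are provided, each paired with its ground-truth partition:

* **GN** (Girvan-Newman): 128 nodes in four planted groups of 32, every
  node with degree 16, a fraction ``mu`` of which crosses group borders.
* **LFR** (Lancichinetti-Fortunato-Radicchi): power-law degree and
  community-size distributions; each node sends a fraction ``mu`` of its
  links outside its community.
* **RC** (relaxed caveman): 16 cliques of heterogeneous sizes on 512
  nodes; a fraction ``D`` (degradation) of each clique's edges is rewired
  to other cliques.

All generators draw from a ``random.Random`` seeded per instance, build
edges by stub matching with bounded retries followed by local edge-swap
repair, and emit simple graphs.  The same spec and seed always reproduce
the identical instance.
"""

from __future__ import annotations

import math
import random
import zlib
from dataclasses import dataclass, field

from .graph import Graph, Node, Partition

RC_N_TOTAL = 512
RC_N_COMMUNITIES = 16
RC_MIN_SIZE = 2
RC_MAX_SIZE = 157
GN_N = 128
GN_DEGREE = 16
GN_GROUPS = 4


@dataclass(frozen=True)
class LFRSpec:
    """Parameters of one LFR instance."""

    N: int = 1000
    k: float = 10.0
    maxk: int = 50
    minc: int = 10
    maxc: int = 50
    mu: float = 0.1
    gamma: float = 2.0
    beta: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.mu <= 1):
            raise ValueError("mu must lie in [0, 1]")
        if not (self.minc <= self.maxc <= self.N):
            raise ValueError("need minc <= maxc <= N")
        if self.k > self.maxk:
            raise ValueError("average degree cannot exceed the maximum degree")


@dataclass(frozen=True)
class RCSpec:
    """Parameters of one relaxed-caveman instance."""

    degradation: float = 0.0
    sizes: tuple[int, ...] | None = None
    seed: int = 0
    n_total: int = RC_N_TOTAL
    n_communities: int = RC_N_COMMUNITIES

    def __post_init__(self):
        if not (0 <= self.degradation <= 1):
            raise ValueError("degradation must lie in [0, 1]")
        if self.sizes is not None:
            s = self.sizes
            if (
                len(s) != self.n_communities
                or min(s) < RC_MIN_SIZE
                or max(s) > RC_MAX_SIZE
                or sum(s) != self.n_total
            ):
                raise ValueError(
                    f"sizes must be {self.n_communities} values in "
                    f"[{RC_MIN_SIZE}, {RC_MAX_SIZE}] summing to {self.n_total}"
                )


@dataclass(frozen=True)
class BenchmarkInstance:
    graph: Graph
    ground_truth: Partition
    spec: object = field(repr=False, default=None)

    def mixing_fraction(self) -> float:
        """Realised fraction of edges crossing ground-truth communities."""
        a = self.ground_truth.assignment
        inter = sum(1 for u, v in self.graph.edges() if a[u] != a[v])
        return inter / self.graph.m if self.graph.m else 0.0


# -- shared machinery ------------------------------------------------------


def _derive_seed(tag: str, param: float, seed: int) -> int:
    """Stable (hash-salt-free) per-instance RNG seed below 2^31."""
    return zlib.crc32(f"{tag}|{param:.6f}|{seed}".encode()) & 0x7FFFFFFF


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _trunc_powerlaw(rng: random.Random, exponent: float, lo: float, hi: float) -> float:
    """One draw from a continuous power law p(x) ~ x^-exponent on [lo, hi]."""
    u = rng.random()
    g = exponent
    if abs(g - 1.0) < 1e-12:
        return lo * (hi / lo) ** u
    a = lo ** (1 - g)
    b = hi ** (1 - g)
    return (a + u * (b - a)) ** (1 / (1 - g))


def _trunc_powerlaw_mean(g: float, lo: float, hi: float) -> float:
    if abs(g - 1.0) < 1e-12:
        return (hi - lo) / math.log(hi / lo)
    norm = (hi ** (1 - g) - lo ** (1 - g)) / (1 - g)
    if abs(g - 2.0) < 1e-12:
        num = math.log(hi / lo)
    else:
        num = (hi ** (2 - g) - lo ** (2 - g)) / (2 - g)
    return num / norm


def _solve_lower_cutoff(g: float, mean: float, hi: float) -> float:
    """Lower cutoff of a truncated power law achieving a target mean."""
    lo, up = 1.0, float(hi)
    if _trunc_powerlaw_mean(g, lo, hi) >= mean:
        return lo
    for _ in range(200):
        mid = (lo + up) / 2
        if _trunc_powerlaw_mean(g, mid, hi) < mean:
            lo = mid
        else:
            up = mid
    return (lo + up) / 2


def _match_stubs(
    stubs: list[Node],
    existing: set[frozenset],
    ok,
    rng: random.Random,
    max_rounds: int = 60,
    swap_tries: int = 200,
) -> list[tuple[Node, Node]]:
    """Pair stubs into new simple edges satisfying the ``ok`` predicate.

    Stubs are shuffled and paired greedily; incompatible pairs are thrown
    back and re-paired.  Residual stubs are settled by degree-preserving
    edge swaps against already-built edges; stubs that still cannot be
    placed are dropped (a small, logged-free shortfall in degree).
    ``existing`` is updated in place.
    """
    edges: list[tuple[Node, Node]] = []
    pool = list(stubs)
    for _ in range(max_rounds):
        if len(pool) < 2:
            break
        rng.shuffle(pool)
        rest: list[Node] = []
        it = iter(range(0, len(pool) - 1, 2))
        for i in it:
            u, v = pool[i], pool[i + 1]
            key = frozenset((u, v))
            if u != v and key not in existing and ok(u, v):
                existing.add(key)
                edges.append((u, v))
            else:
                rest.append(u)
                rest.append(v)
        if len(pool) % 2:
            rest.append(pool[-1])
        if len(rest) == len(pool):
            break  # no progress; go to repair
        pool = rest
    # repair by edge swaps: place (u, v) by breaking an existing edge (a, b)
    # into (u, a) and (v, b), which preserves the degrees of a and b
    while len(pool) >= 2:
        v = pool.pop()
        u = pool.pop()
        placed = False
        if edges:
            for _ in range(swap_tries):
                idx = rng.randrange(len(edges))
                a, b = edges[idx]
                if rng.random() < 0.5:
                    a, b = b, a
                k1, k2 = frozenset((u, a)), frozenset((v, b))
                if (
                    u != a
                    and v != b
                    and k1 != k2
                    and k1 not in existing
                    and k2 not in existing
                    and ok(u, a)
                    and ok(v, b)
                ):
                    existing.discard(frozenset((a, b)))
                    edges[idx] = edges[-1]
                    edges.pop()
                    existing.update((k1, k2))
                    edges.append((u, a))
                    edges.append((v, b))
                    placed = True
                    break
        if not placed:
            pass  # drop both stubs
    return edges


# -- Girvan-Newman ---------------------------------------------------------


def generate_gn(mu: float, seed: int) -> BenchmarkInstance:
    """128-node GN benchmark: four groups of 32, degree 16, mixing ``mu``."""
    if not (0 <= mu <= 1):
        raise ValueError("mu must lie in [0, 1]")
    rng = random.Random(_derive_seed("gn", mu, seed))
    nodes = [str(i) for i in range(GN_N)]
    group = {str(i): i // (GN_N // GN_GROUPS) for i in range(GN_N)}
    k_in = _round_half_away((1 - mu) * GN_DEGREE)
    k_out = GN_DEGREE - k_in

    existing: set[frozenset] = set()
    edges: list[tuple[Node, Node]] = []
    for g in range(GN_GROUPS):
        members = [v for v in nodes if group[v] == g]
        stubs = [v for v in members for _ in range(k_in)]
        edges += _match_stubs(stubs, existing, lambda u, v: True, rng)
    if k_out:
        stubs = [v for v in nodes for _ in range(k_out)]
        edges += _match_stubs(
            stubs, existing, lambda u, v: group[u] != group[v], rng
        )
    graph = Graph.from_edges(edges, extra_nodes=nodes, warn=False)
    truth = Partition.from_assignment({v: group[v] for v in nodes}, graph)
    return BenchmarkInstance(graph=graph, ground_truth=truth, spec=("gn", mu, seed))


# -- relaxed caveman -------------------------------------------------------


def default_rc_sizes(seed: int = 0) -> tuple[int, ...]:
    """16 heterogeneous community sizes in [2, 157] summing to 512.

    Sizes follow a truncated power law on [2, 157] whose exponent is
    calibrated so that the expected total is 512 over 16 communities
    (a mean community size of 32 puts the exponent near 1.05).  Draws are
    stratified — one per probability sixteenth — so every instance spans
    the full small-to-giant range, and the rounded sizes are nudged by
    +-1 where slack remains until they sum to exactly 512.
    """
    rng = random.Random(_derive_seed("rc-sizes", 0.0, seed))
    target_mean = RC_N_TOTAL / RC_N_COMMUNITIES
    lo_e, hi_e = 0.2, 3.0
    for _ in range(100):
        mid = (lo_e + hi_e) / 2
        if _trunc_powerlaw_mean(mid, RC_MIN_SIZE, RC_MAX_SIZE) > target_mean:
            lo_e = mid
        else:
            hi_e = mid
    exponent = (lo_e + hi_e) / 2
    g = exponent
    a = RC_MIN_SIZE ** (1 - g)
    b = RC_MAX_SIZE ** (1 - g)
    sizes = []
    for i in range(RC_N_COMMUNITIES):
        u = (i + rng.random()) / RC_N_COMMUNITIES
        x = (a + u * (b - a)) ** (1 / (1 - g))
        sizes.append(max(RC_MIN_SIZE, min(RC_MAX_SIZE, _round_half_away(x))))
    residual = RC_N_TOTAL - sum(sizes)
    j = 0
    while residual != 0:
        i = j % RC_N_COMMUNITIES
        if residual > 0 and sizes[i] < RC_MAX_SIZE:
            sizes[i] += 1
            residual -= 1
        elif residual < 0 and sizes[i] > RC_MIN_SIZE:
            sizes[i] -= 1
            residual += 1
        j += 1
    return tuple(sizes)


def generate_rc(spec: RCSpec) -> BenchmarkInstance:
    """Relaxed-caveman benchmark: 16 cliques degraded by rewiring."""
    rng = random.Random(_derive_seed("rc", spec.degradation, spec.seed))
    sizes = spec.sizes if spec.sizes is not None else default_rc_sizes(spec.seed)
    nodes: list[Node] = [str(i) for i in range(spec.n_total)]
    comm: dict[Node, int] = {}
    members: list[list[Node]] = []
    nxt = 0
    for c, s in enumerate(sizes):
        ms = [str(i) for i in range(nxt, nxt + s)]
        nxt += s
        members.append(ms)
        for v in ms:
            comm[v] = c

    existing: set[frozenset] = set()
    edges: list[tuple[Node, Node]] = []
    for ms in members:
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                edges.append((ms[i], ms[j]))
                existing.add(frozenset((ms[i], ms[j])))

    if spec.degradation > 0:
        final_edges = []
        for c, ms in enumerate(members):
            clique = [
                (u, v) for u, v in edges if comm[u] == c and comm[v] == c
            ]
            n_rm = _round_half_away(spec.degradation * len(clique))
            doomed = set(rng.sample(range(len(clique)), n_rm)) if n_rm else set()
            for idx, (u, v) in enumerate(clique):
                if idx not in doomed:
                    continue
                existing.discard(frozenset((u, v)))
                keep = u if rng.random() < 0.5 else v
                # rewire the retained endpoint into another community
                for _ in range(200):
                    w = nodes[rng.randrange(spec.n_total)]
                    if comm[w] != comm[keep] and frozenset((keep, w)) not in existing:
                        existing.add(frozenset((keep, w)))
                        final_edges.append((keep, w))
                        break
        edges = [
            (u, v) for u, v in edges if frozenset((u, v)) in existing
        ] + final_edges
        # deduplicate rewired edges against surviving clique edges
        seen: set[frozenset] = set()
        uniq = []
        for u, v in edges:
            key = frozenset((u, v))
            if key not in seen:
                seen.add(key)
                uniq.append((u, v))
        edges = uniq

    graph = Graph.from_edges(edges, extra_nodes=nodes, warn=False)
    truth = Partition.from_assignment(comm, graph)
    return BenchmarkInstance(graph=graph, ground_truth=truth, spec=spec)


# -- LFR -------------------------------------------------------------------


def _lfr_degrees(spec: LFRSpec, rng: random.Random) -> list[int]:
    lo = _solve_lower_cutoff(spec.gamma, spec.k, spec.maxk)
    degrees = [
        max(1, min(spec.maxk, _round_half_away(_trunc_powerlaw(rng, spec.gamma, lo, spec.maxk))))
        for _ in range(spec.N)
    ]
    if sum(degrees) % 2:
        for i in range(spec.N):
            if degrees[i] < spec.maxk:
                degrees[i] += 1
                break
    return degrees


def _lfr_community_sizes(spec: LFRSpec, rng: random.Random) -> list[int]:
    sizes: list[int] = []
    total = 0
    while total < spec.N:
        s = max(
            spec.minc,
            min(spec.maxc, _round_half_away(_trunc_powerlaw(rng, spec.beta, spec.minc, spec.maxc))),
        )
        sizes.append(s)
        total += s
    excess = total - spec.N
    i = len(sizes) - 1
    while excess > 0 and i >= 0:
        take = min(excess, sizes[i] - spec.minc)
        sizes[i] -= take
        excess -= take
        i -= 1
    if excess > 0:
        # every community is at minc; drop one and re-grow the others
        excess -= sizes.pop()
        j = 0
        while excess < 0:
            if sizes[j % len(sizes)] < spec.maxc:
                sizes[j % len(sizes)] += 1
                excess += 1
            j += 1
    return sizes


def generate_lfr(spec: LFRSpec) -> BenchmarkInstance:
    """LFR benchmark with power-law degrees and community sizes.

    Each node's degree splits into intra-community stubs,
    round((1 - mu) * degree), and inter-community stubs (the remainder).
    Nodes are placed into communities large enough to host their intra
    degree; intra and inter edge sets are then realised by stub matching.
    """
    rng = random.Random(
        _derive_seed(f"lfr|{spec.N}|{spec.k:.4f}|{spec.minc}", spec.mu, spec.seed)
    )
    degrees = _lfr_degrees(spec, rng)
    sizes = _lfr_community_sizes(spec, rng)
    n_comm = len(sizes)
    nodes = [str(i) for i in range(spec.N)]
    deg = {str(i): degrees[i] for i in range(spec.N)}
    intra_target = {
        v: min(_round_half_away((1 - spec.mu) * deg[v]), deg[v]) for v in nodes
    }

    # place high-intra-degree nodes first, into communities that can host them
    slots = list(sizes)
    comm: dict[Node, int] = {}
    order = sorted(nodes, key=lambda v: (-intra_target[v], rng.random()))
    for v in order:
        feasible = [c for c in range(n_comm) if slots[c] > 0 and sizes[c] > intra_target[v]]
        if not feasible:
            feasible = [c for c in range(n_comm) if slots[c] > 0]
        c = rng.choice(feasible)
        comm[v] = c
        slots[c] -= 1

    intra = {v: min(intra_target[v], sizes[comm[v]] - 1) for v in nodes}
    members: list[list[Node]] = [[] for _ in range(n_comm)]
    for v in nodes:
        members[comm[v]].append(v)

    existing: set[frozenset] = set()
    edges: list[tuple[Node, Node]] = []
    built = {v: 0 for v in nodes}
    for c in range(n_comm):
        ms = members[c]
        if sum(intra[v] for v in ms) % 2:
            fix = max(ms, key=lambda v: (intra[v], v))
            intra[fix] -= 1
        stubs = [v for v in ms for _ in range(intra[v])]
        new = _match_stubs(stubs, existing, lambda u, v: True, rng)
        for u, v in new:
            built[u] += 1
            built[v] += 1
        edges += new

    if spec.mu > 0:
        inter = {v: max(deg[v] - built[v], 0) for v in nodes}
        if sum(inter.values()) % 2:
            fix = max(nodes, key=lambda v: (inter[v], v))
            inter[fix] -= 1
        stubs = [v for v in nodes for _ in range(inter[v])]
        edges += _match_stubs(stubs, existing, lambda u, v: comm[u] != comm[v], rng)
    # at mu = 0 leftover stubs are dropped: the planted partition must have
    # zero mixing, so a slight degree shortfall beats a crossing edge

    graph = Graph.from_edges(edges, extra_nodes=nodes, warn=False)
    truth = Partition.from_assignment(comm, graph)
    return BenchmarkInstance(graph=graph, ground_truth=truth, spec=spec)


# -- named parameterisations ----------------------------------------------

LFR_FAMILIES = {
    # (N, k, minc, maxc); maxk=50, gamma=2, beta=1 throughout
    "S-SK-SC": dict(N=1000, k=10.0, minc=10, maxc=50),
    "S-SK-LC": dict(N=1000, k=10.0, minc=20, maxc=100),
    "S-LK-SC": dict(N=1000, k=20.0, minc=10, maxc=50),
    "S-LK-LC": dict(N=1000, k=20.0, minc=20, maxc=100),
    "B-SK-SC": dict(N=5000, k=10.0, minc=10, maxc=50),
    "B-SK-LC": dict(N=5000, k=10.0, minc=20, maxc=100),
    "B-LK-SC": dict(N=5000, k=20.0, minc=10, maxc=50),
    "B-LK-LC": dict(N=5000, k=20.0, minc=20, maxc=100),
}


def lfr_family_spec(family: str, mu: float, seed: int) -> LFRSpec:
    """Spec for one of the named small/big, small/large degree/community
    LFR families (e.g. ``"S-LK-SC"``)."""
    key = family.upper().removeprefix("LFR-").replace("_", "-")
    if key not in LFR_FAMILIES:
        raise KeyError(f"unknown LFR family {family!r}; know {sorted(LFR_FAMILIES)}")
    base: dict = dict(LFR_FAMILIES[key])
    return LFRSpec(mu=mu, seed=seed, maxk=50, gamma=2.0, beta=1.0, **base)
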