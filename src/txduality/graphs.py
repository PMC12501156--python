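"""Linear-framework engine: labeled state graphs and their steady states.

A gene-regulatory system is modeled as a continuous-time Markov process on a
finite set of molecular states.  The process is encoded as a directed graph
whose vertices are states and whose edge labels are transition rates; labels
are affine in a single scalar input, the transcription-factor concentration
``x`` (binding edges carry the concentration-proportional part, everything
else is constant).  For a strongly connected graph the stationary
distribution is unique and is a rational function of the labels.

Two production solvers are provided:

* :func:`steady_state_equilibrium` — path products of label ratios from a
  reference state, valid only when the Kolmogorov cycle condition holds
  (detailed balance, i.e. a genuine thermodynamic equilibrium);
* :func:`steady_state_spanning_tree` — the Matrix-Tree construction: the
  unnormalized weight of state ``i`` is the sum over all spanning trees
  rooted at ``i`` (edges oriented toward the root) of the product of edge
  rates.  Valid for any strongly connected graph, equilibrium or not.

Two independent oracles (:func:`steady_state_oracle`) — Laplacian nullspace
and long-time integration of the master equation — exist for verification
and are never used by the model modules.
"""

from __future__ import annotations

import json
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Literal, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.special import logsumexp


class Edge(NamedTuple):
    """Directed transition with an affine rate law ``rate + x_coeff * x``."""

    source: str
    target: str
    rate: float = 0.0
    x_coeff: float = 0.0

    def effective_rate(self, x: float) -> float:
        return self.rate + self.x_coeff * x


class GraphStructureError(ValueError):
    """The graph violates a structural invariant (connectivity, duplicates)."""


class RateDomainError(ValueError):
    """An effective rate is negative at the requested concentration."""


@dataclass(frozen=True)
class RateGraph:
    """Directed labeled graph of molecular states.

    Parameters
    ----------
    vertices
        Opaque state identifiers (order fixes the matrix convention).
    edges
        At most one directed edge per ordered vertex pair; the effective
        rate at TF concentration ``x`` is ``rate + x_coeff * x``.
    transcription_weights
        Per-state transcription rates ``q_i`` (transcripts/time); states
        not listed transcribe at rate 0.
    """

    vertices: tuple[str, ...]
    edges: tuple[Edge, ...]
    transcription_weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.vertices)) != len(self.vertices):
            raise GraphStructureError("duplicate vertex identifiers")
        vset = set(self.vertices)
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.source not in vset or e.target not in vset:
                raise GraphStructureError(f"edge {e.source}->{e.target} uses unknown vertex")
            if e.source == e.target:
                raise GraphStructureError(f"self-loop at {e.source}")
            key = (e.source, e.target)
            if key in seen:
                raise GraphStructureError(f"duplicate edge {e.source}->{e.target}")
            seen.add(key)
        for v in self.transcription_weights:
            if v not in vset:
                raise GraphStructureError(f"transcription weight on unknown vertex {v}")

    # -- basic views -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.vertices)

    def index(self, vertex: str) -> int:
        return self.vertices.index(vertex)

    def edge_index(self) -> dict[tuple[str, str], int]:
        return {(e.source, e.target): i for i, e in enumerate(self.edges)}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from((e.source, e.target) for e in self.edges)
        return g

    def is_strongly_connected(self) -> bool:
        return nx.is_strongly_connected(self.to_networkx())

    def require_strongly_connected(self) -> None:
        g = self.to_networkx()
        if not nx.is_strongly_connected(g):
            comp = max(nx.strongly_connected_components(g), key=len)
            unreachable = sorted(set(self.vertices) - comp)
            raise GraphStructureError(
                f"graph is not strongly connected; vertices outside the largest "
                f"component: {unreachable}"
            )

    def effective_rates(self, x: float) -> np.ndarray:
        """Vector of effective edge rates at concentration ``x`` (edge order)."""
        if np.any(np.asarray(x) < 0):
            raise RateDomainError("TF concentration x must be nonnegative")
        rates = np.array([e.rate + e.x_coeff * x for e in self.edges], dtype=float)
        bad = np.where(rates < 0)[0]
        if bad.size:
            e = self.edges[bad[0]]
            raise RateDomainError(
                f"edge {e.source}->{e.target} has negative effective rate "
                f"{rates[bad[0]]!r} at x={x!r}"
            )
        return rates

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "vertices": list(self.vertices),
                "edges": [
                    {"from": e.source, "to": e.target, "rate": e.rate, "x_coeff": e.x_coeff}
                    for e in self.edges
                ],
                "q": dict(self.transcription_weights),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RateGraph":
        d = json.loads(text)
        return cls(
            vertices=tuple(d["vertices"]),
            edges=tuple(
                Edge(e["from"], e["to"], e["rate"], e["x_coeff"]) for e in d["edges"]
            ),
            transcription_weights=d.get("q", {}),
        )


@dataclass(frozen=True)
class SteadyState:
    """Stationary distribution of a :class:`RateGraph`.

    ``probabilities`` maps each vertex to its stationary probability;
    ``rho`` carries the unnormalized spanning-tree weights when the
    Matrix-Tree solver produced the result.
    """

    probabilities: dict[str, float]
    method: Literal[
        "equilibrium_path_product", "spanning_tree", "nullspace_oracle", "ode_oracle"
    ]
    rho: dict[str, float] | None = None

    def as_array(self, vertices: Sequence[str]) -> np.ndarray:
        return np.array([self.probabilities[v] for v in vertices])


# ---------------------------------------------------------------------------
# Rate matrix and Laplacian
# ---------------------------------------------------------------------------


def evaluate_rate_matrix(graph: RateGraph, x: float) -> np.ndarray:
    """Matrix of effective rates; entry ``[i, j]`` is the rate of ``i -> j``.

    No diagonal convention is imposed; callers form the Laplacian they need.
    """
    rates = graph.effective_rates(x)
    idx = {v: i for i, v in enumerate(graph.vertices)}
    m = np.zeros((graph.n, graph.n))
    for e, r in zip(graph.edges, rates):
        m[idx[e.source], idx[e.target]] = r
    return m


def laplacian(graph: RateGraph, x: float) -> np.ndarray:
    """Generator ``L`` of the master equation ``dP/dt = L @ P`` (column convention)."""
    m = evaluate_rate_matrix(graph, x)
    return m.T - np.diag(m.sum(axis=1))


# ---------------------------------------------------------------------------
# Cycle condition (Kolmogorov criterion / detailed balance)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CycleReport:
    """Per-basis-cycle balance report from :func:`check_cycle_condition`."""

    holds: bool
    cycles: tuple[tuple[tuple[str, ...], float, float], ...]  # (cycle, fwd, back)
    missing_reverse: tuple[tuple[str, str], ...] = ()


def check_cycle_condition(graph: RateGraph, x: float, rtol: float = 1e-9) -> CycleReport:
    """Test the Kolmogorov criterion at concentration ``x``.

    Holds iff every independent cycle has equal forward and backward rate
    products (within ``rtol``), which requires every edge to be reversible.
    The cycle basis is taken from a spanning tree of the undirected support.
    """
    eidx = graph.edge_index()
    missing = tuple(
        (e.source, e.target) for e in graph.edges if (e.target, e.source) not in eidx
    )
    if missing:
        return CycleReport(holds=False, cycles=(), missing_reverse=missing)

    rates = graph.effective_rates(x)
    support = nx.Graph()
    support.add_nodes_from(graph.vertices)
    support.add_edges_from((e.source, e.target) for e in graph.edges)

    cycles: list[tuple[tuple[str, ...], float, float]] = []
    holds = True
    for cyc in nx.cycle_basis(support):
        fwd = 1.0
        back = 1.0
        k = len(cyc)
        for i in range(k):
            u, v = cyc[i], cyc[(i + 1) % k]
            fwd *= rates[eidx[(u, v)]]
            back *= rates[eidx[(v, u)]]
        if fwd == 0.0 and back == 0.0:
            balanced = True  # cycle effectively absent at this x
        else:
            balanced = abs(fwd - back) <= rtol * max(abs(fwd), abs(back))
        if not balanced:
            holds = False
        cycles.append((tuple(cyc), fwd, back))
    return CycleReport(holds=holds, cycles=tuple(cycles))


# ---------------------------------------------------------------------------
# Equilibrium solver: path products of label ratios
# ---------------------------------------------------------------------------


def steady_state_equilibrium(
    graph: RateGraph,
    x: float,
    reference_vertex: str | None = None,
    rtol: float = 1e-9,
    check: bool = True,
) -> SteadyState:
    """Stationary distribution by path products from a reference state.

    Assign the reference state weight 1; the weight of state ``i`` is the
    product of forward/backward rate ratios along any path from the
    reference.  Path independence is guaranteed by the cycle condition,
    which is verified unless ``check=False``.
    """
    graph.require_strongly_connected()
    if check:
        report = check_cycle_condition(graph, x, rtol=rtol)
        if not report.holds:
            raise ValueError(
                "cycle condition does not hold at this x (nonequilibrium steady "
                "state); use steady_state_spanning_tree instead"
            )
    ref = reference_vertex if reference_vertex is not None else graph.vertices[0]
    eidx = graph.edge_index()
    rates = graph.effective_rates(x)

    mu: dict[str, float] = {ref: 1.0}
    queue = deque([ref])
    adj: dict[str, list[str]] = {v: [] for v in graph.vertices}
    for e in graph.edges:
        adj[e.source].append(e.target)
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v in mu:
                continue
            fwd = rates[eidx[(u, v)]]
            rev_key = (v, u)
            if rev_key not in eidx or rates[eidx[rev_key]] == 0.0:
                raise ValueError(f"edge {u}->{v} has no positive reverse rate at x={x}")
            mu[v] = mu[u] * fwd / rates[eidx[rev_key]]
            queue.append(v)
    total = sum(mu.values())
    probs = {v: mu[v] / total for v in graph.vertices}
    return SteadyState(probabilities=probs, method="equilibrium_path_product", rho=dict(mu))


# ---------------------------------------------------------------------------
# Matrix-Tree solver: exhaustive rooted spanning-tree enumeration
# ---------------------------------------------------------------------------

_MAX_ENUMERATION_VERTICES = 12

# Rooted-tree structure depends only on the topology, so cache it keyed by
# (vertices, directed edge pairs); rates are substituted per call.
_tree_cache: dict[tuple, list[list[tuple[int, ...]]]] = {}


def _rooted_spanning_trees(graph: RateGraph) -> list[list[tuple[int, ...]]]:
    """For each root (vertex order), the spanning trees oriented toward it.

    Each tree is a tuple of directed-edge indices.  Enumeration walks every
    spanning tree of the undirected support once and reuses the orientation
    for each root, skipping trees where a required directed edge is absent.
    """
    key = (graph.vertices, tuple((e.source, e.target) for e in graph.edges))
    cached = _tree_cache.get(key)
    if cached is not None:
        return cached

    eidx = graph.edge_index()
    support = nx.Graph()
    support.add_nodes_from(graph.vertices)
    support.add_edges_from((e.source, e.target) for e in graph.edges)

    per_root: list[list[tuple[int, ...]]] = [[] for _ in graph.vertices]
    for tree in nx.SpanningTreeIterator(support):
        for ri, root in enumerate(graph.vertices):
            # orient every tree edge toward the root
            parent = {root: None}
            order = [root]
            stack = [root]
            while stack:
                u = stack.pop()
                for v in tree.neighbors(u):
                    if v not in parent:
                        parent[v] = u
                        order.append(v)
                        stack.append(v)
            if len(order) != graph.n:
                break  # not spanning (cannot happen for SpanningTreeIterator)
            indices = []
            ok = True
            for v in order[1:]:
                key2 = (v, parent[v])
                i = eidx.get(key2)
                if i is None:
                    ok = False
                    break
                indices.append(i)
            if ok:
                per_root[ri].append(tuple(indices))
    _tree_cache[key] = per_root
    return per_root


def _log_rho(graph: RateGraph, x) -> np.ndarray:
    """Log of unnormalized tree weights; supports scalar or 1-D array ``x``.

    Products are accumulated in log space (zero rates contribute ``-inf``)
    and trees are combined with log-sum-exp, so near-underflow parameter
    regimes remain representable in doubles.
    """
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    rates = np.empty((len(graph.edges), xs.size))
    for i, e in enumerate(graph.edges):
        rates[i] = e.rate + e.x_coeff * xs
    if np.any(rates < 0):
        i = int(np.argwhere(rates < 0)[0][0])
        e = graph.edges[i]
        raise RateDomainError(f"edge {e.source}->{e.target} has negative effective rate")
    with np.errstate(divide="ignore"):
        log_rates = np.log(rates)

    per_root = _rooted_spanning_trees(graph)
    out = np.full((graph.n, xs.size), -np.inf)
    for ri, trees in enumerate(per_root):
        if not trees:
            continue
        # all trees for one root have n-1 edges: stack into (trees, n-1, nx)
        idx = np.array(trees, dtype=int)
        sums = log_rates[idx].sum(axis=1)  # (trees, nx)
        out[ri] = logsumexp(sums, axis=0)
    return out if np.ndim(x) else out[:, 0]


def steady_state_spanning_tree(
    graph: RateGraph, x: float, precision: int | None = None
) -> SteadyState:
    """Stationary distribution by the Matrix-Tree construction.

    ``rho_i`` is the sum over spanning trees rooted at ``i`` of the product
    of edge rates; probabilities are ``rho`` normalized.  Exhaustive tree
    enumeration is used up to 12 vertices; larger graphs fall back to the
    Laplacian nullspace with a warning.

    Parameters
    ----------
    precision
        If given, products are evaluated with mpmath real numbers at that
        many significant digits (mirroring extended-precision practice for
        ill-conditioned tree sums); the default is double precision with
        log-space accumulation.
    """
    graph.require_strongly_connected()
    if graph.n > _MAX_ENUMERATION_VERTICES:
        warnings.warn(
            f"{graph.n} vertices exceeds the exhaustive-enumeration limit "
            f"({_MAX_ENUMERATION_VERTICES}); falling back to the nullspace solver",
            RuntimeWarning,
            stacklevel=2,
        )
        ss = steady_state_oracle(graph, x, method="nullspace")
        return SteadyState(probabilities=ss.probabilities, method="spanning_tree")

    if precision is not None:
        import mpmath

        with mpmath.workdps(precision):
            rates = [mpmath.mpf(e.rate) + mpmath.mpf(e.x_coeff) * mpmath.mpf(x) for e in graph.edges]
            per_root = _rooted_spanning_trees(graph)
            rho_mp = []
            for trees in per_root:
                total = mpmath.mpf(0)
                for t in trees:
                    prod = mpmath.mpf(1)
                    for i in t:
                        prod *= rates[i]
                    total += prod
                rho_mp.append(total)
            z = sum(rho_mp)
            if z == 0:
                raise FloatingPointError(
                    "all spanning-tree weights are zero; increase precision or "
                    "check for vanishing rates"
                )
            probs = {v: float(r / z) for v, r in zip(graph.vertices, rho_mp)}
            rho = {v: float(r) for v, r in zip(graph.vertices, rho_mp)}
        return SteadyState(probabilities=probs, method="spanning_tree", rho=rho)

    log_rho = _log_rho(graph, x)
    if np.all(np.isinf(log_rho)):
        raise FloatingPointError(
            "all spanning-tree weights are zero at this x; the steady state is "
            "degenerate or requires a higher-precision backend"
        )
    log_z = logsumexp(log_rho)
    probs_arr = np.exp(log_rho - log_z)
    probs = {v: float(p) for v, p in zip(graph.vertices, probs_arr)}
    rho = {v: float(np.exp(lr)) for v, lr in zip(graph.vertices, log_rho)}
    return SteadyState(probabilities=probs, method="spanning_tree", rho=rho)


def steady_state_sweep(graph: RateGraph, xs: np.ndarray) -> np.ndarray:
    """Vectorized Matrix-Tree steady states over a concentration grid.

    Returns an array of shape ``(len(xs), n_vertices)`` in vertex order.
    """
    graph.require_strongly_connected()
    if graph.n > _MAX_ENUMERATION_VERTICES:
        return np.array(
            [steady_state_oracle(graph, x, "nullspace").as_array(graph.vertices) for x in xs]
        )
    log_rho = _log_rho(graph, np.asarray(xs, dtype=float))  # (n, nx)
    log_z = logsumexp(log_rho, axis=0)
    if np.any(np.isinf(log_z)):
        raise FloatingPointError("all spanning-tree weights are zero at some grid point")
    return np.exp(log_rho - log_z).T


# ---------------------------------------------------------------------------
# Independent oracles (verification only)
# ---------------------------------------------------------------------------


def _gth_kernel(rates: np.ndarray) -> np.ndarray:
    """Stationary vector of a rate matrix (``rates[i, j]`` = rate i -> j)
    by Grassmann–Taksar–Heyman state reduction; subtraction-free, hence
    componentwise relatively accurate."""
    A = np.array(rates, dtype=float)
    n = A.shape[0]
    for k in range(n - 1, 0, -1):
        s = A[k, :k].sum()
        if s <= 0:
            raise FloatingPointError("GTH reduction hit an absorbing block")
        A[:k, k] /= s
        A[:k, :k] += np.outer(A[:k, k], A[k, :k])
        np.fill_diagonal(A[:k, :k], 0.0)
    p = np.zeros(n)
    p[0] = 1.0
    for k in range(1, n):
        p[k] = p[:k] @ A[:k, k]
    return p / p.sum()


def steady_state_oracle(
    graph: RateGraph,
    x: float,
    method: Literal["nullspace", "ode"] = "nullspace",
    ode_horizon: float = 1e14,
    ode_residual: float = 1e-10,
    precision: int | None = None,
) -> SteadyState:
    """Reference steady states by linear algebra or long-time integration.

    ``nullspace`` computes the kernel of the master-equation generator by
    GTH state-reduction elimination — mathematically Gaussian elimination
    on the singular generator, but using only additions and divisions of
    nonnegative quantities, so every component of the stationary vector
    carries full relative accuracy even when probabilities span many
    decades (an SVD-based kernel loses all relative accuracy on tiny
    components).  ``ode`` integrates the time-rescaled master equation
    (identical steady state, unit fastest rate) from the uniform
    distribution until the residual ``max|dP/dt|`` drops below
    ``ode_residual``.

    With ``precision`` (significant digits) the ODE route instead applies
    the exact propagator ``exp(L t)`` in arbitrary-precision arithmetic
    with doubling horizons; double-precision time integration has an
    absolute error floor that swamps the relative accuracy of stationary
    probabilities many decades below 1.
    """
    graph.require_strongly_connected()
    L = laplacian(graph, x)
    if method == "nullspace":
        v = _gth_kernel(evaluate_rate_matrix(graph, x))
        probs = {u: float(p) for u, p in zip(graph.vertices, v)}
        return SteadyState(probabilities=probs, method="nullspace_oracle")
    if method == "ode":
        # integrate the time-rescaled system L/s (same steady state, by
        # scale invariance); otherwise the residual floor ~ ||L||*eps can
        # sit above the tolerance for fast-rate graphs
        scale = np.max(np.abs(np.diag(L)))
        if scale == 0:
            raise ValueError("graph has no transitions")
        Ls = L / scale
        if precision is not None:
            import mpmath

            # the residual must undercut the smallest probability of
            # interest times the spectral gap; at high precision just push
            # it far below the double-precision landscape
            mp_residual = min(ode_residual, 10.0 ** (-precision // 2))
            with mpmath.workdps(precision):
                # rebuild the rescaled generator with exactly-zero column
                # sums; the rounded double-precision Laplacian has a
                # column-sum defect ~1e-17 that floors the residual
                R = evaluate_rate_matrix(graph, x)
                M = mpmath.zeros(graph.n)
                for i in range(graph.n):
                    for j in range(graph.n):
                        if i != j:
                            M[j, i] = mpmath.mpf(R[i, j]) / mpmath.mpf(scale)
                for j in range(graph.n):
                    M[j, j] = -sum(M[i, j] for i in range(graph.n) if i != j)
                P = mpmath.expm(M)  # propagator over one rescaled time unit
                p = mpmath.matrix([mpmath.mpf(1) / graph.n] * graph.n)
                t = 1.0
                # squarings are cheap; allow far longer horizons than the
                # adaptive double-precision path (gaps can be ~1e-15)
                while t < max(ode_horizon, 1e36):
                    P = P * P  # doubling the horizon; stochastic, stays benign
                    t *= 2.0
                    p_t = P * p
                    residual = max(abs(v) for v in (M * p_t))
                    if residual < mp_residual:
                        z = sum(p_t)
                        probs = {
                            u: float(q / z) for u, q in zip(graph.vertices, p_t)
                        }
                        return SteadyState(probabilities=probs, method="ode_oracle")
            raise RuntimeError(
                f"high-precision ODE oracle did not converge within horizon {ode_horizon}"
            )
        p = np.full(graph.n, 1.0 / graph.n)
        t = 0.0
        span = 1.0
        while t < ode_horizon:
            if span <= 1e6:
                sol = solve_ivp(
                    lambda _, y: Ls @ y,
                    (0.0, span),
                    p,
                    method="LSODA",
                    rtol=1e-12,
                    atol=1e-14,
                )
                p = sol.y[:, -1]
            else:
                # asymptotic tail: adaptive steppers stall on near-degenerate
                # spectral gaps, so apply the exact propagator instead (the
                # matrix exponential of a generator is a stochastic matrix,
                # numerically benign under scaling-and-squaring)
                p = expm(Ls * span) @ p
            p = np.clip(p, 0.0, None)
            p = p / p.sum()
            t += span
            span *= 10.0
            residual = np.max(np.abs(Ls @ p))
            if residual < ode_residual:
                probs = {u: float(q) for u, q in zip(graph.vertices, p)}
                return SteadyState(probabilities=probs, method="ode_oracle")
        raise RuntimeError(
            f"ODE oracle did not converge within rescaled horizon {ode_horizon}; "
            f"residual {np.max(np.abs(Ls @ p)):.3e}"
        )
    raise ValueError(f"unknown oracle method {method!r}")


# ---------------------------------------------------------------------------
# Random graph generators (property suites and cross-validation)
# ---------------------------------------------------------------------------


def random_strongly_connected_graph(
    rng: np.random.Generator,
    n_vertices: int,
    rate_range: tuple[float, float] = (1e-3, 1e2),
    extra_edges: int | None = None,
) -> RateGraph:
    """Random strongly connected graph with log-uniform constant rates.

    Built as a random spanning tree with both edge directions present
    (which already guarantees strong connectivity) plus a random number of
    extra one-way chords.
    """
    lo, hi = rate_range

    def draw() -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    verts = tuple(str(i) for i in range(n_vertices))
    edges: dict[tuple[str, str], float] = {}
    perm = rng.permutation(n_vertices)
    for i in range(1, n_vertices):
        u = str(perm[rng.integers(0, i)])
        v = str(perm[i])
        edges[(u, v)] = draw()
        edges[(v, u)] = draw()
    n_extra = int(rng.integers(0, n_vertices)) if extra_edges is None else extra_edges
    for _ in range(n_extra):
        u, v = rng.choice(n_vertices, size=2, replace=False)
        edges.setdefault((str(u), str(v)), draw())
    return RateGraph(verts, tuple(Edge(u, v, r, 0.0) for (u, v), r in edges.items()))


def random_detailed_balance_graph(
    rng: np.random.Generator,
    n_vertices: int,
    potential_range: tuple[float, float] = (1e-3, 1e3),
    symmetric_range: tuple[float, float] = (1e-2, 1e2),
    extra_edges: int | None = None,
) -> RateGraph:
    """Random reversible graph satisfying the cycle condition by construction.

    Each vertex gets an equilibrium weight ``mu_v``; each undirected edge a
    symmetric factor ``s_uv``; rates are ``a(u->v) = s_uv * mu_v``, so every
    cycle balances and the stationary distribution is ``mu`` normalized.
    """
    verts = tuple(str(i) for i in range(n_vertices))
    lo, hi = potential_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_vertices))
    slo, shi = symmetric_range

    pairs: set[tuple[int, int]] = set()
    perm = rng.permutation(n_vertices)
    for i in range(1, n_vertices):
        u = int(perm[rng.integers(0, i)])
        v = int(perm[i])
        pairs.add((min(u, v), max(u, v)))
    n_extra = int(rng.integers(0, n_vertices)) if extra_edges is None else extra_edges
    for _ in range(n_extra):
        u, v = rng.choice(n_vertices, size=2, replace=False)
        pairs.add((min(int(u), int(v)), max(int(u), int(v))))

    edges = []
    for u, v in sorted(pairs):
        s = float(np.exp(rng.uniform(np.log(slo), np.log(shi))))
        edges.append(Edge(str(u), str(v), s * mu[v], 0.0))
        edges.append(Edge(str(v), str(u), s * mu[u], 0.0))
    return RateGraph(verts, tuple(edges))
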