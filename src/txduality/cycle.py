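"""Transcription-cycle models: TF regulation of an irreversible Pol cycle.

The polymerase moves through three states — unbound (1), bound but inactive
(2), actively transcribing (3) — with clockwise rates ``k1, k2, k3`` and a
single reverse rate ``k1r`` (promoter escape and elongation are effectively
irreversible).  Transcription rate is the steady-state flux out of state 3.

A TF binds each cycle state with rate ``aT * x`` and unbinds at ``bT``;
while bound it multiplies cycle rate ``ki`` by a factor ``ei > 0``.  The
full model is a 6-vertex graph (cycle state x TF bound/unbound) and the
transcription rate is ``r(x) = k3 P(3,empty) + e3 k3 P(3,TF)``.

Because the cycle itself dissipates energy, incoherent TFs (mixed
accelerating/decelerating effects) can produce nonmonotonic dose responses
even when the TF-binding subsystem satisfies detailed balance (e1 = e1r = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .graphs import Edge, GraphStructureError, RateGraph, steady_state_spanning_tree, steady_state_sweep

CycleMode = Literal["coherent_positive", "coherent_negative", "incoherent", "neutral"]

# Vertex labels: cycle state i with TF absent "(i,0)" or bound "(i,T)".
UNBOUND = tuple(f"({i},0)" for i in (1, 2, 3))
BOUND = tuple(f"({i},T)" for i in (1, 2, 3))


@dataclass(frozen=True)
class CycleParams:
    """Rates of the TF-regulated 3-state transcription cycle.

    k1/k1r: reversible Pol recruitment (1/time); k2: activation, k3:
    transcript completion and promoter clearance (irreversible, 1/time).
    aT (1/(concentration*time)) and bT (1/time) are TF binding/unbinding,
    identical on all cycle states.  ``e1, e1r, e2, e3`` multiply the
    corresponding rate while TF is bound (all default 1 = no effect).
    """

    k1: float
    k1r: float
    k2: float
    k3: float
    aT: float
    bT: float
    e1: float = 1.0
    e1r: float = 1.0
    e2: float = 1.0
    e3: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k1", "k1r", "k2", "k3", "aT", "bT", "e1", "e1r", "e2", "e3"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")


def reference_incoherent_cycle_params(bT: float = 1.0) -> CycleParams:
    """Printed incoherent parameter set: TF accelerates activation (e2=15)
    and slows completion (e3=0.01)."""
    return CycleParams(k1=0.01, k1r=1.0, k2=0.2, k3=0.05, aT=0.1, bT=bT, e2=15.0, e3=0.01)


def build_cycle_graph(p: CycleParams) -> RateGraph:
    """Six-vertex graph: the bare cycle and its TF-bound copy, coupled by binding."""
    if p.aT == 0:
        raise GraphStructureError("aT = 0 disconnects the TF-bound layer")
    u1, u2, u3 = UNBOUND
    t1, t2, t3 = BOUND
    edges = (
        # bare cycle
        Edge(u1, u2, p.k1, 0.0),
        Edge(u2, u1, p.k1r, 0.0),
        Edge(u2, u3, p.k2, 0.0),
        Edge(u3, u1, p.k3, 0.0),
        # TF-bound cycle
        Edge(t1, t2, p.e1 * p.k1, 0.0),
        Edge(t2, t1, p.e1r * p.k1r, 0.0),
        Edge(t2, t3, p.e2 * p.k2, 0.0),
        Edge(t3, t1, p.e3 * p.k3, 0.0),
        # TF binding/unbinding on each cycle state
        Edge(u1, t1, 0.0, p.aT),
        Edge(t1, u1, p.bT, 0.0),
        Edge(u2, t2, 0.0, p.aT),
        Edge(t2, u2, p.bT, 0.0),
        Edge(u3, t3, 0.0, p.aT),
        Edge(t3, u3, p.bT, 0.0),
    )
    return RateGraph(
        vertices=UNBOUND + BOUND,
        edges=edges,
        transcription_weights={u3: p.k3, t3: p.e3 * p.k3},
    )


def cycle_rate(p: CycleParams, x: float, precision: int | None = None) -> float:
    """Transcription rate = flux out of state 3 summed over TF layers."""
    g = build_cycle_graph(p)
    ss = steady_state_spanning_tree(g, x, precision=precision)
    return p.k3 * ss.probabilities[UNBOUND[2]] + p.e3 * p.k3 * ss.probabilities[BOUND[2]]


def cycle_rate_sweep(p: CycleParams, xs: np.ndarray) -> np.ndarray:
    """Vectorized transcription rate over a concentration grid."""
    g = build_cycle_graph(p)
    probs = steady_state_sweep(g, xs)  # vertex order UNBOUND + BOUND
    return p.k3 * probs[:, 2] + p.e3 * p.k3 * probs[:, 5]


def classify_cycle_mode(p: CycleParams) -> CycleMode:
    """Regulatory mode from the signs of the TF's effects on the cycle.

    An effect is accelerating when it raises cycle flux: e1, e2, e3 > 1 or
    e1r < 1.  Coherent modes have all effects one-sided (at least one
    strict); mixed effects are incoherent; no effect is neutral.
    """
    ups = [p.e1 > 1, p.e2 > 1, p.e3 > 1, p.e1r < 1]
    downs = [p.e1 < 1, p.e2 < 1, p.e3 < 1, p.e1r > 1]
    if any(ups) and not any(downs):
        return "coherent_positive"
    if any(downs) and not any(ups):
        return "coherent_negative"
    if any(ups) and any(downs):
        return "incoherent"
    return "neutral"


def cycle_flux_balance(p: CycleParams, x: float) -> tuple[float, float, float]:
    """Net layer-summed fluxes (1->2, 2->3, 3->1); equal at steady state."""
    g = build_cycle_graph(p)
    ss = steady_state_spanning_tree(g, x)
    P = ss.probabilities
    u1, u2, u3 = UNBOUND
    t1, t2, t3 = BOUND
    f12 = p.k1 * P[u1] - p.k1r * P[u2] + p.e1 * p.k1 * P[t1] - p.e1r * p.k1r * P[t2]
    f23 = p.k2 * P[u2] + p.e2 * p.k2 * P[t2]
    f31 = p.k3 * P[u3] + p.e3 * p.k3 * P[t3]
    return f12, f23, f31


def sample_cycle_params(
    rng: np.random.Generator,
    n: int,
    mode: Literal["positive", "negative", "any"] = "any",
) -> list[CycleParams]:
    """Log-uniform cycle parameter sets, optionally restricted to a coherent mode."""
    out = []
    for _ in range(n):
        k1 = 10.0 ** rng.uniform(-3, 1)
        k1r = 10.0 ** rng.uniform(-3, 1)
        k2 = 10.0 ** rng.uniform(-3, 1)
        k3 = 10.0 ** rng.uniform(-3, 1)
        aT = 10.0 ** rng.uniform(-4, 0)
        bT = 10.0 ** rng.uniform(-3, 2)
        if mode == "any":
            e1, e1r, e2, e3 = 10.0 ** rng.uniform(-2, 2, size=4)
        else:
            m1, m1r, m2, m3 = 10.0 ** rng.uniform(0.05, 2, size=4)
            if mode == "positive":
                e1, e1r, e2, e3 = m1, 1 / m1r, m2, m3
            else:
                e1, e1r, e2, e3 = 1 / m1, m1r, 1 / m2, 1 / m3
        out.append(CycleParams(k1, k1r, k2, k3, aT, bT, e1, e1r, e2, e3))
    return out
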