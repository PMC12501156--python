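"""Regulated-recruitment models: a TF modulating Pol binding and activity.

The regulatory region is in one of four states — empty ("1"), TF bound
("2"), Pol bound ("3"), TF and Pol bound ("4") — and transcription proceeds
from the Pol-bound states at rates ``q3`` (basal) and ``q4 = eps * q3``
(TF-modulated).  The steady-state transcription rate is the probability-
weighted sum ``r*(x) = sum_i q_i P_i*(x)`` and the response fold change is
``F(x) = r*(x) / r*(0)`` (mRNA decay cancels).

At thermodynamic equilibrium the model collapses to three ratio parameters
(TF affinity ``KT``, Pol affinity ``Kp`` with the Pol concentration
absorbed, TF–Pol cooperativity ``omega``) plus ``eps``, and the rate has
the closed form

    r*(x) = q3 (Kp + eps Kp KT omega x) / (1 + KT x + Kp + Kp KT omega x)

whose derivative sign — constant in ``x``, hence responses are always
monotone — is the sign of ``Kp omega (eps - 1) + eps omega - 1``.  Away
from equilibrium the eight independent rates are solved on the graph, and
incoherent parameter sets can make the response nonmonotonic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .graphs import Edge, RateGraph, steady_state_spanning_tree, steady_state_sweep

RegulatoryMode = Literal["coherent_positive", "coherent_negative", "incoherent", "neutral"]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class EquilibriumRecruitmentParams:
    """Equilibrium parameterization: affinities, cooperativity, activity factor.

    KT : TF affinity constant (1/concentration)
    Kp : Pol affinity (dimensionless, Pol concentration absorbed)
    omega : TF–Pol binding cooperativity (dimensionless)
    eps : factor change in the basal transcription rate when TF is bound
    q3 : basal transcription rate (transcripts/time)
    """

    KT: float
    Kp: float
    omega: float
    eps: float
    q3: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(KT=self.KT, Kp=self.Kp, omega=self.omega, eps=self.eps, q3=self.q3)


@dataclass(frozen=True)
class NoneqRecruitmentParams:
    """Full rate parameterization of the 4-state recruitment graph.

    ``aT``/``aT_p`` are TF binding rates to the empty / Pol-bound state
    (1/(concentration*time)); ``bT``/``bT_Tp`` the matching unbinding rates
    (1/time).  ``ap``/``ap_T`` are Pol binding rates to the empty / TF-bound
    state and ``bp``/``bp_Tp`` the unbinding rates (1/time; the Pol
    concentration is absorbed into the binding rates).  ``q3``, ``q4`` are
    the transcription rates of the Pol-bound states.
    """

    aT: float
    aT_p: float
    bT: float
    bT_Tp: float
    ap: float
    ap_T: float
    bp: float
    bp_Tp: float
    q3: float = 1.0
    q4: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(
            aT=self.aT, aT_p=self.aT_p, bT=self.bT, bT_Tp=self.bT_Tp,
            ap=self.ap, ap_T=self.ap_T, bp=self.bp, bp_Tp=self.bp_Tp,
            q3=self.q3, q4=self.q4,
        )

    @property
    def eps(self) -> float:
        """Activity modulation factor ``q4 / q3``."""
        return self.q4 / self.q3

    def equilibrium_params(self) -> EquilibriumRecruitmentParams:
        """Ratio parameterization (meaningful when the cycle condition holds)."""
        KT = self.aT / self.bT
        return EquilibriumRecruitmentParams(
            KT=KT,
            Kp=self.ap / self.bp,
            omega=(self.aT_p / self.bT_Tp) / KT,
            eps=self.eps,
            q3=self.q3,
        )


# Fig-style printed parameter set for the incoherent nonequilibrium regime:
# TF enhances Pol recruitment (ap_T/ap = 10, bp/bp_Tp = 10) but reduces its
# activity once bound (q4/q3 = 0.01).  bT is the swept affinity axis.
def incoherent_reference_params(bT: float = 0.1) -> NoneqRecruitmentParams:
    return NoneqRecruitmentParams(
        aT=0.01, aT_p=0.01, bT=bT, bT_Tp=bT,
        ap=0.01, ap_T=0.1, bp=0.1, bp_Tp=0.01,
        q3=1.0, q4=0.01,
    )


def recruitment_rate_equilibrium(p: EquilibriumRecruitmentParams, x) -> np.ndarray | float:
    """Closed-form equilibrium transcription rate; accepts scalar or array x."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    num = p.q3 * (p.Kp + p.eps * p.Kp * p.KT * p.omega * x)
    den = 1.0 + p.KT * x + p.Kp + p.Kp * p.KT * p.omega * x
    out = num / den
    return float(out) if out.ndim == 0 else out


def direction_sign_equilibrium(p: EquilibriumRecruitmentParams) -> int:
    """Sign of the (x-independent) derivative of the equilibrium response.

    +1: increasing for all x; -1: decreasing; 0: flat (neutral TF).
    """
    expr = p.Kp * p.omega * (p.eps - 1.0) + p.eps * p.omega - 1.0
    return int(np.sign(expr))


def classify_regulatory_mode(p: EquilibriumRecruitmentParams, tol: float = 0.0) -> RegulatoryMode:
    """Coherent positive (omega>1 and eps>1), negative (both <1), else incoherent.

    Boundary cases (omega or eps within ``tol`` of 1) are flagged neutral.
    """
    w, e = p.omega, p.eps
    if abs(w - 1.0) <= tol or abs(e - 1.0) <= tol:
        return "neutral"
    if w > 1 and e > 1:
        return "coherent_positive"
    if w < 1 and e < 1:
        return "coherent_negative"
    return "incoherent"


def build_recruitment_graph(p: NoneqRecruitmentParams) -> RateGraph:
    """Four-state graph: 1 empty, 2 TF, 3 Pol, 4 TF+Pol.

    TF-binding edges scale with concentration (x_coeff); Pol binding carries
    the Pol concentration inside the rate constant.
    """
    edges = (
        Edge("1", "2", 0.0, p.aT),
        Edge("2", "1", p.bT, 0.0),
        Edge("3", "4", 0.0, p.aT_p),
        Edge("4", "3", p.bT_Tp, 0.0),
        Edge("1", "3", p.ap, 0.0),
        Edge("3", "1", p.bp, 0.0),
        Edge("2", "4", p.ap_T, 0.0),
        Edge("4", "2", p.bp_Tp, 0.0),
    )
    return RateGraph(
        vertices=("1", "2", "3", "4"),
        edges=edges,
        transcription_weights={"3": p.q3, "4": p.q4},
    )


def recruitment_rate(p: NoneqRecruitmentParams, x: float, precision: int | None = None) -> float:
    """Steady-state transcription rate from the graph (spanning-tree solver)."""
    g = build_recruitment_graph(p)
    ss = steady_state_spanning_tree(g, x, precision=precision)
    return p.q3 * ss.probabilities["3"] + p.q4 * ss.probabilities["4"]


def recruitment_rate_sweep(p: NoneqRecruitmentParams, xs: np.ndarray) -> np.ndarray:
    """Vectorized transcription rate over a concentration grid."""
    g = build_recruitment_graph(p)
    probs = steady_state_sweep(g, xs)  # (nx, 4); vertex order 1,2,3,4
    return p.q3 * probs[:, 2] + p.q4 * probs[:, 3]


# ---------------------------------------------------------------------------
# Samplers for the numerical property suites
# ---------------------------------------------------------------------------


def sample_equilibrium_params(
    rng: np.random.Generator,
    n: int,
    KT=(1e-4, 1e2), Kp=(1e-3, 1e3), omega=(1e-3, 1e3), eps=(1e-3, 1e3),
) -> list[EquilibriumRecruitmentParams]:
    """Log-uniform equilibrium parameter sets over broad plausible ranges."""
    def lu(lo_hi, size):
        lo, hi = lo_hi
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))

    return [
        EquilibriumRecruitmentParams(KT=kt, Kp=kp, omega=w, eps=e, q3=1.0)
        for kt, kp, w, e in zip(lu(KT, n), lu(Kp, n), lu(omega, n), lu(eps, n))
    ]


def sample_coherent_noneq_params(
    rng: np.random.Generator, n: int, mode: Literal["positive", "negative"] = "positive"
) -> list[NoneqRecruitmentParams]:
    """Random rate sets constrained to a coherent regulatory regime.

    Coherence here means every TF effect on Pol points the same way: the
    cooperativity analogue (aT_p/bT_Tp)/(aT/bT), the activity factor q4/q3,
    and the TF-induced changes to Pol binding (ap_T/ap) and retention
    (bp/bp_Tp) all sit on the same side of 1.  This excludes both published
    flavors of incoherence (opposite-signed on/off-rate modulation, and
    opposite recruitment-vs-activity effects).
    """
    out = []
    for _ in range(n):
        aT = 10.0 ** rng.uniform(-4, 0)
        bT = 10.0 ** rng.uniform(-3, 2)
        ap = 10.0 ** rng.uniform(-3, 1)
        bp = 10.0 ** rng.uniform(-3, 2)
        # same-signed multipliers (>1 for positive mode) applied to every channel
        m_omega, m_ap, m_bp, m_eps = 10.0 ** rng.uniform(0.05, 2, size=4)
        if mode == "negative":
            m_omega, m_ap, m_bp, m_eps = 1 / m_omega, 1 / m_ap, 1 / m_bp, 1 / m_eps
        out.append(
            NoneqRecruitmentParams(
                aT=aT, bT=bT,
                aT_p=aT * m_omega, bT_Tp=bT,
                ap=ap, ap_T=ap * m_ap,
                bp=bp, bp_Tp=bp / m_bp,
                q3=1.0, q4=m_eps,
            )
        )
    return out


def sample_equilibrium_consistent_noneq_params(
    rng: np.random.Generator, n: int
) -> list[NoneqRecruitmentParams]:
    """Random rate sets satisfying the cycle condition (detailed balance).

    The single independent cycle 1-2-4-3 balances when
    ``aT * ap_T * bT_Tp * bp == ap * aT_p * bp_Tp * bT``; bT_Tp is solved
    from the other seven free rates.
    """
    out = []
    for _ in range(n):
        aT = 10.0 ** rng.uniform(-4, 0)
        bT = 10.0 ** rng.uniform(-3, 2)
        ap = 10.0 ** rng.uniform(-3, 1)
        bp = 10.0 ** rng.uniform(-3, 2)
        aT_p = 10.0 ** rng.uniform(-4, 0)
        ap_T = 10.0 ** rng.uniform(-3, 1)
        bp_Tp = 10.0 ** rng.uniform(-3, 2)
        bT_Tp = ap * aT_p * bp_Tp * bT / (aT * ap_T * bp)
        q4 = 10.0 ** rng.uniform(-2, 2)
        out.append(
            NoneqRecruitmentParams(
                aT=aT, aT_p=aT_p, bT=bT, bT_Tp=bT_Tp,
                ap=ap, ap_T=ap_T, bp=bp, bp_Tp=bp_Tp,
                q3=1.0, q4=q4,
            )
        )
    return out
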