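"""Cancer-cell lineage algebra and agent rules.

Cancer cells come in three states: cancer stem-like cells (CSC) with
unlimited divisions, progenitor cells with at most ``d_max`` divisions, and
senescent cells that no longer divide and die at rate ``mu``.  A fraction
``k`` of CSC divisions is asymmetric (one CSC + one progenitor daughter);
the rest are symmetric.  The deterministic mean-field of these rules is a
linear ODE chain whose long-time growth rate is r = (1-k) * r_s, so the
CSC division rate consistent with a prescribed whole-tumor growth rate r
is r_s = r / (1 - k).  The chain's asymptotic composition is closed-form:

    P_1/S_c -> p = k*r_s / ((1-k)*r_s + r_p)
    P_i/P_{i-1} -> l1 = 2*r_p / ((1-k)*r_s + r_p)
    S_n/P_dmax -> l2 = 2*r_p / ((1-k)*r_s + mu)

giving steady fractions (1/q, p*l1^(i-1)/q, p*l1^(dmax-1)*l2/q) with
q = 1 + p*(l1^dmax - 1)/(l1 - 1) + p*l1^(dmax-1)*l2 (geometric sum; the
l1 -> 1 limit is q = 1 + p*d_max + p*l2).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .registry import ParameterRegistry

__all__ = [
    "LineageRates",
    "derive_lineage_rates",
    "steady_fractions",
    "lineage_ode_oracle",
]

_L1_UNITY_TOL = 1e-9


@dataclass(frozen=True)
class LineageRates:
    r: float  # net population growth rate, 1/day
    k: float  # asymmetric division probability
    r_s: float  # CSC division rate, 1/day
    r_p: float  # progenitor division rate, 1/day
    mu: float  # senescent death rate, 1/day
    d_max: int  # max progenitor divisions
    p: float = field(init=False)
    l1: float = field(init=False)
    l2: float = field(init=False)
    q: float = field(init=False)
    move_prob_csc: float = 0.05
    move_prob_prog: float = 0.0

    def __post_init__(self) -> None:
        denom_p = (1.0 - self.k) * self.r_s + self.r_p
        p = self.k * self.r_s / denom_p if denom_p > 0 else 0.0
        l1 = 2.0 * self.r_p / denom_p if denom_p > 0 else 0.0
        denom_l2 = (1.0 - self.k) * self.r_s + self.mu
        l2 = 2.0 * self.r_p / denom_l2 if denom_l2 > 0 else 0.0
        if abs(l1 - 1.0) < _L1_UNITY_TOL:
            geo = float(self.d_max)
        else:
            geo = (l1**self.d_max - 1.0) / (l1 - 1.0)
        q = 1.0 + p * geo + p * l1 ** (self.d_max - 1) * l2
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "l1", l1)
        object.__setattr__(self, "l2", l2)
        object.__setattr__(self, "q", q)


def derive_lineage_rates(
    r: float,
    k: float,
    r_p: float,
    mu: float,
    d_max: int,
    move_prob_csc: float = 0.05,
    move_prob_prog: float = 0.0,
) -> LineageRates:
    """Derive agent-rule rates from the whole-tumor growth rate r.

    ``k`` is prescribed and the CSC division rate back-calculated as
    r_s = r/(1-k), so the stochastic lineage grows at the rate the
    compartmental module expects.
    """
    if not 0.0 <= k < 1.0:
        raise ValueError("asymmetric division probability k must be in [0, 1)")
    if min(r, r_p, mu) < 0:
        raise ValueError("rates must be nonnegative")
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    r_s = r / (1.0 - k)
    return LineageRates(
        r=r,
        k=k,
        r_s=r_s,
        r_p=r_p,
        mu=mu,
        d_max=int(d_max),
        move_prob_csc=move_prob_csc,
        move_prob_prog=move_prob_prog,
    )


def rates_from_registry(reg: ParameterRegistry) -> LineageRates:
    return derive_lineage_rates(
        r=reg["k_C_growth"],
        k=reg["k_asym_div"],
        r_p=reg["r_p"],
        mu=reg["mu_senescent"],
        d_max=int(reg["d_max"]),
        move_prob_csc=reg["move_prob_csc"],
        move_prob_prog=reg["move_prob_prog"],
    )


def steady_fractions(rates: LineageRates) -> np.ndarray:
    """Asymptotic composition over (S_c, P_1..P_dmax, S_n); sums to 1.

    Used to seed freshly populated voxels so that filling never perturbs
    the subtype mix.
    """
    p, l1, l2, q = rates.p, rates.l1, rates.l2, rates.q
    fr = np.empty(rates.d_max + 2)
    fr[0] = 1.0 / q
    for i in range(1, rates.d_max + 1):
        fr[i] = p * l1 ** (i - 1) / q
    fr[-1] = p * l1 ** (rates.d_max - 1) * l2 / q
    # normalization identity holds analytically; renormalize round-off only
    return fr / fr.sum()


def lineage_ode_oracle(
    rates: LineageRates,
    initial: np.ndarray | list[float],
    t_end: float,
    n_out: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the mean-field lineage chain; the test oracle for the ABM.

    State ordering matches :func:`steady_fractions`:
    (S_c, P_1, ..., P_dmax, S_n).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    y0 = np.asarray(initial, dtype=float)
    if y0.shape != (rates.d_max + 2,):
        raise ValueError("initial counts must have length d_max + 2")
    k, r_s, r_p, mu, d_max = rates.k, rates.r_s, rates.r_p, rates.mu, rates.d_max

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        dy[0] = (1.0 - k) * r_s * y[0]
        dy[1] = k * r_s * y[0] - r_p * y[1]
        for i in range(2, d_max + 1):
            dy[i] = 2.0 * r_p * y[i - 1] - r_p * y[i]
        dy[d_max + 1] = 2.0 * r_p * y[d_max] - mu * y[d_max + 1]
        return dy

    t_eval = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=1e-10, atol=1e-12, t_eval=t_eval)
    if not sol.success:
        raise ArithmeticError(f"lineage oracle integration failed: {sol.message}")
    return sol.t, sol.y.T
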