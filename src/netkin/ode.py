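"""Vectorized mass-action ODE construction, evaluation and integration.

A compiled reaction system with n elements and m reactions maps onto the
state-space form Ẋ = F(X, K) = H · V(X, K):

* ``H`` is the n×m *net* stoichiometry matrix (products minus substrates per
  element; a catalyst appearing on both sides nets to 0 but still enters the
  rate product);
* ``V`` is the reaction-rate vector.  Under mass action
  v_i = kF_i·∏ reactants − kB_i·∏ products, evaluated for all reactions at
  once as element-wise products over fixed-width reactant/product index
  tables.  Reactions with fewer participants than the table width point at a
  reserved pseudo-element that holds the constant 1, so the evaluation is a
  fixed chain of array products with no per-reaction branching.

``naive_derivatives`` is the deliberately unvectorized per-reaction
reference used to cross-check the matrix formulation in tests.

Integration uses a BDF/NDF-class stiff implicit solver with an analytic
Jacobian assembled from H and the index tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .compiler import ReactionSystem

_NEG_TOL = 1e-9


class SimulationError(RuntimeError):
    pass


@dataclass
class Trajectory:
    times: np.ndarray      # hours, strictly increasing
    states: np.ndarray     # (n_times, n_elements), copies per µl

    def to_frame(self, element_names: list[str] | None = None):
        import pandas as pd

        n = self.states.shape[1]
        names = element_names or [str(i) for i in range(n)]
        records = []
        for ti, t in enumerate(self.times):
            for ei in range(n):
                records.append((t, names[ei], self.states[ti, ei]))
        return pd.DataFrame(records, columns=["time_h", "element", "value"])


@dataclass
class OdeSystem:
    """The assembled state-space system.

    ``r_table``/``p_table`` have shape (arity, m); entries are element
    indices, with the padding index n denoting the constant-one
    pseudo-element.  ``kf_idx`` maps reactions to forward parameter slots;
    ``kb_idx`` uses −1 for irreversible reactions (their backward constant
    is held at exactly 0).
    """

    n: int
    m: int
    n_parameters: int
    H: sp.csr_matrix
    r_table: np.ndarray
    p_table: np.ndarray
    kf_idx: np.ndarray
    kb_idx: np.ndarray
    special: list[tuple[int, str, float]] = field(default_factory=list)
    element_names: list[str] = field(default_factory=list)
    parameter_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        # dense H is faster than sparse matmul at desk scale
        self._H_dense = self.H.toarray() if self.n * self.m <= 1_000_000 else None

    @property
    def H_fast(self):
        return self._H_dense if self._H_dense is not None else self.H

    # ------------------------------------------------------------------
    def split_K(self, K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        K = np.asarray(K, dtype=float)
        if K.shape != (self.n_parameters,):
            raise ValueError(f"K must have length {self.n_parameters}")
        KF = K[self.kf_idx]
        KB = np.where(self.kb_idx >= 0, K[np.clip(self.kb_idx, 0, None)], 0.0)
        return KF, KB

    def rates(self, X: np.ndarray, K: np.ndarray) -> np.ndarray:
        """Reaction-rate vector V(X, K), vectorized over all reactions."""
        X = np.asarray(X, dtype=float)
        if X.shape != (self.n,):
            raise ValueError(f"X must have length {self.n}")
        if np.any(X < -_NEG_TOL * (1.0 + np.abs(X))):
            raise ValueError("state vector has negative entries beyond tolerance")
        KF, KB = self.split_K(K)
        Xa = np.append(np.maximum(X, 0.0), 1.0)
        fwd = KF.copy()
        for row in self.r_table:
            fwd *= Xa[row]
        bwd = KB.copy()
        for row in self.p_table:
            bwd *= Xa[row]
        V = fwd - bwd
        for j, law, coef in self.special:
            V[j] = self._special_rate(j, law, coef, Xa, K)
        return V

    def _special_rate(self, j: int, law: str, coef: float,
                      Xa: np.ndarray, K: np.ndarray) -> float:
        ridx = [i for i in self.r_table[:, j] if i != self.n]
        if law == "michaelis_menten":
            # v = kcat·E·S/(Km+S); kcat in the forward slot, Km in the backward
            kcat = K[self.kf_idx[j]]
            km = K[self.kb_idx[j]] if self.kb_idx[j] >= 0 else 1.0
            s = Xa[ridx[-1]]
            e = Xa[ridx[0]] if len(ridx) > 1 else 1.0
            return kcat * e * s / (km + s)
        if law == "hill":
            vmax = K[self.kf_idx[j]]
            kh = K[self.kb_idx[j]] if self.kb_idx[j] >= 0 else 1.0
            s = Xa[ridx[0]]
            return vmax * s ** coef / (kh ** coef + s ** coef)
        raise ValueError(f"unknown rate law {law!r}")

    def derivatives(self, X: np.ndarray, K: np.ndarray) -> np.ndarray:
        """Ẋ = H · V(X, K)."""
        return self.H @ self.rates(X, K)

    def rate_jacobian(self, X: np.ndarray, K: np.ndarray) -> np.ndarray | None:
        """dV/dX (m×n dense), analytic for pure mass-action systems."""
        if self.special:
            return None
        KF, KB = self.split_K(K)
        Xa = np.append(np.maximum(np.asarray(X, dtype=float), 0.0), 1.0)
        J = np.zeros((self.m, self.n + 1))
        for side, Ktab, table in (("f", KF, self.r_table), ("b", KB, self.p_table)):
            arity = table.shape[0]
            sgn = 1.0 if side == "f" else -1.0
            for s in range(arity):
                partial = sgn * Ktab.copy()
                for s2 in range(arity):
                    if s2 != s:
                        partial *= Xa[table[s2]]
                np.add.at(J, (np.arange(self.m), table[s]), partial)
        return J[:, : self.n]

    def jacobian(self, X: np.ndarray, K: np.ndarray) -> np.ndarray | None:
        dV = self.rate_jacobian(X, K)
        if dV is None:
            return None
        return self.H_fast @ dV

    # ------------------------------------------------------------------
    def simulate(self, X0: np.ndarray, times: np.ndarray, K: np.ndarray,
                 rtol: float = 1e-6, atol: float = 1e-9,
                 method: str = "LSODA",
                 max_rhs_evals: int | None = None) -> Trajectory:
        """Integrate with a stiff implicit method.

        The default LSODA solver switches to its BDF mode on stiff
        stretches; "BDF" and "Radau" are accepted for a fully implicit run.
        Reported states are clipped to 0 where the integrator left them
        within −1e−9 of zero.  On failure the error names the fastest
        reactions at the last state as a stiffness diagnostic.
        ``max_rhs_evals`` caps right-hand-side evaluations so that a
        pathological parameter set cannot stall a parameter search; hitting
        the cap raises :class:`SimulationError`.
        """
        times = np.asarray(times, dtype=float)
        if times.ndim != 1 or len(times) < 2 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing with >= 2 points")
        X0 = np.asarray(X0, dtype=float)
        if X0.shape != (self.n,):
            raise ValueError(f"X0 must have length {self.n}")

        jac = None
        if not self.special and self._H_dense is not None:
            def jac(t, x):  # noqa: ANN001
                return self.jacobian(x, K)

        H = self.H_fast
        KF, KB = self.split_K(K)
        any_backward = bool(np.any(self.kb_idx >= 0))
        Xa = np.empty(self.n + 1)
        Xa[self.n] = 1.0
        n_calls = 0

        def rhs(t, x):  # noqa: ANN001
            nonlocal n_calls
            n_calls += 1
            if max_rhs_evals is not None and n_calls > max_rhs_evals:
                raise SimulationError(
                    f"integration exceeded {max_rhs_evals} RHS evaluations")
            Xa[: self.n] = x
            with np.errstate(over="ignore", invalid="ignore"):
                V = KF.copy()
                for row in self.r_table:
                    V *= Xa[row]
                if any_backward:
                    bwd = KB.copy()
                    for row in self.p_table:
                        bwd *= Xa[row]
                    V -= bwd
                for j, law, coef in self.special:
                    V[j] = self._special_rate(j, law, coef, np.maximum(Xa, 0.0), K)
                return H @ V

        try:
            sol = solve_ivp(
                rhs, (times[0], times[-1]), X0, method=method, t_eval=times,
                rtol=rtol, atol=atol, jac=jac,
            )
        except SimulationError:
            raise
        except (ValueError, FloatingPointError, OverflowError) as err:
            raise SimulationError(f"stiff integration failed: {err}") from err
        if not sol.success or sol.y.shape[1] != len(times):
            x_last = sol.y[:, -1] if sol.y.size else X0
            V = np.abs(self._rates_unchecked(x_last, K))
            top = np.argsort(V)[::-1][:5]
            raise SimulationError(
                "stiff integration failed: " + sol.message
                + "; fastest reactions at last state: "
                + ", ".join(f"r{j} (|v|={V[j]:.3g})" for j in top))
        states = sol.y.T.copy()
        states[(states < 0) & (states > -_NEG_TOL)] = 0.0
        states[0] = X0
        return Trajectory(times=times, states=states)

    def _rates_unchecked(self, X: np.ndarray, K: np.ndarray) -> np.ndarray:
        """Rates without the negativity guard (integrators probe x<0)."""
        KF, KB = self.split_K(K)
        Xa = np.append(X, 1.0)
        fwd = KF.copy()
        for row in self.r_table:
            fwd *= Xa[row]
        bwd = KB.copy()
        for row in self.p_table:
            bwd *= Xa[row]
        V = fwd - bwd
        for j, law, coef in self.special:
            V[j] = self._special_rate(j, law, coef, np.maximum(Xa, 0.0), K)
        return V


def build(sys_: ReactionSystem) -> OdeSystem:
    """Assemble the OdeSystem (H, index tables, parameter maps).

    Ordering is deterministic: elements by ascending id, reactions in the
    compiled order.  H uses net stoichiometry, so catalysts contribute 0.
    """
    n, m = sys_.n_elements, sys_.n_reactions
    p_arity = max((len(r.reactants) for r in sys_.reactions), default=1) or 1
    q_arity = max((len(r.products) for r in sys_.reactions), default=1) or 1

    H = sp.lil_matrix((n, m), dtype=float)
    r_table = np.full((p_arity, m), n, dtype=np.int64)
    p_table = np.full((q_arity, m), n, dtype=np.int64)
    kf_idx = np.zeros(m, dtype=np.int64)
    kb_idx = np.full(m, -1, dtype=np.int64)
    special: list[tuple[int, str, float]] = []

    for j, r in enumerate(sys_.reactions):
        for s, ei in enumerate(r.reactants):
            r_table[s, j] = ei
            H[ei, j] -= 1.0
        for s, ei in enumerate(r.products):
            p_table[s, j] = ei
            H[ei, j] += 1.0
        kf_idx[j] = r.kf_index
        if r.kb_index is not None:
            kb_idx[j] = r.kb_index
        if r.rate_law != "mass_action":
            special.append((j, r.rate_law, r.hill_coefficient))

    return OdeSystem(
        n=n, m=m, n_parameters=sys_.n_parameters, H=H.tocsr(),
        r_table=r_table, p_table=p_table, kf_idx=kf_idx, kb_idx=kb_idx,
        special=special,
        element_names=[el.name for el in sys_.elements],
        parameter_names=list(sys_.parameter_names),
    )


def naive_derivatives(sys_: ReactionSystem, X: np.ndarray,
                      K: np.ndarray) -> np.ndarray:
    """Reaction-by-reaction reference evaluation of Ẋ (test oracle).

    Loops over reactions, computes each rate from the reactant/product lists
    directly, and accumulates ±v per participant occurrence — the per-index
    summation the vectorized formulation must reproduce.
    """
    X = np.asarray(X, dtype=float)
    K = np.asarray(K, dtype=float)
    dx = np.zeros(sys_.n_elements)
    for r in sys_.reactions:
        if r.rate_law == "mass_action":
            fwd = K[r.kf_index]
            for ei in r.reactants:
                fwd *= X[ei]
            bwd = 0.0
            if r.kb_index is not None:
                bwd = K[r.kb_index]
                for ei in r.products:
                    bwd *= X[ei]
            v = fwd - bwd
        elif r.rate_law == "michaelis_menten":
            kcat = K[r.kf_index]
            km = K[r.kb_index] if r.kb_index is not None else 1.0
            if len(r.reactants) > 1:
                e, s = X[r.reactants[0]], X[r.reactants[-1]]
            else:
                e, s = 1.0, X[r.reactants[0]]
            v = kcat * e * s / (km + s)
        elif r.rate_law == "hill":
            vmax = K[r.kf_index]
            kh = K[r.kb_index] if r.kb_index is not None else 1.0
            s = X[r.reactants[0]]
            h = r.hill_coefficient
            v = vmax * s ** h / (kh ** h + s ** h)
        else:  # pragma: no cover
            raise ValueError(f"unknown rate law {r.rate_law!r}")
        for ei in r.reactants:
            dx[ei] -= v
        for ei in r.products:
            dx[ei] += v
    return dx
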