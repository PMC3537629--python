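"""Integrate reaction schemes into species time courses and survival signals.

The photolysis experiment is modeled as an initial-value problem: at t=0 a
fraction ``phi`` of the hemes has its CO photodissociated into the primary
docking site, and the subsequent relaxation across the scheme is followed
over ~1 ns - 10 s.  The measured observable is the fraction of unliganded
photoproduct N(t), a weighted sum of the unliganded-state populations
normalized to 1 at t=0.

Two ligand-pool treatments are supported:

* ``pool_mode="fixed"`` (default): the free-CO concentration is constant
  (pseudo-first-order conditions, CO in large excess over heme).  The
  system is then linear and is propagated exactly through an
  eigendecomposition of the rate matrix.
* ``pool_mode="explicit"``: the free-ligand concentration is depleted and
  replenished explicitly (needed e.g. for stopped-flow mixing where ligand
  and protein are comparable); the resulting nonlinear stiff system is
  integrated with a BDF solver (rtol 1e-10, atol 1e-14, analytic Jacobian).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .scheme import NetworkModel, RateSet, StateSpec, validate_rates

__all__ = [
    "Trajectory",
    "TimeTrace",
    "IntegrationError",
    "log_time_grid",
    "rate_matrix",
    "integrate_network",
    "survival_signal",
    "equilibrium_hexa_fraction",
]


class IntegrationError(RuntimeError):
    """Stiff-solver failure; message carries the offending rate span."""


def log_time_grid(t_min: float = 1e-9, t_max: float = 10.0,
                  points_per_decade: int = 100) -> np.ndarray:
    """Log-spaced time grid covering [t_min, t_max], inclusive."""
    if not 0 < t_min < t_max:
        raise ValueError("need 0 < t_min < t_max")
    decades = np.log10(t_max / t_min)
    n = int(round(decades * points_per_decade)) + 1
    return np.logspace(np.log10(t_min), np.log10(t_max), n)


@dataclass
class Trajectory:
    """Species time courses for the protein states plus the free ligand."""

    times: np.ndarray                    # s, strictly increasing
    populations: np.ndarray              # (n_times, n_protein_states)
    protein_states: tuple[StateSpec, ...]
    free_ligand: np.ndarray              # M, per time point
    init: np.ndarray                     # protein fractions at t = 0

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.protein_states)

    def population(self, name: str) -> np.ndarray:
        return self.populations[:, self.state_names.index(name)]

    def conservation_error(self) -> float:
        return float(np.max(np.abs(self.populations.sum(axis=1) - 1.0)))


@dataclass
class TimeTrace:
    """One measured or synthetic relaxation curve with metadata."""

    times: np.ndarray
    signal: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.times.shape:
                raise ValueError("sigma must match times in length")
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(self.times <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing and > 0")
        if self.signal.shape != self.times.shape:
            raise ValueError("signal must match times in length")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")
        T = self.metadata.get("temperature_K")
        if T is not None and not T > 0:
            raise ValueError("temperature_K must be > 0")

    def __len__(self):
        return self.times.size


# ---------------------------------------------------------------------------
# Rate matrix and propagation
# ---------------------------------------------------------------------------

def rate_matrix(model: NetworkModel, rates: RateSet,
                co_molar: float) -> np.ndarray:
    """First-order rate matrix K over protein states, d x/dt = K x.

    Bimolecular steps enter as pseudo-first-order rates k * [ligand].
    """
    protein = model.protein_states
    idx = {s.name: i for i, s in enumerate(protein)}
    K = np.zeros((len(protein), len(protein)))
    for t in model.transitions:
        k = rates[t.rate_symbol]
        if t.order == "bimolecular":
            k = k * co_molar
        i, j = idx[t.target], idx[t.source]
        K[i, j] += k
        K[j, j] -= k
    return K


def _propagate_linear(K: np.ndarray, x0: np.ndarray,
                      times: np.ndarray) -> np.ndarray | None:
    """Exact solution of dx/dt = K x via eigendecomposition.

    Returns None when the eigenvector matrix is too ill-conditioned to
    trust (caller falls back to the stiff integrator).
    """
    lam, V = np.linalg.eig(K)
    if np.linalg.cond(V) > 1e10:
        return None
    b = np.linalg.solve(V, x0.astype(complex))
    # exp(lam*t) underflows harmlessly to 0 for fast-decaying modes
    with np.errstate(over="raise", under="ignore"):
        try:
            modes = np.exp(np.outer(times, lam))
        except FloatingPointError:
            return None
    out = (modes * b) @ V.T
    if np.max(np.abs(out.imag)) > 1e-8:
        return None
    return out.real


def integrate_network(model: NetworkModel, rates: RateSet,
                      init: dict[str, float], co_molar: float,
                      times: np.ndarray, *, pool_mode: str = "fixed",
                      heme_molar: float = 1e-6, method: str = "auto",
                      rtol: float = 1e-10, atol: float = 1e-14) -> Trajectory:
    """Solve the mass-action kinetics of a scheme on a given time grid.

    Parameters
    ----------
    init:
        initial fractions per protein state (missing states start at 0);
        must sum to 1.
    co_molar:
        free-ligand concentration at t=0 (held constant in fixed-pool mode).
    pool_mode:
        ``"fixed"`` (pseudo-first-order) or ``"explicit"`` (pool depleted,
        requires ``heme_molar`` to convert fractions to concentrations).
    method:
        ``"auto"`` (exact linear propagator when the system is linear,
        BDF otherwise), ``"linear"``, or ``"bdf"``.
    """
    validate_rates(model, rates)
    if co_molar < 0:
        raise ValueError("co_molar must be >= 0")
    times = np.asarray(times, dtype=float)
    if np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing and >= 0")
    protein = model.protein_states
    names = [s.name for s in protein]
    unknown = set(init) - set(names)
    if unknown:
        raise ValueError(f"init names unknown states: {sorted(unknown)}")
    x0 = np.array([init.get(n, 0.0) for n in names])
    if abs(x0.sum() - 1.0) > 1e-9:
        raise ValueError("initial protein fractions must sum to 1")

    linear = pool_mode == "fixed"
    if pool_mode not in ("fixed", "explicit"):
        raise ValueError(f"unknown pool_mode {pool_mode!r}")
    if method == "linear" and not linear:
        raise ValueError("linear propagation requires pool_mode='fixed'")

    pops = None
    ligand = None
    if linear and method in ("auto", "linear"):
        K = rate_matrix(model, rates, co_molar)
        pops = _propagate_linear(K, x0, times)
        if pops is None and method == "linear":
            raise IntegrationError("eigendecomposition ill-conditioned; "
                                   "use method='bdf'")
        if pops is not None:
            ligand = np.full(times.size, co_molar)

    if pops is None:
        pops, ligand = _integrate_bdf(model, rates, x0, co_molar, times,
                                      linear, heme_molar, rtol, atol)

    return Trajectory(times=times, populations=pops,
                      protein_states=protein, free_ligand=ligand, init=x0)


def _integrate_bdf(model, rates, x0, co_molar, times, fixed_pool,
                   heme_molar, rtol, atol):
    protein = model.protein_states
    idx = {s.name: i for i, s in enumerate(protein)}
    n = len(protein)

    # decompose transitions once
    first = []    # (i_src, i_tgt, k, releases_ligand)
    bimol = []    # (i_src, i_tgt, k)
    for t in model.transitions:
        k = rates[t.rate_symbol]
        i, j = idx[t.source], idx[t.target]
        if t.order == "bimolecular":
            bimol.append((i, j, k))
        else:
            first.append((i, j, k, t.ligand_partner is not None))

    K0 = np.zeros((n, n))
    for i, j, k, _ in first:
        K0[j, i] += k
        K0[i, i] -= k

    if fixed_pool:
        def rhs(t, y):
            x = y
            dx = K0 @ x
            for i, j, k in bimol:
                f = k * co_molar * x[i]
                dx[i] -= f
                dx[j] += f
            return dx

        def jac(t, y):
            J = K0.copy()
            for i, j, k in bimol:
                J[i, i] -= k * co_molar
                J[j, i] += k * co_molar
            return J

        y0 = x0
    else:
        def rhs(t, y):
            x, L = y[:n], y[n]
            dx = K0 @ x
            dL = 0.0
            for i, j, k in bimol:
                f = k * L * x[i]
                dx[i] -= f
                dx[j] += f
                dL -= f * heme_molar
            for i, j, k, rel in first:
                if rel:
                    dL += k * x[i] * heme_molar
            return np.append(dx, dL)

        def jac(t, y):
            x, L = y[:n], y[n]
            J = np.zeros((n + 1, n + 1))
            J[:n, :n] = K0
            for i, j, k in bimol:
                J[i, i] -= k * L
                J[j, i] += k * L
                J[i, n] -= k * x[i]
                J[j, n] += k * x[i]
                J[n, i] -= k * L * heme_molar
                J[n, n] -= k * x[i] * heme_molar
            for i, j, k, rel in first:
                if rel:
                    J[n, i] += k * heme_molar
            return J

        y0 = np.append(x0, co_molar)

    t_end = times[-1]
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="BDF", jac=jac,
                    t_eval=times, rtol=rtol, atol=atol)
    if not sol.success:
        kvals = list(rates.values.values())
        raise IntegrationError(
            f"BDF integration failed: {sol.message} "
            f"(rate span {min(kvals):.3g} .. {max(kvals):.3g} s^-1)")
    if fixed_pool:
        return sol.y.T, np.full(times.size, co_molar)
    return sol.y[:n].T, np.maximum(sol.y[n], 0.0)


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

def survival_signal(traj: Trajectory,
                    weights: dict[str, float] | None = None,
                    metadata: dict | None = None) -> TimeTrace:
    """Project a trajectory onto the photolysis survival observable N(t).

    ``signal(t) = sum_i w_i x_i(t)``, normalized to 1 at t=0.  Default
    weights are 1 for every unliganded heme state (docked ligand, penta-
    and hexacoordinated deoxy, ferric intermediate) and 0 for the
    ligand-bound complex and reaction product.
    """
    names = traj.state_names
    if weights is None:
        w = np.array([s.weight for s in traj.protein_states])
    else:
        unknown = set(weights) - set(names)
        if unknown:
            raise ValueError(f"weights name unknown states: {sorted(unknown)}")
        w = np.array([weights.get(n, 0.0) for n in names])
    if np.any(w < 0):
        raise ValueError("observable weights must be >= 0")
    if not np.any(w > 0):
        raise ValueError("at least one observable weight must be positive")
    norm = float(w @ traj.init)
    if norm <= 0:
        raise ValueError("observable is zero at t=0; cannot normalize")
    signal = (traj.populations @ w) / norm
    return TimeTrace(times=traj.times, signal=signal,
                     metadata=dict(metadata or {}))


def equilibrium_hexa_fraction(k_b: float, k_neg_b: float) -> float:
    """Equilibrium fraction of the bis-histidyl hexacoordinated species.

    With His binding rate ``k_b`` and dissociation rate ``k_neg_b``,
    K = k_b/k_neg_b and the hexacoordinated fraction is K/(1+K).
    """
    if not (k_b > 0 and k_neg_b > 0):
        raise ValueError("rates must be > 0")
    K = k_b / k_neg_b
    return K / (1.0 + K)
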