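"""Integration of biomass-space and simplex-projected dynamics.

Biomass space: ``dX/dt = S @ J(X)``.  Dividing by total biomass ``N`` and
substituting ``Y = X/N`` yields the rescaled flow on the unit simplex,

    ``dY/dt = S @ J(Y) - mu(Y) * Y``,    ``mu(Y) = sum(S @ J(Y))``,

which, for networks with degree-one homogeneous fluxes, evolves
independently of ``N``.  The long-term growth rate is the time average of
``mu`` along a trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .network import ReactionNetwork

__all__ = [
    "Trajectory",
    "GrowthEstimate",
    "BlowupWarning",
    "biomass_rhs",
    "mu_instantaneous",
    "simplex_rhs",
    "simulate_biomass",
    "simulate_simplex",
    "simulate_simplex_euler",
    "lambda_time_average",
]

SIMPLEX_ATOL = 1e-8
CLAMP_FLOOR = -1e-10
LOGN_GUARD = 250.0

DEFAULT_SOLVER_OPTS: dict = {"method": "LSODA", "rtol": 1e-9, "atol": 1e-12}


class BlowupWarning(UserWarning):
    """Biomass-space integration hit the overflow guard."""


@dataclass
class Trajectory:
    """Uniformly sampled path of the rescaled system.

    ``Y`` rows live on the unit simplex (clamped and renormalized on
    output); ``logN`` tracks the log system size; ``mu`` the instantaneous
    growth rate at each sample.
    """

    t: np.ndarray
    Y: np.ndarray
    logN: np.ndarray
    mu: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def X(self) -> np.ndarray:
        return np.exp(self.logN)[:, None] * self.Y

    def after(self, t0: float) -> "Trajectory":
        """Sub-trajectory with ``t >= t0`` (used for burn-in removal)."""
        keep = self.t >= t0
        if keep.sum() < 2:
            raise ValueError("burn-in leaves fewer than two samples")
        return Trajectory(self.t[keep], self.Y[keep], self.logN[keep], self.mu[keep], dict(self.meta))

    def to_frame(self):
        import pandas as pd

        n = self.Y.shape[1]
        cols = {"t": self.t}
        names = self.meta.get("nodes", [f"Y{k + 1}" for k in range(n)])
        for k in range(n):
            cols[f"Y_{names[k]}"] = self.Y[:, k]
        cols["logN"] = self.logN
        cols["mu"] = self.mu
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h:
            h.create_dataset("t", data=self.t)
            h.create_dataset("Y", data=self.Y)
            h.create_dataset("logN", data=self.logN)
            h.create_dataset("mu", data=self.mu)
            g = h.create_group("meta")
            for k, v in self.meta.items():
                try:
                    g.attrs[k] = v
                except TypeError:
                    g.attrs[k] = str(v)


@dataclass
class GrowthEstimate:
    """Long-term growth rate from the running time average of ``mu``."""

    lam: float
    running: np.ndarray
    running_t: np.ndarray
    converged: bool
    tol: float
    burn_in: float

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.lam


def _check_simplex(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if abs(Y.sum() - 1.0) > SIMPLEX_ATOL:
        raise ValueError(f"Y is not normalized: sum = {Y.sum()!r}")
    if Y.min() < CLAMP_FLOOR:
        raise ValueError(f"Y has a negative component: {Y.min()!r}")
    return np.clip(Y, 0.0, None)


def biomass_rhs(network: ReactionNetwork, X: np.ndarray) -> np.ndarray:
    """``dX/dt = S @ J(X)`` for one state or a batch of states."""
    X = np.asarray(X, dtype=float)
    if X.min() < CLAMP_FLOOR:
        raise ValueError(f"negative biomass component: {X.min()!r}")
    J = network.flux_values(np.clip(X, 0.0, None))
    return network.S @ J


def mu_instantaneous(network: ReactionNetwork, Y: np.ndarray) -> float:
    """Instantaneous growth rate from composition alone: ``sum(S @ J(Y))``."""
    Y = _check_simplex(Y)
    return float(np.sum(network.S @ network.flux_values(Y)))


def simplex_rhs(network: ReactionNetwork, Y: np.ndarray) -> np.ndarray:
    """Rescaled flow; components sum to zero by construction."""
    Y = _check_simplex(Y)
    v = network.S @ network.flux_values(Y)
    return v - v.sum() * Y


SUM_RESTORE_RATE = 10.0


def _raw_simplex_rhs(network: ReactionNetwork, Y: np.ndarray) -> np.ndarray:
    """Unvalidated simplex RHS for use inside integrator loops.

    Accepts shape (n,) or (n, B); clamps negatives before flux evaluation
    (safe: upstream-limited fluxes vanish at depleted nodes).  Fluxes are
    evaluated at the normalized composition and a restoring term pulls the
    component sum back to 1: the raw projected equations make the simplex
    transversally unstable whenever ``mu < 0`` (the sum defect obeys
    ``d(1 - sum Y)/dt = -mu (1 - sum Y)``), so without stabilization
    round-off drift grows exponentially for decaying systems.  The extra
    term vanishes identically on the manifold.
    """
    Yc = np.clip(Y, 0.0, None)
    s = Yc.sum(axis=0)
    Yn = Yc / s
    v = network.S @ network.flux_values(Yn)
    mu = v.sum(axis=0)
    return v - mu * Yn + SUM_RESTORE_RATE * (1.0 - s) * Yn


def simulate_biomass(
    network: ReactionNetwork,
    X0: Sequence[float],
    t_end: float,
    n_points: int = 2001,
    solver_opts: Mapping | None = None,
) -> Trajectory:
    """Integrate ``dX/dt = S @ J(X)`` on a uniform output grid.

    Exponentially growing systems overflow in this representation; when
    ``logN`` exceeds ~250 the run is truncated with a :class:`BlowupWarning`
    recommending the simplex representation.
    """
    X0 = np.asarray(X0, dtype=float)
    if X0.min() < 0 or X0.sum() <= 0:
        raise ValueError("X0 must be nonnegative and nonzero")
    opts = dict(DEFAULT_SOLVER_OPTS)
    if solver_opts:
        opts.update(solver_opts)

    def rhs(t, X):
        return biomass_rhs(network, X)

    def guard(t, X):
        return np.log(max(X.sum(), 1e-300)) - LOGN_GUARD

    guard.terminal = True
    guard.direction = 1.0
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), X0, t_eval=t_eval, events=guard, **opts)
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"biomass integration failed: {sol.message}")
    X = np.clip(sol.y.T, 0.0, None)
    if sol.status == 1:
        warnings.warn(
            f"biomass blow-up guard hit at t={sol.t_events[0][0]:.3g}; "
            "use simulate_simplex beyond logN ~ 250",
            BlowupWarning,
        )
    Ntot = X.sum(axis=1)
    Y = X / Ntot[:, None]
    mu = np.array([mu_instantaneous(network, y) for y in Y])
    meta = {
        "representation": "biomass",
        "solver": opts.get("method"),
        "rtol": opts.get("rtol"),
        "atol": opts.get("atol"),
        "X0": X0.tolist(),
        "nodes": list(network.nodes),
        "truncated": bool(sol.status == 1),
    }
    return Trajectory(sol.t, Y, np.log(Ntot), mu, meta)


def simulate_simplex(
    network: ReactionNetwork,
    Y0: Sequence[float],
    t_end: float,
    n_points: int = 2001,
    logN0: float = 0.0,
    solver_opts: Mapping | None = None,
) -> Trajectory:
    """Integrate the rescaled flow together with ``d(logN)/dt = mu(Y)``.

    The simplex is compact, so there is no blow-up; ``logN`` is recovered by
    quadrature of ``mu`` as part of the same ODE solve.
    """
    Y0 = _check_simplex(Y0)
    Y0 = Y0 / Y0.sum()
    opts = dict(DEFAULT_SOLVER_OPTS)
    if solver_opts:
        opts.update(solver_opts)
    n = network.n

    def rhs(t, z):
        Yc = np.clip(z[:n], 0.0, None)
        s = Yc.sum()
        Yn = Yc / s
        v = network.S @ network.flux_values(Yn)
        mu = v.sum()
        out = np.empty(n + 1)
        # restoring term: see _raw_simplex_rhs for why the sum defect must
        # be actively damped (transversally unstable when mu < 0)
        out[:n] = v - mu * Yn + SUM_RESTORE_RATE * (1.0 - s) * Yn
        out[n] = mu
        return out

    z0 = np.concatenate([Y0, [logN0]])
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), z0, t_eval=t_eval, **opts)
    if not sol.success:
        raise RuntimeError(f"simplex integration failed: {sol.message}")
    Y = sol.y[:n].T
    Y = np.clip(Y, 0.0, None)
    Y = Y / Y.sum(axis=1, keepdims=True)
    logN = sol.y[n]
    mu = np.array([float(np.sum(network.S @ network.flux_values(y))) for y in Y])
    meta = {
        "representation": "simplex",
        "solver": opts.get("method"),
        "rtol": opts.get("rtol"),
        "atol": opts.get("atol"),
        "Y0": Y0.tolist(),
        "nodes": list(network.nodes),
    }
    return Trajectory(sol.t, Y, logN, mu, meta)


def simulate_simplex_euler(
    network: ReactionNetwork,
    Y0: Sequence[float],
    t_end: float,
    dt: float = 1e-3,
    record_every: int | None = None,
) -> Trajectory:
    """Fixed-step explicit Euler on the simplex.

    This is the zero-noise limit of the stochastic integrator and shares its
    discretization bit-for-bit; prefer :func:`simulate_simplex` for accuracy.
    """
    from .stochastic import NoiseSpec, simulate_simplex_sde

    return simulate_simplex_sde(
        network, Y0, t_end, dt=dt, noise=NoiseSpec(sigma=0.0), record_every=record_every
    )


def lambda_time_average(
    traj: Trajectory,
    burn_in: float | None = None,
    tol: float = 1e-3,
    window: float = 0.2,
) -> GrowthEstimate:
    """Long-term growth rate as the trapezoidal time average of ``mu``.

    ``burn_in`` defaults to the first 20% of the trajectory.  The estimate
    is flagged converged only when the running average varies by less than
    ``tol`` over the trailing ``window`` fraction of the averaged span.
    """
    t_span = traj.t[-1] - traj.t[0]
    if burn_in is None:
        burn_in = traj.t[0] + 0.2 * t_span
    sub = traj.after(burn_in)
    t, mu = sub.t, sub.mu
    dt = np.diff(t)
    inc = 0.5 * (mu[1:] + mu[:-1]) * dt
    cum = np.concatenate([[0.0], np.cumsum(inc)])
    elapsed = t - t[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        running = np.where(elapsed > 0, cum / np.where(elapsed > 0, elapsed, 1.0), mu[0])
    lam = float(running[-1])
    tail = running[t >= t[-1] - window * (t[-1] - t[0])]
    converged = bool(len(tail) >= 2 and (tail.max() - tail.min()) <= tol)
    return GrowthEstimate(
        lam=lam,
        running=running,
        running_t=t,
        converged=converged,
        tol=tol,
        burn_in=float(burn_in),
    )
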