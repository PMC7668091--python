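"""Stochastic composition dynamics on the simplex.

Euler–Maruyama discretization of the rescaled flow with a noise increment
confined to the simplex tangent space (increments sum to zero), so the path
stays on the simplex up to the clamp-and-renormalize boundary rule.  With
zero noise the integrator reduces bit-for-bit to fixed-step explicit Euler.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dynamics import Trajectory, lambda_time_average
from .network import ReactionNetwork

__all__ = ["NoiseSpec", "simulate_simplex_sde", "is_regenerative", "unified_lambda", "UnifiedLambda"]

_SCHEMES = ("tangent_additive", "multiplicative")
MAX_STEP_JUMP = 0.1


@dataclass(frozen=True)
class NoiseSpec:
    """Composition-noise settings.

    ``tangent_additive``: i.i.d. Gaussian increments with the cross-component
    mean removed.  ``multiplicative``: per-component increments scaled by
    ``Y_k`` and projected to the tangent space, so boundary faces are nearly
    absorbing.
    """

    sigma: float = 0.0
    scheme: str = "tangent_additive"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}")


def simulate_simplex_sde(
    network: ReactionNetwork,
    Y0: Sequence[float],
    t_end: float,
    dt: float = 1e-3,
    noise: NoiseSpec | None = None,
    record_every: int | None = None,
    logN0: float = 0.0,
) -> Trajectory:
    """Euler–Maruyama path of the rescaled flow plus composition noise.

    Boundary rule: after each step negative components are clamped to zero
    and the vector renormalized.  A step with ``max |dY| > 0.1`` raises —
    the drift is too stiff for the chosen ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    noise = noise or NoiseSpec(sigma=0.0)
    Y = np.asarray(Y0, dtype=float)
    if abs(Y.sum() - 1.0) > 1e-8 or Y.min() < -1e-10:
        raise ValueError("Y0 must lie on the unit simplex")
    Y = np.clip(Y, 0.0, None)
    Y = Y / Y.sum()
    n = network.n
    n_steps = int(round(t_end / dt))
    if record_every is None:
        record_every = max(1, n_steps // 4000)
    rng = np.random.default_rng(noise.seed)
    sig_dt = noise.sigma * np.sqrt(dt)

    n_rec = n_steps // record_every + 1
    t_out = np.empty(n_rec)
    Y_out = np.empty((n_rec, n))
    logN_out = np.empty(n_rec)
    mu_out = np.empty(n_rec)

    S = network.S
    logN = logN0
    v = S @ network.flux_values(Y)
    mu = float(v.sum())
    k_rec = 0
    t_out[0], Y_out[0], logN_out[0], mu_out[0] = 0.0, Y, logN, mu
    for step in range(1, n_steps + 1):
        drift = (v - mu * Y) * dt
        if np.abs(drift).max() > MAX_STEP_JUMP:
            raise RuntimeError(
                f"step rejected at t={step * dt:.4g}: |dY| > {MAX_STEP_JUMP}; reduce dt"
            )
        if noise.sigma > 0:
            eta = rng.standard_normal(n)
            if noise.scheme == "tangent_additive":
                xi = eta - eta.mean()
            else:  # multiplicative
                z = Y * eta
                xi = z - z.sum() * Y
            Y = Y + drift + sig_dt * xi
        else:
            Y = Y + drift
        np.clip(Y, 0.0, None, out=Y)
        s = Y.sum()
        if s <= 0:
            raise RuntimeError("composition collapsed to zero")
        Y = Y / s
        logN += mu * dt
        v = S @ network.flux_values(Y)
        mu = float(v.sum())
        if step % record_every == 0:
            k_rec += 1
            t_out[k_rec] = step * dt
            Y_out[k_rec] = Y
            logN_out[k_rec] = logN
            mu_out[k_rec] = mu
    meta = {
        "representation": "simplex_sde",
        "solver": "euler_maruyama",
        "dt": dt,
        "sigma": noise.sigma,
        "scheme": noise.scheme,
        "seed": noise.seed,
        "Y0": np.asarray(Y0, dtype=float).tolist(),
        "nodes": list(network.nodes),
    }
    return Trajectory(t_out[: k_rec + 1], Y_out[: k_rec + 1], logN_out[: k_rec + 1], mu_out[: k_rec + 1], meta)


def is_regenerative(network: ReactionNetwork) -> bool:
    """Every node is producible by a flux not maintained by that node.

    Purely structural: node ``x`` qualifies when some flux has ``x`` among
    its downstream nodes while ``x`` is absent from that flux's maintenance
    set, i.e. the network can rebuild ``x`` from the other components.
    """
    for node in network.nodes:
        if not any(
            node in f.downstream and node not in f.maintenance for f in network.fluxes
        ):
            return False
    return True


@dataclass
class UnifiedLambda:
    """Per-start stochastic growth-rate estimates and their spread."""

    lams: np.ndarray
    ses: np.ndarray
    spread: float

    def consistent(self, k: float = 3.0) -> bool:
        """True when all pairwise gaps are within ``k`` combined batch SEs."""
        m = len(self.lams)
        for i in range(m):
            for j in range(i + 1, m):
                se = np.hypot(self.ses[i], self.ses[j])
                if abs(self.lams[i] - self.lams[j]) > k * se:
                    return False
        return True


def _batch_means_se(t: np.ndarray, mu: np.ndarray, n_batches: int = 20) -> float:
    """Standard error of the time-averaged mu by non-overlapping batch means."""
    edges = np.linspace(t[0], t[-1], n_batches + 1)
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        keep = (t >= lo) & (t <= hi)
        if keep.sum() >= 2:
            tt, mm = t[keep], mu[keep]
            means.append(np.trapezoid(mm, tt) / (tt[-1] - tt[0]))
    means = np.asarray(means)
    if len(means) < 2:
        return np.inf
    return float(means.std(ddof=1) / np.sqrt(len(means)))


def unified_lambda(
    network: ReactionNetwork,
    noise: NoiseSpec,
    Y0_list: Sequence[Sequence[float]],
    t_end: float,
    dt: float = 1e-3,
    burn_in_frac: float = 0.2,
) -> UnifiedLambda:
    """Growth rate from several starts under noise; regenerative SRNs only.

    For a regenerative SRN with composition noise there is a single ergodic
    measure, so the per-start estimates should agree within Monte-Carlo
    error (batch-means standard errors are returned alongside).
    """
    if noise.sigma <= 0:
        raise ValueError("unified_lambda requires sigma > 0")
    if not is_regenerative(network):
        raise ValueError(
            "network is not regenerative: some node cannot be rebuilt from the "
            "others, so a unique ergodic measure is not guaranteed and "
            "basin-independence of lambda cannot be asserted"
        )
    lams, ses = [], []
    for i, Y0 in enumerate(Y0_list):
        run_noise = NoiseSpec(sigma=noise.sigma, scheme=noise.scheme, seed=noise.seed + i)
        traj = simulate_simplex_sde(network, Y0, t_end, dt=dt, noise=run_noise)
        est = lambda_time_average(traj, burn_in=burn_in_frac * t_end)
        sub = traj.after(burn_in_frac * t_end)
        lams.append(est.lam)
        ses.append(_batch_means_se(sub.t, sub.mu))
    lams = np.asarray(lams)
    return UnifiedLambda(lams=lams, ses=np.asarray(ses), spread=float(lams.max() - lams.min()))
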