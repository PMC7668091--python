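"""Attractor classification, occupation measures, and phase-diagram scans.

Long-term behavior of the rescaled flow is summarized by the support of its
attractor: the diameter separates fixed points from extended attractors,
the power spectrum separates periodic from quasiperiodic motion, and the
largest Lyapunov exponent flags chaos.  The occupation (ergodic) measure of
a trajectory turns the time-averaged growth rate into a space average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks, periodogram

from .dynamics import Trajectory, lambda_time_average, simulate_simplex
from .network import ReactionNetwork

__all__ = [
    "AttractorSummary",
    "OccupationMeasure",
    "ScanResult",
    "ClassifyOptions",
    "attractor_diameter",
    "classify_attractor",
    "largest_lyapunov",
    "occupation_measure",
    "lambda_space_average",
    "scan_phase_diagram",
]

MAX_EXACT_DIAMETER = 5000


@dataclass
class ClassifyOptions:
    diam_tol: float = 1e-4
    lle_tol: float = 0.005
    burn_in_frac: float = 0.5
    peak_prominence_factor: float = 10.0
    dwell_threshold: float = 0.95
    min_dwell_visits: int = 4
    lle_opts: dict = field(default_factory=dict)


@dataclass
class AttractorSummary:
    label: str  # fixed_point | limit_cycle | quasiperiodic | chaotic | heteroclinic_suspect | unresolved
    diameter: float
    period: float | None
    lle: float | None
    lam: float
    support_points: np.ndarray


@dataclass
class OccupationMeasure:
    """Histogram measure on the simplex in barycentric bins.

    ``bin_ids`` are flat indices into the (conceptual) product grid over the
    first ``n - 1`` barycentric coordinates; only occupied bins are stored.
    """

    n: int
    bins_per_axis: int
    bin_ids: np.ndarray
    masses: np.ndarray
    mean_mu: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.masses.sum() - 1.0) > 1e-12:
            raise ValueError("occupation measure masses must sum to 1")


@dataclass
class ScanResult:
    axes: dict[str, np.ndarray]
    lam: np.ndarray
    diameter: np.ndarray
    label: np.ndarray
    provenance: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        names = list(self.axes)
        grids = np.meshgrid(*self.axes.values(), indexing="ij")
        data = {nm: g.ravel() for nm, g in zip(names, grids)}
        data["lambda"] = self.lam.ravel()
        data["diameter"] = self.diameter.ravel()
        data["label"] = self.label.ravel()
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h:
            for nm, g in self.axes.items():
                h.create_dataset(f"axes/{nm}", data=np.asarray(g))
            h.create_dataset("lambda", data=self.lam)
            h.create_dataset("diameter", data=self.diameter)
            h.create_dataset("label", data=self.label.astype("S"))
            for k, v in self.provenance.items():
                h.attrs[k] = str(v)


def attractor_diameter(points: np.ndarray, max_exact: int = MAX_EXACT_DIAMETER,
                       seed: int = 0) -> float:
    """Max pairwise Euclidean distance over post-transient samples.

    Exact for up to ``max_exact`` points; larger clouds are subsampled
    (uniformly, seeded) which can only underestimate — the subsample bound
    is documented rather than corrected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need at least two points")
    if len(pts) > max_exact:
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(len(pts), size=max_exact, replace=False)]
    best = 0.0
    block = 512
    for i in range(0, len(pts), block):
        chunk = pts[i : i + block]
        d2 = ((chunk[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        best = max(best, float(d2.max()))
    return float(np.sqrt(best))


def _spectral_peaks(traj: Trajectory, prominence_factor: float) -> tuple[np.ndarray, np.ndarray]:
    """Frequencies and powers of prominent peaks of the mean-removed signal."""
    dt = traj.t[1] - traj.t[0]
    sig = traj.Y[:, traj.Y.var(axis=0).argmax()]
    sig = sig - sig.mean()
    freqs, power = periodogram(sig, fs=1.0 / dt)
    freqs, power = freqs[1:], power[1:]
    med = np.median(power)
    floor = prominence_factor * max(med, 1e-300)
    peaks, _ = find_peaks(power, height=floor, prominence=floor)
    order = np.argsort(power[peaks])[::-1]
    f, p = freqs[peaks][order], power[peaks][order]
    if len(p):
        # drop leakage peaks orders of magnitude below the dominant one
        keep = p >= 1e-3 * p[0]
        f, p = f[keep], p[keep]
    return f, p


def _is_harmonic_series(freqs: np.ndarray, rel_tol: float = 0.03) -> bool:
    """True when every listed frequency is an integer multiple of the base."""
    base = freqs.min()
    ratios = freqs / base
    return bool(np.all(np.abs(ratios - np.round(ratios)) <= rel_tol * ratios))


def _dwell_times(traj: Trajectory, threshold: float) -> list[tuple[int, float]]:
    """Contiguous (vertex, duration) episodes with max Y_k above threshold."""
    kmax = traj.Y.argmax(axis=1)
    high = traj.Y.max(axis=1) > threshold
    dt = traj.t[1] - traj.t[0]
    episodes: list[tuple[int, float]] = []
    cur_k, cur_len = -1, 0
    for h, k in zip(high, kmax):
        if h and (cur_k == k or cur_len == 0):
            cur_k = k
            cur_len += 1
        else:
            if cur_len > 0:
                episodes.append((cur_k, cur_len * dt))
            cur_k, cur_len = (k, 1) if h else (-1, 0)
    # an episode still open at the end of the window is truncated: drop it
    # so it cannot break the strictly-increasing dwell criterion
    return episodes


def classify_attractor(
    traj: Trajectory,
    network: ReactionNetwork | None = None,
    opts: ClassifyOptions | None = None,
    lle: float | None = None,
) -> AttractorSummary:
    """Decision cascade over the post-transient part of a trajectory.

    Order: near-zero diameter => fixed point; single prominent spectral peak
    (plus harmonics) with non-positive Lyapunov signature => limit cycle;
    several incommensurate peaks => quasiperiodic; positive largest Lyapunov
    exponent => chaotic; monotonically lengthening near-vertex dwells =>
    heteroclinic suspect; anything else => unresolved.  ``lle`` is computed
    from ``network`` when not supplied; without either, the Lyapunov leg of
    the cascade is skipped.
    """
    opts = opts or ClassifyOptions()
    sub = traj.after(traj.t[0] + opts.burn_in_frac * (traj.t[-1] - traj.t[0]))
    pts = sub.Y
    diam = attractor_diameter(pts)
    lam = lambda_time_average(traj, burn_in=sub.t[0]).lam
    if diam <= opts.diam_tol:
        return AttractorSummary("fixed_point", diam, None, lle, lam, pts)

    if lle is None and network is not None:
        lle = largest_lyapunov(
            network, np.clip(pts[-1], 1e-9, None) / np.clip(pts[-1], 1e-9, None).sum(),
            **{"t_end": 400.0, **opts.lle_opts},
        )

    freqs, powers = _spectral_peaks(sub, opts.peak_prominence_factor)
    lle_small = lle is not None and abs(lle) <= opts.lle_tol
    lle_pos = lle is not None and lle > opts.lle_tol

    if len(freqs) >= 1 and _is_harmonic_series(freqs) and not lle_pos:
        return AttractorSummary("limit_cycle", diam, float(1.0 / freqs.min()), lle, lam, pts)
    if len(freqs) >= 2 and lle_small:
        return AttractorSummary("quasiperiodic", diam, None, lle, lam, pts)
    if lle_pos:
        return AttractorSummary("chaotic", diam, None, lle, lam, pts)

    episodes = _dwell_times(sub, opts.dwell_threshold)
    durations = [d for _, d in episodes]
    if len(durations) >= opts.min_dwell_visits:
        tail = durations[-opts.min_dwell_visits :]
        if all(b > a for a, b in zip(tail, tail[1:])):
            return AttractorSummary("heteroclinic_suspect", diam, None, lle, lam, pts)
    return AttractorSummary("unresolved", diam, None, lle, lam, pts)


def largest_lyapunov(
    network: ReactionNetwork,
    Y0: Sequence[float],
    t_end: float = 500.0,
    renorm_dt: float = 0.5,
    dt: float = 0.01,
    d0: float = 1e-7,
    seed: int = 0,
    discard_frac: float = 0.1,
) -> float:
    """Benettin two-trajectory estimate restricted to the simplex tangent space.

    The reference and perturbed states are advanced together with fixed-step
    RK4 (both columns in one batched flux evaluation); every ``renorm_dt``
    the separation is renormalized to ``d0`` and the log stretch recorded.
    The initial perturbation (and thus all separations, since the flow
    conserves the component sum) lies in the tangent space.
    """
    from .dynamics import _raw_simplex_rhs

    rng = np.random.default_rng(seed)
    Y0 = np.asarray(Y0, dtype=float)
    if abs(Y0.sum() - 1.0) > 1e-8:
        raise ValueError("Y0 must lie on the simplex")
    if Y0.min() <= 0:
        raise ValueError("Y0 must be interior")
    pert = rng.standard_normal(network.n)
    pert -= pert.mean()
    pert *= d0 / np.linalg.norm(pert)
    Z = np.stack([Y0, Y0 + pert], axis=1)  # (n, 2)

    steps_per_block = max(1, int(round(renorm_dt / dt)))
    h = renorm_dt / steps_per_block
    n_blocks = int(round(t_end / renorm_dt))
    logs = np.empty(n_blocks)

    def f(Z):
        return _raw_simplex_rhs(network, Z)

    for b in range(n_blocks):
        for _ in range(steps_per_block):
            k1 = f(Z)
            k2 = f(Z + 0.5 * h * k1)
            k3 = f(Z + 0.5 * h * k2)
            k4 = f(Z + h * k3)
            Z = Z + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if Z[:, 0].min() < -1e-6:
            raise RuntimeError(f"trajectory left the simplex at block {b}; boundary hit")
        delta = Z[:, 1] - Z[:, 0]
        d1 = np.linalg.norm(delta)
        if d1 <= 0:
            d1 = 1e-300
        logs[b] = np.log(d1 / d0)
        Z[:, 1] = Z[:, 0] + delta * (d0 / d1)
    keep = logs[int(discard_frac * n_blocks) :]
    return float(keep.sum() / (len(keep) * renorm_dt))


def occupation_measure(traj: Trajectory, bins: int = 50, burn_in: float | None = None) -> OccupationMeasure:
    """Normalized histogram of the composition path over barycentric bins.

    Requires a uniform time grid (every recorded sample carries the same
    weight).  The per-axis bin count is coarsened so the conceptual product
    grid never exceeds 1e6 cells.
    """
    if burn_in is not None:
        traj = traj.after(burn_in)
    if len(traj.t) == 0:
        raise ValueError("empty trajectory")
    dts = np.diff(traj.t)
    if len(dts) and (dts.max() - dts.min()) > 1e-9 * dts.mean():
        raise ValueError("occupation_measure requires a uniform time grid; resample first")
    n = traj.Y.shape[1]
    axes = max(1, n - 1)
    while bins**axes > 1_000_000 and bins > 2:
        bins = int(np.floor(1_000_000 ** (1.0 / axes)))
    idx = np.clip((traj.Y[:, : n - 1] * bins).astype(int), 0, bins - 1) if n > 1 else np.zeros((len(traj.t), 1), dtype=int)
    flat = np.ravel_multi_index(idx.T, dims=(bins,) * idx.shape[1])
    uniq, inv = np.unique(flat, return_inverse=True)
    # trapezoid time weights (half weight at the window endpoints), so the
    # discrete space average reproduces the trapezoidal time average exactly
    w = np.ones(len(flat))
    if len(w) > 1:
        w[0] = w[-1] = 0.5
    mass_sums = np.bincount(inv, weights=w)
    mu_sums = np.bincount(inv, weights=w * traj.mu)
    masses = mass_sums / mass_sums.sum()
    mean_mu = mu_sums / mass_sums
    return OccupationMeasure(n=n, bins_per_axis=bins, bin_ids=uniq, masses=masses, mean_mu=mean_mu)


def lambda_space_average(measure: OccupationMeasure) -> float:
    """Discrete space average: sum of per-bin mass times per-bin mean mu."""
    return float(measure.masses @ measure.mean_mu)


def scan_phase_diagram(
    model_factory: Callable[..., ReactionNetwork],
    axes: Mapping[str, Sequence[float]],
    opts: Mapping | None = None,
) -> ScanResult:
    """Grid scan: build -> simulate -> classify -> lambda at every point.

    ``model_factory(**point_params)`` must return a valid network.  Failures
    at individual grid points are recorded as label ``"error"`` with NaN
    numbers rather than aborting the scan.
    """
    opts = dict(opts or {})
    t_end = opts.get("t_end", 400.0)
    n_points = opts.get("n_points", 2001)
    Y0 = opts.get("Y0")
    seed = opts.get("seed", 0)
    classify_opts = opts.get("classify_opts") or ClassifyOptions()
    solver_opts = opts.get("solver_opts")
    with_lle = opts.get("with_lle", False)

    axes = {k: np.asarray(v, dtype=float) for k, v in axes.items()}
    shape = tuple(len(v) for v in axes.values())
    lam = np.full(shape, np.nan)
    diam = np.full(shape, np.nan)
    label = np.full(shape, "error", dtype=object)
    rng = np.random.default_rng(seed)
    for midx in product(*(range(s) for s in shape)):
        params = {k: float(v[i]) for (k, v), i in zip(axes.items(), midx)}
        try:
            net = model_factory(**params)
            y0 = np.asarray(Y0, dtype=float) if Y0 is not None else rng.dirichlet(np.ones(net.n))
            traj = simulate_simplex(net, y0, t_end, n_points=n_points, solver_opts=solver_opts)
            summ = classify_attractor(traj, network=net if with_lle else None, opts=classify_opts)
            lam[midx] = summ.lam
            diam[midx] = summ.diameter
            label[midx] = summ.label
        except Exception as exc:  # recorded, not fatal
            label[midx] = f"error:{type(exc).__name__}"
    return ScanResult(
        axes=axes,
        lam=lam,
        diameter=diam,
        label=label,
        provenance={"seed": seed, "t_end": t_end, "n_points": n_points},
    )
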