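"""Small bundled dynamical-regime models.

All constructors return validated networks whose fluxes pass the three
scalability conditions; rate constants default to the registry values.
"""

from __future__ import annotations

from ..network import ReactionNetwork, build_network, flux
from .registry import defaults_for

__all__ = [
    "birth_death",
    "cycle3",
    "bistable3",
    "heteroclinic3",
    "single_repressilator",
    "double_repressilator",
]


def birth_death(r: float | None = None, d: float | None = None) -> ReactionNetwork:
    """One node, catalyzed import at rate ``r`` and export at rate ``d``.

    The composition is pinned at ``Y = (1,)`` so ``mu == r - d`` identically;
    handy as an exactly solvable reference.
    """
    p = defaults_for("birth_death")
    r = p["r"] if r is None else r
    d = p["d"] if d is None else d
    fluxes = [
        flux("birth", f"{r}*x1", {"x1": +1}, upstream=(), downstream=("x1",), maintenance=("x1",)),
        flux("death", f"{d}*x1", {"x1": -1}),
    ]
    return build_network(["x1"], fluxes)


def cycle3(c: float | None = None, K: float | None = None, theta: float | None = None,
           d: float | None = None) -> ReactionNetwork:
    """Three-node ring of cyclically repressed imports: a simplex limit cycle.

    Node ``x_i`` is fed by an import whose rate is repressed by the previous
    node's biomass fraction (Hill form), and drained by linear export.  For
    steep repression the rescaled flow settles on a closed orbit in the
    interior of the two-simplex.
    """
    p = defaults_for("cycle3")
    c = p["c"] if c is None else c
    K = p["K"] if K is None else K
    theta = p["theta"] if theta is None else theta
    d = p["d"] if d is None else d
    nodes = ["x1", "x2", "x3"]
    rep = {"x1": "x3", "x2": "x1", "x3": "x2"}
    fluxes = []
    for x in nodes:
        fluxes.append(
            flux(
                f"in_{x}",
                f"{c}*N/(1 + {K}*({rep[x]}/N)^{theta})",
                {x: +1},
                upstream=(),
                downstream=(x,),
                maintenance=(),
            )
        )
        fluxes.append(flux(f"out_{x}", f"{d}*{x}", {x: -1}))
    return build_network(nodes, fluxes)


def _competition_fluxes(nodes, a, prefix="comp"):
    """Quadratic pairwise-competition exports ``a[i][j] * X_i * X_j / N``."""
    out = []
    for i, xi in enumerate(nodes):
        for j, xj in enumerate(nodes):
            if a[i][j] <= 0:
                continue
            mt = {xi, xj}
            out.append(
                flux(
                    f"{prefix}_{xi}_{xj}",
                    f"{a[i][j]}*{xi}*{xj}/N",
                    {xi: -1},
                    upstream=(xi,),
                    downstream=(),
                    maintenance=sorted(mt),
                )
            )
    return out


def bistable3(r=None, a=None, eps: float | None = None) -> ReactionNetwork:
    """Mutual-exclusion community with two stable fixed points.

    Species 1 and 2 suppress each other strongly, species 3 is inferior
    everywhere, and a weak conversion ring (rate ``eps``) makes the network
    regenerative so noise can carry the composition between basins.
    """
    p = defaults_for("bistable3")
    r = p["r"] if r is None else r
    a = p["a"] if a is None else a
    eps = p["eps"] if eps is None else eps
    nodes = ["x1", "x2", "x3"]
    fluxes = [
        flux(f"grow_{x}", f"{r[i]}*{x}", {x: +1}, upstream=(), downstream=(x,), maintenance=(x,))
        for i, x in enumerate(nodes)
    ]
    fluxes += _competition_fluxes(nodes, a)
    for i, x in enumerate(nodes):
        nxt = nodes[(i + 1) % 3]
        fluxes.append(flux(f"conv_{x}_{nxt}", f"{eps}*{x}", {x: -1, nxt: +1}))
    return build_network(nodes, fluxes)


def heteroclinic3(r: float | None = None, a_self: float | None = None,
                  a_weak: float | None = None, a_strong: float | None = None) -> ReactionNetwork:
    """Rock-paper-scissors competition with an attracting boundary cycle.

    Cyclic dominance with loss outweighing gain (``a_weak + a_strong >
    2 * a_self``) destabilizes the interior fixed point; trajectories dwell
    near each vertex for progressively longer stretches.
    """
    p = defaults_for("heteroclinic3")
    r = p["r"] if r is None else r
    a_self = p["a_self"] if a_self is None else a_self
    a_weak = p["a_weak"] if a_weak is None else a_weak
    a_strong = p["a_strong"] if a_strong is None else a_strong
    nodes = ["x1", "x2", "x3"]
    a = [
        [a_self, a_weak, a_strong],
        [a_strong, a_self, a_weak],
        [a_weak, a_strong, a_self],
    ]
    fluxes = [
        flux(f"grow_{x}", f"{r}*{x}", {x: +1}, upstream=(), downstream=(x,), maintenance=(x,))
        for x in nodes
    ]
    fluxes += _competition_fluxes(nodes, a)
    return build_network(nodes, fluxes)


def _hill(numer: str, pairs: list[tuple[float, str, float]]) -> str:
    """``numer / prod_i (1 + K_i * (rep_i / N)^theta_i)``."""
    denom = "*".join(f"(1 + {K}*({rep}/N)^{theta})" for K, rep, theta in pairs)
    return f"{numer}/({denom})"


def single_repressilator(theta: float | None = None, K: float | None = None, **extra) -> ReactionNetwork:
    """Four-node autocatalytic repressilator.

    ``x1`` is replenished by an influx activated by the total ring biomass
    (``J1``) and drained by export (``J5``); synthesis fluxes ``J2..J4``
    convert ``x1`` into the ring nodes ``x2..x4`` under cyclic sigmoidal
    repression with Hill coefficient ``theta`` and strength ``K``.  Low
    ``theta`` gives balanced growth; steep repression gives a limit cycle
    with a sharply higher growth rate.
    """
    p = defaults_for("single_repressilator")
    theta = p["theta"] if theta is None else theta
    K = p["K"] if K is None else K
    for k, v in extra.items():
        if k not in p:
            raise ValueError(f"unknown parameter {k!r}")
        p[k] = v
    if theta < 0 or K < 0:
        raise ValueError("theta >= 0 and K >= 0 required")
    c1, c, d = p["c1"], p["c"], p["d"]
    nodes = ["x1", "x2", "x3", "x4"]
    repressor = {"x2": "x3", "x3": "x4", "x4": "x2"}
    fluxes = [
        flux(
            "J1",
            f"{c1}*(x2 + x3 + x4)",
            {"x1": +1},
            upstream=(),
            downstream=("x1",),
            maintenance=(),
        )
    ]
    for i, x in enumerate(["x2", "x3", "x4"], start=2):
        rate = _hill(f"{c}*x1", [(K, repressor[x], theta)]) if K > 0 else f"{c}*x1"
        fluxes.append(
            flux(f"J{i}", rate, {"x1": -1, x: +1}, upstream=("x1",), downstream=(x,), maintenance=("x1",))
        )
    fluxes.append(flux("J5", f"{d}*x1", {"x1": -1}))
    return build_network(nodes, fluxes)


def double_repressilator(alpha: float | None = None, **extra) -> ReactionNetwork:
    """Two mutually inhibiting repressilator rings sharing one source node.

    Ring A (``x2..x4``) and ring B (``x5..x7``) are each cyclically
    repressed; in addition every synthesis flux of one ring is repressed by
    the corresponding node of the other ring.  ``alpha`` multiplies the
    cross-ring repression constants acting on ring B (the ratio of
    repression strengths between the oscillators); ring B also runs at a
    detuned intrinsic rate (``c_ratio``) so the uncoupled oscillators are
    incommensurate.
    """
    p = defaults_for("double_repressilator")
    alpha = p["alpha"] if alpha is None else alpha
    for k, v in extra.items():
        if k not in p:
            raise ValueError(f"unknown parameter {k!r}")
        p[k] = v
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    theta, K, Kx = p["theta"], p["K"], p["Kx"]
    theta_x = p.get("theta_x") or theta
    shift = int(p.get("cross_shift", 0))
    c1, c, cr, d = p["c1"], p["c"], p["c_ratio"], p["d"]
    nodes = ["x1", "x2", "x3", "x4", "x5", "x6", "x7"]
    ringA = ["x2", "x3", "x4"]
    ringB = ["x5", "x6", "x7"]
    rep = {
        "x2": "x3", "x3": "x4", "x4": "x2",
        "x5": "x6", "x6": "x7", "x7": "x5",
    }
    # cross-ring inhibition partner; a nonzero shift frustrates the phase
    # relation between the rings
    partner = {}
    for i, (a, b) in enumerate(zip(ringA, ringB)):
        partner[a] = ringB[(i + shift) % 3]
        partner[b] = ringA[(i + shift) % 3]
    fluxes = [
        flux(
            "J1",
            f"{c1}*(x2 + x3 + x4 + x5 + x6 + x7)",
            {"x1": +1},
            upstream=(),
            downstream=("x1",),
            maintenance=(),
        )
    ]
    for i, x in enumerate(ringA + ringB, start=2):
        in_b = x in ringB
        rate0 = f"{c * cr}*x1" if in_b else f"{c}*x1"
        cross_K = Kx * alpha if in_b else Kx
        rate = _hill(rate0, [(K, rep[x], theta), (cross_K, partner[x], theta_x)])
        fluxes.append(
            flux(f"J{i}", rate, {"x1": -1, x: +1}, upstream=("x1",), downstream=(x,), maintenance=("x1",))
        )
    fluxes.append(flux("J8", f"{d}*x1", {"x1": -1}))
    return build_network(nodes, fluxes)
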