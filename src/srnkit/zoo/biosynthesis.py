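"""24-node autocatalytic biosynthesis toy model with explicit ATP bookkeeping.

Three external nutrients are imported by transporters ``P1..P3`` into
metabolites ``m1..m3``, converted through intermediates ``m4..m6`` into
amino acids ``m7..m10``, which are either polymerized (costing ATP) into
transporters, enzymes ``Q1..Q8`` and ribosomes ``R``, or catabolized
(regenerating ATP from ADP).  Every reaction that moves phosphate swaps
ATP and ADP one-for-one per unit, so the adenosine moiety is conserved by
the stoichiometry; a slow nucleotide-synthesis flux replenishes the
adenosine pool against dilution.

Stoichiometric energy accounting per amino-acid unit: catabolism yields
``atp_yield`` ATP, amino-acid synthesis costs 2 ATP, polymerization costs
3 ATP.
"""

from __future__ import annotations

import numpy as np

from ..network import ReactionNetwork, build_network, flux
from .registry import defaults_for

__all__ = [
    "biosynthesis_toy",
    "AA_NODES",
    "predicted_optimal_fraction",
    "catabolic_flux_fraction",
]

AA_NODES = ["m7", "m8", "m9", "m10"]
POLYMERS = ["P1", "P2", "P3", "Q1", "Q2", "Q3", "Q4", "Q5", "Q6", "Q7", "Q8", "R"]
SYNTH_COST = 2.0
POLYM_COST = 3.0


def biosynthesis_toy(
    thetaR: float | None = None,
    nutrient_level: float | None = None,
    atp_yield: float | None = None,
    **overrides,
) -> ReactionNetwork:
    """Build the 24-node model.

    ``thetaR`` scales the ribosome-producing polymerization flux,
    ``nutrient_level`` scales all three imports (the external pools are an
    ideal reservoir, so they enter as parameters rather than nodes), and
    ``atp_yield`` is the ATP produced per catabolized amino acid.
    """
    p = defaults_for("biosynthesis_toy")
    thetaR = p["thetaR"] if thetaR is None else thetaR
    nutrient_level = p["nutrient_level"] if nutrient_level is None else nutrient_level
    atp_yield = p["atp_yield"] if atp_yield is None else atp_yield
    for k, v in overrides.items():
        if k not in p:
            raise ValueError(f"unknown parameter {k!r}")
        p[k] = v
    if thetaR <= 0 or nutrient_level < 0 or atp_yield <= 0:
        raise ValueError("thetaR > 0, nutrient_level >= 0, atp_yield > 0 required")
    v_imp, v_enz, v_cat, v_pol = p["v_imp"], p["v_enz"], p["v_cat"], p["v_pol"]
    K, K_atp = p["K"], p["K_atp"]

    nodes = [f"m{i}" for i in range(1, 11)] + POLYMERS[:3] + POLYMERS[3:11] + ["R", "ATP", "ADP"]
    fluxes = []

    def mm(sub: str, cat: str, v: float) -> str:
        return f"{v}*{sub}*{cat}/({sub} + {K}*N)"

    def atp_sat(expr: str) -> str:
        return f"({expr})*ATP/(ATP + {K_atp}*N)"

    def adp_sat(expr: str) -> str:
        return f"({expr})*ADP/(ADP + {K_atp}*N)"

    # nutrient import, transporter-catalyzed (external pools are parameters,
    # not nodes); at zero nutrient the imports are absent rather than a
    # constant-zero rate, which would fail strict positivity
    if nutrient_level > 0:
        for i in (1, 2, 3):
            fluxes.append(
                flux(
                    f"imp_m{i}",
                    f"{v_imp * nutrient_level}*P{i}",
                    {f"m{i}": +1},
                    upstream=(),
                    downstream=(f"m{i}",),
                    maintenance=(f"P{i}",),
                )
            )
    # intermediate metabolism m1..m3 -> m4..m6
    for i in (1, 2, 3):
        fluxes.append(
            flux(
                f"cnv_m{i}_m{i + 3}",
                mm(f"m{i}", f"Q{i}", v_enz),
                {f"m{i}": -1, f"m{i + 3}": +1},
                upstream=(f"m{i}",),
                downstream=(f"m{i + 3}",),
                maintenance=(f"m{i}", f"Q{i}"),
            )
        )
    # amino-acid synthesis, 2 ATP each
    aa_routes = {"m7": ("m4", "Q4"), "m8": ("m5", "Q5"), "m9": ("m6", "Q6"), "m10": ("m4", "Q7")}
    for aa, (prec, enz) in aa_routes.items():
        fluxes.append(
            flux(
                f"aa_{aa}",
                atp_sat(mm(prec, enz, v_enz)),
                {prec: -1, aa: +1, "ATP": -SYNTH_COST, "ADP": +SYNTH_COST},
                upstream=(prec, "ATP"),
                downstream=(aa, "ADP"),
                maintenance=(prec, enz, "ATP"),
            )
        )
    # catabolism: amino acid + y ADP -> y ATP (amino-acid mass leaves the system)
    for aa in AA_NODES:
        fluxes.append(
            flux(
                f"cat_{aa}",
                adp_sat(mm(aa, "Q8", v_cat)),
                {aa: -1, "ADP": -atp_yield, "ATP": +atp_yield},
                upstream=(aa, "ADP"),
                downstream=("ATP",),
                maintenance=(aa, "Q8", "ADP"),
            )
        )
    # ribosome-catalyzed polymerization: one amino-acid unit + 3 ATP -> polymer
    aa_sat = "*".join(f"(m{k}/(m{k} + {K}*N))" for k in (7, 8, 9, 10))
    for pol in POLYMERS:
        w = thetaR if pol == "R" else 1.0
        fluxes.append(
            flux(
                f"pol_{pol}",
                atp_sat(f"{v_pol * w}*R*{aa_sat}"),
                {
                    "m7": -0.25, "m8": -0.25, "m9": -0.25, "m10": -0.25,
                    pol: +1, "ATP": -POLYM_COST, "ADP": +POLYM_COST,
                },
                upstream=("m7", "m8", "m9", "m10", "ATP"),
                downstream=(pol, "ADP"),
                maintenance=("R", "m7", "m8", "m9", "m10", "ATP"),
            )
        )
    # nucleotide synthesis keeps the adenosine pool from diluting away
    fluxes.append(
        flux(
            "adp_syn",
            mm("m6", "Q7", 0.5 * v_enz),
            {"m6": -1, "ADP": +1},
            upstream=("m6",),
            downstream=("ADP",),
            maintenance=("m6", "Q7"),
        )
    )
    return build_network(nodes, fluxes)


def default_y0(network: ReactionNetwork) -> np.ndarray:
    """Uniform composition start used by the shipped analyses."""
    return np.full(network.n, 1.0 / network.n)


def predicted_optimal_fraction(atp_yield: float, synth_cost: float = SYNTH_COST,
                               polym_cost: float = POLYM_COST) -> float:
    """ATP-balancing catabolic fraction of amino-acid consumption.

    Per amino-acid unit the anabolic route consumes ``synth_cost +
    polym_cost`` ATP while the catabolic route nets ``atp_yield -
    synth_cost``; the consumption fraction routed to catabolism that
    balances production against consumption is their ratio normalized.
    """
    if atp_yield <= synth_cost:
        raise ValueError("atp_yield must exceed the synthesis cost")
    anab = synth_cost + polym_cost
    return anab / (anab + (atp_yield - synth_cost))


def catabolic_flux_fraction(network: ReactionNetwork, traj, burn_in: float | None = None) -> float:
    """Time-averaged catabolic share of total amino-acid consumption.

    Classified from stoichiometry: a flux consumes amino acids when it has
    negative stoichiometry on any of ``m7..m10``; it is catabolic when it
    also produces ATP, anabolic otherwise.  The weight of each flux is its
    total amino-acid consumption per unit flux.
    """
    if burn_in is None:
        burn_in = traj.t[0] + 0.2 * (traj.t[-1] - traj.t[0])
    sub = traj.after(burn_in)
    cat_w = np.zeros(network.m)
    ana_w = np.zeros(network.m)
    for a, fx in enumerate(network.fluxes):
        w = -sum(min(fx.stoich.get(k, 0.0), 0.0) for k in AA_NODES)
        if w <= 0:
            continue
        if fx.stoich.get("ATP", 0.0) > 0:
            cat_w[a] = w
        else:
            ana_w[a] = w
    J = network.flux_values(sub.Y.T)  # (m, T)
    cat = np.trapezoid(cat_w @ J, sub.t)
    ana = np.trapezoid(ana_w @ J, sub.t)
    total = cat + ana
    if total <= 0:
        raise ZeroDivisionError("no amino-acid consumption along the trajectory")
    return float(cat / total)
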