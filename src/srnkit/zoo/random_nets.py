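"""Seeded random network generator with power-law node selection.

Fluxes are drawn from the scalable rate-law families (linear, saturating,
quadratic-competitive, sigmoidal-repressed), with upstream/downstream/
catalyst nodes sampled under a power-law weight over a seeded node
permutation — a few hub nodes collect most connections.  Every generated
network passes the scalability checks by construction.
"""

from __future__ import annotations

import numpy as np

from ..network import ReactionNetwork, build_network, flux
from .registry import defaults_for

__all__ = ["random_srn", "DEFAULT_FAMILY_WEIGHTS"]

DEFAULT_FAMILY_WEIGHTS: dict[str, float] = {
    "import": 0.25,
    "conversion": 0.2,
    "mm_conversion": 0.15,
    "export": 0.2,
    "competition": 0.1,
    "repressed_conversion": 0.1,
}


def _power_law_picker(n: int, exponent: float, rng: np.random.Generator):
    ranks = rng.permutation(n) + 1
    w = ranks.astype(float) ** (-exponent)
    w /= w.sum()

    def pick(exclude: set[int] | None = None) -> int:
        if not exclude:
            return int(rng.choice(n, p=w))
        mask = np.ones(n, bool)
        mask[list(exclude)] = False
        ww = np.where(mask, w, 0.0)
        return int(rng.choice(n, p=ww / ww.sum()))

    return pick


def random_srn(
    n_nodes: int | None = None,
    n_fluxes: int | None = None,
    connectivity_exponent: float | None = None,
    flux_family_weights: dict[str, float] | None = None,
    seed: int = 0,
) -> ReactionNetwork:
    """Draw one random scalable network (deterministic given ``seed``)."""
    d = defaults_for("random_srn")
    n = d["n_nodes"] if n_nodes is None else n_nodes
    m = d["n_fluxes"] if n_fluxes is None else n_fluxes
    gamma = d["connectivity_exponent"] if connectivity_exponent is None else connectivity_exponent
    if n < 1 or m < 1:
        raise ValueError("need n_nodes >= 1 and n_fluxes >= 1")
    weights = dict(DEFAULT_FAMILY_WEIGHTS)
    if flux_family_weights:
        weights.update(flux_family_weights)
    fams = sorted(weights)
    probs = np.array([weights[f] for f in fams], dtype=float)
    probs /= probs.sum()

    rng = np.random.default_rng(seed)
    pick = _power_law_picker(n, gamma, rng)
    nodes = [f"x{i + 1}" for i in range(n)]

    def rc(lo=0.2, hi=2.0) -> float:
        return float(np.round(np.exp(rng.uniform(np.log(lo), np.log(hi))), 6))

    fluxes = []
    for a in range(m):
        fam = fams[int(rng.choice(len(fams), p=probs))]
        if n == 1:
            fam = "import" if fam in ("conversion", "mm_conversion", "repressed_conversion", "competition") else fam
        r = rc()
        if fam == "import":
            t = pick()
            c = pick()
            fluxes.append(
                flux(f"f{a}_imp", f"{r}*{nodes[c]}", {nodes[t]: +1},
                     upstream=(), downstream=(nodes[t],), maintenance=(nodes[c],))
            )
        elif fam == "conversion":
            u = pick()
            t = pick(exclude={u})
            fluxes.append(flux(f"f{a}_cnv", f"{r}*{nodes[u]}", {nodes[u]: -1, nodes[t]: +1}))
        elif fam == "mm_conversion":
            u = pick()
            t = pick(exclude={u})
            z = pick()
            K = rc(0.5, 20.0)
            fluxes.append(
                flux(
                    f"f{a}_mm",
                    f"{r}*{nodes[u]}*{nodes[z]}/({nodes[u]} + {K}*N)",
                    {nodes[u]: -1, nodes[t]: +1},
                    upstream=(nodes[u],),
                    downstream=(nodes[t],),
                    maintenance=sorted({nodes[u], nodes[z]}),
                )
            )
        elif fam == "export":
            u = pick()
            fluxes.append(flux(f"f{a}_exp", f"{r}*{nodes[u]}", {nodes[u]: -1}))
        elif fam == "competition":
            u = pick()
            j = pick()
            fluxes.append(
                flux(
                    f"f{a}_cmp",
                    f"{r}*{nodes[u]}*{nodes[j]}/N",
                    {nodes[u]: -1},
                    upstream=(nodes[u],),
                    downstream=(),
                    maintenance=sorted({nodes[u], nodes[j]}),
                )
            )
        else:  # repressed_conversion
            u = pick()
            t = pick(exclude={u})
            pnode = pick()
            K = rc(0.5, 20.0)
            theta = int(rng.integers(1, 4))
            fluxes.append(
                flux(
                    f"f{a}_rep",
                    f"{r}*{nodes[u]}/(1 + {K}*({nodes[pnode]}/N)^{theta})",
                    {nodes[u]: -1, nodes[t]: +1},
                )
            )
    return build_network(nodes, fluxes)
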