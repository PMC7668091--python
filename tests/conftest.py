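import numpy as np
import pytest

from srnkit import build_network, flux
from srnkit.zoo import (
    bistable3,
    birth_death,
    cycle3,
    double_repressilator,
    heteroclinic3,
    single_repressilator,
)


@pytest.fixture(scope="session")
def birth_death_net():
    return birth_death(r=0.5, d=0.2)


@pytest.fixture(scope="session")
def repressilator_fp():
    """Registry balanced-growth regime: theta=1, K=500."""
    return single_repressilator(theta=1.0, K=500.0)


@pytest.fixture(scope="session")
def repressilator_lc():
    """Registry periodic regime: theta=3, K=500."""
    return single_repressilator(theta=3.0, K=500.0)


@pytest.fixture(scope="session")
def cycle3_net():
    return cycle3()


@pytest.fixture(scope="session")
def bistable_net():
    return bistable3()


@pytest.fixture(scope="session")
def heteroclinic_net():
    return heteroclinic3()


@pytest.fixture(scope="session")
def double_rep_default():
    return double_repressilator()


@pytest.fixture(scope="session")
def conversion_only_net():
    """Two-node pure interconversion: N is conserved, mu == 0."""
    return build_network(
        ["x1", "x2"],
        [
            flux("fwd", "1.0*x1", {"x1": -1, "x2": +1}),
            flux("bwd", "0.5*x2", {"x2": -1, "x1": +1}),
        ],
    )


def random_linear_srn(seed: int, n_max: int = 5):
    """Random linear network plus its independently assembled rate matrix M.

    Fluxes are all linear (``r * x_k``) imports/conversions/exports, so the
    biomass dynamics are exactly ``dX/dt = M X`` with Metzler ``M`` built
    here coefficient by coefficient, bypassing the network evaluator.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"x{i + 1}" for i in range(n)]
    M = np.zeros((n, n))
    fluxes = []
    m = int(rng.integers(n, 2 * n + 3))
    for a in range(m):
        kind = rng.choice(["imp", "cnv", "exp"], p=[0.4, 0.4, 0.2])
        r = float(np.round(rng.uniform(0.1, 1.0), 4))
        if kind == "imp":
            t = int(rng.integers(n))
            c = int(rng.integers(n))
            fluxes.append(
                flux(f"f{a}", f"{r}*{nodes[c]}", {nodes[t]: +1},
                     upstream=(), downstream=(nodes[t],), maintenance=(nodes[c],))
            )
            M[t, c] += r
        elif kind == "cnv":
            u = int(rng.integers(n))
            t = int((u + 1 + rng.integers(n - 1)) % n)
            fluxes.append(flux(f"f{a}", f"{r}*{nodes[u]}", {nodes[u]: -1, nodes[t]: +1}))
            M[u, u] -= r
            M[t, u] += r
        else:
            u = int(rng.integers(n))
            fluxes.append(flux(f"f{a}", f"{r}*{nodes[u]}", {nodes[u]: -1}))
            M[u, u] -= r
    # guarantee irreducibility with a weak conversion ring
    for i in range(n):
        j = (i + 1) % n
        fluxes.append(flux(f"ring{i}", f"0.05*{nodes[i]}", {nodes[i]: -1, nodes[j]: +1}))
        M[i, i] -= 0.05
        M[j, i] += 0.05
    return build_network(nodes, fluxes), M
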