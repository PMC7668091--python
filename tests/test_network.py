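import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srnkit import (
    build_network,
    check_homogeneity,
    check_scalability,
    check_upstream_limited,
    flux,
    flux_from_unit_volume,
)
from srnkit.network import NetworkValidationError, check_positivity_smoothness


class TestBuildNetwork:
    def test_minimal_autocatalytic_import(self):
        fx = flux("J", "0.3*x1", {"x1": +1}, upstream=(), downstream=("x1",), maintenance=("x1",))
        net = build_network(["x1"], [fx])
        assert net.S.shape == (1, 1)
        assert net.S[0, 0] == 1.0

    def test_negative_stoich_requires_upstream(self):
        with pytest.raises(NetworkValidationError, match="upstream"):
            flux("J", "0.3*x1", {"x1": -1}, upstream=(), downstream=(), maintenance=())

    def test_upstream_must_be_maintained(self):
        with pytest.raises(NetworkValidationError, match="maintenance"):
            flux("J", "x1*x2/N", {"x1": -1}, upstream=("x1",), downstream=(), maintenance=())

    def test_duplicate_node_id(self):
        fx = flux("J", "0.3*x1", {"x1": +1}, maintenance=("x1",))
        with pytest.raises(NetworkValidationError, match="duplicate"):
            build_network(["x1", "x1"], [fx])

    def test_unknown_stoich_node(self):
        fx = flux("J", "0.3*x1", {"x1": -1, "zz": +1})
        with pytest.raises(NetworkValidationError, match="undeclared"):
            build_network(["x1"], [fx])

    def test_repressilator_shape_and_columns(self, repressilator_fp):
        net = repressilator_fp
        assert net.S.shape == (4, 5)
        sums = net.S.sum(axis=0)
        by_id = dict(zip([f.id for f in net.fluxes], sums))
        assert by_id["J1"] == 1.0  # import
        assert by_id["J5"] == -1.0  # export
        for fid in ("J2", "J3", "J4"):  # conversions conserve mass
            assert by_id[fid] == 0.0

    def test_rate_expression_validated_eagerly(self):
        fx = flux("J", "0.3*x9", {"x1": +1})
        with pytest.raises(NetworkValidationError, match="unknown symbols"):
            build_network(["x1"], [fx])


class TestHomogeneity:
    def test_linear_passes(self):
        fx = flux("J", "0.7*x1", {"x1": -1})
        v = check_homogeneity(fx, nodes=["x1", "x2"], n_samples=100, tol=1e-9, seed=0)
        assert v.passed and v.symbolic is True

    def test_quadratic_fraction_passes(self):
        # r * Y_j^a * Y_k^b * N family, a=2, b=1
        fx = flux("J", "1.3*(x1/N)^2*(x2/N)*N", {"x1": -1}, maintenance=("x1", "x2"))
        v = check_homogeneity(fx, nodes=["x1", "x2", "x3"], n_samples=100, tol=1e-9, seed=1)
        assert v.passed

    def test_asymptotically_scalable_fails_strict(self):
        # rational regulation with nonzero higher-order coefficients
        fx = flux(
            "J",
            "x1*(1.0 + 0.5*x2 + 0.2*x2^2)/(1.0 + 0.3*x2 + 0.1*x2^2)",
            {"x1": -1},
        )
        v = check_homogeneity(fx, nodes=["x1", "x2"], n_samples=100, tol=1e-9, seed=2)
        assert not v.passed
        assert v.counterexamples

    def test_constant_rate_fails(self):
        fx = flux("J", "2.5", {"x1": +1}, downstream=("x1",))
        v = check_homogeneity(fx, nodes=["x1"], n_samples=50, tol=1e-9, seed=3)
        assert not v.passed

    def test_callable_rate_numeric_only(self):
        fx = flux("J", lambda v: 0.7 * v["x1"], {"x1": -1})
        v = check_homogeneity(fx, nodes=["x1"], n_samples=50, tol=1e-9, seed=4)
        assert v.passed and v.symbolic is None


class TestUpstreamLimited:
    def test_two_substrate_fraction_passes(self):
        fx = flux(
            "J",
            "1.1*x1*x2/(0.5*x1 + 0.25*x2 + 0.1*N)",
            {"x1": -1, "x2": -1},
            maintenance=("x1", "x2"),
        )
        assert check_upstream_limited(fx, nodes=["x1", "x2", "x3"], seed=0).passed

    def test_undeclared_dependence_fails(self):
        fx = flux("J", "0.9*x1", {"x1": -1}, upstream=("x1", "x2"), maintenance=("x1", "x2"))
        v = check_upstream_limited(fx, nodes=["x1", "x2"], seed=1)
        assert not v.passed
        assert v.counterexamples[0][0] == "x2"

    def test_maintenance_node_hill_passes(self):
        # r * x1^theta * x3 / (x1^theta + K * N^theta), maintained by x3
        fx = flux(
            "J",
            "0.8*x1^2*x3/(x1^2 + 5.0*N^2)",
            {"x1": -1},
            maintenance=("x1", "x3"),
        )
        assert check_upstream_limited(fx, nodes=["x1", "x2", "x3"], seed=2).passed


class TestScalabilityReport:
    def test_scalable_family_network(self):
        nodes = ["x1", "x2", "x3"]
        fluxes = [
            flux("lin", "0.5*x1", {"x1": -1, "x2": +1}),
            flux("quad", "0.8*(x1/N)*(x2/N)*N", {"x1": -1}, maintenance=("x1", "x2")),
            flux("hill", "1.2*x1^2*x3/(x1^2 + 7.0*N^2)", {"x1": -1, "x3": +1}, maintenance=("x1", "x3")),
            flux("mm", "0.6*x1*x2/(0.2*x1 + 0.3*x2 + 0.5*N)", {"x1": -1, "x2": -1},
                 maintenance=("x1", "x2")),
            flux("imp", "0.4*x2", {"x1": +1}, upstream=(), downstream=("x1",), maintenance=("x2",)),
        ]
        net = build_network(nodes, fluxes)
        report = check_scalability(net, n_samples=60, seed=0)
        assert report.is_srn

    def test_constant_flux_named(self):
        net = build_network(
            ["x1"],
            [
                flux("ok", "0.3*x1", {"x1": +1}, upstream=(), downstream=("x1",), maintenance=("x1",)),
                flux("bad", "1.0", {"x1": +1}, downstream=("x1",)),
            ],
        )
        report = check_scalability(net, n_samples=40, seed=0)
        assert not report.is_srn
        assert report.failing_fluxes() == ["bad"]

    def test_asymptotic_flag_reported(self):
        net = build_network(
            ["x1", "x2"],
            [
                flux("ok", "0.3*x1", {"x1": +1}, upstream=(), downstream=("x1",), maintenance=("x1",)),
                flux("asym", "x1*(1.0 + 0.5*x2 + 0.2*x2^2)/(1.0 + 0.3*x2 + 0.1*x2^2)", {"x1": -1}),
            ],
        )
        report = check_scalability(net, n_samples=40, seed=0)
        assert not report.is_srn
        chk = report.checks["asym"]
        assert not chk.homogeneous.passed
        assert chk.asymptotically_scalable

    def test_reordering_stability(self, repressilator_lc):
        net = repressilator_lc
        base = check_scalability(net, n_samples=40, seed=0).is_srn
        perm = net.reordered(node_order=["x3", "x1", "x4", "x2"], flux_order=["J4", "J1", "J5", "J2", "J3"])
        assert check_scalability(perm, n_samples=40, seed=0).is_srn == base

    def test_vanishing_at_origin_scale(self, repressilator_lc):
        # homogeneity implies J(c X) -> 0 linearly in c
        net = repressilator_lc
        X1 = np.full(net.n, 1.0 / net.n)
        J1 = net.flux_values(X1)
        Jsmall = net.flux_values(1e-12 * X1)
        assert np.all(np.abs(Jsmall) <= 1e-10 * np.abs(J1) + 1e-300)


class TestUnitVolumeLift:
    def test_linear_collapses(self):
        rate = flux_from_unit_volume("2.0*x1", b=1.7, nodes=["x1"])
        fx = flux("J", rate, {"x1": -1})
        assert check_homogeneity(fx, nodes=["x1"], n_samples=50, seed=0).passed
        # b*N * k * x1/(b*N) == k*x1 exactly
        import sympy as sp

        assert sp.simplify(sp.sympify(rate.replace("^", "**")) - sp.sympify("2.0*x1")) == 0

    def test_michaelis_menten(self):
        rate = flux_from_unit_volume("0.9*x1/(0.4 + x1)", b=2.0, nodes=["x1", "x2"])
        fx = flux("J", rate, {"x1": -1})
        v = check_homogeneity(fx, nodes=["x1", "x2"], n_samples=100, tol=1e-9, seed=0)
        assert v.passed

    def test_mass_action_quadratic_matches_family(self):
        rate = flux_from_unit_volume("3.0*x1*x2", b=1.0, nodes=["x1", "x2"])
        fx = flux("J", rate, {"x1": -1}, maintenance=("x1", "x2"))
        assert check_homogeneity(fx, nodes=["x1", "x2"], n_samples=100, seed=0).passed
        import sympy as sp

        from srnkit.network import parse_rate

        # equals k * X1 * X2 / (b N): the quadratic scalable family
        nodes = ["x1", "x2"]
        assert sp.simplify(parse_rate(rate, nodes) - parse_rate("3.0*x1*x2/N", nodes)) == 0

    def test_invalid_b(self):
        with pytest.raises(ValueError):
            flux_from_unit_volume("x1", b=0.0, nodes=["x1"])


@st.composite
def unit_rate_grammar(draw):
    """Small grammar of per-unit-volume rate laws over two concentrations."""
    k = draw(st.floats(0.1, 5.0))
    K = draw(st.floats(0.1, 5.0))
    form = draw(st.sampled_from(["lin", "mm", "prod", "ratio"]))
    if form == "lin":
        return f"{k}*x1"
    if form == "mm":
        return f"{k}*x1/({K} + x1)"
    if form == "prod":
        return f"{k}*x1*x2"
    return f"{k}*x1*x2/({K} + x1 + x2)"


@given(junit=unit_rate_grammar(), b=st.floats(0.1, 10.0), seed=st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_unit_volume_lift_is_homogeneous(junit, b, seed):
    rate = flux_from_unit_volume(junit, b=b, nodes=["x1", "x2"])
    fx = flux("J", rate, {"x1": -1})
    assert check_homogeneity(fx, nodes=["x1", "x2"], n_samples=30, tol=1e-9, seed=seed).passed


def test_positivity_check_flags_nonpositive():
    fx = flux("J", "x1 - x2", {"x1": -1})
    v = check_positivity_smoothness(fx, nodes=["x1", "x2"], n_samples=60, seed=0)
    assert not v.passed
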