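import numpy as np
import pytest

from irtlink import (
    DegenerateDesignError,
    IdentifiabilityError,
    Item3PL,
    ItemSlopeIntercept,
    LinearLink,
    SlopeInterceptLink,
    apply_link,
    apply_link_theta,
    compose_links,
    evaluate_3pl,
    invert_link,
    link_from_one_item,
    link_from_two_items_b,
    link_from_two_persons,
    si_apply_link,
    si_link_from_design,
    to_slope_intercept,
)
from conftest import random_item

GRID = np.linspace(-4, 4, 101)


def random_link(rng):
    return LinearLink(float(rng.uniform(0.3, 3.0)), float(rng.uniform(-2, 2)))


class TestApplyLink:
    def test_identity(self):
        item = Item3PL(1.4, 0.3, 0.2)
        assert apply_link(item, LinearLink(1.0, 0.0)) == item

    def test_worked_example_item1(self):
        # common item 1: calibration-1 estimates mapped by the per-item link
        # land on the calibration-2 difficulty estimate
        moved = apply_link(Item3PL(2.612, -0.843, 0.213), LinearLink(1.208, -0.707))
        assert round(moved.b, 3) == -1.725

    def test_probability_invariance(self, rng):
        for _ in range(50):
            item, link = random_item(rng), random_link(rng)
            moved = apply_link(item, link)
            p0 = evaluate_3pl(GRID, item)
            p1 = evaluate_3pl(apply_link_theta(GRID, link), moved)
            assert np.max(np.abs(p0 - p1)) < 1e-12

    def test_c_bit_exact(self, rng):
        for _ in range(20):
            item, link = random_item(rng), random_link(rng)
            assert apply_link(item, link).c == item.c

    def test_invalid_slope_rejected(self):
        with pytest.raises(ValueError):
            LinearLink(0.0, 1.0)

    def test_componentwise_monotone(self, rng):
        link = random_link(rng)
        bs = np.linspace(-3, 3, 21)
        a_s = np.linspace(0.2, 3, 21)
        assert (np.diff([apply_link(Item3PL(1, b, 0), link).b for b in bs]) > 0).all()
        assert (np.diff([apply_link(Item3PL(a, 0, 0), link).a for a in a_s]) > 0).all()
        assert (np.diff(apply_link_theta(bs, link)) > 0).all()


class TestLinkAlgebra:
    def test_theta_identity(self):
        assert apply_link_theta(0.0, LinearLink(1.0, 0.0)) == 0.0

    def test_theta_b_degeneracy_preserved(self, rng):
        # theta = b maps to the transformed difficulty under the same phi
        item, link = random_item(rng), random_link(rng)
        assert apply_link_theta(item.b, link) == pytest.approx(
            apply_link(item, link).b, abs=1e-12)

    def test_invert_example(self):
        inv = invert_link(LinearLink(2.0, 1.0))
        assert (inv.u, inv.v) == (0.5, -0.5)

    def test_compose_with_inverse(self):
        link = LinearLink(1.2, -0.7)
        ident = compose_links(link, invert_link(link))
        assert ident.u == pytest.approx(1.0, abs=1e-12)
        assert ident.v == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_theta(self, rng):
        link = random_link(rng)
        th = rng.normal(size=11)
        back = apply_link_theta(apply_link_theta(th, link), invert_link(link))
        assert np.allclose(back, th, atol=1e-12)

    def test_compose_chain_matches_sequential(self, rng):
        links = [random_link(rng) for _ in range(3)]
        item = random_item(rng)
        seq = item
        for lk in links:
            seq = apply_link(seq, lk)
        combined = compose_links(compose_links(links[0], links[1]), links[2])
        direct = apply_link(item, combined)
        assert direct.a == pytest.approx(seq.a, abs=1e-12)
        assert direct.b == pytest.approx(seq.b, abs=1e-12)


class TestDesignIdentification:
    def test_one_item_identity(self):
        item = Item3PL(1.3, 0.4, 0.2)
        link = link_from_one_item(item, item)
        assert (link.u, link.v) == (1.0, 0.0)

    def test_one_item_worked_example(self):
        link = link_from_one_item(Item3PL(2.612, -0.843, 0.213),
                                  Item3PL(2.162, -1.725, 0.191))
        assert round(link.u, 3) == 1.208
        assert round(link.v, 3) == -0.707

    def test_one_item_round_trip(self, rng):
        for _ in range(20):
            item, link = random_item(rng), random_link(rng)
            est = link_from_one_item(item, apply_link(item, link))
            assert est.u == pytest.approx(link.u, abs=1e-12)
            assert est.v == pytest.approx(link.v, abs=1e-12)

    def test_two_items_trivial(self):
        link = link_from_two_items_b((0.0, 1.0), (0.0, 1.0))
        assert (link.u, link.v) == (1.0, 0.0)

    def test_two_items_worked_values(self):
        # difficulties of common items 1 and 2 in the two calibrations
        link = link_from_two_items_b((-0.843, -0.558), (-1.725, -1.333))
        assert round(link.u, 3) == 1.375

    def test_two_items_exact_recovery(self, rng):
        link = random_link(rng)
        b = rng.normal(size=2)
        est = link_from_two_items_b(b, link.u * b + link.v,
                                    consistency_tol=1e-10)
        assert est.u == pytest.approx(link.u, abs=1e-12)
        assert est.v == pytest.approx(link.v, abs=1e-12)

    def test_two_items_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            link_from_two_items_b((0.5, 0.5), (0.1, 0.9))

    def test_two_persons_trivial_and_stretch(self):
        assert link_from_two_persons((0.0, 1.0), (0.0, 1.0)).u == 1.0
        link = link_from_two_persons((-1.0, 1.0), (-2.0, 2.0))
        assert (link.u, link.v) == (2.0, 0.0)

    def test_two_persons_exact_recovery(self, rng):
        link = random_link(rng)
        th = rng.normal(size=2)
        est = link_from_two_persons(th, link.u * th + link.v)
        assert est.u == pytest.approx(link.u, abs=1e-12)
        assert est.v == pytest.approx(link.v, abs=1e-12)

    def test_single_person_not_identifiable(self):
        with pytest.raises(IdentifiabilityError):
            link_from_two_persons(0.3, 0.9)
        with pytest.raises(IdentifiabilityError):
            link_from_two_persons((0.3, 0.3), (0.9, 1.1))


class TestSlopeInterceptLinking:
    def test_identity_link(self):
        item = ItemSlopeIntercept(1.2, -0.4, 0.2)
        moved, theta, residual = si_apply_link(item, 0.7,
                                               SlopeInterceptLink(0.0, 1.0, 1.0))
        assert moved == item
        assert theta == 0.7
        assert residual == 0.0

    def test_c_untouched(self, rng):
        link = SlopeInterceptLink(0.2, 1.3, 0.8)
        item = ItemSlopeIntercept(1.5, 0.3, 0.17)
        moved, _, _ = si_apply_link(item, 1.0, link)
        assert moved.c == 0.17

    def test_design_identity(self):
        item = ItemSlopeIntercept(1.2, -0.4, 0.2)
        link = si_link_from_design(item, item, 0.8, 0.8)
        assert (link.u, link.v, link.w) == (0.0, 1.0, 1.0)

    def test_known_link_recovery(self, rng):
        true = SlopeInterceptLink(0.3, 1.4, 0.9)
        item = ItemSlopeIntercept(2.0, -0.5, 0.2)
        vt = 1.7
        moved = ItemSlopeIntercept((item.alpha - true.u) / true.v,
                                   item.beta + true.u, item.c)
        vt2 = (vt - true.u) / true.w
        est = si_link_from_design(item, moved, vt, vt2)
        assert est.u == pytest.approx(true.u, abs=1e-12)
        assert est.v == pytest.approx(true.v, abs=1e-12)
        assert est.w == pytest.approx(true.w, abs=1e-12)

    def test_item_only_design_rejected(self):
        item = ItemSlopeIntercept(1.0, 0.0, 0.0)
        with pytest.raises(IdentifiabilityError):
            si_link_from_design(item, item, None, None)
        with pytest.raises(IdentifiabilityError):
            si_link_from_design(None, None, 0.5, 0.7)

    def test_cross_parameterization_residual_vanishes(self):
        # a scenario generated by a standard-parameterization link, expressed
        # in slope-intercept form, yields a consistent (u, v, w) whose
        # logit-invariance residual vanishes on the design's item and person
        std = LinearLink(1.2, -0.7)
        item = Item3PL(1.5, 0.4, 0.2)
        theta = 0.9
        si1 = to_slope_intercept(item)
        si2 = to_slope_intercept(apply_link(item, std))
        vt1, vt2 = theta, apply_link_theta(theta, std)
        link = si_link_from_design(si1, si2, vt1, vt2)
        moved, vt_star, residual = si_apply_link(si1, vt1, link)
        assert abs(residual) < 1e-10
        assert moved.alpha == pytest.approx(si2.alpha, abs=1e-10)
        assert moved.beta == pytest.approx(si2.beta, abs=1e-10)
        assert vt_star == pytest.approx(vt2, abs=1e-10)
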