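import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cgrembed.alignment import RankedRecord
from cgrembed.losses import (
    default_betas,
    default_margins,
    ladder_group_loss,
    ladder_loss,
    ladder_loss_grad,
    make_ladder_groups,
    make_triplets,
    triplet_loss,
    triplet_loss_grad,
)


def cosine(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def ranked(scores, anchor="q"):
    return RankedRecord(
        anchor_id=anchor,
        neighbors=tuple((f"n{i}", float(s)) for i, s in enumerate(scores)),
    )


class TestMakeTriplets:
    def test_distinct_scores_all_pairs(self):
        ts = make_triplets(ranked([5, 3, 1]))
        assert ts.n == 3
        assert all(t.anchor == "q" for t in ts.triplets)

    def test_all_tied_scores_give_no_triplets(self):
        assert make_triplets(ranked([2, 2, 2])).n == 0

    def test_count_matches_strict_pair_enumeration(self, rng):
        scores = sorted(rng.integers(0, 5, size=10).tolist(), reverse=True)
        rec = ranked(scores)
        expected = sum(
            scores[i] > scores[j]
            for i in range(10)
            for j in range(i + 1, 10)
        )
        assert make_triplets(rec).n == expected

    def test_cap_subsamples_deterministically(self):
        rec = ranked(list(range(20, 0, -1)))
        full = make_triplets(rec)
        capped = make_triplets(rec, cap=10, seed=4)
        assert capped.n == 10
        assert set(capped.triplets) <= set(full.triplets)
        assert capped == make_triplets(rec, cap=10, seed=4)


class TestMakeLadderGroups:
    def test_even_split(self):
        g = make_ladder_groups(ranked([9, 8, 7, 6, 5, 4, 3, 2, 1]), 3)
        assert [len(x) for x in g.groups] == [3, 3, 3]

    def test_remainder_to_early_groups(self):
        g = make_ladder_groups(ranked(list(range(10, 0, -1))), 3)
        assert [len(x) for x in g.groups] == [4, 3, 3]

    def test_ties_never_straddle_boundary(self):
        rec = ranked([9, 8, 8, 8, 5, 4, 3, 2, 1])
        g = make_ladder_groups(rec, 3)
        score = {f"n{i}": s for i, (_, s) in enumerate(rec.neighbors)}
        for gi in range(len(g.groups) - 1):
            last = rec.score_of(g.groups[gi][-1])
            first = rec.score_of(g.groups[gi + 1][0])
            assert last > first

    def test_group_scores_pairwise_ordered(self, rng):
        scores = sorted(rng.integers(0, 40, size=17).tolist(), reverse=True)
        rec = ranked(scores)
        g = make_ladder_groups(rec, 4)
        for gi in range(len(g.groups)):
            for gj in range(gi + 1, len(g.groups)):
                for a in g.groups[gi]:
                    for b in g.groups[gj]:
                        assert rec.score_of(a) >= rec.score_of(b)

    def test_too_many_groups_rejected(self):
        with pytest.raises(ValueError, match="cannot split"):
            make_ladder_groups(ranked([3, 2]), 3)


class TestTripletLoss:
    def test_zero_when_margin_exactly_met(self):
        fx = np.array([1.0, 0.0])
        fn = np.array([1.0, 1.0])  # squared distance 1
        assert triplet_loss(fx, fx, fn, alpha=1.0) == 0.0

    def test_equal_pos_neg_gives_alpha(self):
        fx = np.array([0.3, -0.2, 0.5])
        other = np.array([1.0, 2.0, 3.0])
        assert triplet_loss(fx, other, other, alpha=0.7) == pytest.approx(0.7)

    def test_batch_matches_scalar_oracle(self, rng):
        fx, fp, fn = rng.normal(size=(3, 5, 4))
        alpha = 0.4
        expected = 0.0
        for i in range(5):
            d_pos = float(((fx[i] - fp[i]) ** 2).sum())
            d_neg = float(((fx[i] - fn[i]) ** 2).sum())
            expected += max(d_pos - d_neg + alpha, 0.0)
        assert triplet_loss(fx, fp, fn, alpha) == pytest.approx(expected)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            triplet_loss(np.ones(3), np.ones(4), np.ones(4), 0.1)

    @given(st.integers(0, 2**31 - 1))
    def test_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        fx, fp, fn = rng.normal(size=(3, 4, 6))
        shift = rng.normal(size=6)
        a = triplet_loss(fx, fp, fn, 0.3)
        b = triplet_loss(fx + shift, fp + shift, fn + shift, 0.3)
        assert a == pytest.approx(b)

    def test_gradient_matches_finite_difference(self, rng):
        fx, fp, fn = rng.normal(size=(3, 4, 5))
        _, gx, gp, gn = triplet_loss_grad(fx, fp, fn, 0.3)
        eps = 1e-6
        for arr, g in ((fx, gx), (fp, gp), (fn, gn)):
            i, k = 2, 3
            up, dn = arr.copy(), arr.copy()
            up[i, k] += eps
            dn[i, k] -= eps
            num = (
                triplet_loss(up if arr is fx else fx, up if arr is fp else fp,
                             up if arr is fn else fn, 0.3)
                - triplet_loss(dn if arr is fx else fx, dn if arr is fp else fp,
                               dn if arr is fn else fn, 0.3)
            ) / (2 * eps)
            assert g[i, k] == pytest.approx(num, abs=1e-4)


class TestLadderLoss:
    def _separated_case(self):
        """Embeddings engineered so every margin is satisfied — including the
        tier-1 requirement that all samples sit at least alpha_1 below the
        anchor's self-cosine of 1."""
        q = np.array([1.0, 0.0])
        g1 = np.array([[1.0, 0.6]])      # cosine ~ 0.857 <= 1 - alpha_1
        g2 = np.array([[-1.0, 0.0]])     # cosine -1
        return q, [g1, g2]

    def test_zero_when_margins_satisfied(self):
        q, groups = self._separated_case()
        assert ladder_loss(q, groups, np.array([0.1, 0.1]), np.ones(2)) == 0.0

    def test_group_one_identical_embeddings(self):
        """All candidates equal to q: tier-1 loss is n * alpha_1."""
        q = np.array([0.5, 0.5, 0.1])
        groups = [np.tile(q, (3, 1)), np.tile(q, (2, 1))]
        loss = ladder_group_loss(q, groups, 1, alpha_i=0.25)
        assert loss == pytest.approx(5 * 0.25)

    def test_matches_double_loop_oracle(self, rng):
        q = rng.normal(size=5)
        groups = [rng.normal(size=(n, 5)) for n in (3, 2, 4)]
        margins, betas = np.array([0.1, 0.2, 0.3]), np.array([1.0, 0.5, 2.0])
        expected = 0.0
        flat = [(gi, x) for gi, g in enumerate(groups) for x in g]
        for i in range(1, 4):
            term = 0.0
            positives = [np.copy(q)] if i == 1 else list(groups[i - 2])
            negatives = [x for gi, x in flat if gi >= i - 1]
            for xp in positives:
                sp = 1.0 if i == 1 else cosine(q, xp)
                for xn in negatives:
                    term += max(margins[i - 1] - sp + cosine(q, xn), 0.0)
            expected += betas[i - 1] * term
        assert ladder_loss(q, groups, margins, betas) == pytest.approx(expected)

    def test_all_zero_betas_zero_loss(self, rng):
        q = rng.normal(size=4)
        groups = [rng.normal(size=(2, 4)), rng.normal(size=(3, 4))]
        assert ladder_loss(q, groups, np.array([0.5, 0.5]), np.zeros(2)) == 0.0

    def test_m2_beta_01_reduces_to_single_tier_term(self, rng):
        q = rng.normal(size=4)
        groups = [rng.normal(size=(3, 4)), rng.normal(size=(2, 4))]
        margins = np.array([0.3, 0.15])
        full = ladder_loss(q, groups, margins, np.array([0.0, 1.0]))
        only_tier2 = ladder_group_loss(q, groups, 2, alpha_i=0.15)
        assert full == pytest.approx(only_tier2)

    def test_composition_over_groups(self, rng):
        q = rng.normal(size=6)
        groups = [rng.normal(size=(n, 6)) for n in (2, 3, 2, 4)]
        margins = default_margins(4)
        betas = default_betas(4)
        total = sum(
            betas[i - 1] * ladder_group_loss(q, groups, i, margins[i - 1])
            for i in range(1, 5)
        )
        assert ladder_loss(q, groups, margins, betas) == pytest.approx(total)

    def test_loss_decreases_when_positive_cosine_rises(self, rng):
        """Monotone direction: raising a positive's cosine to q cannot
        increase the tier loss in which it is the positive (tier-1 weight
        zeroed so the member acts purely as a positive)."""
        q = rng.normal(size=4)
        groups = [rng.normal(size=(2, 4)), rng.normal(size=(3, 4))]
        margins, betas = np.array([0.4, 0.4]), np.array([0.0, 1.0])
        base = ladder_loss(q, groups, margins, betas)
        moved = [g.copy() for g in groups]
        moved[0][0] = moved[0][0] + 0.5 * (q - moved[0][0])  # toward q
        assert ladder_loss(q, moved, margins, betas) <= base + 1e-12

    def test_gradient_matches_finite_difference(self, rng):
        q = rng.normal(size=5)
        groups = [rng.normal(size=(2, 5)), rng.normal(size=(3, 5))]
        margins, betas = np.array([0.2, 0.3]), np.array([1.0, 0.7])
        _, gq, gg = ladder_loss_grad(q, groups, margins, betas)
        eps = 1e-6

        def f(qv, gs):
            return ladder_loss(qv, gs, margins, betas)

        for k in range(5):
            up, dn = q.copy(), q.copy()
            up[k] += eps
            dn[k] -= eps
            assert gq[k] == pytest.approx((f(up, groups) - f(dn, groups)) / (2 * eps), abs=1e-4)
        up = [g.copy() for g in groups]
        dn = [g.copy() for g in groups]
        up[1][2, 4] += eps
        dn[1][2, 4] -= eps
        assert gg[1][2, 4] == pytest.approx((f(q, up) - f(q, dn)) / (2 * eps), abs=1e-4)

    def test_empty_group_contributes_zero(self, rng):
        q = rng.normal(size=3)
        groups = [rng.normal(size=(2, 3)), np.zeros((0, 3)), rng.normal(size=(2, 3))]
        margins, betas = default_margins(3), default_betas(3)
        loss = ladder_loss(q, groups, margins, betas)
        assert np.isfinite(loss) and loss >= 0.0
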