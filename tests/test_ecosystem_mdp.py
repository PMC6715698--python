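import itertools

import numpy as np
import pytest

from ecovoi import (
    EcosystemConfig,
    EcosystemState,
    FeedbackStructure,
    build_mdp_family,
    build_motif,
    ef_support_term,
    reward_vector,
    species_survival_probability,
)

ALL_EXTANT = [1, 1, 1, 1]


def make_config(web, **kw):
    kw.setdefault("alpha", 0.8)
    kw.setdefault("p0", 0.8)
    kw.setdefault("b", 0.9)
    return EcosystemConfig(web=web, **kw)


class TestEcosystemState:
    def test_state_id_round_trips_with_presence(self):
        for sid in range(16):
            st = EcosystemState.from_id(sid, 4)
            assert EcosystemState.from_presence(st.presence).state_id == sid

    def test_initial_state_is_all_ones(self):
        assert EcosystemState.initial(4).presence == (1, 1, 1, 1)
        assert EcosystemState.initial(4).state_id == 15


class TestEfSupportTerm:
    def test_member_with_provider_extant_gets_full_support_retention(self, linear_web):
        cfg = make_config(linear_web, ef_term_mode="retention")
        f = FeedbackStructure.from_members({2})
        assert ef_support_term(cfg, f, ALL_EXTANT, 2) == 1.0

    def test_member_with_provider_extinct_keeps_residual(self, linear_web):
        cfg = make_config(linear_web, ef_term_mode="retention", alpha=0.8)
        f = FeedbackStructure.from_members({2})
        term = ef_support_term(cfg, f, [1, 1, 1, 0], 2)  # provider 4 extinct
        assert term == pytest.approx(0.2)

    @pytest.mark.parametrize("mode", ["retention", "scaled", "shared", "dependence"])
    def test_non_member_unaffected_except_dependence(self, linear_web, mode):
        cfg = make_config(linear_web, ef_term_mode=mode, alpha=0.8)
        f = FeedbackStructure.from_members({3})
        term = ef_support_term(cfg, f, ALL_EXTANT, 2)
        assert term == pytest.approx(0.2 if mode == "dependence" else 1.0)

    def test_shared_mode_splits_support_across_members(self, linear_web):
        cfg = make_config(linear_web, ef_term_mode="shared", alpha=0.8)
        f = FeedbackStructure.from_members({2, 3})
        # (1 - 0.8) + 0.8 * x_provider / |f| with provider extant
        assert ef_support_term(cfg, f, ALL_EXTANT, 2) == pytest.approx(0.6)

    def test_alpha_zero_removes_all_feedback_dependence(self, linear_web):
        cfg = make_config(linear_web, alpha=0.0)
        for sid in (0, 5, 15):
            state = EcosystemState.from_id(sid, 4)
            for f_id in range(16):
                f = FeedbackStructure.from_id(f_id, 4)
                assert ef_support_term(cfg, f, state, 2) == 1.0


class TestSurvivalProbability:
    def test_four_factor_product_hand_value(self, linear_web):
        # p0 * prey * (1 - b) * ef = 0.8 * 1 * 0.1 * 1
        cfg = make_config(linear_web, p0=0.8, b=0.9, ef_term_mode="retention")
        f = FeedbackStructure.from_members({3})  # species 2 not a member
        p = species_survival_probability(cfg, f, ALL_EXTANT, action=1, species=2)
        assert p == pytest.approx(0.08)

    def test_reduces_to_baseline_without_predators(self, linear_web):
        cfg = make_config(linear_web, p0=0.8, ef_term_mode="retention")
        f = FeedbackStructure.from_members(set())
        # species 1's only predator (2) is extinct
        p = species_survival_probability(cfg, f, [1, 0, 1, 1], action=3, species=1)
        assert p == pytest.approx(0.8)

    def test_consumer_with_no_prey_left_cannot_survive(self, linear_web):
        cfg = make_config(linear_web)
        f = FeedbackStructure.from_members(set())
        p = species_survival_probability(cfg, f, [0, 1, 1, 1], action=3, species=2)
        assert p == 0.0

    def test_absolute_protection_guarantees_survival(self, linear_web):
        cfg = make_config(linear_web, protection_mode="absolute")
        f = FeedbackStructure.from_members(set())
        p = species_survival_probability(cfg, f, [0, 1, 1, 1], action=2, species=2)
        assert p == 1.0

    def test_prey_limited_protection_cannot_feed_a_starved_consumer(self, linear_web):
        cfg = make_config(linear_web, protection_mode="prey_limited")
        f = FeedbackStructure.from_members(set())
        assert species_survival_probability(cfg, f, [0, 1, 1, 1], 2, 2) == 0.0
        assert species_survival_probability(cfg, f, ALL_EXTANT, 2, 2) == 1.0

    @pytest.mark.parametrize(
        "mode", ["absolute", "prey_limited", "boost"]
    )
    def test_protection_never_hurts(self, omnivory_web, mode):
        cfg = make_config(omnivory_web, protection_mode=mode)
        f = FeedbackStructure.from_id(9, 4)
        for sid in range(1, 16):
            st = EcosystemState.from_id(sid, 4)
            for j in range(1, 5):
                if not st.presence[j - 1]:
                    continue
                prot = species_survival_probability(cfg, f, st, j, j)
                unprot = species_survival_probability(cfg, f, st, (j % 4) + 1, j)
                assert prot >= unprot - 1e-12

    def test_querying_extinct_species_raises(self, linear_web):
        cfg = make_config(linear_web)
        f = FeedbackStructure.from_members(set())
        with pytest.raises(ValueError, match="extant"):
            species_survival_probability(cfg, f, [0, 1, 1, 1], 2, 1)

    def test_increasing_predation_strength_weakly_lowers_survival(self, omnivory_web):
        f = FeedbackStructure.from_id(5, 4)
        for p0, state_id, j in itertools.product(
            (0.4, 0.9), (7, 11, 15), (1, 2, 3)
        ):
            st = EcosystemState.from_id(state_id, 4)
            if not st.presence[j - 1]:
                continue
            probs = [
                species_survival_probability(
                    make_config(omnivory_web, p0=p0, b=b), f, st, 4, j
                )
                for b in (0.1, 0.4, 0.7, 0.9)
            ]
            assert all(x >= y - 1e-12 for x, y in zip(probs, probs[1:]))


class TestRewards:
    def test_biodiversity_counts_extant_species(self, linear_web):
        cfg = make_config(linear_web, objective="biodiversity")
        assert reward_vector(cfg, ALL_EXTANT, 1) == 4.0
        assert reward_vector(cfg, [1, 0, 1, 0], 1) == 2.0

    def test_service_flows_only_while_provider_extant(self, linear_web):
        cfg = make_config(linear_web, objective="service", alpha=0.8)
        assert reward_vector(cfg, ALL_EXTANT, 1) == pytest.approx(0.2)
        assert reward_vector(cfg, [1, 1, 1, 0], 1) == 0.0

    def test_management_cost_is_subtracted(self, linear_web):
        cfg = make_config(
            linear_web, objective="biodiversity", costs=[0.0, 0.5, 1.0, 1.5]
        )
        assert reward_vector(cfg, ALL_EXTANT, 3) == 3.0


class TestMDPFamily:
    def test_shapes_and_row_stochasticity(self, omnivory_web):
        fam = build_mdp_family(make_config(omnivory_web))
        assert fam.P.shape == (16, 4, 16, 16)
        assert fam.R.shape == (16, 4)
        np.testing.assert_allclose(fam.P.sum(axis=-1), 1.0, atol=1e-12)
        assert np.all(fam.P >= 0)

    def test_all_extinct_state_is_absorbing(self, omnivory_web):
        fam = build_mdp_family(make_config(omnivory_web))
        assert np.all(fam.P[:, :, 0, 0] == 1.0)

    def test_extinct_species_never_resurrect(self, omnivory_web):
        fam = build_mdp_family(make_config(omnivory_web))
        for s in range(16):
            for t in range(16):
                # a species absent in s but present in t is a resurrection
                if (~s) & t & 0xF:
                    assert np.all(fam.P[:, :, s, t] == 0.0)

    # "scaled" is excluded: there alpha scales the support itself, so alpha=0
    # starves members instead of disconnecting the feedback
    @pytest.mark.parametrize("mode", ["retention", "shared", "dependence"])
    def test_alpha_zero_makes_all_structures_identical(self, omnivory_web, mode):
        fam = build_mdp_family(
            make_config(omnivory_web, alpha=0.0, ef_term_mode=mode)
        )
        for f in range(1, 16):
            np.testing.assert_array_equal(fam.P[f], fam.P[0])

    def test_validation_rejects_out_of_range_parameters(self, linear_web):
        with pytest.raises(ValueError):
            make_config(linear_web, b=1.0)
        with pytest.raises(ValueError):
            make_config(linear_web, p0=0.0)
        with pytest.raises(ValueError):
            make_config(linear_web, alpha=1.0)
        with pytest.raises(ValueError):
            make_config(linear_web, costs=[-1, 0, 0, 0])
        with pytest.raises(ValueError):
            make_config(linear_web, objective="profit")
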