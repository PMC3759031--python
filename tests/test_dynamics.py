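"""Leaky-integrator dynamics: update rule, stepping, trials."""

import numpy as np
import pytest

from tisk.dynamics import ParameterSet, TiskNetwork, update_unit
from tisk.lexicon import Lexicon, PhonemeInventory, Word
from tisk.recognition import RecognitionCriterion, recognize


class TestUpdateUnit:
    def test_zero_net_is_pure_decay(self):
        assert update_unit(0.8, 0.0, 0.1) == pytest.approx(0.72)

    def test_resting_unit_cannot_go_negative(self):
        assert update_unit(0.0, -0.5, 0.1) == 0.0

    def test_saturation_at_one(self):
        assert update_unit(1.0, 0.7, 0.0) == 1.0

    def test_positive_net_scaled_by_headroom(self):
        # A' = A(1-decay) + net(1-A)
        assert update_unit(0.5, 0.2, 0.1) == pytest.approx(0.5 * 0.9 + 0.2 * 0.5)

    def test_negative_net_scaled_by_activation(self):
        assert update_unit(0.5, -0.2, 0.1) == pytest.approx(0.5 * 0.9 - 0.2 * 0.5)

    def test_clamped_to_unit_interval(self):
        assert update_unit(0.9, 5.0, 0.0) == 1.0
        assert update_unit(0.1, -5.0, 0.0) == 0.0


@pytest.fixture
def tiny_network():
    inv = PhonemeInventory(("a", "b", "c"))
    lex = Lexicon([Word("abc", ("a", "b", "c")), Word("cab", ("c", "a", "b"))],
                  inv)
    return TiskNetwork(inv, lex)


class TestNetInput:
    def test_zero_state_zero_net_on_words(self, tiny_network):
        state = tiny_network.zero_state()
        assert tiny_network.net_input(state, "abc") == 0.0

    def test_single_source(self, tiny_network):
        state = tiny_network.zero_state()
        drive = np.zeros(len(tiny_network.nphones))
        i = tiny_network.nphones.index(("a", "b"))
        drive[i] = 0.25
        assert tiny_network.net_input(state, ("a", "b"), drive) == pytest.approx(
            0.25
        )

    def test_full_support_normalization(self, tiny_network):
        # a 3-phoneme word has 6 nphones; with all six at 1.0 the word's net
        # equals the nphone->word gain exactly
        state = tiny_network.zero_state()
        for u in [("a",), ("b",), ("c",), ("a", "b"), ("a", "c"), ("b", "c")]:
            state.nphone[tiny_network.nphones.index(u)] = 1.0
        assert tiny_network.net_input(state, "abc") == pytest.approx(
            tiny_network.params.gain_word
        )


class TestStep:
    def test_zero_fixed_point(self, tiny_network):
        s0 = tiny_network.zero_state()
        s1 = tiny_network.step(s0)
        assert not s1.nphone.any() and not s1.word.any()
        assert s1.cycle == 1

    def test_boundedness_under_random_drives(self, tiny_network):
        rng = np.random.default_rng(17)
        state = tiny_network.zero_state()
        state.nphone = rng.uniform(0, 1, len(tiny_network.nphones))
        state.word = rng.uniform(0, 1, len(tiny_network.words))
        for _ in range(500):
            drive = rng.uniform(-1, 2, len(tiny_network.nphones))
            state = tiny_network.step(state, drive)
            assert (state.nphone >= 0).all() and (state.nphone <= 1).all()
            assert (state.word >= 0).all() and (state.word <= 1).all()

    def test_boundedness_over_random_parameter_draws(self):
        inv = PhonemeInventory(("a", "b"))
        lex = Lexicon([Word("ab", ("a", "b")), Word("ba", ("b", "a"))], inv)
        rng = np.random.default_rng(23)
        for _ in range(20):
            p = ParameterSet(
                decay_nphone=float(rng.uniform(0, 1)),
                decay_word=float(rng.uniform(0, 1)),
                gain_input=float(rng.uniform(0.01, 2)),
                gain_word=float(rng.uniform(0.01, 2)),
                inhibition_nphone=float(-rng.uniform(0, 0.5)),
                inhibition_word=float(-rng.uniform(0, 0.5)),
            )
            net = TiskNetwork(inv, lex, p)
            traj = net.run_trial("ab")
            assert (traj.word_history >= 0).all()
            assert (traj.word_history <= 1).all()
            assert (traj.nphone_history >= 0).all()
            assert (traj.nphone_history <= 1).all()

    def test_decay_only_closed_form(self, tiny_network):
        # with no drive and a single active unit per layer there is no input
        # of any kind, so A(t) = A(0) (1 - decay)^t to machine precision
        p = tiny_network.params
        state = tiny_network.zero_state()
        # a diphone in no word's support, so it feeds nothing downstream
        i = tiny_network.nphones.index(("b", "a"))
        state.nphone[i] = 0.9
        state.word[0] = 0.7
        for t in range(1, 60):
            state = tiny_network.step(state)
            assert state.nphone[i] == pytest.approx(
                0.9 * (1 - p.decay_nphone) ** t, abs=0, rel=1e-12
            )
            assert state.word[0] == pytest.approx(
                0.7 * (1 - p.decay_word) ** t, abs=0, rel=1e-12
            )

    def test_monotone_rise_under_constant_clamp(self):
        # inhibition off, one diphone driven constantly: activation is
        # non-decreasing until the drive is released
        inv = PhonemeInventory(("a", "b"))
        lex = Lexicon([Word("ab", ("a", "b"))], inv)
        p = ParameterSet(inhibition_nphone=-0.0, inhibition_word=-0.0)
        net = TiskNetwork(inv, lex, p)
        state = net.zero_state()
        drive = np.zeros(len(net.nphones))
        drive[net.nphones.index(("a", "b"))] = 0.2
        prev = 0.0
        for _ in range(100):
            state = net.step(state, drive)
            a = state.nphone[net.nphones.index(("a", "b"))]
            assert a >= prev
            prev = a


class TestRunTrial:
    def test_trajectory_runs_to_max_cycles(self, tiny_network):
        traj = tiny_network.run_trial("abc")
        assert traj.n_cycles == tiny_network.params.max_cycles
        assert traj.word_history.shape == (100, 2)

    def test_word_longer_than_bank_rejected(self):
        inv = PhonemeInventory(("a", "b"))
        lex = Lexicon([Word("ab", ("a", "b"))], inv)
        net = TiskNetwork(inv, lex, ParameterSet(T=2))
        with pytest.raises(ValueError, match="exceeds T"):
            net.run_trial(("a", "b", "a"))

    def test_unknown_phoneme_rejected(self, tiny_network):
        with pytest.raises(ValueError, match="unknown phoneme"):
            tiny_network.run_trial(("a", "x"))

    def test_determinism(self, anadrome_lexicon):
        inv, lex = anadrome_lexicon
        t1 = TiskNetwork(inv, lex).run_trial("dag")
        t2 = TiskNetwork(inv, lex).run_trial("dag")
        assert np.array_equal(t1.word_history, t2.word_history)
        assert np.array_equal(t1.nphone_history, t2.nphone_history)

    def test_anadrome_dominance_once_order_information_arrives(
        self, anadrome_lexicon
    ):
        inv, lex = anadrome_lexicon
        net = TiskNetwork(inv, lex)
        traj = net.run_trial("dag")
        tgt = traj.word_activation("dag")
        rev = traj.word_activation("gad")
        # the first-order-breaking diphone crosses threshold at the second
        # phoneme's onset; from shortly after, the presented order dominates
        d = net.params.clamp_cycles
        assert (tgt[d + 2 :] > rev[d + 2 :]).all()
        assert recognize(traj, RecognitionCriterion(kind="time")).recognized == "dag"

    def test_repeated_phoneme_word_diphones(self, tiny_network):
        # presenting a-b-a activates diphones {ab, aa, ba}, never ones with
        # unseen phonemes, and the repeated phone /a/ gets two input episodes
        inv = PhonemeInventory(("a", "b", "c"))
        lex = Lexicon([Word("aba", ("a", "b", "a"))], inv)
        net = TiskNetwork(inv, lex)
        traj = net.run_trial("aba")
        final = traj.nphone_history[-1]
        idx = {u: i for i, u in enumerate(net.nphones)}
        for u in [("a", "b"), ("b", "a"), ("a", "a")]:
            assert traj.nphone_history[:, idx[u]].max() > 0.1
        for u in [("a", "c"), ("c", "a"), ("b", "c"), ("b", "b")]:
            assert traj.nphone_history[:, idx[u]].max() == 0.0
        # two separate episodes for phone /a/: rises during first clamp,
        # decays during /b/, rises again during the second /a/ clamp
        d = net.params.clamp_cycles
        a_phone = traj.nphone_history[:, idx[("a",)]]
        assert a_phone[d - 1] > 0            # first episode
        assert a_phone[2 * d - 1] < a_phone[d - 1]  # decays during /b/
        assert a_phone[3 * d - 1] > a_phone[2 * d - 1]  # second episode
        del final
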