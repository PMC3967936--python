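"""Single-cell dynamics: rule evaluation, update schemes, delays, stability."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epilogic.fixtures import random_model, random_state
from epilogic.logic_core import (
    LogicalModel,
    ModelError,
    evaluate_targets,
    is_stable,
    stable_states,
    successor_synchronous,
    successors_asynchronous,
)
from epilogic.modelfile import parse_model

TOGGLE = """
components: [{name: x}]
rules:
  x:
    - {to: 1, when: "!x"}
"""

IDENTITY = """
components: [{name: x}]
rules:
  x:
    - {to: 1, when: "x"}
"""

DELAYED = """
components:
  - {name: sig, input: true}
  - {name: slow, delay: 2}
rules:
  slow:
    - {to: 1, when: "sig"}
"""


class TestPhenomenologicalModel:
    def test_structure(self, phenom_model):
        assert len(phenom_model.rules) == 3
        assert set(phenom_model.inputs) == {"EGF", "BMP", "anterior", "Roof_adj"}
        assert phenom_model.component("EGF").max_level == 2

    @pytest.mark.parametrize(
        "state_kwargs, expected_roof",
        [
            (dict(EGF=1, anterior=1), 1),  # intermediate EGF permits roof
            (dict(EGF=2, anterior=1), 0),  # high EGF represses it
            (dict(EGF=1, BMP=1, anterior=1), 0),  # BMP represses it
            (dict(), 0),  # no input: default clause
        ],
    )
    def test_roof_target(self, phenom_model, state_kwargs, expected_roof):
        state = phenom_model.zero_state(**state_kwargs)
        targets = evaluate_targets(phenom_model, state)
        assert targets["Roof"] == expected_roof

    def test_all_inputs_zero_gives_all_zero_targets(self, phenom_model):
        targets = evaluate_targets(phenom_model, phenom_model.zero_state())
        assert set(targets.values()) == {0}

    def test_four_output_patterns_in_anterior(self, phenom_model):
        """Within the competence region the outputs take exactly the four
        patterns none / roof / floor(+operculum) / operculum."""
        idx = [phenom_model.index[n] for n in ("Roof", "Floor", "Operculum")]
        patterns = {
            tuple(s[i] for i in idx)
            for s in stable_states(phenom_model, fixed_inputs={"anterior": 1})
        }
        assert patterns == {(0, 0, 0), (1, 0, 0), (0, 1, 1), (0, 0, 1)}


class TestValidation:
    def test_out_of_range_atom(self):
        bad = TOGGLE.replace('"!x"', '"x:3"')
        with pytest.raises(ModelError):
            parse_model(bad)

    def test_missing_rule(self):
        with pytest.raises(ModelError, match="missing rule"):
            parse_model("components: [{name: x}]\nrules: {}\n")

    def test_rule_on_input(self):
        with pytest.raises(ModelError, match="input"):
            parse_model(
                "components: [{name: x, input: true}]\n"
                'rules: {x: [{to: 1, when: "x"}]}\n'
            )

    def test_bad_clause_target(self):
        with pytest.raises(ModelError):
            parse_model("components: [{name: x}]\nrules: {x: [{to: 2, when: \"x\"}]}\n")


class TestSynchronous:
    def test_unit_step_toward_distant_target(self, mech_model):
        # dpERK jumps are forbidden: level 0 with target 2 moves to 1
        state = mech_model.zero_state(Grk=3)
        targets = evaluate_targets(mech_model, state)
        assert targets["dpERK"] == 2
        nxt, _ = successor_synchronous(mech_model, state)
        assert nxt[mech_model.index["dpERK"]] == 1

    def test_stable_state_is_fixed_point(self, mech_model):
        state = mech_model.zero_state()
        assert is_stable(mech_model, state)
        nxt, _ = successor_synchronous(mech_model, state)
        assert nxt == state

    def test_determinism(self, mech_model):
        state = mech_model.zero_state(Grk=2, Br_adj=1)
        a, _ = successor_synchronous(mech_model, state)
        b, _ = successor_synchronous(mech_model, state)
        assert a == b

    def test_delay_holds_then_fires(self):
        model = parse_model(DELAYED)
        state = model.zero_state(sig=1)
        counters = None
        levels = []
        for _ in range(4):
            state, counters = successor_synchronous(model, state, counters)
            levels.append(state[model.index["slow"]])
        # unchanged for two ticks, rises on the third
        assert levels == [0, 0, 1, 1]

    def test_delay_counter_resets_on_reversal(self):
        model = parse_model(DELAYED)
        state = model.zero_state(sig=1)
        state, counters = successor_synchronous(model, state)  # counting: 1
        off = list(state)
        off[model.index["sig"]] = 0
        state, counters = successor_synchronous(model, tuple(off), counters)
        on = list(state)
        on[model.index["sig"]] = 1
        state, counters = successor_synchronous(model, tuple(on), counters)
        assert state[model.index["slow"]] == 0  # the count started over
        assert counters["slow"] == 1


class TestAsynchronous:
    def test_one_successor_per_unstable_component(self, phenom_model):
        state = phenom_model.zero_state(EGF=2, BMP=1, anterior=1, Roof_adj=1)
        succ = successors_asynchronous(phenom_model, state)
        assert set(succ) == {"Floor", "Operculum"}  # exactly the 2 unstable

    def test_stable_state_has_no_successors(self, mech_model):
        assert successors_asynchronous(mech_model, mech_model.zero_state()) == {}

    def test_matches_clause_recomputation(self, mech_model):
        """Every asynchronous successor equals an independent re-evaluation
        of the clause lists, one unit move at a time (R1-type inputs)."""
        state = mech_model.zero_state(Grk=3, Dpp=1, Aos_ext=2, Rho_ext=2)
        succ = successors_asynchronous(mech_model, state)
        # oracle: recompute each component's first matching clause by hand
        levels = mech_model.levels_of(state)
        urgent_hit = False
        for cls in mech_model.async_priorities:
            expected = {}
            for name in cls:
                tgt = mech_model.rules[name].target(levels)
                cur = levels[name]
                if tgt != cur:
                    vec = list(state)
                    vec[mech_model.index[name]] = cur + (1 if tgt > cur else -1)
                    expected[name] = tuple(vec)
            if expected:
                assert succ == expected
                urgent_hit = True
                break
        assert urgent_hit


class TestStableStatesOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_scan(self, seed):
        model = random_model(seed, n_components=5, max_level=2, n_inputs=1)
        found = set(stable_states(model))
        scan = set()
        for combo in itertools.product(
            *(range(c.max_level + 1) for c in model.components)
        ):
            if is_stable(model, combo):
                scan.add(combo)
        assert found == scan

    def test_identity_component_has_two_stable_states(self):
        model = parse_model(IDENTITY)
        assert stable_states(model) == [(0,), (1,)]

    def test_toggle_has_none(self):
        model = parse_model(TOGGLE)
        assert stable_states(model) == []

    def test_cap_refusal(self, mech_model):
        from epilogic.logic_core import StateSpaceCapExceeded

        with pytest.raises(StateSpaceCapExceeded):
            stable_states(mech_model, cap=10)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 500), state_seed=st.integers(0, 500))
def test_scheme_stability_agreement(seed, state_seed):
    """A state is stable under the synchronous scheme iff it has no
    asynchronous successors, and |next - current| <= 1 per component."""
    model = random_model(seed % 50, n_components=4, max_level=2, n_inputs=1)
    rng = np.random.default_rng(state_seed)
    state = random_state(rng, model)
    nxt, _ = successor_synchronous(model, state)
    succ = successors_asynchronous(model, state)
    assert (nxt == state) == (len(succ) == 0)
    assert all(abs(a - b) <= 1 for a, b in zip(nxt, state))
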