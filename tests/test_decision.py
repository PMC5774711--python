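"""Random-utility core, per-type criteria, trust dynamics, contact choice."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from woodmarket.config import substream
from woodmarket.decision import (CRITERIA, ContextState, DecisionError,
                                 PartWorthTable, PhonebookEntry, accept,
                                 build_context, decision_model_for,
                                 load_part_worth_file, select_contacts,
                                 update_trust, utility)


class TestUtility:
    def test_single_term(self):
        pw = PartWorthTable(betas={"price": 2.0}, beta0=0.0)
        assert utility(pw, {"price": 3.0}) == pytest.approx(6.0)

    def test_threshold_only(self):
        pw = PartWorthTable(betas={"a": 1.0, "b": 1.0}, beta0=1.0)
        assert utility(pw, {"a": 0.0, "b": 0.0}) == pytest.approx(-1.0)

    def test_matches_brute_force_recompute_over_random_draws(self):
        # independent oracle: re-sum beta_i * c_i with plain Python floats
        rng = np.random.default_rng(42)
        names = [f"c{i}" for i in range(6)]
        for _ in range(1000):
            betas = {n: float(rng.normal()) for n in names}
            ctx = {n: float(rng.normal()) for n in names}
            beta0 = float(rng.normal())
            expected = sum(betas[n] * ctx[n] for n in names) - beta0
            got = utility(PartWorthTable(betas=betas, beta0=beta0), ctx)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_missing_part_worth_is_a_contract_violation(self):
        pw = PartWorthTable(betas={"price": 1.0})
        with pytest.raises(DecisionError):
            utility(pw, {"trust": 0.5})

    def test_epsilon_requires_rng(self):
        pw = PartWorthTable(betas={"p": 1.0}, epsilon_scale=1.0)
        with pytest.raises(DecisionError):
            utility(pw, {"p": 1.0})
        rng = np.random.default_rng(0)
        assert np.isfinite(utility(pw, {"p": 1.0}, rng))


class TestAccept:
    @pytest.mark.parametrize("u,expected", [
        (0.0, False),      # strictly greater than zero
        (1e-9, True),
        (-5.0, False),
        (1.0, True),
    ])
    def test_strict_threshold(self, u, expected):
        assert accept(u) is expected

    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           u_terms=st.lists(st.tuples(
               st.floats(-10, 10), st.floats(-10, 10)), min_size=1,
               max_size=5),
           beta0=st.floats(-10, 10))
    @settings(max_examples=200, deadline=None)
    def test_acceptance_invariant_under_joint_rescaling(self, scale,
                                                        u_terms, beta0):
        """The linear utility is homogeneous: scaling all part-worths and
        the threshold by a positive constant never flips the decision."""
        betas = {f"c{i}": b for i, (b, _) in enumerate(u_terms)}
        ctx = {f"c{i}": c for i, (_, c) in enumerate(u_terms)}
        u1 = utility(PartWorthTable(betas=betas, beta0=beta0), ctx)
        scaled = {k: v * scale for k, v in betas.items()}
        u2 = utility(PartWorthTable(betas=scaled, beta0=beta0 * scale), ctx)
        if abs(u1) > 1e-7:      # away from the knife edge
            assert accept(u1) == accept(u2)


class TestBuildContext:
    def test_public_manager_sell_criteria(self):
        st_ = ContextState(ref_price=90.0, trust=0.6, remaining_annual=500.0,
                           annual_plan=1000.0, monthly_plan=100.0,
                           harvest_cost=50.0)
        ctx = build_context("public", "sell", price=95.0, amount=80.0,
                            state=st_)
        assert set(ctx) == {"amount_available", "amount_in_demand", "trust",
                            "margin"}
        assert ctx["amount_available"] == pytest.approx(0.5)
        assert ctx["amount_in_demand"] == pytest.approx(0.8)
        assert ctx["margin"] == pytest.approx((95.0 - 50.0) / 90.0)

    def test_importer_uses_price_only(self):
        ctx = build_context("importer", "sell", price=100.0, amount=50.0,
                            state=ContextState(ref_price=90.0,
                                               border_price=95.0))
        assert set(ctx) == {"price"}
        assert ctx["price"] == pytest.approx(5.0 / 90.0)

    def test_sawmill_with_full_stock_saturates_utilization(self):
        st_ = ContextState(ref_price=60.0, stock_utilization=2.5,
                           cost_basis=30.0)
        ctx = build_context("sawmill", "sell", price=55.0, amount=10.0,
                            state=st_)
        assert ctx["stock_utilization"] == 1.0

    def test_unknown_type_side_is_a_configuration_error(self):
        with pytest.raises(DecisionError):
            decision_model_for("energy", "sell")
        with pytest.raises(DecisionError):
            build_context("importer", "buy", 1.0, 1.0, ContextState())

    def test_every_model_produces_exactly_its_criteria(self):
        pairs = [("public", "sell"), ("private", "sell"), ("sawmill", "buy"),
                 ("sawmill", "sell"), ("energy", "buy"),
                 ("industrial", "buy"), ("trader", "buy"), ("trader", "sell"),
                 ("bundler", "buy"), ("bundler", "sell"),
                 ("importer", "sell"), ("exporter", "buy")]
        for atype, side in pairs:
            model = decision_model_for(atype, side)
            ctx = build_context(atype, side, 90.0, 100.0,
                                ContextState(ref_price=90.0))
            assert set(ctx) == set(CRITERIA[model])


class TestTrust:
    def test_success_strictly_increases(self):
        e = PhonebookEntry(contact_id=1, trust=0.5)
        update_trust(e, "success")
        assert e.trust > 0.5

    def test_clamped_at_one(self):
        e = PhonebookEntry(contact_id=1, trust=1.0)
        update_trust(e, "success")
        assert e.trust == 1.0

    def test_failure_strictly_decreases_and_clamps_at_zero(self):
        e = PhonebookEntry(contact_id=1, trust=0.05)
        update_trust(e, "failure", failure_step=0.1)
        assert e.trust == 0.0

    def test_symmetric_steps_return_to_start(self):
        # additive recurrence: +s then -s is the identity away from bounds
        e = PhonebookEntry(contact_id=1, trust=0.5)
        for _ in range(100):
            update_trust(e, "success", success_step=0.03, failure_step=0.03)
            update_trust(e, "failure", success_step=0.03, failure_step=0.03)
            assert e.trust == pytest.approx(0.5, abs=1e-9)

    def test_bounded_under_long_random_outcome_sequences(self):
        rng = np.random.default_rng(7)
        e = PhonebookEntry(contact_id=1, trust=0.5)
        outcomes = rng.random(100_000) < 0.5
        for ok in outcomes:
            update_trust(e, "success" if ok else "failure")
            assert 0.0 <= e.trust <= 1.0

    def test_repeated_success_converges_to_one(self):
        e = PhonebookEntry(contact_id=1, trust=0.0)
        for _ in range(200):
            update_trust(e, "success")
        assert e.trust == 1.0

    def test_unknown_outcome_rejected(self):
        with pytest.raises(DecisionError):
            update_trust(PhonebookEntry(contact_id=1, trust=0.5), "maybe")


class TestSelectContacts:
    def test_k_zero_returns_empty(self):
        book = [PhonebookEntry(contact_id=1, trust=0.5)]
        assert select_contacts(book, 0, substream(1, "t")) == []

    def test_k_beyond_size_returns_all(self):
        book = [PhonebookEntry(contact_id=i, trust=0.5) for i in range(3)]
        assert select_contacts(book, 10, substream(1, "t")) == [0, 1, 2]

    def test_weight_ratio_matches_exact_oracle(self):
        # two contacts, trusts 0.9/0.1, floor 0.05:
        # P(high) = 0.95 / (0.95 + 0.15), checked within 3 sigma
        book = [PhonebookEntry(contact_id=0, trust=0.9),
                PhonebookEntry(contact_id=1, trust=0.1)]
        rng = substream(99, "weights")
        n = 10_000
        hits = sum(select_contacts(book, 1, rng)[0] == 0 for _ in range(n))
        p = 0.95 / (0.95 + 0.15)
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * sigma

    def test_equal_trust_is_uniform(self):
        book = [PhonebookEntry(contact_id=i, trust=0.5) for i in range(4)]
        rng = substream(5, "uniform")
        counts = np.zeros(4)
        n = 8000
        for _ in range(n):
            counts[select_contacts(book, 1, rng)[0]] += 1
        assert np.allclose(counts / n, 0.25, atol=3 * np.sqrt(0.25 * 0.75 / n))

    def test_sampling_without_replacement(self):
        book = [PhonebookEntry(contact_id=i, trust=0.5) for i in range(10)]
        rng = substream(2, "wo-replacement")
        picked = select_contacts(book, 5, rng)
        assert len(picked) == len(set(picked)) == 5

    def test_negative_k_rejected(self):
        with pytest.raises(DecisionError):
            select_contacts([], -1, substream(1, "t"))


class TestPartWorthFile:
    def test_shipped_table_loads_and_matches_defaults(self):
        import importlib.resources

        from woodmarket.config import DecisionSpec

        src = importlib.resources.files("woodmarket.data") / "part_worths.csv"
        with importlib.resources.as_file(src) as path:
            betas, beta0 = load_part_worth_file(path)
        spec = DecisionSpec()
        assert betas == spec.part_worths
        assert beta0 == spec.beta0

    def test_missing_criterion_rejected(self, tmp_path):
        p = tmp_path / "pw.csv"
        p.write_text("model,criterion,beta\nimporter_sell,price,1.0\n")
        with pytest.raises(DecisionError):
            load_part_worth_file(p)

    def test_unknown_model_rejected(self, tmp_path):
        p = tmp_path / "pw.csv"
        p.write_text("model,criterion,beta\nwizard_buy,price,1.0\n")
        with pytest.raises(DecisionError):
            load_part_worth_file(p)
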