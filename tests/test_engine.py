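"""Gillespie loop: waiting times, hierarchical selection, event application."""

import numpy as np
import pytest
from scipy import stats

from evosim.diagnostics import end_state_counts
from evosim.engine import (
    EngineError,
    apply_event,
    evolve_branch,
    next_event_time,
    select_event,
)
from evosim.indels import DeletionProcess, InsertionProcess, LengthDistribution, SiteTemplate
from evosim.models import build_unrest, transition_probabilities
from evosim.sequence import (
    RateAuditError,
    attach_process,
    make_root_from_string,
    make_root_sequence,
    set_site_property,
)


class TestNextEventTime:
    def test_zero_rate_means_no_event(self, rng):
        assert next_event_time(0.0, rng) is None

    def test_negative_rate_is_internal_error(self, rng):
        with pytest.raises(EngineError):
            next_event_time(-1.0, rng)

    def test_exponential_mean(self):
        rng = np.random.default_rng(11)
        n = 100_000
        draws = [next_event_time(2.0, rng) for _ in range(n)]
        assert np.mean(draws) == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n))

    def test_determinism(self):
        a = next_event_time(1.3, np.random.default_rng(5))
        b = next_event_time(1.3, np.random.default_rng(5))
        assert a == b


class TestSelectEvent:
    def test_sites_chosen_proportionally_to_rate(self, jc):
        seq = make_root_from_string("AC", [(0, 2, jc)])
        set_site_property(seq, 0, jc, "rate_multiplier", 3.0)  # rates 3 : 1
        rng = np.random.default_rng(2)
        n = 50_000
        hits = sum(select_event(seq, rng).site == 0 for _ in range(n))
        sigma = np.sqrt(0.75 * 0.25 / n)
        assert hits / n == pytest.approx(0.75, abs=3 * sigma)

    def test_k80_transition_target_probability(self, k80_2):
        # from A, targets G (0.5), C (0.25), T (0.25)
        seq = make_root_from_string("A", [(0, 1, k80_2)])
        rng = np.random.default_rng(3)
        n = 50_000
        to_g = sum(select_event(seq, rng).to_state == "G" for _ in range(n))
        sigma = np.sqrt(0.25 / n)
        assert to_g / n == pytest.approx(0.5, abs=3 * sigma)

    def test_single_possible_event_always_selected(self, jc):
        seq = make_root_from_string("AC", [(0, 1, jc)])  # site 1 unbound
        rng = np.random.default_rng(4)
        for _ in range(20):
            assert select_event(seq, rng).site == 0

    def test_matches_flat_event_enumeration(self, jc):
        """Hierarchical selection reproduces the flat concrete-event law."""
        proc = DeletionProcess(rate=0.5)
        seq = make_root_from_string("AG", [(0, 2, jc)])
        attach_process(seq, (0, 2), proc)
        set_site_property(seq, 1, jc, "rate_multiplier", 2.0)
        # flat enumeration: per site, 3 substitution targets at mult * 1/3
        # each, plus one deletion proposal at 0.5
        flat = {}
        for i, mult in [(0, 1.0), (1, 2.0)]:
            for tgt in "ACGT".replace(seq.sites[i].state, ""):
                flat[("substitution", i, tgt)] = mult / 3
            flat[("deletion", i)] = 0.5
        total = sum(flat.values())
        rng = np.random.default_rng(6)
        n = 60_000
        counts = {k: 0 for k in flat}
        for _ in range(n):
            ev = select_event(seq, rng)
            key = (
                ("substitution", ev.site, ev.to_state)
                if ev.kind == "substitution"
                else ("deletion", ev.site)
            )
            counts[key] += 1
        for key, rate in flat.items():
            p = rate / total
            sigma = np.sqrt(p * (1 - p) / n)
            assert counts[key] / n == pytest.approx(p, abs=4 * sigma), key

    def test_audit_error_on_corrupted_cache(self, jc):
        seq = make_root_from_string("ACGT", [(0, 4, jc)])
        seq.cached_site_rates[2] *= 1.5
        with pytest.raises(RateAuditError):
            for _ in range(200):  # corrupted site must eventually be drawn
                select_event(seq, np.random.default_rng(1))


class TestApplyEvent:
    def test_substitution_changes_exactly_one_position(self, jc):
        seq = make_root_from_string("ACGT", [(0, 4, jc)])
        rng = np.random.default_rng(8)
        before = seq.text()
        ev = select_event(seq, rng)
        apply_event(seq, ev, [])
        after = seq.text()
        assert sum(a != b for a, b in zip(before, after)) == 1
        assert after[ev.site] == ev.to_state

    def test_accepted_deletion_shrinks_and_logs_gap_ops(self, jc, rng):
        proc = DeletionProcess(rate=1.0, lengths=LengthDistribution("fixed", {"value": 2}))
        seq = make_root_from_string("ACGTACGTAC", [(0, 10, jc)])
        attach_process(seq, (0, 10), proc)
        from evosim.indels import propose_deletion
        from evosim.engine import Event

        span = propose_deletion(seq, proc, 3, rng)
        uids = [s.uid for s in seq.sites[3:5]]
        ops = []
        ev = Event("deletion", site=3, rate=1.0, span=span, accepted=True)
        apply_event(seq, ev, ops)
        assert len(seq) == 8
        assert len(ops) == 1 and list(ops[0].uids) == uids

    def test_rejected_proposal_changes_nothing(self, jc, rng):
        proc = DeletionProcess(rate=1.0)
        seq = make_root_from_string("ACGT", [(0, 4, jc)])
        attach_process(seq, (0, 4), proc)
        from evosim.indels import propose_deletion
        from evosim.engine import Event

        before = seq.text()
        ops = []
        ev = Event("deletion", site=1, rate=1.0,
                   span=propose_deletion(seq, proc, 1, rng), accepted=False)
        apply_event(seq, ev, ops)
        assert seq.text() == before and ops == []


class TestEvolveBranch:
    def test_zero_length_branch(self, jc, rng):
        seq = make_root_from_string("ACGT", [(0, 4, jc)])
        res = evolve_branch(seq, 0.0, rng)
        assert res.events == [] and seq.text() == "ACGT"

    def test_zero_total_rate(self, rng):
        seq = make_root_from_string("ACGT")  # no processes at all
        res = evolve_branch(seq, 5.0, rng)
        assert res.events == []

    def test_substitution_count_is_poisson(self, jc):
        # 500 sites, t = 0.4, unit rate -> Poisson(200)
        seq = make_root_sequence(500, jc, np.random.default_rng(12))
        res = evolve_branch(seq, 0.4, np.random.default_rng(13))
        assert abs(len(res.events) - 200) < 4 * np.sqrt(200)

    def test_determinism_given_seed(self, jc):
        outs = []
        for _ in range(2):
            seq = make_root_sequence(100, jc, np.random.default_rng(1))
            res = evolve_branch(seq, 0.5, np.random.default_rng(2))
            outs.append((seq.text(), len(res.events)))
        assert outs[0] == outs[1]

    @pytest.mark.parametrize("model_name", ["k80", "unrest"])
    def test_end_state_matches_matrix_exponential(self, model_name, k80_2):
        """Jump-chain correctness against the expm oracle (chi-square)."""
        if model_name == "k80":
            model = k80_2
        else:
            model = build_unrest(np.random.default_rng(40).uniform(0.2, 2.0, 12))
        t, n = 0.4, 20_000
        counts = end_state_counts(model, "A", t, n, np.random.default_rng(41))
        expected = transition_probabilities(model, t)[model.alphabet.index["A"]] * n
        p = stats.chisquare(counts, expected).pvalue
        assert p > 0.001

    def test_time_additivity(self, k80_2):
        """Evolving a+b equals evolving a then b, in distribution."""
        n = 6000
        one = np.zeros(4, int)
        split = np.zeros(4, int)
        idx = k80_2.alphabet.index
        for r in range(n):
            rng = np.random.default_rng(1000 + r)
            seq = make_root_from_string("A", [(0, 1, k80_2)])
            evolve_branch(seq, 0.5, rng)
            one[idx[seq.sites[0].state]] += 1
            rng = np.random.default_rng(5000 + r)
            seq = make_root_from_string("A", [(0, 1, k80_2)])
            evolve_branch(seq, 0.2, rng)
            evolve_branch(seq, 0.3, rng)
            split[idx[seq.sites[0].state]] += 1
        p = stats.chi2_contingency(np.vstack([one, split])).pvalue
        assert p > 0.01

    def test_rejected_proposals_only_consume_time(self, jc):
        """With an always-rejected deletion process alongside substitutions,
        substitution events stay Poisson at their own rate (superposition):
        rejection costs a step, never substitution probability mass."""
        proc = DeletionProcess(rate=1.0)
        seq = make_root_sequence(1000, jc, np.random.default_rng(21))
        attach_process(seq, (0, 1000), proc, {"deletion_tolerance": 0.0})
        res = evolve_branch(seq, 0.3, np.random.default_rng(22))
        subs = [e for e in res.events if e.kind == "substitution"]
        dels = [e for e in res.events if e.kind == "deletion"]
        assert dels and not any(e.accepted for e in dels)
        assert abs(len(subs) - 300) < 4 * np.sqrt(300)

    def test_periodic_audit_runs_clean_with_indels(self, jc):
        del_proc = DeletionProcess(rate=0.1, mode="fast_field",
                                   lengths=LengthDistribution("geometric", {"p": 0.5}))
        ins_proc = InsertionProcess(rate=0.1, template=SiteTemplate(model=jc),
                                    lengths=LengthDistribution("geometric", {"p": 0.5}))
        seq = make_root_sequence(300, jc, np.random.default_rng(31))
        attach_process(seq, (0, 300), del_proc, {"deletion_tolerance": 0.5})
        attach_process(seq, (0, 300), ins_proc)
        res = evolve_branch(seq, 3.0, np.random.default_rng(32), audit_interval=50)
        assert len(res.events) > 500  # audits ran many times without raising
        seq.audit()


class TestStationarity:
    def test_long_run_frequencies_converge_to_pi(self):
        """End states of a long single-site run are distributed as pi."""
        from evosim.models import build_gtr

        m = build_gtr([1.2, 2.0, 0.7, 1.1, 3.0, 0.9], [0.1, 0.2, 0.3, 0.4])
        n = 20_000
        counts = end_state_counts(m, "A", 8.0, n, np.random.default_rng(71))
        assert stats.chisquare(counts, m.pi * n).pvalue > 0.001


class TestPartitionIndependence:
    def test_per_partition_substitution_budgets(self, jc, k80_2):
        """Two partitions under different models, no indels: each partition's
        substitution count matches its own Poisson expectation."""
        seq = make_root_sequence(800, jc, np.random.default_rng(81))
        # rebind the right half to K80 at half speed
        for i in range(400, 800):
            seq.sites[i].bindings.clear()
            seq.refresh_site(i)
        attach_process(seq, (400, 800), k80_2, {"rate_multiplier": 0.5})
        res = evolve_branch(seq, 0.5, np.random.default_rng(82))
        by_label = {}
        for e in res.events:
            by_label[e.process_label] = by_label.get(e.process_label, 0) + 1
        assert abs(by_label[jc.label] - 200) < 3 * np.sqrt(200)
        assert abs(by_label[k80_2.label] - 100) < 3 * np.sqrt(100)
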