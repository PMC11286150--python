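"""Emission training, forward likelihoods and two-hypothesis site calls."""

import numpy as np
import pandas as pd
import pytest

from amorthmm.hmm_caller import (
    EmissionTable,
    GaussianParams,
    SiteCall,
    TransitionParams,
    call_site,
    enumerate_path_loglik,
    event_sequence_loglik,
    methylation_frequency,
    restrict_training_events,
    train_emission_table,
)
from amorthmm.kmer_core import decompose_window
from amorthmm.signal_sim import (
    generate_pore_model,
    generate_reference,
    simulate_events,
)


def events_frame(rows):
    return pd.DataFrame(rows, columns=["read_id", "position", "kmer", "current"])


class TestTrainEmissionTable:
    def test_mle_by_hand(self):
        ev = events_frame([(0, i, "GATTTM", c) for i, c in enumerate([1.0, 2.0, 3.0])])
        table = train_emission_table(ev, min_events=3)
        p = table.params("GATTTM")
        assert p.mu == pytest.approx(2.0)
        assert p.var == pytest.approx(2.0 / 3.0)  # ML (biased) variance
        assert table.provenance("GATTTM") == "learned"

    def test_below_support_gets_pooled_default(self):
        rows = [(0, i, "GATTTM", 1.0 + i) for i in range(12)]
        rows += [(0, 100, "ATTTMG", 5.0), (0, 101, "ATTTMG", 6.0)]
        table = train_emission_table(events_frame(rows), min_events=10)
        assert table.provenance("GATTTM") == "learned"
        assert table.provenance("ATTTMG") == "default"
        assert table.params("ATTTMG") == table.default_params

    def test_empty_events_raise(self):
        with pytest.raises(ValueError):
            train_emission_table(events_frame([]))

    def test_estimates_recover_simulated_model(self):
        model = generate_pore_model(seed=0)
        ref = generate_reference(seed=1, length=4000, n_window_types=15)
        events = simulate_events(ref, model, n_reads=600, read_length=400, seed=2)
        table = train_emission_table(events, min_events=50)
        checked, close = 0, 0
        for kmer in table.kmers():
            if table.provenance(kmer) != "learned":
                continue
            n = (events["kmer"] == kmer).sum()
            if n < 200:
                continue
            se = np.sqrt(model.var(kmer) / n)
            checked += 1
            close += abs(table.params(kmer).mu - model.mean(kmer)) < 5 * se
        assert checked > 50 and close / checked >= 0.99

    def test_variance_floor_applied(self):
        ev = events_frame([(0, i, "GATTTM", 2.0) for i in range(5)])
        table = train_emission_table(ev, min_events=3, variance_floor=1e-6)
        assert table.params("GATTTM").var == pytest.approx(1e-6)


class TestRestrictTrainingEvents:
    def _mixed(self):
        return events_frame(
            [
                (0, 0, "GATTTM", 1.0),
                (0, 1, "ATTTMG", 2.0),
                (0, 2, "AAAAAA", 3.0),
                (0, 3, "GATTTC", 4.0),
            ]
        )

    def test_identity_when_all_allowed(self):
        ev = self._mixed()
        out = restrict_training_events(ev, {"GATTTM", "ATTTMG"})
        assert len(out) == len(ev)

    def test_empty_allowed_drops_all_modified(self):
        out = restrict_training_events(self._mixed(), set())
        assert not out["kmer"].astype(str).str.contains("M").any()
        assert len(out) == 2

    def test_partial_filter(self):
        out = restrict_training_events(self._mixed(), {"GATTTM"})
        kept = set(out["kmer"].astype(str))
        assert kept == {"GATTTM", "AAAAAA", "GATTTC"}

    def test_categorical_kmer_column(self):
        ev = self._mixed()
        ev["kmer"] = ev["kmer"].astype("category")
        out = restrict_training_events(ev, {"GATTTM"})
        assert set(out["kmer"].astype(str)) == {"GATTTM", "AAAAAA", "GATTTC"}


def toy_table(entries):
    t = EmissionTable()
    for kmer, mu, var in entries:
        t.set(kmer, GaussianParams(mu, var), "learned")
    return t


class TestForwardAlgorithm:
    def test_single_event_single_kmer_is_log_density(self):
        em = toy_table([("GATTTM", 1.0, 4.0)])
        ll = event_sequence_loglik([2.0], ["GATTTM"], em)
        expected = -0.5 * (np.log(2 * np.pi * 4.0) + 1.0 / 4.0)
        assert ll == pytest.approx(expected)

    def test_degenerate_regime_matches_factorized_sum(self):
        path = decompose_window("GATTTMGCAAC")
        em = toy_table([(s, 90 + i, 2.0) for i, s in enumerate(path)])
        x = [90.5, 91.2, 92.1, 92.9, 94.5, 95.1]
        ll = event_sequence_loglik(x, path, em)
        expected = sum(
            -0.5 * (np.log(2 * np.pi * 2.0) + (xi - (90 + i)) ** 2 / 2.0)
            for i, xi in enumerate(x)
        )
        assert ll == pytest.approx(expected)

    def test_length_mismatch_is_minus_inf_without_stay_skip(self):
        path = decompose_window("GATTTMGCAAC")
        em = toy_table([(s, 90.0, 2.0) for s in path])
        assert event_sequence_loglik([90.0] * 4, path, em) == -np.inf
        assert event_sequence_loglik([90.0] * 8, path, em) == -np.inf

    def test_matches_exhaustive_enumeration(self):
        """Forward recursion equals the sum over all stay/step/skip paths."""
        rng = np.random.default_rng(0)
        path6 = decompose_window("GATTTMGCAAC")
        for trial in range(25):
            n_k = int(rng.integers(1, 7))
            n_e = int(rng.integers(1, 7))
            path = path6[:n_k]
            em = toy_table(
                [(s, float(rng.normal(90, 5)), float(rng.uniform(1, 4))) for s in path]
            )
            tr = TransitionParams(
                p_stay=float(rng.uniform(0, 0.3)), p_skip=float(rng.uniform(0, 0.3))
            )
            x = rng.normal(90, 5, size=n_e)
            ll = event_sequence_loglik(x, path, em, tr)
            oracle = enumerate_path_loglik(x, path, em, tr)
            if np.isinf(oracle):
                assert np.isinf(ll)
            else:
                assert ll == pytest.approx(oracle, abs=1e-9)

    def test_missing_kmer_identified(self):
        em = toy_table([("GATTTM", 90.0, 2.0)])
        with pytest.raises(KeyError, match="ATTTMG"):
            event_sequence_loglik([90.0, 91.0], ["GATTTM", "ATTTMG"], em)


class TestCallSite:
    def _window_table(self, window, meth_shift):
        path = decompose_window(window)
        t = EmissionTable()
        for i, s in enumerate(path):
            t.set(s, GaussianParams(90 + i + meth_shift, 2.0), "learned")
            t.set(s.replace("M", "C"), GaussianParams(90 + i, 2.0), "learned")
        return t, path

    def test_indistinguishable_hypotheses_give_zero_llr(self):
        table, path = self._window_table("GATTTMGCAAC", meth_shift=0.0)
        ev = events_frame([(0, 10 + i, s, 90.0 + i) for i, s in enumerate(path)])
        call = call_site(ev, site=15, window="GATTTMGCAAC", em=table)
        assert call.llr == pytest.approx(0.0, abs=1e-12)
        assert call.call is False

    def test_unit_toy_llr_half(self):
        """means 0 (C) and 1 (M), unit variances, observation 1 => llr = 0.5."""
        t = EmissionTable()
        t.set("AAAAAM", GaussianParams(1.0, 1.0), "learned")
        t.set("AAAAAC", GaussianParams(0.0, 1.0), "learned")
        ll_m = event_sequence_loglik([1.0], ["AAAAAM"], t)
        ll_c = event_sequence_loglik([1.0], ["AAAAAC"], t)
        assert ll_m - ll_c == pytest.approx(0.5)

    def test_separated_means_call_methylated(self):
        rng = np.random.default_rng(3)
        table, path = self._window_table("GATTTMGCAAC", meth_shift=4.0)
        correct = 0
        for rep in range(200):
            rows = [
                (r, 10 + i, s, rng.normal(90 + i + 4.0, np.sqrt(2.0)))
                for r in range(5)
                for i, s in enumerate(path)
            ]
            call = call_site(events_frame(rows), 15, "GATTTMGCAAC", table)
            correct += call.call
        assert correct / 200 > 0.99

    def test_no_covering_read_raises(self):
        table, path = self._window_table("GATTTMGCAAC", 1.0)
        ev = events_frame([(0, 10, path[0], 90.0)])  # covers one position only
        with pytest.raises(ValueError, match="covers"):
            call_site(ev, 15, "GATTTMGCAAC", table)

    def test_restriction_only_changes_sites_containing_the_kmer(self):
        """Dropping one k-mer from training leaves other sites' calls intact."""
        model = generate_pore_model(seed=0)
        ref = generate_reference(seed=1, length=4000, n_window_types=12)
        events = simulate_events(ref, model, n_reads=400, read_length=300, seed=2)
        full = train_emission_table(events, min_events=2)
        victim = ref.site_windows[0]
        dropped = set(decompose_window(victim))
        restricted = train_emission_table(
            restrict_training_events(events, full.learned_modified_kmers() - dropped),
            min_events=2,
        ).ensure_complete(full.kmers())
        for s, w in zip(ref.cpg_sites[:8], ref.site_windows[:8]):
            try:
                a = call_site(events, int(s), w, full)
                b = call_site(events, int(s), w, restricted)
            except ValueError:
                continue
            if set(decompose_window(w)).isdisjoint(dropped):
                assert a.llr == pytest.approx(b.llr, abs=1e-9)


class TestSeparationMonotonicity:
    def test_accuracy_improves_with_mean_separation(self):
        """Fully-trained calling error decreases as the 5mC shift grows."""
        from amorthmm.eval_harness import error_metrics, evaluate_table

        errors = []
        for shift in (0.5, 2.0, 6.0):
            model = generate_pore_model(seed=4, methylation_shift_scale=shift)
            ref = generate_reference(seed=5, length=6000, n_window_types=25)
            events = simulate_events(ref, model, n_reads=500, read_length=300, seed=6)
            table = train_emission_table(events, min_events=2)
            needed = {
                s
                for w in ref.site_windows
                for s in decompose_window(w)
            }
            needed |= {s.replace("M", "C") for s in needed}
            table = table.ensure_complete(needed)
            per_read, per_site = evaluate_table(
                events, ref.cpg_sites, ref.site_windows, table
            )
            m = error_metrics(per_read, per_site, ref.methylation_state)
            errors.append(m["read_error"])
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 0.02


class TestMethylationFrequency:
    def _call(self, pos, read_llrs):
        llr = float(sum(read_llrs.values()))
        return SiteCall(pos, llr, llr > 0, read_llrs)

    def test_counting(self):
        calls = [
            self._call(10, {0: 1.0, 1: 2.0}),
            self._call(20, {0: 1.0, 1: 1.0, 2: -1.0, 3: 2.0}),
        ]
        freq = methylation_frequency(calls)
        assert freq[10] == 1.0
        assert freq[20] == 0.75

    def test_order_invariance(self):
        a = self._call(5, {0: 1.0, 1: -1.0, 2: 3.0})
        b = self._call(5, {2: 3.0, 0: 1.0, 1: -1.0})
        assert a.methylated_fraction == b.methylated_fraction


class TestTransitionParams:
    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            TransitionParams(p_stay=0.75, p_skip=0.25)  # p_step == 0
        with pytest.raises(ValueError):
            TransitionParams(p_stay=-0.1)

    def test_call_consistency_enforced(self):
        with pytest.raises(ValueError):
            SiteCall(position=1, llr=2.0, call=False)
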