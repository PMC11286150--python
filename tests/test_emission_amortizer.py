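"""Symmetrized-KL loss, predictor training, imputation policies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amorthmm.emission_amortizer import (
    AmortizerConfig,
    EmissionPredictor,
    TrainingPair,
    build_training_pairs,
    combined_policy_call,
    fit_amortizer,
    grid_search_amortizer,
    impute_emission_table,
    override_all_emissions,
    sym_kl,
    sym_kl_arrays,
)
from amorthmm.hmm_caller import EmissionTable, GaussianParams
from amorthmm.kmer_core import featurize_kmer, single_m_kmers
from amorthmm.signal_sim import generate_pore_model

params = st.tuples(
    st.floats(-50, 50), st.floats(0.01, 100)
).map(lambda t: GaussianParams(*t))


class TestSymKL:
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            ((0.0, 1.0), (0.0, 1.0), 0.0),
            ((0.0, 1.0), (1.0, 1.0), 1.0),  # each directed KL is 0.5
            ((0.0, 1.0), (0.0, 4.0), 1.125),  # 1/8 + 2 - 1
        ],
    )
    def test_closed_form_values(self, p, q, expected):
        assert sym_kl(p, q) == pytest.approx(expected)

    @given(params, params)
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_nonnegative(self, p, q):
        assert sym_kl(p, q) == pytest.approx(sym_kl(q, p))
        assert sym_kl(p, q) >= -1e-12
        assert sym_kl(p, p) == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(-20, 20), st.floats(-20, 20))
    @settings(max_examples=100, deadline=None)
    def test_equal_unit_variance_limit_is_squared_mean_difference(self, m1, m2):
        assert sym_kl((m1, 1.0), (m2, 1.0)) == pytest.approx((m1 - m2) ** 2)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            sym_kl((0.0, 0.0), (0.0, 1.0))


class TestBuildTrainingPairs:
    def _table(self, n_learned=10, n_default=5):
        t = EmissionTable(default_params=GaussianParams(90.0, 25.0))
        kmers = sorted(single_m_kmers())
        for s in kmers[:n_learned]:
            t.set(s, GaussianParams(90.0 + hash(s) % 7, 2.0), "learned")
        for s in kmers[n_learned : n_learned + n_default]:
            t.set(s, t.default_params, "default")
        t.set("AAAAAA", GaussianParams(80.0, 2.0), "learned")  # unmodified
        return t

    def test_provenance_filter(self):
        pairs = build_training_pairs(self._table())
        assert len(pairs) == 10
        assert all("M" in p.kmer for p in pairs)

    def test_feature_length_and_target_roundtrip(self):
        table = self._table()
        for p in build_training_pairs(table):
            assert p.features.shape == (141,)
            assert p.target == table.params(p.kmer)

    def test_no_learned_rows_raise(self):
        t = EmissionTable(default_params=GaussianParams(90.0, 25.0))
        t.set("GATTTM", t.default_params, "default")
        with pytest.raises(ValueError):
            build_training_pairs(t)


def pairs_from_model(model, kmers):
    return [
        TrainingPair(s, featurize_kmer(s), GaussianParams(*model.table[s]))
        for s in kmers
    ]


class TestFitAmortizer:
    def test_learnable_limit_recovers_parameters(self):
        """Residual-free, fixed-variance tables are fit nearly exactly."""
        model = generate_pore_model(
            seed=5, residual_scale=0.0, noise_var_range=(2.25, 2.25)
        )
        kmers = sorted(single_m_kmers())
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(kmers))
        train = [kmers[i] for i in idx[:1500]]
        test = [kmers[i] for i in idx[1500:1900]]
        pred = fit_amortizer(pairs_from_model(model, train), AmortizerConfig(seed=1))
        mu, var = pred.predict_kmers(test)
        tm = np.array([model.table[s][0] for s in test])
        tv = np.array([model.table[s][1] for s in test])
        held = float(sym_kl_arrays(tm, tv, mu, var).mean())
        assert held < 0.05
        # pooled-default baseline is the bar amortization must clear
        pool_mu = np.mean([model.table[s][0] for s in train])
        pool_var = np.var([model.table[s][0] for s in train]) + 2.25
        baseline = float(
            sym_kl_arrays(
                tm, tv, np.full(len(test), pool_mu), np.full(len(test), pool_var)
            ).mean()
        )
        assert held < baseline / 5

    def test_constant_targets_converge_to_constant(self):
        kmers = sorted(single_m_kmers())[:40]
        pairs = [
            TrainingPair(s, featurize_kmer(s), GaussianParams(95.0, 3.0))
            for s in kmers
        ]
        pred = fit_amortizer(pairs, AmortizerConfig(epochs=600, seed=0))
        mu, var = pred.predict_kmers(kmers)
        assert np.allclose(mu, 95.0, atol=0.2)
        assert np.allclose(var, 3.0, rtol=0.2)

    def test_same_seed_is_deterministic(self):
        model = generate_pore_model(seed=2)
        pairs = pairs_from_model(model, sorted(single_m_kmers())[:60])
        cfg = AmortizerConfig(epochs=100, seed=9)
        a = fit_amortizer(pairs, cfg)
        b = fit_amortizer(pairs, cfg)
        assert np.array_equal(a.history["train_loss"], b.history["train_loss"])
        assert all(np.array_equal(x, y) for x, y in zip(a.weights, b.weights))

    def test_too_few_pairs_rejected(self):
        model = generate_pore_model(seed=2)
        with pytest.raises(ValueError):
            fit_amortizer(pairs_from_model(model, ["GATTTM"]), AmortizerConfig())

    def test_config_grid_validation(self):
        with pytest.raises(ValueError):
            AmortizerConfig(d=2)
        with pytest.raises(ValueError):
            AmortizerConfig(h=100)

    def test_grid_search_returns_best_by_validation_loss(self):
        model = generate_pore_model(seed=3)
        pairs = pairs_from_model(model, sorted(single_m_kmers())[:120])
        best, results = grid_search_amortizer(
            pairs, d_values=(3,), h_values=(16, 32),
            base=AmortizerConfig(epochs=120, seed=0),
        )
        assert len(results) == 2
        assert best.h == min(results, key=lambda r: r["val_loss"])["h"]

    def test_serialization_roundtrip(self, tmp_path):
        model = generate_pore_model(seed=4)
        pairs = pairs_from_model(model, sorted(single_m_kmers())[:60])
        pred = fit_amortizer(pairs, AmortizerConfig(epochs=100, seed=0))
        path = tmp_path / "predictor.json"
        pred.to_json(path)
        again = EmissionPredictor.from_json(path)
        kmers = sorted(single_m_kmers())[100:140]
        np.testing.assert_allclose(
            pred.predict_kmers(kmers)[0], again.predict_kmers(kmers)[0]
        )


@pytest.fixture(scope="module")
def trained():
    model = generate_pore_model(seed=7)
    kmers = sorted(single_m_kmers())
    table = EmissionTable(default_params=GaussianParams(90.0, 30.0))
    for s in kmers[:300]:
        table.set(s, GaussianParams(*model.table[s]), "learned")
    for s in kmers[300:400]:
        table.set(s, table.default_params, "default")
    table.set("AAAAAC", GaussianParams(85.0, 2.0), "learned")
    pred = fit_amortizer(
        build_training_pairs(table), AmortizerConfig(epochs=200, seed=0)
    )
    return table, pred


class TestImputationPolicies:
    def test_impute_replaces_defaults_and_completes(self, trained):
        table, pred = trained
        out = impute_emission_table(table, pred)
        assert all(s in out for s in single_m_kmers())
        for s in sorted(single_m_kmers()):
            assert out.provenance(s) in ("learned", "imputed")

    def test_learned_rows_bit_identical_after_imputation(self, trained):
        table, pred = trained
        out = impute_emission_table(table, pred)
        for s in table.learned_modified_kmers():
            assert out.params(s) == table.params(s)
            assert out.provenance(s) == "learned"

    def test_no_defaults_means_identity_on_modified_rows(self, trained):
        table, pred = trained
        learned_only = EmissionTable(default_params=table.default_params)
        for s in table.learned_modified_kmers():
            learned_only.set(s, table.params(s), "learned")
        out = impute_emission_table(learned_only, pred, kmers=sorted(learned_only.kmers()))
        for s in learned_only.kmers():
            assert out.params(s) == learned_only.params(s)

    def test_override_marks_every_modified_row_imputed(self, trained):
        table, pred = trained
        out = override_all_emissions(table, pred)
        assert all(
            out.provenance(s) == "imputed" for s in out.kmers() if "M" in s
        )
        assert out.provenance("AAAAAC") == "learned"  # unmodified untouched

    def test_override_equals_impute_for_perfectly_memorized_rows(self, trained):
        table, pred = trained
        imputed = impute_emission_table(table, pred)
        overridden = override_all_emissions(table, pred)
        for s in table.learned_modified_kmers():
            mu_o, var_o = overridden.params(s)
            mu_p, var_p = pred.predict(s)
            assert mu_o == pytest.approx(mu_p, rel=1e-12)
            assert var_o == pytest.approx(var_p, rel=1e-12)
            if (mu_p, var_p) == tuple(imputed.params(s)):  # memorized exactly
                assert tuple(overridden.params(s)) == tuple(imputed.params(s))


class TestCombinedPolicy:
    def test_routing(self):
        window = "GATTTMGCAAC"
        from amorthmm.kmer_core import decompose_window

        constituents = set(decompose_window(window))
        seen = lambda w: "seen"
        unseen = lambda w: "unseen"
        assert combined_policy_call(seen, unseen, constituents, window) == "seen"
        assert combined_policy_call(seen, unseen, set(), window) == "unseen"
        partial = set(list(constituents)[:3])
        assert combined_policy_call(seen, unseen, partial, window) == "unseen"
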