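"""NNLS refit, best-subset elimination, bootstrap refit, presence test."""

import itertools

import numpy as np
import pandas as pd
import pytest

import sigcrypt as sc
from sigcrypt.nmf import poisson_loglik
from sigcrypt.refitting import (
    SignatureRefit,
    best_subset_refit,
    bootstrap_refit,
    exhaustive_best_subset,
    nnls_refit,
    presence_test,
)

from conftest import make_catalog


def _mini_signatures(n_channels=4):
    # two clearly different signatures on a tiny schema-free matrix;
    # wrapped into an SBS7-like frame by padding to 7 channels
    S = np.zeros((7, 2))
    S[:, 0] = [0.7, 0.1, 0.1, 0.1, 0.0, 0.0, 0.0]
    S[:, 1] = [0.0, 0.0, 0.1, 0.1, 0.1, 0.0, 0.7]
    schema = sc.get_schema("SBS7")
    return sc.SignatureSet(
        pd.DataFrame(S, index=list(schema.labels), columns=["sigA", "sigB"]),
        schema,
    )


class TestNnlsRefit:
    def test_exact_system_recovered(self):
        sigs = _mini_signatures()
        E_true = np.array([[120.0, 40.0], [80.0, 260.0]])
        M = np.rint(sigs.matrix @ E_true).astype(int)
        # choose E so the product is integral: scale rows accordingly
        M = (sigs.matrix @ E_true * 10).round().astype(int)
        cat = make_catalog(
            {"s1": M[:, 0].tolist(), "s2": M[:, 1].tolist()}, "SBS7"
        )
        E = nnls_refit(cat, sigs)
        resid = np.linalg.norm(cat.matrix - sigs.matrix @ E.matrix)
        assert resid < 1e-6

    def test_matches_exhaustive_grid_search(self):
        # brute-force oracle on an integer grid over a 2-signature system
        sigs = _mini_signatures()
        m = np.array([30, 5, 10, 10, 5, 0, 40], dtype=float)
        cat = make_catalog({"s": m.astype(int).tolist()}, "SBS7")
        E = nnls_refit(cat, sigs).matrix[:, 0]
        S = sigs.matrix
        best = min(
            (np.sum((m - S @ np.array([a, b], float)) ** 2), a, b)
            for a, b in itertools.product(range(0, 101), repeat=2)
        )
        ours = np.sum((m - S @ E) ** 2)
        assert ours <= best[0] + 1e-9
        assert np.allclose(E, [best[1], best[2]], atol=1.0)

    def test_poisson_noise_recovery_within_five_percent(self):
        rng = np.random.default_rng(0)
        sigs = sc.make_reference_signatures("SBS96", 1, seed=2)
        lam = sigs.matrix[:, 0] * 10_000
        counts = rng.poisson(lam)
        cat = sc.MutationCatalog(
            pd.DataFrame({"s": counts}, index=list(sigs.schema.labels)),
            sigs.schema,
        )
        E = nnls_refit(cat, sigs)
        assert E.matrix[0, 0] == pytest.approx(10_000, rel=0.05)

    def test_collinear_signatures_warn(self):
        schema = sc.get_schema("SBS7")
        base = np.array([0.5, 0.2, 0.1, 0.1, 0.05, 0.03, 0.02])
        near = base + 1e-3
        sigs = sc.SignatureSet(
            pd.DataFrame({"a": base, "b": near}, index=list(schema.labels)),
            schema,
        )
        cat = make_catalog({"s": [10, 4, 2, 2, 1, 1, 0]}, "SBS7")
        with pytest.warns(UserWarning, match="near-duplicate"):
            nnls_refit(cat, sigs)


class TestBestSubset:
    def _two_of_ten(self, seed):
        refs = sc.make_reference_signatures("SBS96", 10, separation=0.5, seed=11)
        active = [refs.signature_ids[1], refs.signature_ids[6]]
        mixture = sc.GeneratingMixture.null(refs.subset(active))
        design = sc.CohortDesign(
            mice_per_group=2, clones_per_mouse=1,
            mutations_per_clone=5000, seed=seed,
        )
        catalog, truth = sc.simulate_cohort(design, mixture)
        return catalog, refs, set(active), truth

    def test_generating_pair_selected_exactly(self):
        catalog, refs, active, _ = self._two_of_ten(seed=0)
        res = best_subset_refit(catalog, refs)
        for sample, sel in res.selected.items():
            assert set(sel) == active

    def test_zero_delta_keeps_everything_useful(self):
        catalog, refs, _, _ = self._two_of_ten(seed=1)
        strict = best_subset_refit(catalog, refs, max_delta=0.0)
        plain = nnls_refit(catalog, refs)
        # no removal can be accepted on noisy data at delta 0, so the
        # exposures coincide with the plain refit
        assert np.allclose(strict.exposures.matrix, plain.matrix, atol=1e-6)

    def test_trace_deltas_bounded_for_accepted_removals(self):
        catalog, refs, _, _ = self._two_of_ten(seed=2)
        res = best_subset_refit(catalog, refs, max_delta=0.004)
        accepted = res.trace[res.trace["accepted"]]
        assert (accepted["delta"] <= 0.004 + 1e-12).all()

    def test_greedy_agrees_with_exhaustive_oracle(self):
        # candidate set of 7 containing both generating signatures: the
        # well-separated regime where greedy elimination and the
        # exhaustive subset search select the same signatures
        catalog, refs, _, _ = self._two_of_ten(seed=3)
        small = refs.subset(refs.signature_ids[:7])
        m = catalog.matrix[:, 0].astype(float)
        greedy = best_subset_refit(catalog.subset([catalog.sample_ids[0]]), small)
        sel_g = set(greedy.selected[catalog.sample_ids[0]])
        sel_e, _, _ = exhaustive_best_subset(m, small)
        assert sel_g == set(sel_e)

    def test_invalid_max_delta_rejected(self):
        catalog, refs, _, _ = self._two_of_ten(seed=4)
        with pytest.raises(ValueError):
            best_subset_refit(catalog, refs, max_delta=1.0)


class TestBootstrapRefit:
    def test_strong_signature_always_found_weak_never(self):
        refs = sc.make_reference_signatures("SBS96", 6, separation=0.3, seed=13)
        active = refs.signature_ids[:2]
        mixture = sc.GeneratingMixture.null(refs.subset(active))
        design = sc.CohortDesign(
            mice_per_group=1, clones_per_mouse=1,
            mutations_per_clone=5000, seed=5,
        )
        catalog, _ = sc.simulate_cohort(design, mixture)
        res = bootstrap_refit(
            catalog, refs, sc.BootstrapConfig(n_replicates=50, seed=1)
        )
        for sid in active:  # each contributes ~50% of 5000 mutations
            assert (res.found_fraction.loc[sid] >= 0.99).all()
        for sid in refs.signature_ids[2:]:
            assert (res.found_fraction.loc[sid] < 0.10).all()

    def test_single_replicate_fractions_are_binary(self):
        refs = sc.make_reference_signatures("SBS96", 3, seed=17)
        mixture = sc.GeneratingMixture.null(refs)
        catalog, _ = sc.simulate_cohort(
            sc.CohortDesign(mice_per_group=1, clones_per_mouse=1,
                            mutations_per_clone=1000, seed=0),
            mixture,
        )
        res = bootstrap_refit(
            catalog, refs, sc.BootstrapConfig(n_replicates=1, seed=2)
        )
        assert set(np.unique(res.found_fraction.to_numpy())) <= {0.0, 1.0}

    def test_zero_mutation_sample_named(self):
        cat = make_catalog({"empty": [0] * 7}, "SBS7")
        sigs = _mini_signatures()
        with pytest.raises(ValueError, match="empty"):
            bootstrap_refit(cat, sigs, sc.BootstrapConfig(1, 0))


class TestPresenceTest:
    @pytest.fixture(scope="class")
    def refs(self):
        return sc.make_reference_signatures("SBS96", 8, separation=0.3, seed=23)

    def test_strongly_present_signature_significant(self, refs):
        rng = np.random.default_rng(0)
        target = refs.signature_ids[0]
        other = refs.signature_ids[1]
        lam = 0.6 * refs.df[target] + 0.4 * refs.df[other]
        m = rng.poisson(lam.to_numpy() * 3000)
        res = presence_test(
            pd.Series(m, index=list(refs.schema.labels)), refs, target
        )
        assert res.p_value < 0.001
        assert res.llr > 0

    def test_absent_signature_not_significant(self, refs):
        rng = np.random.default_rng(1)
        lam = refs.df[refs.signature_ids[1]].to_numpy() * 3000
        m = rng.poisson(lam)
        res = presence_test(
            pd.Series(m, index=list(refs.schema.labels)),
            refs, refs.signature_ids[5],
        )
        assert res.p_value > 0.05

    def test_nesting_llr_nonnegative_and_duplicate_target_llr_zero(self, refs):
        rng = np.random.default_rng(2)
        m = rng.poisson(refs.matrix.mean(axis=1) * 2000)
        series = pd.Series(m, index=list(refs.schema.labels))
        for target in refs.signature_ids[:4]:
            assert presence_test(series, refs, target).llr >= 0
        # duplicate the target inside the set: models become identical
        dup = refs.df.copy()
        dup["copy"] = dup[refs.signature_ids[0]]
        dup_set = sc.SignatureSet(dup, refs.schema)
        res = presence_test(series, dup_set, refs.signature_ids[0])
        assert res.llr < 1e-3
        assert res.non_identifiable

    def test_loglik_matches_direct_evaluation(self, refs):
        rng = np.random.default_rng(3)
        m = rng.poisson(refs.matrix[:, 0] * 500)
        series = pd.Series(m, index=list(refs.schema.labels))
        res = presence_test(series, refs, refs.signature_ids[0])
        # the reported log-likelihoods must be attainable Poisson logliks
        assert res.loglik_with <= poisson_loglik(m, m + 1e-12) + 1e-6


class TestRefitModel:
    def test_strict_fit_summary_and_explained_fraction(self):
        refs = sc.make_reference_signatures("SBS96", 5, separation=0.4, seed=31)
        mixture = sc.GeneratingMixture.null(refs.subset(refs.signature_ids[:2]))
        catalog, _ = sc.simulate_cohort(
            sc.CohortDesign(mice_per_group=2, clones_per_mouse=1,
                            mutations_per_clone=4000, seed=6),
            mixture,
        )
        res = SignatureRefit(catalog, refs).fit(method="strict")
        assert (res.explained_fraction() > 0.95).all()
        assert "Signature refit" in res.summary()
        table = SignatureRefit(catalog, refs).presence_test(
            [refs.signature_ids[0]]
        )
        assert len(table) == len(catalog.sample_ids)
        assert (table["llr"] >= 0).all()

    def test_plain_fit_equals_nnls(self):
        refs = sc.make_reference_signatures("SBS96", 3, seed=37)
        mixture = sc.GeneratingMixture.null(refs)
        catalog, _ = sc.simulate_cohort(
            sc.CohortDesign(mice_per_group=1, clones_per_mouse=2,
                            mutations_per_clone=2000, seed=7),
            mixture,
        )
        model = SignatureRefit(catalog, refs)
        assert np.allclose(
            model.fit(method="plain").exposures.matrix,
            nnls_refit(catalog, refs).matrix,
        )
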