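"""lnROR matrix construction and correlation-matrix PCA identities."""

import numpy as np
import pandas as pd
import pytest

import pvsignal as pv
from pvsignal.errors import ConfigurationError, ConstantColumnError
from pvsignal.pca import (RorMatrix, biplot, build_ror_matrix, pca_correlation,
                          select_entities)
from pvsignal.signals import Contingency2x2, compute_ror


def _rows_from_counts(counts):
    """Analysis rows from {(drug, term): count}; every term is target-class."""
    records = []
    for (drug, term), n in counts.items():
        records += [{"drug_name": drug, "preferred_term": term,
                     "is_target_event": True}] * n
    return pd.DataFrame(records)


class TestSelectEntities:
    def test_strict_inequality_at_drug_threshold(self):
        rows = _rows_from_counts({("d1", "u"): 50, ("d2", "u"): 51})
        drugs, events = select_entities(rows, ["d1", "d2"],
                                        drug_min_reports=50, event_min_reports=70)
        assert drugs == ["d2"]          # exactly 50 reports is excluded ("more than 50")
        assert events == ["u"]          # 101 reports > 70

    def test_reference_term_table_yields_22_events_above_70(self):
        ref = pv.load_fracture_terms()
        rows = _rows_from_counts({("drug", t): int(n) for t, n in
                                  zip(ref["preferred_term"], ref["reporting_times"])})
        _, selected = select_entities(rows, ["drug"], drug_min_reports=0,
                                      event_min_reports=70)
        assert len(selected) == 22
        assert "Cervical vertebral fracture" in selected   # 74 reports
        assert "Clavicle fracture" not in selected         # 67 reports

    def test_empty_selection_suggests_thresholds(self):
        rows = _rows_from_counts({("d", "t"): 5})
        with pytest.raises(ConfigurationError, match="thresholds"):
            select_entities(rows, ["d"], drug_min_reports=50, event_min_reports=70)


class TestRorMatrix:
    def test_entries_match_signals_module_elementwise(self, default_cohort):
        rows = default_cohort.rows
        drugs = ["alendronic acid", "prednisolone", "zolpidem"]
        events = ["Atypical femur fracture", "Fracture", "Femoral neck fracture"]
        matrix = build_ror_matrix(rows, drugs, events)
        for i, d in enumerate(drugs):
            for j, e in enumerate(events):
                is_d = rows["drug_name"] == d
                is_e = rows["preferred_term"] == e
                t = Contingency2x2(int((is_d & is_e).sum()), int((~is_d & is_e).sum()),
                                   int((is_d & ~is_e).sum()), int((~is_d & ~is_e).sum()))
                _, ln_ror, _ = compute_ror(t)
                assert matrix.values[i, j] == pytest.approx(ln_ror, rel=1e-12)

    def test_symmetric_toy_cohort_all_zero(self):
        counts = {(d, t): 5 for d in ("d1", "d2") for t in ("t1", "t2")}
        rows = _rows_from_counts(counts)
        matrix = build_ror_matrix(rows, ["d1", "d2"], ["t1", "t2"])
        assert np.allclose(matrix.values, 0.0)

    def test_never_coreported_pair_finite(self, default_cohort):
        matrix = build_ror_matrix(default_cohort.rows,
                                  ["acetaminophen"], ["Jaw fracture", "Ulna fracture"])
        assert np.isfinite(matrix.values).all()

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            RorMatrix(drugs=["a"], events=["x", "y"], values=np.zeros((2, 2)))


class TestPcaIdentities:
    @staticmethod
    def _random_matrix(n=40, p=6, seed=0):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(n, p)) @ rng.normal(size=(p, p))
        return RorMatrix(drugs=[f"d{i}" for i in range(n)],
                         events=[f"e{j}" for j in range(p)], values=values)

    def test_eigenvalues_sum_to_event_count(self):
        pm = pca_correlation(self._random_matrix())
        assert pm.eigenvalues.sum() == pytest.approx(6.0, abs=1e-10)
        assert pm.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-12)

    def test_eigenvectors_orthonormal(self):
        pm = pca_correlation(self._random_matrix(seed=1))
        gram = pm.components.T @ pm.components
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_reconstruction_of_standardized_matrix(self):
        matrix = self._random_matrix(seed=2)
        pm = pca_correlation(matrix)
        X = matrix.values
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        assert np.allclose(pm.scores @ pm.components.T, Z, atol=1e-8)

    def test_two_perfectly_correlated_columns_rank_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        matrix = RorMatrix(drugs=[f"d{i}" for i in range(30)], events=["a", "b"],
                           values=np.column_stack([x, 2.0 * x + 1.0]))
        pm = pca_correlation(matrix)
        assert pm.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_columns_flat_spectrum(self):
        rng = np.random.default_rng(4)
        p = 5
        matrix = RorMatrix(drugs=[f"d{i}" for i in range(500)],
                           events=[f"e{j}" for j in range(p)],
                           values=rng.normal(size=(500, p)))
        pm = pca_correlation(matrix)
        assert np.all(np.abs(pm.explained_variance_ratio - 1.0 / p) < 0.04)

    def test_sign_convention_max_loading_positive(self):
        pm = pca_correlation(self._random_matrix(seed=5))
        for k in range(pm.loadings.shape[1]):
            j = np.argmax(np.abs(pm.loadings[:, k]))
            assert pm.loadings[j, k] > 0

    def test_loadings_are_variable_component_correlations(self):
        matrix = self._random_matrix(seed=6)
        pm = pca_correlation(matrix)
        X = matrix.values
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        for k in range(2):
            for j in range(Z.shape[1]):
                r = np.corrcoef(Z[:, j], pm.scores[:, k])[0, 1]
                assert pm.loadings[j, k] == pytest.approx(r, abs=1e-8)

    def test_scale_invariance_of_loadings(self):
        matrix = self._random_matrix(seed=7)
        scaled = RorMatrix(drugs=matrix.drugs, events=matrix.events,
                           values=matrix.values * np.array([1, 5, 0.2, 1, 3, 1.0]))
        pm1, pm2 = pca_correlation(matrix), pca_correlation(scaled)
        assert np.allclose(pm1.loadings, pm2.loadings, atol=1e-10)

    def test_constant_column_error_names_event(self):
        values = np.random.default_rng(8).normal(size=(10, 3))
        values[:, 1] = 4.2
        matrix = RorMatrix(drugs=[f"d{i}" for i in range(10)],
                           events=["a", "flat term", "c"], values=values)
        with pytest.raises(ConstantColumnError, match="flat term"):
            pca_correlation(matrix)

    def test_agrees_with_sklearn_on_spectrum(self):
        """Cross-check the eigen-spectrum against an independent PCA routine."""
        from sklearn.decomposition import PCA
        matrix = self._random_matrix(seed=9)
        pm = pca_correlation(matrix)
        X = matrix.values
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        sk = PCA().fit(Z)
        assert np.allclose(np.sort(pm.eigenvalues)[::-1],
                           np.sort(sk.explained_variance_)[::-1], atol=1e-8)


class TestStructureRecovery:
    def test_planted_block_dominates_one_component(self):
        """A resorption-inhibitor drug block elevating a designated event
        block shows up as same-signed, dominant loadings on one PC."""
        cfg = pv.pca_block_scenario(seed=11, single_block=True)
        demo, drug, reac, _ = pv.generate_cohort(cfg)
        rows, _ = pv.build_analysis_table(demo, drug, reac)
        block_drugs = ["alendronic acid", "risedronic acid", "zoledronic acid",
                       "minodronic acid", "denosumab"]
        background = [f"background {i:02d}" for i in range(10)]
        events = sorted(set(rows.loc[rows["is_target_event"], "preferred_term"]))
        matrix = build_ror_matrix(rows, block_drugs + background, events)
        pm = pca_correlation(matrix)
        loadings = pm.loadings_frame()["PC1"]
        block_events = ["Atypical femur fracture", "Jaw fracture",
                        "Ulna fracture", "Atypical fracture"]
        block = loadings[block_events]
        off = loadings.drop(block_events)
        assert (np.sign(block) == np.sign(block.iloc[0])).all()
        assert block.abs().min() > off.abs().max()


def test_biplot_files_created(tmp_path):
    rng = np.random.default_rng(10)
    matrix = RorMatrix(drugs=[f"d{i}" for i in range(12)],
                       events=[f"e{j}" for j in range(4)],
                       values=rng.normal(size=(12, 4)))
    pm = pca_correlation(matrix)
    p1, p2 = biplot(pm, tmp_path / "loadings.png", tmp_path / "scores.png")
    assert p1.stat().st_size > 0 and p2.stat().st_size > 0
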