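"""Expression preparation: normalization formulas, the expressed-gene
filter, hidden-factor adjustment, PCA partition, sex inference, epoch
deltas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from devqtl import simgen, xprep


def toy_counts(values, sample_ids=None):
    arr = np.atleast_2d(np.asarray(values))
    cols = sample_ids or [f"S{i:04d}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=cols)


class TestLog2Cpm:
    def test_zero_count_closed_form(self):
        # one gene carries the whole library so libsize is exactly 999,999
        counts = toy_counts([[0], [999_999]])
        log2 = xprep.compute_log2cpm(counts)
        assert log2.iloc[0, 0] == pytest.approx(-1.0, abs=1e-9)

    def test_unit_count_closed_form(self):
        counts = toy_counts([[1], [999_999 - 1]])
        log2 = xprep.compute_log2cpm(counts)
        assert log2.iloc[0, 0] == pytest.approx(np.log2(1.5), abs=1e-9)

    def test_scale_invariance_up_to_pseudocount(self):
        # the pseudocount perturbation is O(1/count), so exact scale
        # invariance holds in the large-count regime
        rng = np.random.default_rng(0)
        base = rng.integers(100_000, 1_000_000, size=(20, 4))
        counts = toy_counts(base)
        doubled = toy_counts(base * 2)
        a = xprep.compute_log2cpm(counts).to_numpy()
        b = xprep.compute_log2cpm(doubled).to_numpy()
        assert np.abs(a - b).max() < 1e-5

    def test_all_zero_sample_named(self):
        counts = toy_counts([[0, 5], [0, 3]])
        with pytest.raises(ValueError, match="S0000"):
            xprep.compute_log2cpm(counts)


class TestFilterExpressed:
    def _st(self, n, period=1, sex="male"):
        return pd.DataFrame(
            {"sample_id": [f"S{i:04d}" for i in range(n)], "period": period, "sex": sex}
        )

    def test_half_of_stratum_passes(self):
        # CPM (1.2, 1.1, 0.3, 0.2) in 4 male period-1 samples: 2/4 = 50% kept
        cpm = toy_counts([[1.2, 1.1, 0.3, 0.2]])
        kept = xprep.filter_expressed(cpm, self._st(4))
        assert kept == ["g0"]

    def test_below_one_cpm_everywhere_dropped(self):
        cpm = toy_counts([[0.99] * 6])
        assert xprep.filter_expressed(cpm, self._st(6)) == []

    def test_any_stratum_suffices(self):
        st_tab = pd.DataFrame(
            {
                "sample_id": [f"S{i:04d}" for i in range(4)],
                "period": [1, 1, 2, 2],
                "sex": ["male", "male", "female", "female"],
            }
        )
        # expressed only in the period-2 female stratum
        cpm = toy_counts([[0.0, 0.0, 2.0, 2.0]])
        assert xprep.filter_expressed(cpm, st_tab) == ["g0"]

    def test_monotone_in_added_samples(self):
        rng = np.random.default_rng(1)
        cpm = toy_counts(rng.uniform(0, 3, size=(30, 6)))
        st6 = self._st(6)
        kept_before = set(xprep.filter_expressed(cpm, st6))
        extra = cpm.copy()
        extra["S0006"] = 2.0  # CPM >= 1 everywhere
        st7 = self._st(7)
        kept_after = set(xprep.filter_expressed(extra, st7))
        assert kept_before <= kept_after


class TestAdjustExpression:
    def test_zero_hidden_is_identity(self, small_study):
        out = xprep.adjust_expression(small_study.log2cpm, small_study.samples, 0)
        pd.testing.assert_frame_equal(out, small_study.log2cpm)

    def test_planted_batch_factor_removed(self, cohort):
        rng = np.random.default_rng(2)
        n_genes = 200
        batch = rng.standard_normal(len(cohort))
        load = np.zeros(n_genes)
        affected = rng.choice(n_genes, size=60, replace=False)
        load[affected] = rng.uniform(1.0, 2.0, size=60)
        expr = rng.normal(0, 0.3, size=(n_genes, len(cohort))) + np.outer(load, batch)
        log2 = pd.DataFrame(expr, index=[f"g{i}" for i in range(n_genes)],
                            columns=cohort["sample_id"])
        adj = xprep.adjust_expression(log2, cohort, n_hidden=1)
        # period/sex-space signal is retained by design, so removal is
        # judged against the design-orthogonal part of the batch factor
        D = pd.get_dummies(cohort["period"].astype("category"), drop_first=True)
        X = np.column_stack([np.ones(len(cohort)), D.to_numpy(float),
                             (cohort["sex"] == "male").to_numpy(float)])
        q, _ = np.linalg.qr(X)
        batch_perp = batch - q @ (q.T @ batch)
        cors = [abs(np.corrcoef(adj.iloc[i], batch_perp)[0, 1]) for i in affected]
        assert np.mean(np.array(cors) < 0.05) >= 0.95

    def test_residual_variance_never_increases(self, small_study):
        adj = xprep.adjust_expression(small_study.log2cpm, small_study.samples, 3)
        def resid_var(mat):
            st_ = small_study.samples
            X = pd.get_dummies(st_["period"].astype("category"), drop_first=True)
            X = np.column_stack([np.ones(len(st_)), X.to_numpy(float),
                                 (st_["sex"] == "male").to_numpy(float)])
            Y = mat.to_numpy(float)
            beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
            R = Y - (X @ beta).T
            return (R**2).sum(axis=1)
        assert (resid_var(adj) <= resid_var(small_study.log2cpm) + 1e-8).all()

    def test_idempotent_when_residual_rank_covered(self, cohort):
        # residual structure of exactly rank 2: removing 2 PCs leaves a
        # residual of (numerical) rank 0, so a second pass is a no-op
        rng = np.random.default_rng(3)
        factors = rng.standard_normal((2, len(cohort)))
        load = rng.standard_normal((40, 2))
        log2 = pd.DataFrame(load @ factors, index=[f"g{i}" for i in range(40)],
                            columns=cohort["sample_id"])
        once = xprep.adjust_expression(log2, cohort, n_hidden=2)
        twice = xprep.adjust_expression(once, cohort, n_hidden=2)
        assert np.abs(once.to_numpy() - twice.to_numpy()).max() < 1e-8

    def test_excessive_n_hidden_rejected(self, small_study):
        with pytest.raises(ValueError, match="n_hidden"):
            xprep.adjust_expression(small_study.log2cpm, small_study.samples, 10_000)


class TestPcaVariancePartition:
    def test_covariate_equal_to_pc_scores(self, rng):
        Y = rng.standard_normal((40, 30))
        log2 = pd.DataFrame(Y, index=[f"g{i}" for i in range(40)],
                            columns=[f"S{i}" for i in range(30)])
        centered = Y.T - Y.T.mean(axis=0)
        U, s, _ = np.linalg.svd(centered, full_matrices=False)
        cov = pd.DataFrame({"pc1_copy": U[:, 0] * s[0], "noise": rng.standard_normal(30)})
        tab = xprep.pca_variance_partition(log2, cov, n_pcs=3)
        assert tab.loc[tab["pc"] == 1, "pc1_copy"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_age_driven_expression_loads_on_pc1(self, cohort):
        rng = np.random.default_rng(4)
        age = np.log2(cohort["age_days"].to_numpy())
        slopes = rng.uniform(-1, 1, size=150)
        Y = np.outer(slopes, age) + rng.normal(0, 0.3, size=(150, len(cohort)))
        log2 = pd.DataFrame(Y, index=[f"g{i}" for i in range(150)],
                            columns=cohort["sample_id"])
        cov = pd.DataFrame({
            "period": cohort["period"].astype("category"),
            "sex": cohort["sex"],
        })
        tab = xprep.pca_variance_partition(log2, cov, n_pcs=2)
        assert tab.loc[tab["pc"] == 1, "period"].iloc[0] > 0.8

    def test_variance_fractions_sum_to_one(self, small_study):
        cov = pd.DataFrame({"sex": small_study.samples["sex"]})
        full = xprep.pca_variance_partition(small_study.log2cpm, cov,
                                            n_pcs=min(small_study.log2cpm.shape) - 1)
        # fractions over ALL PCs sum to 1; here we recompute the total
        Y = small_study.log2cpm.to_numpy().T
        s = np.linalg.svd(Y - Y.mean(axis=0), compute_uv=False)
        assert (s**2 / (s**2).sum()).sum() == pytest.approx(1.0)
        assert (full["variance_fraction"] <= 1).all()

    def test_collinear_covariates_rejected(self, cohort):
        rng = np.random.default_rng(5)
        log2 = pd.DataFrame(rng.standard_normal((20, len(cohort))),
                            index=[f"g{i}" for i in range(20)],
                            columns=cohort["sample_id"])
        x = rng.standard_normal(len(cohort))
        cov = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            xprep.pca_variance_partition(log2, cov)


class TestInferSex:
    def _marker_matrix(self, cohort, sep=4.0, noise=0.5, seed=6, markers=None):
        rng = np.random.default_rng(seed)
        male = (cohort["sex"] == "male").to_numpy()
        genes = markers or (["XIST"] + xprep.DEFAULT_SEX_MARKERS["male_high"][:5])
        rows = {}
        for g in genes:
            high_in_male = g != "XIST"
            base = np.where(male == high_in_male, sep, 0.0)
            rows[g] = base + rng.normal(0, noise, len(cohort))
        return pd.DataFrame(rows).T.set_axis(cohort["sample_id"], axis=1)

    def test_full_concordance_on_separated_markers(self, cohort):
        calls = xprep.infer_sex(self._marker_matrix(cohort))
        assert (calls["sex_call"].to_numpy() == cohort["sex"].to_numpy()).all()
        assert not calls["ambiguous"].any()

    def test_xist_only_flagged_single_marker(self, cohort):
        mat = self._marker_matrix(cohort, markers=["XIST"])
        calls = xprep.infer_sex(mat)
        assert calls["single_marker"].all()
        assert (calls["sex_call"].to_numpy() == cohort["sex"].to_numpy()).all()

    def test_no_markers_rejected(self, cohort):
        mat = pd.DataFrame(np.zeros((2, len(cohort))), index=["a", "b"],
                           columns=cohort["sample_id"])
        with pytest.raises(ValueError, match="marker"):
            xprep.infer_sex(mat)


class TestEpochDelta:
    def test_delta_and_flags(self, cohort):
        e1 = (cohort["epoch"] == 1).to_numpy()
        e3 = (cohort["epoch"] == 3).to_numpy()
        X = np.zeros((3, len(cohort)))
        X[0] = np.where(e3, 3.0, 1.0)            # delta 2, no flags
        X[1] = np.where(e1, -6.0, 2.0)           # epoch3-specific riser
        X[2] = 1.5                               # constant
        log2 = pd.DataFrame(X, index=["a", "b", "c"], columns=cohort["sample_id"])
        tab = xprep.epoch_delta(log2, cohort).set_index("gene_id")
        assert tab.loc["a", "delta"] == pytest.approx(2.0)
        assert not tab.loc["a", "epoch3_specific"] and not tab.loc["a", "epoch1_specific"]
        assert tab.loc["b", "epoch3_specific"]
        assert tab.loc["c", "delta"] == pytest.approx(0.0)

    def test_missing_epoch_rejected(self):
        t = simgen.simulate_samples(n_per_period=[5, 0, 5, 5, 5, 0, 0, 0, 0, 0, 0, 0], seed=0)
        log2 = pd.DataFrame(np.zeros((2, len(t))), index=["a", "b"], columns=t["sample_id"])
        with pytest.raises(ValueError, match="epoch"):
            xprep.epoch_delta(log2, t)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_filter_monotone_property(seed):
    """Adding a sample with CPM >= 1 never removes a gene."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 8))
    cpm = pd.DataFrame(rng.uniform(0, 2, size=(10, n)),
                       index=[f"g{i}" for i in range(10)],
                       columns=[f"S{i:04d}" for i in range(n)])
    st_tab = pd.DataFrame({"sample_id": cpm.columns,
                           "period": rng.integers(1, 4, n), "sex": "male"})
    before = set(xprep.filter_expressed(cpm, st_tab))
    cpm2 = cpm.copy()
    cpm2[f"S{n:04d}"] = 1.0 + rng.uniform(0, 2, size=10)
    st2 = pd.concat([st_tab, pd.DataFrame({"sample_id": [f"S{n:04d}"],
                                           "period": [int(rng.integers(1, 4))],
                                           "sex": ["male"]})], ignore_index=True)
    after = set(xprep.filter_expressed(cpm2, st2))
    assert before <= after
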