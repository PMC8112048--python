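"""Moderated DE: filtering, fits, EB prior, moderated t, BH, PCA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pufgba.diffexpr import (
    DeConfig,
    DesignSpec,
    GeneFit,
    bh_adjust,
    estimate_prior,
    filter_low_abundance,
    fit_group_means,
    moderated_test,
    sample_pca,
)
from pufgba.proteoquant import AbundanceStudy


def _study_from(matrix: np.ndarray, groups: dict):
    """Build an imputed-scale study with the given (strain,tp)->n layout."""
    cols, rows = [], []
    for (strain, tp), n in groups.items():
        for r in range(1, n + 1):
            cols.append(f"{strain}_{tp}_R{r}")
            rows.append({"sample": f"{strain}_{tp}_R{r}", "strain": strain,
                         "timepoint": tp, "replicate": r, "phase": "early"})
    samples = pd.DataFrame(rows).set_index("sample")
    prot = pd.DataFrame({"length_aa": 100, "is_puf": False, "annotation": ""},
                        index=pd.Index([f"P{i}" for i in range(matrix.shape[0])],
                                       name="protein"))
    mat = pd.DataFrame(matrix, index=prot.index, columns=cols)
    return AbundanceStudy(matrix=mat, samples=samples, proteins=prot,
                          scale="imputed")


def _design(groups: dict, contrast=(("B", "T1"), ("A", "T1"), "early")):
    sample_ids = {g: [f"{g[0]}_{g[1]}_R{r}" for r in range(1, n + 1)]
                  for g, n in groups.items()}
    return DesignSpec(groups=sample_ids, contrasts=[contrast])


class TestAbundanceFilter:
    def test_boundary_closed_above(self):
        study = _study_from(np.array([[22.9] * 4, [23.0] * 4]),
                            {("A", "T1"): 4})
        out, report = filter_low_abundance(study)
        assert list(out.matrix.index) == ["P1"]
        assert report == {"retained": 1, "removed": 1}

    def test_minus_infinity_cutoff_is_identity(self, study_bundle):
        study = study_bundle["study"]
        out, _ = filter_low_abundance(study, DeConfig(low_abundance_cutoff=-np.inf))
        assert out.matrix.shape == study.matrix.shape

    def test_matches_bruteforce_mean_comparison(self, study_bundle):
        study = study_bundle["study"]
        out, _ = filter_low_abundance(study, DeConfig(low_abundance_cutoff=25.0))
        expected = {p for p in study.matrix.index
                    if study.matrix.loc[p].mean() >= 25.0}
        assert set(out.matrix.index) == expected


class TestGroupMeans:
    def test_hand_computed_two_group_toy(self):
        groups = {("A", "T1"): 4, ("B", "T1"): 4}
        mat = np.array([[1.0, 2, 3, 4, 2, 4, 6, 8]])
        study = _study_from(mat, groups)
        fits = fit_group_means(study, _design(groups))
        beta = fits.means[("B", "T1")] - fits.means[("A", "T1")]
        assert beta.iloc[0] == pytest.approx(2.5)
        # pooled variance by hand: SS_A + SS_B over 8 - 2 df
        ss = np.sum((np.array([1, 2, 3, 4]) - 2.5) ** 2) \
            + np.sum((np.array([2, 4, 6, 8]) - 5.0) ** 2)
        assert fits.s2.iloc[0] == pytest.approx(ss / 6.0)
        assert fits.df_resid == 6

    def test_constant_groups_zero_variance(self):
        groups = {("A", "T1"): 4, ("B", "T1"): 4}
        study = _study_from(np.array([[5.0] * 4 + [7.0] * 4]), groups)
        fits = fit_group_means(study, _design(groups))
        assert fits.s2.iloc[0] == 0.0

    def test_shift_invariance_of_variance(self, rng):
        groups = {("A", "T1"): 4, ("B", "T1"): 4}
        mat = rng.normal(size=(10, 8))
        f1 = fit_group_means(_study_from(mat, groups), _design(groups))
        f2 = fit_group_means(_study_from(mat + 3.7, groups), _design(groups))
        assert np.allclose(f1.s2, f2.s2)
        assert not np.allclose(f1.means, f2.means)

    def test_single_sample_group_rejected(self):
        groups = {("A", "T1"): 4, ("B", "T1"): 1}
        with pytest.raises(ValueError):
            _design(groups)


def _simulate_fits(n_prot, d0, s0=0.05, dg=6, rng=None, outlier_frac=0.0):
    rng = rng or np.random.default_rng(0)
    sigma2 = s0 * d0 / rng.chisquare(d0, n_prot) if math.isfinite(d0) \
        else np.full(n_prot, s0)
    s2 = sigma2 * rng.chisquare(dg, n_prot) / dg
    if outlier_frac:
        n_out = int(n_prot * outlier_frac)
        s2[:n_out] *= 50.0
    A = rng.uniform(20, 30, n_prot)
    idx = pd.Index([f"P{i}" for i in range(n_prot)], name="protein")
    return GeneFit(proteins=list(idx), group_names=[("A", "T1"), ("B", "T1")],
                   means=pd.DataFrame({("A", "T1"): 0.0, ("B", "T1"): 0.0},
                                      index=idx),
                   s2=pd.Series(s2, index=idx), df_resid=dg,
                   avg_abundance=pd.Series(A, index=idx),
                   group_sizes={("A", "T1"): 4, ("B", "T1"): 4})


class TestPrior:
    def test_equal_variances_give_infinite_d0(self):
        fits = _simulate_fits(1000, math.inf, s0=0.04)
        prior = estimate_prior(fits)
        assert math.isinf(prior.d0)
        assert np.allclose(prior.s02, 0.04, rtol=0.2)

    def test_d0_recovery_within_25_percent(self):
        fits = _simulate_fits(5000, d0=4.0, rng=np.random.default_rng(42))
        prior = estimate_prior(fits, DeConfig(robust=False))
        assert abs(prior.d0 - 4.0) / 4.0 < 0.25

    def test_robust_mode_resists_outlier_variances(self):
        rng = np.random.default_rng(7)
        clean = _simulate_fits(4000, d0=6.0, rng=rng)
        dirty = _simulate_fits(4000, d0=6.0, rng=np.random.default_rng(7),
                               outlier_frac=0.01)
        d0_clean = estimate_prior(clean, DeConfig(robust=True)).d0
        d0_dirty = estimate_prior(dirty, DeConfig(robust=True)).d0
        assert abs(d0_dirty - d0_clean) / d0_clean < 0.10

    def test_requires_enough_proteins(self):
        with pytest.raises(ValueError):
            estimate_prior(_simulate_fits(10, 4.0))


class TestModeratedT:
    def test_d0_zero_is_ordinary_t(self, rng):
        groups = {("A", "T1"): 4, ("B", "T1"): 4}
        mat = rng.normal(25, 1, size=(50, 8))
        study = _study_from(mat, groups)
        design = _design(groups)
        fits = fit_group_means(study, design)
        from pufgba.diffexpr import ModerationPrior
        prior = ModerationPrior(d0=1e-12, s02=pd.Series(1.0, index=fits.s2.index))
        res = moderated_test(fits, prior, design.contrasts[0])
        a = mat[:, 4:]
        b = mat[:, :4]
        t_ref, _ = stats.ttest_ind(a.T, b.T)
        assert np.max(np.abs(res["t"].to_numpy() - t_ref)) < 1e-6

    def test_d0_infinite_uses_prior_exactly(self, rng):
        groups = {("A", "T1"): 4, ("B", "T1"): 4}
        study = _study_from(rng.normal(25, 1, size=(30, 8)), groups)
        design = _design(groups)
        fits = fit_group_means(study, design)
        from pufgba.diffexpr import ModerationPrior
        prior = ModerationPrior(d0=math.inf,
                                s02=pd.Series(0.7, index=fits.s2.index))
        res = moderated_test(fits, prior, design.contrasts[0])
        beta = res["log2FC"].to_numpy()
        v = 0.25 + 0.25
        assert np.allclose(res["t"], beta / np.sqrt(0.7 * v))

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(77)
        groups = {("A", "T1"): 4, ("B", "T1"): 4}
        n = 2000
        sigma = np.sqrt(np.exp(rng.normal(-1.8, 0.4, n)))
        mat = 25.0 + rng.normal(size=(n, 8)) * sigma[:, None]
        study = _study_from(mat, groups)
        design = _design(groups)
        fits = fit_group_means(study, design)
        prior = estimate_prior(fits)
        res = moderated_test(fits, prior, design.contrasts[0])
        rate = (res["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) <= 3 * se


class TestBH:
    def test_hand_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_bruteforce_definition(self, rng):
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 40)))
            m = len(p)
            order = np.argsort(p)
            expected = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                expected[i] = running
            assert np.allclose(bh_adjust(p), expected)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, p):
        q = bh_adjust(p)
        assert np.all(q <= 1.0) and np.all(q >= np.asarray(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestPca:
    def test_duplicated_sample_identical_coordinates(self, rng):
        groups = {("A", "T1"): 4, ("B", "T1"): 4}
        mat = rng.normal(size=(40, 8))
        mat[:, 1] = mat[:, 0]
        study = _study_from(mat, groups)
        coords, _ = sample_pca(study)
        assert np.allclose(coords.iloc[0], coords.iloc[1], atol=1e-9)

    def test_variance_explained_shape(self, study_bundle):
        coords, varexp = sample_pca(study_bundle["study"], n_components=5)
        assert varexp.sum() <= 1.0 + 1e-9
        assert np.all(np.diff(varexp) <= 1e-12)

    def test_planted_two_cluster_separation(self, rng):
        from sklearn.metrics import silhouette_score
        groups = {("A", "T1"): 6, ("B", "T1"): 6}
        mat = rng.normal(size=(100, 12)) * 0.3
        mat[:, 6:] += rng.normal(size=(100, 1))  # shared shift for B samples
        study = _study_from(25 + mat, groups)
        coords, _ = sample_pca(study)
        labels = [0] * 6 + [1] * 6
        assert silhouette_score(coords[["PC1"]], labels) > 0.5

    def test_too_few_samples_rejected(self, rng):
        groups = {("A", "T1"): 2}
        study = _study_from(rng.normal(size=(10, 2)), groups)
        with pytest.raises(ValueError):
            sample_pca(study)


def test_default_design_uses_phase_matching(study_bundle):
    design = DesignSpec.from_samples(study_bundle["study"].samples)
    labels = [c[2] for c in design.contrasts]
    assert labels == ["early", "mid", "late"]
    # strainB's mid-log group is its second timepoint
    mid = [c for c in design.contrasts if c[2] == "mid"][0]
    assert mid[0] == ("strainB", "T2")
    # strainB's late group is its fourth timepoint (not the third)
    late = [c for c in design.contrasts if c[2] == "late"][0]
    assert late[0] == ("strainB", "T4")
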