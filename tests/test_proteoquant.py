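"""Quantification chain: rollup, validity, normalization, imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pufgba.proteoquant import (
    QuantConfig,
    impute_lod,
    normalize_across_samples,
    normalize_length_run,
    quantify,
    rollup,
    validity_filter,
)
from pufgba.simulate import SimStudyConfig, sim_study


def _tiny_tables():
    samples = pd.DataFrame({
        "strain": ["A"] * 4, "timepoint": ["T1"] * 4,
        "replicate": [1, 2, 3, 4], "phase": ["early"] * 4,
    }, index=pd.Index([f"s{i}" for i in range(1, 5)], name="sample"))
    proteins = pd.DataFrame({
        "length_aa": [100, 200], "is_puf": [False, True],
        "annotation": ["x", "y"],
    }, index=pd.Index(["P1", "P2"], name="protein"))
    return samples, proteins


class TestRollup:
    def test_sums_peptides(self):
        samples, proteins = _tiny_tables()
        pep = pd.DataFrame([
            ("a", "P1", "s1", 10.0, 2), ("b", "P1", "s1", 20.0, 3),
            ("a", "P2", "s1", 1.0, 1),
        ], columns=["peptide", "protein", "sample", "intensity", "psm_count"])
        study, counts = rollup(pep, samples, proteins)
        assert study.matrix.loc["P1", "s1"] == 30.0
        row = counts[(counts["protein"] == "P1") & (counts["sample"] == "s1")]
        assert row["n_peptides"].iloc[0] == 2 and row["n_psms"].iloc[0] == 5

    def test_all_missing_cell_stays_missing(self):
        samples, proteins = _tiny_tables()
        pep = pd.DataFrame([
            ("a", "P1", "s1", np.nan, 0), ("a", "P1", "s2", 5.0, 2),
        ], columns=["peptide", "protein", "sample", "intensity", "psm_count"])
        study, counts = rollup(pep, samples, proteins)
        assert np.isnan(study.matrix.loc["P1", "s1"])
        assert not ((counts["protein"] == "P1") & (counts["sample"] == "s1")).any()

    def test_unknown_protein_rejected(self):
        samples, proteins = _tiny_tables()
        pep = pd.DataFrame([("a", "PX", "s1", 1.0, 1)],
                           columns=["peptide", "protein", "sample", "intensity", "psm_count"])
        with pytest.raises(ValueError, match="unknown"):
            rollup(pep, samples, proteins)

    def test_matches_groupby_oracle_on_random_table(self, rng):
        n = 1000
        samples, _ = _tiny_tables()
        prot_ids = [f"P{i}" for i in range(20)]
        proteins = pd.DataFrame({"length_aa": 100, "is_puf": False,
                                 "annotation": ""}, index=pd.Index(prot_ids, name="protein"))
        pep = pd.DataFrame({
            "peptide": [f"pep{i}" for i in range(n)],
            "protein": rng.choice(prot_ids, n),
            "sample": rng.choice(samples.index, n),
            "intensity": rng.uniform(1, 100, n),
            "psm_count": rng.integers(1, 5, n),
        })
        study, _ = rollup(pep, samples, proteins)
        expected = {}
        for rec in pep.itertuples():
            expected[(rec.protein, rec.sample)] = (
                expected.get((rec.protein, rec.sample), 0.0) + rec.intensity)
        for (p, s), v in expected.items():
            assert study.matrix.loc[p, s] == pytest.approx(v)


class TestValidity:
    def test_single_peptide_protein_dropped(self):
        samples, proteins = _tiny_tables()
        rows = []
        for s in samples.index:
            rows.append(("only", "P1", s, 10.0, 5))      # 1 peptide: invalid
            rows.append(("a", "P2", s, 10.0, 2))
            rows.append(("b", "P2", s, 10.0, 2))
        pep = pd.DataFrame(rows, columns=["peptide", "protein", "sample",
                                          "intensity", "psm_count"])
        study, counts = rollup(pep, samples, proteins)
        filtered = validity_filter(study, counts)
        assert "P1" not in filtered.matrix.index
        assert "P2" in filtered.matrix.index
        assert (filtered.filter_report["protein"] == "P1").any()

    def test_two_of_four_replicates_retained(self):
        samples, proteins = _tiny_tables()
        rows = []
        for s in ["s1", "s2"]:  # valid in exactly 2 of 4 replicates
            rows.append(("a", "P1", s, 10.0, 2))
            rows.append(("b", "P1", s, 10.0, 2))
        for s in samples.index:
            rows.append(("a", "P2", s, 10.0, 2))
            rows.append(("b", "P2", s, 10.0, 2))
        pep = pd.DataFrame(rows, columns=["peptide", "protein", "sample",
                                          "intensity", "psm_count"])
        study, counts = rollup(pep, samples, proteins)
        filtered = validity_filter(study, counts)
        assert "P1" in filtered.matrix.index

    def test_one_of_four_replicates_group_erased(self):
        samples, proteins = _tiny_tables()
        rows = [("a", "P1", "s1", 10.0, 2), ("b", "P1", "s1", 10.0, 2)]
        for s in samples.index:
            rows.append(("a", "P2", s, 10.0, 2))
            rows.append(("b", "P2", s, 10.0, 2))
        pep = pd.DataFrame(rows, columns=["peptide", "protein", "sample",
                                          "intensity", "psm_count"])
        study, counts = rollup(pep, samples, proteins)
        filtered = validity_filter(study, counts)
        assert "P1" not in filtered.matrix.index

    def test_planted_invalid_proteins_exactly_removed(self):
        config = SimStudyConfig(n_proteins=100, n_puf=5, n_invalid=10,
                                lod_quantile=0.0, seed=21)
        peptides, samples, proteins, truth = sim_study(config)
        study, counts = rollup(peptides, samples, proteins)
        filtered = validity_filter(study, counts)
        dropped = set(study.matrix.index) - set(filtered.matrix.index)
        assert dropped == truth.true_invalid

    @given(st.integers(min_value=1, max_value=5))
    @settings(max_examples=5, deadline=None)
    def test_filtering_monotone_in_min_peptides(self, min_pep):
        config = SimStudyConfig(n_proteins=60, n_puf=0, n_invalid=5,
                                lod_quantile=0.1, seed=7)
        peptides, samples, proteins, _ = sim_study(config)
        study, counts = rollup(peptides, samples, proteins)
        cells = [
            validity_filter(study, counts, QuantConfig(min_peptides=mp))
            .matrix.notna().sum().sum()
            for mp in (min_pep, min_pep + 1)
        ]
        assert cells[0] >= cells[1]


class TestNormalization:
    def _raw_study(self, values):
        samples, proteins = _tiny_tables()
        matrix = pd.DataFrame(values, index=proteins.index, columns=samples.index)
        from pufgba.proteoquant import AbundanceStudy
        return AbundanceStudy(matrix=matrix, samples=samples, proteins=proteins)

    def test_length_division_ratio(self):
        study = self._raw_study(np.full((2, 4), 100.0))
        out = normalize_length_run(study)
        ratio = out.matrix.loc["P1"] / out.matrix.loc["P2"]
        assert np.allclose(ratio, 2.0)  # lengths 100 vs 200

    def test_run_totals_equalized(self, rng):
        study = self._raw_study(rng.uniform(10, 1000, (2, 4)))
        out = normalize_length_run(study)
        totals = out.matrix.sum(axis=0)
        assert np.allclose(totals, totals.iloc[0], rtol=1e-9)

    def test_two_step_oracle_cellwise(self, rng):
        vals = rng.uniform(10, 1000, (2, 4))
        study = self._raw_study(vals)
        out = normalize_length_run(study)
        lengths = np.array([100.0, 200.0])
        per_len = vals / lengths[:, None]
        totals = per_len.sum(axis=0)
        expected = per_len * (totals.mean() / totals)
        assert np.allclose(out.matrix.to_numpy(), expected)

    def test_quantile_normalization_hand_example(self):
        samples, proteins = _tiny_tables()
        samples = samples.iloc[:2]
        matrix = pd.DataFrame([[1.0, 2.0], [2.0, 4.0], [4.0, 8.0]],
                              index=["P1", "P2", "P3"], columns=samples.index)
        proteins = pd.DataFrame({"length_aa": 1, "is_puf": False, "annotation": ""},
                                index=pd.Index(["P1", "P2", "P3"], name="protein"))
        from pufgba.proteoquant import AbundanceStudy
        study = AbundanceStudy(matrix=matrix, samples=samples, proteins=proteins,
                               scale="normalized")
        out = normalize_across_samples(study)
        # log2 columns are {0,1,2} and {1,2,3}; rank-wise mean {0.5,1.5,2.5}
        expected = np.array([[0.5, 0.5], [1.5, 1.5], [2.5, 2.5]])
        assert np.allclose(out.matrix.to_numpy(), expected)

    def test_single_sample_study_is_log2_only(self):
        samples, proteins = _tiny_tables()
        samples = samples.iloc[:1]
        matrix = pd.DataFrame([[8.0], [2.0]], index=proteins.index,
                              columns=samples.index)
        from pufgba.proteoquant import AbundanceStudy
        study = AbundanceStudy(matrix=matrix, samples=samples, proteins=proteins,
                               scale="normalized")
        out = normalize_across_samples(study)
        assert np.allclose(out.matrix.to_numpy().ravel(), [3.0, 1.0])

    def test_scale_tag_enforces_order(self):
        study = self._raw_study(np.full((2, 4), 10.0))
        with pytest.raises(ValueError, match="normalized"):
            normalize_across_samples(study)  # still raw
        with pytest.raises(ValueError):
            impute_lod(study)


class TestImputation:
    def test_no_missing_is_identity_and_deterministic(self, study_bundle):
        study = study_bundle["study"]
        mask = study.imputed_mask
        observed = study.matrix.where(~mask)
        config = SimStudyConfig(n_proteins=60, n_puf=0, lod_quantile=0.1, seed=13)
        peptides, samples, proteins, _ = sim_study(config)
        study1 = quantify(peptides, samples, proteins, QuantConfig(seed=99))
        study2 = quantify(peptides, samples, proteins, QuantConfig(seed=99))
        assert study1.matrix.equals(study2.matrix)
        # observed cells are untouched by imputation in the shared bundle
        pre = study.matrix.where(~mask)
        assert pre.equals(observed)

    def test_lod_quantile_zero_means_no_missing(self):
        config = SimStudyConfig(n_proteins=50, n_puf=0, lod_quantile=0.0, seed=2)
        peptides, *_ = sim_study(config)
        assert not peptides["intensity"].isna().any()

    def test_imputed_cell_distribution(self):
        """Imputed values track Normal(mu - 1.8 sd, (0.3 sd)^2) per sample."""
        rng = np.random.default_rng(4)
        samples, _ = _tiny_tables()
        n = 2000
        prot = pd.DataFrame({"length_aa": 100, "is_puf": False, "annotation": ""},
                            index=pd.Index([f"P{i}" for i in range(n)], name="protein"))
        vals = rng.normal(25.0, 2.0, (n, 4))
        matrix = pd.DataFrame(vals, index=prot.index, columns=samples.index)
        miss = rng.random((n, 4)) < 0.15
        matrix = matrix.mask(miss)
        from pufgba.proteoquant import AbundanceStudy
        study = AbundanceStudy(matrix=matrix, samples=samples, proteins=prot,
                               scale="log2")
        out = impute_lod(study, QuantConfig(seed=0))
        for j, sid in enumerate(samples.index):
            obs = matrix[sid].dropna()
            mu, sd = obs.mean(), obs.std(ddof=1)
            imputed = out.matrix.loc[miss[:, j], sid]
            n_imp = len(imputed)
            assert n_imp >= 200
            se = 0.3 * sd / np.sqrt(n_imp)
            assert abs(imputed.mean() - (mu - 1.8 * sd)) < 3 * se


def test_full_chain_scale_progression(study_bundle):
    study = study_bundle["study"]
    assert study.scale == "imputed"
    assert not study.matrix.isna().any().any()
    # quantile property: complete samples have identical sorted values
    cols = study.matrix.columns[:2]
    a = np.sort(study.matrix[cols[0]].to_numpy())
    b = np.sort(study.matrix[cols[1]].to_numpy())
    n = min(len(a), len(b))
    # only strictly comparable when both samples were complete pre-imputation;
    # compare the central quantiles which are insensitive to tail imputation
    assert np.allclose(a[n // 4: n // 2], b[n // 4: n // 2], atol=0.35)
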