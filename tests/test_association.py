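"""Correlation screens, wobble-group aggregation, N-end rule and motif checks."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import codonlife as cl
from codonlife.codon_tables import GC_ENDING, standard_table


class TestPearson:
    def test_perfect_affine(self):
        x = np.arange(10.0)
        assert cl.pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert cl.pearson_r(x, -x) == pytest.approx(-1.0)

    def test_closed_form_hand_example(self):
        # deviations (-1.5,-0.5,.5,1.5)/( -1.5,.5,-.5,1.5): cov=1, var=1.25 each
        assert cl.pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_is_undefined(self):
        assert math.isnan(cl.pearson_r([1, 1, 1, 1], [1, 2, 3, 4]))

    def test_errors(self):
        with pytest.raises(ValueError):
            cl.pearson_r([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            cl.pearson_r([1, 2], [3, 4])

    def test_symmetry_and_affine_invariance(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert cl.pearson_r(x, y) == pytest.approx(cl.pearson_r(y, x))
        assert cl.pearson_r(3 * x + 7, y) == pytest.approx(cl.pearson_r(x, y))


class TestCorrelationProfile:
    def test_single_dataset_mean_and_sem(self, planted_features, planted_cohort):
        prof = cl.correlation_profile(planted_features,
                                      {"only": planted_cohort.responses["ds0"]})
        assert prof.n_datasets == 1
        assert (prof.sem_r == 0).all()
        r_direct = cl.pearson_r(planted_features.values["aa_A"],
                                planted_cohort.responses["ds0"])
        assert prof.mean_r["aa_A"] == pytest.approx(r_direct)

    def test_identical_datasets_zero_sem(self, planted_features, planted_cohort):
        y = planted_cohort.responses["ds0"]
        prof = cl.correlation_profile(planted_features, {"a": y, "b": y.copy()})
        assert np.allclose(prof.sem_r, 0)

    def test_planted_signs_recovered(self, planted_features, planted_cohort):
        # wobble effect: +delta on G/C-ending codons, -delta on A/U-ending
        responses = {f"ds{i}": planted_cohort.responses[f"ds{i}"] for i in range(8)}
        prof = cl.correlation_profile(planted_features, responses)
        assert prof.mean_r["codon_GCC"] > 0 > prof.mean_r["codon_GCA"]

    def test_mean_within_range_and_bounds(self, planted_features, planted_cohort):
        responses = {f"ds{i}": planted_cohort.responses[f"ds{i}"] for i in range(8)}
        prof = cl.correlation_profile(planted_features, responses)
        valid = prof.per_dataset.dropna()
        assert ((valid >= -1) & (valid <= 1)).all().all()
        assert (prof.mean_r >= prof.per_dataset.min(axis=1) - 1e-12).all()
        assert (prof.mean_r <= prof.per_dataset.max(axis=1) + 1e-12).all()

    def test_small_overlap_dataset_skipped(self, planted_features, planted_cohort):
        tiny = planted_cohort.responses["ds0"].iloc[:2]
        with pytest.warns(UserWarning, match="skipped"):
            prof = cl.correlation_profile(
                planted_features,
                {"full": planted_cohort.responses["ds0"], "tiny": tiny})
        assert prof.n_datasets == 1


class TestWobbleSummary:
    def test_21_rows_with_sixfold_split(self, planted_features, planted_cohort):
        responses = {f"ds{i}": planted_cohort.responses[f"ds{i}"] for i in range(8)}
        prof = cl.correlation_profile(planted_features, responses)
        summary = cl.wobble_group_summary(prof)
        assert summary.table.shape[0] == 21
        for aa3 in ("Leu", "Arg", "Ser"):
            assert sum(ix.startswith(aa3) for ix in summary.table.index) == 2

    def test_flat_profile_gives_zero_differences(self):
        names = [f"codon_{c}" for c in standard_table().sense_codons]
        per_dataset = pd.DataFrame({"d1": 0.3, "d2": 0.3}, index=names)
        prof = cl.CorrelationProfile(per_dataset=per_dataset,
                                     mean_r=per_dataset.mean(axis=1),
                                     sem_r=per_dataset.std(axis=1), n_datasets=2)
        summary = cl.wobble_group_summary(prof)
        assert (summary.table["difference"] == 0).all()
        assert not (summary.table["p_value"] < 0.05).any()

    def test_planted_wobble_effect_all_21_subgroups(self, planted_features,
                                                    planted_cohort):
        responses = {f"ds{i}": planted_cohort.responses[f"ds{i}"] for i in range(8)}
        prof = cl.correlation_profile(planted_features, responses)
        summary = cl.wobble_group_summary(prof)
        assert summary.n_gc_greater == 21

    def test_class_means_match_brute_force_scan(self, planted_features, planted_cohort):
        table = standard_table()
        responses = {f"ds{i}": planted_cohort.responses[f"ds{i}"] for i in range(4)}
        prof = cl.correlation_profile(planted_features, responses)
        summary = cl.wobble_group_summary(prof)
        for name, members in table.synonymous_subgroups.items():
            gc = [c for c in members if table.wobble_class[c] == GC_ENDING]
            au = [c for c in members if c not in gc]
            expected_gc = np.mean([prof.per_dataset.loc[f"codon_{c}"].mean() for c in gc])
            expected_au = np.mean([prof.per_dataset.loc[f"codon_{c}"].mean() for c in au])
            assert summary.table.loc[name, "mean_r_gc"] == pytest.approx(expected_gc)
            assert summary.table.loc[name, "mean_r_au"] == pytest.approx(expected_au)

    def test_null_effect_gives_binomial_like_counts(self):
        # with no planted wobble effect the GC>AU direction is a coin flip per
        # subgroup: the mean count over seeds should sit near 21/2
        counts = []
        for seed in range(6):
            config = cl.SyntheticConfig(n_proteins=250, length_range=(40, 120),
                                        seed=seed, effect_map={}, replicate_r=0.5)
            cohort = cl.generate_cds_cohort(config)
            cl.plant_replicates(cohort, config, [f"d{i}" for i in range(4)])
            fm = cl.assemble_feature_matrix(cohort.records)
            prof = cl.correlation_profile(fm, cohort.responses)
            counts.append(cl.wobble_group_summary(prof).n_gc_greater)
        assert 5 <= np.mean(counts) <= 16


class TestNEndRule:
    def test_response_equal_to_rule_gives_r2_one(self, small_cohort):
        rule = {aa: float(i) for i, aa in enumerate(standard_table().amino_acids)}
        response = pd.Series(
            {r.id: rule[r.protein[1]] for r in small_cohort.records})
        r2 = cl.nend_rule_association(small_cohort.records, response, rule)
        assert r2 == pytest.approx(1.0)

    def test_independent_response_near_zero(self, planted_cohort):
        rule = {aa: float(i) for i, aa in enumerate(standard_table().amino_acids)}
        r2 = cl.nend_rule_association(planted_cohort.records,
                                      planted_cohort.responses["ds0"], rule)
        assert r2 < 0.05

    def test_shuffled_map_changes_r2(self, small_cohort):
        aas = list(standard_table().amino_acids)
        identity = {aa: float(i) for i, aa in enumerate(aas)}
        shuffled = {aa: identity[aas[(i + 7) % 20]] for i, aa in enumerate(aas)}
        response = pd.Series({r.id: identity[r.protein[1]] for r in small_cohort.records})
        r2_id = cl.nend_rule_association(small_cohort.records, response, identity)
        r2_sh = cl.nend_rule_association(small_cohort.records, response, shuffled)
        assert r2_id != pytest.approx(r2_sh)

    def test_missing_residue_listed(self, small_cohort):
        with pytest.raises(ValueError, match="residues"):
            cl.nend_rule_association(small_cohort.records,
                                     pd.Series({r.id: 1.0 for r in small_cohort.records}),
                                     {"A": 1.0})


class TestMotifs:
    def test_planted_carrier_effect_detected(self, planted_cohort):
        carriers = np.array(["DEG" in r.protein for r in planted_cohort.records])
        assert 10 < carriers.sum() < len(carriers) - 10
        y = planted_cohort.responses["ds0"].copy()
        y.loc[[r.id for r, c in zip(planted_cohort.records, carriers) if c]] += \
            3 * y.std()
        table = cl.motif_association(planted_cohort.records, y, ["DEG"])
        assert table.loc["DEG", "r"] > 0
        assert table.loc["DEG", "p_adjusted"] < 0.05

    def test_constant_presence_is_undefined(self, small_cohort):
        y = small_cohort.responses["lifetime"]
        table = cl.motif_association(small_cohort.records, y,
                                     ["M", "WWWWWWWWWW"])  # all / no carriers
        assert math.isnan(table.loc["M", "r"])
        assert math.isnan(table.loc["WWWWWWWWWW", "r"])

    def test_empty_motif_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            cl.motif_association(small_cohort.records,
                                 small_cohort.responses["lifetime"], [""])


class TestCrossParameterMatrix:
    def test_structure(self, planted_cohort):
        responses = {k: planted_cohort.responses[k] for k in ("ds0", "ds1", "ds2")}
        m = cl.cross_parameter_matrix(responses)
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)

    def test_independent_responses_near_zero(self, planted_cohort, planted_config,
                                             rng):
        y = planted_cohort.responses["ds0"]
        noise = pd.Series(rng.normal(size=len(y)), index=y.index)
        m = cl.cross_parameter_matrix({"a": y, "b": noise})
        assert m.loc["a", "b"] < 0.01

    def test_replicate_pair_r2_matches_squared_target(self, planted_cohort):
        m = cl.cross_parameter_matrix({k: planted_cohort.responses[k]
                                       for k in ("ds0", "ds1")})
        assert m.loc["ds0", "ds1"] == pytest.approx(0.69 ** 2, abs=0.05)
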