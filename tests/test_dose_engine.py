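import numpy as np
import pandas as pd
import pytest

from mirdpk import reference
from mirdpk.dose_engine import (
    DOSE_SOURCES,
    ICRP26_WEIGHTS,
    ICRP60_WEIGHTS,
    SValueSet,
    build_svalue_set,
    compute_doses,
    effective_dose,
    effective_dose_equivalent,
    load_svalue_set,
    summarize_doses,
)


def tiny_svalue_set():
    S = pd.DataFrame(0.0, index=["spleen", "liver"], columns=list(DOSE_SOURCES))
    S.loc["spleen", "spleen"] = 0.1
    S.loc["liver", "liver"] = 0.05
    return SValueSet("Cu-64", "male", S, "test")


class TestComputeDoses:
    def test_single_source_diagonal(self):
        doses = compute_doses({"spleen": 1.0}, tiny_svalue_set())
        assert doses["spleen"] == pytest.approx(0.1)
        assert doses["liver"] == 0.0

    def test_linearity_in_residence_times(self):
        svals = load_svalue_set("male")
        tau = {s: 0.5 for s in DOSE_SOURCES}
        d1 = compute_doses(tau, svals)
        d2 = compute_doses({s: 1.0 for s in DOSE_SOURCES}, svals)
        for organ in d1:
            assert d2[organ] == pytest.approx(2 * d1[organ], rel=1e-12)

    def test_source_permutation_invariance(self):
        svals = load_svalue_set("female")
        tau = {s: t for s, t in zip(DOSE_SOURCES, [1.0, 0.2, 0.1, 4.7, 0.07, 0.2, 8.9])}
        permuted = dict(reversed(list(tau.items())))
        assert compute_doses(tau, svals) == compute_doses(permuted, svals)

    def test_matches_explicit_loop_oracle(self, rng):
        svals = load_svalue_set("male")
        for _ in range(20):
            tau = {s: float(rng.uniform(0, 5)) for s in DOSE_SOURCES}
            doses = compute_doses(tau, svals)
            for organ in svals.S.index:
                expected = sum(tau[s] * svals.S.loc[organ, s] for s in DOSE_SOURCES)
                assert doses[organ] == pytest.approx(expected, abs=1e-12, rel=1e-12)

    def test_unknown_source_rejected(self):
        with pytest.raises(KeyError):
            compute_doses({"excreted": 1.0}, tiny_svalue_set())

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            compute_doses({"spleen": -1.0}, tiny_svalue_set())


class TestSValueResources:
    @pytest.mark.parametrize("sex", ["male", "female"])
    def test_packaged_csv_matches_generator(self, sex):
        packaged = load_svalue_set(sex)
        built = build_svalue_set(sex)
        pd.testing.assert_frame_equal(packaged.S, built.S, check_exact=False, rtol=1e-12)

    @pytest.mark.parametrize("sex", ["male", "female"])
    def test_matrix_invariants(self, sex):
        svals = load_svalue_set(sex)
        assert (svals.S.values >= 0).all()
        assert set(DOSE_SOURCES) <= set(svals.S.columns)
        # self-dose dominates cross-fire for solid source organs
        for organ in ("liver", "spleen", "kidneys"):
            assert svals.S.loc[organ, organ] > 10 * svals.S.drop(index=organ)[organ].max()

    def test_sex_specific_targets(self):
        assert "testes" in load_svalue_set("male").S.index
        assert "uterus" not in load_svalue_set("male").S.index
        assert "ovaries" in load_svalue_set("female").S.index


class TestEffectiveDose:
    def test_uniform_doses_collapse_to_the_weighted_sum(self):
        svals = load_svalue_set("female")
        doses = {organ: 0.02 for organ in svals.S.index}
        assert effective_dose(doses, "female") == pytest.approx(0.02, rel=1e-12)
        assert effective_dose_equivalent(doses, "female") == pytest.approx(0.02, rel=1e-12)

    def test_single_nonzero_organ(self):
        svals = load_svalue_set("male")
        doses = {organ: 0.0 for organ in svals.S.index}
        doses["liver"] = 0.1
        assert effective_dose(doses, "male") == pytest.approx(0.05 * 0.1, rel=1e-12)

    def test_weight_normalisation(self):
        for scheme in (ICRP60_WEIGHTS, ICRP26_WEIGHTS):
            assert sum(scheme.w.values()) + scheme.remainder_weight == pytest.approx(1.0)

    def test_effective_dose_between_min_and_max_organ_dose(self):
        for pid, doses in reference.doses_from_printed_taus().items():
            organ_doses = {o: d for o, d in doses.items() if o != "total_body"}
            ed = effective_dose(organ_doses, reference.dose_table_sexes()[pid])
            ede = effective_dose_equivalent(organ_doses, reference.dose_table_sexes()[pid])
            assert min(organ_doses.values()) <= ed <= max(organ_doses.values())
            assert min(organ_doses.values()) <= ede <= max(organ_doses.values())


class TestSummaries:
    def test_printed_spleen_and_liver_rows_reproduce_printed_averages(self):
        summary = reference.dose_summary()
        assert round(summary.loc["spleen", "average"], 3) == 0.142
        assert round(summary.loc["liver", "average"], 3) == 0.052

    def test_sex_stratified_means(self):
        summary = reference.dose_summary()
        assert round(summary.loc["spleen", "m_average"], 3) == 0.144
        assert round(summary.loc["spleen", "f_average"], 3) == 0.138

    def test_identical_values_have_zero_sd(self):
        tables = {"A": {"spleen": 0.1}, "B": {"spleen": 0.1}}
        s = summarize_doses(tables, {"A": "male", "B": "male"})
        assert s.loc["spleen", "sd"] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_doses({}, {})


class TestRankProperties:
    def test_spleen_tops_most_participants(self):
        """Spleen is the highest-dosed parenchymal organ for most of the cohort."""
        assert reference.spleen_rank_count() >= 7

    def test_red_marrow_in_top_two_for_most_participants(self):
        count = sum(
            "red_marrow" in reference.organ_rank(d)[:2]
            for d in reference.doses_from_printed_taus().values()
        )
        assert count >= 7
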