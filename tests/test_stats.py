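"""IS assignment, normalization, t-test screening and the significance rule."""

import math

import numpy as np
import pytest
from scipy.special import stdtr

from bileprof.stats import (
    StudyDesign,
    assign_internal_standard,
    differential_test,
    is_significant,
    normalize,
    summarize_profile,
)

# Published-style isomer-screen p-values (22 entries, same order as the table)
TABLE1_P_VALUES = [
    0.0082, 0.032, 0.015, 0.027, 0.028, 0.0018, 0.035, 0.010, 0.018, 0.013,
    0.031, 0.014, 0.043, 0.0057, 0.0078, 0.036, 0.021, 0.043, 0.0026, 0.031,
    0.030, 0.010,
]
# Published-style sulfate-conjugate (p, fold change) pairs (9 entries)
TABLE2_P_FC = [
    (0.035, 20.7), (0.025, 8.2), (0.000085, 5.9), (0.00025, 8.5), (0.0015, 6.3),
    (0.0026, 6.9), (0.0017, 6.5), (0.013, 8.3), (0.013, 14.0),
]


def _oracle_student_t(lo, hi):
    """Independent pooled-variance t-test: textbook formula + t CDF."""
    lo, hi = np.asarray(lo, float), np.asarray(hi, float)
    n1, n2 = len(hi), len(lo)
    sp2 = ((n1 - 1) * hi.var(ddof=1) + (n2 - 1) * lo.var(ddof=1)) / (n1 + n2 - 2)
    t = (hi.mean() - lo.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2.0 * (1.0 - stdtr(df, abs(t)))
    return t, p


class TestAssignInternalStandard:
    def test_labeled_analog_outranks_everything(self, library):
        chosen = assign_internal_standard("GCA", "glycine", 10.2, library.internal_standards)
        assert chosen.name == "d4-GCA"

    def test_same_class_nearest_rt(self, library):
        # unconjugated target at 25.3 min: d4-DCA (24.3) is the nearest
        # unconjugated IS (d4-CDCA 23.3, d4-LCA 34.5)
        chosen = assign_internal_standard(None, "unconjugated", 25.3, library.internal_standards)
        assert chosen.name == "d4-DCA"

    def test_fallback_to_global_nearest_rt(self, library):
        taurine_only = [e for e in library.internal_standards if e.conjugation_class == "taurine"]
        chosen = assign_internal_standard(None, "glycine", 14.0, taurine_only)
        assert chosen.name == "d6-TDCA"  # reference RT 14.1

    def test_empty_is_library_rejected(self):
        with pytest.raises(ValueError):
            assign_internal_standard("GCA", "glycine", 10.0, [])


class TestNormalize:
    def test_simple_ratio(self):
        ratios, flagged = normalize({"S1": 2000.0}, {"S1": 1000.0})
        assert ratios == {"S1": 2.0}
        assert flagged == []

    def test_missing_is_flagged(self):
        ratios, flagged = normalize({"S1": 2000.0, "S2": 1500.0}, {"S1": 1000.0})
        assert ratios == {"S1": 2.0}
        assert flagged == ["S2"]


class TestDifferentialTest:
    def test_identical_groups(self):
        r = differential_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert r.p_value == 1.0
        assert r.fold_change == 1.0
        assert not r.significant

    def test_textbook_sixfold_case(self):
        r = differential_test([1.0, 1.1, 0.9], [6.0, 6.6, 5.4])
        assert r.fold_change == pytest.approx(6.0, abs=1e-12)
        assert r.t_stat == pytest.approx(14.2374, abs=1e-4)
        assert r.p_value == pytest.approx(1.413455e-4, rel=1e-5)
        assert r.significant

    def test_swapping_groups_inverts_fc_and_keeps_p(self):
        rng = np.random.default_rng(5)
        lo, hi = rng.lognormal(0, 0.2, 3), rng.lognormal(1, 0.2, 3)
        fwd = differential_test(lo, hi)
        rev = differential_test(hi, lo)
        assert rev.fold_change == pytest.approx(1.0 / fwd.fold_change, abs=1e-12)
        assert rev.p_value == pytest.approx(fwd.p_value, abs=1e-12)

    def test_p_values_match_independent_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n1, n2 = rng.integers(2, 9, size=2)
            lo = rng.lognormal(0, 0.3, n2)
            hi = rng.lognormal(rng.normal(0, 1), 0.3, n1)
            r = differential_test(lo, hi)
            t_ref, p_ref = _oracle_student_t(lo, hi)
            assert r.p_value == pytest.approx(p_ref, abs=1e-9)
            assert r.t_stat == pytest.approx(t_ref, abs=1e-9)

    def test_zero_baseline_flags_undefined_fc(self):
        r = differential_test([0.0, 0.0, 0.0], [1.0, 1.2, 0.8])
        assert math.isnan(r.fold_change)
        assert "fc_undefined" in r.flags
        assert not r.significant

    def test_requires_two_ratios_per_side(self):
        with pytest.raises(ValueError):
            differential_test([1.0], [2.0, 2.1])

    def test_welch_flag_changes_degenerate_variance_case(self):
        lo, hi = [1.0, 1.01, 0.99], [5.0, 9.0, 2.0]
        student = differential_test(lo, hi, equal_var=True)
        welch = differential_test(lo, hi, equal_var=False)
        assert student.p_value != welch.p_value


class TestSignificanceRule:
    def test_published_isomer_table_has_five_below_0p01(self):
        assert sum(p < 0.01 for p in TABLE1_P_VALUES) == 5

    def test_published_sulfate_table_all_significant(self):
        assert all(is_significant(p, fc) for p, fc in TABLE2_P_FC)

    def test_rule_requires_both_conditions(self):
        assert not is_significant(0.2, 10.0)
        assert not is_significant(0.001, 1.5)
        assert not is_significant(0.001, 0.2)
        assert is_significant(0.001, 0.2, direction_agnostic=True)


class TestStudyDesign:
    def test_duplicate_samples_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign({"75": ("a", "b"), "600": ("b", "c")})

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign({"75": ("a",), "600": ("b", "c")})

    def test_csv_roundtrip(self, tmp_path):
        path = tmp_path / "design.csv"
        path.write_text("sample_id,group\na,75\nb,75\nc,600\nd,600\n")
        design = StudyDesign.from_csv(path)
        assert design.groups == {"75": ("a", "b"), "600": ("c", "d")}


def test_summarize_profile_counts(pipeline_result):
    counts = summarize_profile(pipeline_result.results)
    assert counts["identified"] == 13
    assert counts["isomer"] == 22
    assert counts["conjugate_tentative"] == 9
    assert counts["sulfate_conjugates"] == 9
    assert counts["glucuronide_conjugates"] == 0


def test_summarize_profile_empty():
    counts = summarize_profile([])
    assert all(v == 0 for v in counts.values())
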