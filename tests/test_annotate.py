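"""Tiered library annotation: target list, assignment, isomer grouping."""

import pytest

from bileprof.annotate import (
    Feature,
    annotate_features,
    build_target_list,
    group_isomers,
    read_feature_csv,
)
from bileprof.chem import mz_mh_minus, parse_formula

# Seven published-style keto-DCA isomer retention times (C24H38O5)
KETO_DCA_ISOMER_RTS = [10.2, 15.3, 15.8, 17.8, 18.5, 20.2, 23.0]


@pytest.fixture(scope="module")
def targets(library):
    return build_target_list(library)


def _feature(mz, rt, sample="S1", fid="F1", area=1000.0):
    return Feature(sample_id=sample, mz=mz, rt=rt, area=area, feature_id=fid)


class TestBuildTargetList:
    def test_analyte_and_conjugate_counts(self, library, targets):
        analytes = [t for t in targets if t.kind == "analyte"]
        conjugates = [t for t in targets if t.kind == "conjugate"]
        assert len(analytes) == 46
        # one per analyte x {sulfation, glucuronidation}, collapsed by formula
        assert len(conjugates) <= 92
        assert len({(str(t.formula), t.delta_name) for t in conjugates}) == len(conjugates)

    def test_cdca_sulfate_target_mz(self, targets):
        sulf = [t for t in targets if str(t.formula) == "C24H40O7S"]
        assert len(sulf) == 1
        assert sulf[0].mz == pytest.approx(471.2422, abs=5e-4)
        assert sulf[0].name == "CDCA+SO3"  # lexicographically first parent
        assert set(sulf[0].members) >= {"CDCA", "DCA", "UDCA", "HDCA"}

    def test_empty_delta_list_gives_only_analytes(self, library):
        targets = build_target_list(library, deltas=())
        assert len(targets) == 46
        assert all(t.kind == "analyte" for t in targets)


class TestAnnotateFeatures:
    def test_identified_within_both_tolerances(self, library, targets):
        gca = library["GCA"]
        f = _feature(gca.mz * (1 + 3e-6), gca.reference_rt + 0.02)
        (a,) = annotate_features([f], targets)
        assert a.tier == "identified"
        assert a.target_name == "GCA"
        assert a.ppm == pytest.approx(3.0, abs=0.01)
        assert a.delta_rt == pytest.approx(0.02, abs=1e-9)

    def test_isomer_when_rt_disagrees(self, targets):
        # a C24H40O4 formula match far from every library RT of that formula
        f = _feature(mz_mh_minus("C24H40O4"), 25.3)
        (a,) = annotate_features([f], targets)
        assert a.tier == "isomer"
        assert a.target_formula == parse_formula("C24H40O4")
        assert a.target_name.endswith(" isomer")

    def test_conjugate_tier_by_mass_shift(self, targets):
        f = _feature(471.2412, 21.6)  # CDCA+SO3 observed ion
        (a,) = annotate_features([f], targets)
        assert a.tier == "conjugate_tentative"
        assert a.delta_name == "sulfation"
        assert a.ppm == pytest.approx(-2.1, abs=0.05)

    def test_outside_tolerance_unassigned(self, targets):
        f = _feature(mz_mh_minus("C24H40O4") * (1 + 11e-6), 25.3)
        (a,) = annotate_features([f], targets, ppm_tol=10.0)
        assert a.tier == "unassigned"
        assert a.target_name is None

    def test_same_formula_exemplar_chosen_by_rt(self, library, targets):
        # CDCA (23.3) and DCA (24.3) share C24H40O4; RT picks the exemplar
        mz = mz_mh_minus("C24H40O4")
        a_cdca, a_dca = annotate_features(
            [_feature(mz, 23.25, fid="F1"), _feature(mz, 24.35, fid="F2")], targets
        )
        assert {a_cdca.target_name, a_dca.target_name} == {"CDCA", "DCA"}

    def test_monotone_in_ppm_tolerance(self, study, targets):
        feats = study.feature_objects()[:300]
        counts = []
        for tol in (10.0, 5.0, 2.0, 1.0):
            anns = annotate_features(feats, targets, ppm_tol=tol)
            counts.append(sum(a.tier != "unassigned" for a in anns))
        assert counts == sorted(counts, reverse=True)

    def test_deterministic_for_any_input_order(self, targets):
        mz = mz_mh_minus("C24H38O5")
        feats = [_feature(mz, rt, fid=f"F{i}") for i, rt in enumerate(KETO_DCA_ISOMER_RTS)]
        forward = annotate_features(feats, targets)
        backward = annotate_features(list(reversed(feats)), targets)
        assert [a.feature.feature_id for a in forward] == [
            a.feature.feature_id for a in backward
        ]


class TestGroupIsomers:
    def test_keto_dca_isomer_group(self, targets):
        mz = mz_mh_minus("C24H38O5")
        feats = [_feature(mz, rt, fid=f"F{i}") for i, rt in enumerate(KETO_DCA_ISOMER_RTS)]
        groups = group_isomers(annotate_features(feats, targets))
        assert list(groups) == ["C24H38O5"]
        members = groups["C24H38O5"]
        assert len(members) == 7
        assert [a.feature.rt for a in members] == sorted(KETO_DCA_ISOMER_RTS)

    def test_single_member_group(self, targets):
        (a,) = annotate_features([_feature(mz_mh_minus("C24H40O4"), 25.3)], targets)
        groups = group_isomers([a])
        assert groups == {"C24H40O4": [a]}

    def test_equal_rt_tiebreak_by_feature_id(self, targets):
        mz = mz_mh_minus("C24H40O4")
        feats = [_feature(mz, 25.3, fid="F2"), _feature(mz, 25.3, fid="F1")]
        groups = group_isomers(annotate_features(feats, targets))
        assert [a.feature.feature_id for a in groups["C24H40O4"]] == ["F1", "F2"]


class TestFeatureIO:
    def test_reads_and_validates(self, tmp_path):
        path = tmp_path / "features.csv"
        path.write_text(
            "sample_id,mz,rt_min,area,feature_id\nS1,400.1,10.0,1000,F1\nS1,401.2,11.0,500,F2\n"
        )
        feats = read_feature_csv(path)
        assert len(feats) == 2
        assert feats[0].mz == 400.1

    def test_rejects_missing_columns_and_bad_rows(self, tmp_path):
        bad_cols = tmp_path / "cols.csv"
        bad_cols.write_text("sample_id,mz\nS1,400.1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_feature_csv(bad_cols)
        bad_row = tmp_path / "row.csv"
        bad_row.write_text("sample_id,mz,rt_min,area\nS1,-5.0,10.0,100\n")
        with pytest.raises(ValueError, match="row 2"):
            read_feature_csv(bad_row)
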