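import numpy as np
import pytest
from hypothesis import given, strategies as st

from histonet.metafeatures import (
    DEFAULT_FEATURES,
    absolute_areas,
    build_feature_table,
    cd45_fraction,
    compute_metafeatures,
    isotype_delta,
    relative_areas,
    tissue_area,
)
from histonet.palette import BGR, MAIN_CLASSES, NEC, TAR, TUM
from histonet.synthetic_data import SMTCohort, CohortSample, synth_smt_cohort


class TestAbsoluteAreas:
    def test_two_by_two_map(self):
        f = absolute_areas(np.array([[TUM, TUM], [NEC, BGR]]))
        assert f.tolist() == [2, 0, 1, 0, 0, 0, 0, 1]

    def test_conservation(self, rng):
        labels = rng.integers(0, 8, (17, 23))
        f = absolute_areas(labels)
        assert f.sum() == labels.size

    def test_matches_naive_loop(self, rng):
        labels = rng.integers(0, 8, (64, 64))
        f = absolute_areas(labels)
        loop = np.zeros(8, dtype=int)
        for v in labels.ravel():
            loop[v] += 1
        assert (f == loop).all()

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            absolute_areas(np.array([[8]]))


class TestTissueArea:
    def test_background_excluded(self):
        f = np.array([2, 0, 1, 0, 0, 0, 0, 1])
        assert tissue_area(f) == 3

    def test_artifact_and_background_only_gives_zero(self):
        f = np.zeros(8, dtype=int)
        f[TAR] = 10
        f[BGR] = 20
        assert tissue_area(f) == 0

    def test_identity_with_pixel_count(self, rng):
        labels = rng.integers(0, 8, (32, 32))
        f = absolute_areas(labels)
        assert tissue_area(f) == labels.size - f[TAR] - f[BGR]


class TestRelativeAreas:
    def test_example_fractions(self):
        f = np.array([2, 0, 1, 0, 0, 0, 0, 1])
        rel = relative_areas(f)
        assert rel[TUM] == pytest.approx(2 / 3)
        assert rel[NEC] == pytest.approx(1 / 3)
        assert np.isnan(rel[BGR])  # excluded from the tissue simplex

    def test_single_class_tumor_map(self):
        rel = relative_areas(absolute_areas(np.full((4, 4), TUM)))
        assert rel[TUM] == 1.0

    def test_zero_area_flags_undefined(self):
        rel = relative_areas(absolute_areas(np.full((4, 4), BGR)))
        assert np.isnan(rel).all()

    @given(st.integers(0, 10_000))
    def test_main_class_fractions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 8, (12, 12))
        f = absolute_areas(labels)
        rel = relative_areas(f)
        if tissue_area(f) > 0:
            assert np.nansum(rel[list(MAIN_CLASSES)]) == pytest.approx(1.0)


class TestIsotypeDelta:
    def test_isotype_against_itself_is_zero(self, rng):
        labels = rng.integers(0, 8, (16, 16))
        feats = compute_metafeatures(labels, cd45_fraction_value=0.2)
        for which in ("TUM", "NEC", "MST", "area", "cd45"):
            assert isotype_delta(feats, feats, which, "abs") == 0.0
        for which in ("TUM", "NEC"):
            assert isotype_delta(feats, feats, which, "rel") == 0.0

    def test_area_delta(self):
        a = compute_metafeatures(np.full((10, 12), TUM))
        b = compute_metafeatures(np.full((10, 10), TUM))
        assert isotype_delta(a, b, "area") == 20.0

    @given(st.integers(0, 10_000))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        fa = compute_metafeatures(rng.integers(0, 8, (8, 8)))
        fb = compute_metafeatures(rng.integers(0, 8, (8, 8)))
        for which, mode in (("TUM", "abs"), ("NEC", "abs"), ("area", "abs")):
            d1 = isotype_delta(fa, fb, which, mode)
            d2 = isotype_delta(fb, fa, which, mode)
            assert d1 == pytest.approx(-d2)

    def test_undefined_operand_propagates_nan(self):
        defined = compute_metafeatures(np.full((4, 4), TUM))
        undefined = compute_metafeatures(np.full((4, 4), BGR))
        assert np.isnan(isotype_delta(defined, undefined, "TUM", "rel"))


class TestCD45Fraction:
    def test_definition(self):
        pos = np.zeros((20, 20))
        pos[:5, :10] = 1.0  # 50 positive pixels
        cs = np.zeros((20, 20))
        cs[:10, :] = 1.0  # 200 counterstain pixels
        assert cd45_fraction(pos, cs, positive_threshold=0.5, counterstain_threshold=0.5) == 0.25

    def test_no_positive_pixels_gives_zero(self):
        cs = np.zeros((10, 10))
        cs[:5] = 1.0
        assert cd45_fraction(np.zeros((10, 10)), cs, positive_threshold=0.5, counterstain_threshold=0.5) == 0.0

    def test_no_counterstain_gives_nan(self):
        assert np.isnan(
            cd45_fraction(np.ones((5, 5)), np.zeros((5, 5)), positive_threshold=0.5, counterstain_threshold=0.5)
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cd45_fraction(np.zeros((4, 4)), np.zeros((5, 5)))


class TestScaleCovariance:
    def test_2x_upsampling_quadruples_absolute_leaves_relative(self, rng):
        labels = rng.integers(0, 8, (16, 16))
        up = np.kron(labels, np.ones((2, 2), dtype=int))
        f1, f2 = absolute_areas(labels), absolute_areas(up)
        assert (f2 == 4 * f1).all()
        assert tissue_area(f2) == 4 * tissue_area(f1)
        r1, r2 = relative_areas(f1), relative_areas(f2)
        assert np.allclose(r1[list(MAIN_CLASSES)], r2[list(MAIN_CLASSES)], equal_nan=True)


@pytest.fixture(scope="module")
def cohort():
    return synth_smt_cohort(4, effect=1.0, seed=11, map_shape=(32, 32), cd45_shape=(32, 32))


class TestFeatureTable:
    def test_rows_are_treated_samples_only(self, cohort):
        table, labels = build_feature_table(cohort)
        assert len(table) == 12  # 4 models x 3 treated arms
        assert list(table.columns) == list(DEFAULT_FEATURES)
        assert set(labels.unique()) <= {"responder", "non_responder"}

    def test_values_match_per_sample_recomputation(self, cohort):
        from histonet.metafeatures import _cd45_fraction_from_image

        table, _ = build_feature_table(cohort)
        sample = cohort.treated()[0]
        iso = cohort.isotype_of(sample.model_id)
        feats = compute_metafeatures(
            sample.tissue_map, _cd45_fraction_from_image(sample.cd45.image)
        )
        iso_feats = compute_metafeatures(
            iso.tissue_map, _cd45_fraction_from_image(iso.cd45.image)
        )
        row = table.iloc[0]
        assert row["abs_TUM"] == feats.value("TUM", "abs")
        assert row["rel_TUM"] == pytest.approx(feats.value("TUM", "rel"))
        assert row["d_rel_NEC"] == pytest.approx(
            isotype_delta(feats, iso_feats, "NEC", "rel")
        )
        assert row["d_area"] == pytest.approx(isotype_delta(feats, iso_feats, "area"))

    def test_identical_samples_have_zero_deltas(self):
        base = synth_smt_cohort(2, effect=0.0, seed=1, map_shape=(24, 24), cd45_shape=(24, 24))
        clones = []
        for s in base.samples:
            iso = base.isotype_of(s.model_id)
            clones.append(
                CohortSample(s.model_id, s.treatment, s.response, iso.tissue_map, iso.cd45)
            )
        cohort = SMTCohort(clones)
        table, _ = build_feature_table(cohort)
        for col in table.columns:
            if col.startswith("d_"):
                assert np.allclose(table[col], 0.0)

    def test_missing_isotype_names_model(self, cohort):
        broken = SMTCohort.__new__(SMTCohort)
        broken.samples = [s for s in cohort.samples if s.treatment != "isotype"]
        with pytest.raises(ValueError, match="M01"):
            build_feature_table(broken)

    def test_unknown_response_excluded(self, cohort):
        modified = [
            CohortSample(s.model_id, s.treatment, "unknown", s.tissue_map, s.cd45)
            if (s.treatment == "antiPDL1" and s.model_id == "M01")
            else s
            for s in cohort.samples
        ]
        table, _ = build_feature_table(SMTCohort(modified))
        assert len(table) == 11
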