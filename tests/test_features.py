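"""Feature computations checked against independent naive-loop oracles."""

import numpy as np
import pytest

from pressurepose.features import (
    FeatureDescriptor,
    FeatureExtractor,
    UndefinedFeatureError,
    area_statistics,
    center_of_pressure,
    compute_features,
    contact_area_proportion,
    enumerate_feature_set,
    pressure_ratio,
    read_manifest,
    relative_features,
    write_manifest,
)
from pressurepose.pressuremap import MatGeometry, PressureFrame

# ---------------------------------------------------------------------------
# naive oracles (independent of the vectorized implementation)


def naive_cop(frame, mask):
    sx = sy = sp = 0.0
    cs = frame.geometry.cell_size
    for r in range(frame.geometry.n_rows):
        for c in range(frame.geometry.n_cols):
            if mask[r, c]:
                p = frame.values[r, c]
                sp += p
                sx += p * c * cs
                sy += p * r * cs
    return sx / sp, sy / sp


def naive_contact(frame, mask, threshold):
    hits = total = 0
    for r in range(frame.geometry.n_rows):
        for c in range(frame.geometry.n_cols):
            if mask[r, c]:
                total += 1
                if frame.values[r, c] > threshold:
                    hits += 1
    return hits / total


def naive_ratio(frame, mask_a, mask_b):
    a = sum(
        frame.values[r, c]
        for r in range(frame.geometry.n_rows)
        for c in range(frame.geometry.n_cols)
        if mask_a[r, c]
    )
    b = sum(
        frame.values[r, c]
        for r in range(frame.geometry.n_rows)
        for c in range(frame.geometry.n_cols)
        if mask_b[r, c]
    )
    return a / (a + b)


def naive_stats(frame, mask):
    vals = [
        frame.values[r, c]
        for r in range(frame.geometry.n_rows)
        for c in range(frame.geometry.n_cols)
        if mask[r, c]
    ]
    return (
        sum(vals) / len(vals),
        max(vals),
        sum(vals) * frame.geometry.cell_area,
    )


def small_geometry(side="backrest", n=6):
    return MatGeometry(side, n, n, 1.0)


def test_cop_single_cell_and_uniform_rectangle():
    geo = small_geometry()
    v = np.zeros((6, 6))
    v[2, 4] = 5.0
    assert center_of_pressure(PressureFrame(geo, v), np.ones((6, 6), bool)) == (4.0, 2.0)
    rect = np.zeros((6, 6), bool)
    rect[1:4, 2:6] = True
    uniform = PressureFrame(geo, np.ones((6, 6)))
    x, y = center_of_pressure(uniform, rect)
    assert (x, y) == pytest.approx(((2 + 5) / 2, (1 + 3) / 2))


def test_cop_zero_load_is_undefined():
    geo = small_geometry()
    with pytest.raises(UndefinedFeatureError):
        center_of_pressure(PressureFrame(geo, np.zeros((6, 6))), np.ones((6, 6), bool))


def test_contact_proportion_examples(rng):
    geo = small_geometry()
    frame = PressureFrame(geo, rng.random((6, 6)) + 0.5)
    assert contact_area_proportion(frame, np.ones((6, 6), bool), 0.0) == 1.0
    zero = PressureFrame(geo, np.zeros((6, 6)))
    assert contact_area_proportion(zero, np.ones((6, 6), bool), 0.0) == 0.0
    # 10-cell mask with exactly 3 cells above threshold
    mask = np.zeros((6, 6), bool)
    mask.ravel()[:10] = True
    v = np.zeros((6, 6))
    v.ravel()[:3] = 2.0
    assert contact_area_proportion(PressureFrame(geo, v), mask, 1.0) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        contact_area_proportion(frame, mask, -0.5)


def test_pressure_ratio_examples():
    geo = small_geometry()
    a = np.zeros((6, 6), bool)
    b = np.zeros((6, 6), bool)
    a[:, :3] = True
    b[:, 3:] = True
    v = np.zeros((6, 6))
    v[0, 0] = 3.0
    v[0, 5] = 1.0
    frame = PressureFrame(geo, v)
    assert pressure_ratio(frame, a, b) == pytest.approx(0.75)
    assert pressure_ratio(PressureFrame(geo, np.ones((6, 6))), a, b) == pytest.approx(0.5)
    only_a = np.zeros((6, 6))
    only_a[1, 1] = 2.0
    assert pressure_ratio(PressureFrame(geo, only_a), a, b) == 1.0
    with pytest.raises(ValueError, match="disjoint"):
        pressure_ratio(frame, a, a)
    with pytest.raises(UndefinedFeatureError):
        pressure_ratio(PressureFrame(geo, np.zeros((6, 6))), a, b)


def test_area_statistics_constant_and_spike():
    geo = small_geometry()
    mask = np.zeros((6, 6), bool)
    mask[:2, :3] = True
    mean, peak, total = area_statistics(PressureFrame(geo, np.full((6, 6), 2.0)), mask)
    assert (mean, peak) == (2.0, 2.0)
    assert total == pytest.approx(2.0 * 6 * geo.cell_area)
    spike = np.zeros((6, 6))
    spike[1, 1] = 9.0
    assert area_statistics(PressureFrame(geo, spike), mask)[1] == 9.0


@pytest.mark.parametrize("trial", range(10))
def test_elementary_ops_match_naive_loops(trial):
    rng = np.random.default_rng(100 + trial)
    geo = small_geometry(n=6)
    frame = PressureFrame(geo, rng.random((6, 6)))
    mask = rng.random((6, 6)) < 0.6
    mask[0, 0] = True  # never empty
    other = ~mask
    assert center_of_pressure(frame, mask) == pytest.approx(naive_cop(frame, mask), rel=1e-9)
    thr = float(rng.uniform(0, 1))
    assert contact_area_proportion(frame, mask, thr) == pytest.approx(
        naive_contact(frame, mask, thr), rel=1e-9
    )
    assert pressure_ratio(frame, mask, other) == pytest.approx(
        naive_ratio(frame, mask, other), rel=1e-9
    )
    assert area_statistics(frame, mask) == pytest.approx(naive_stats(frame, mask), rel=1e-9)


class TestEnumeration:
    def test_exactly_200_candidates(self, backrest_scheme, seatpan_scheme):
        descriptors = enumerate_feature_set(backrest_scheme, seatpan_scheme)
        assert len(descriptors) == 200

    def test_names_unique_and_areas_resolvable(self, backrest_scheme, seatpan_scheme):
        descriptors = enumerate_feature_set(backrest_scheme, seatpan_scheme)
        names = [d.name for d in descriptors]
        assert len(set(names)) == len(names)
        schemes = {"backrest": backrest_scheme, "seatpan": seatpan_scheme}
        for d in descriptors:
            scheme = schemes[d.side]
            assert scheme.area_mask(d.area).any()
            if d.area2 is not None:
                assert scheme.area_mask(d.area2).any()
                assert not (scheme.area_mask(d.area) & scheme.area_mask(d.area2)).any()

    def test_manifest_round_trip(self, tmp_path, backrest_scheme, seatpan_scheme):
        descriptors = enumerate_feature_set(backrest_scheme, seatpan_scheme)
        path = tmp_path / "manifest.tsv"
        write_manifest(descriptors, path)
        assert read_manifest(path) == descriptors


class TestComputeFeatures:
    def test_all_zero_frames_take_sentinel_replacements(self, extractor):
        b = np.zeros((42, 44))
        s = np.zeros((42, 44))
        fv = extractor.compute(
            PressureFrame(MatGeometry.backrest(), b),
            PressureFrame(MatGeometry.seatpan(), s),
        )
        for d, v in zip(fv.descriptors, fv.values):
            if d.kind == "pressure_ratio":
                assert v == 0.5
            elif d.kind in ("cop_x", "cop_y"):
                assert np.isfinite(v)  # geometric center of the area
            else:
                assert v == 0.0

    def test_zero_load_cop_is_area_geometric_center(self, extractor):
        fv = extractor.compute(
            PressureFrame(MatGeometry.backrest(), np.zeros((42, 44))),
            PressureFrame(MatGeometry.seatpan(), np.zeros((42, 44))),
        )
        by_name = dict(zip(fv.names, fv.values))
        # global CoP x of a 44-column mat: center at (43/2) * 1.27 cm
        assert by_name["B_cop_x"] == pytest.approx(43 / 2 * 1.27)
        assert by_name["B_cop_y"] == pytest.approx(41 / 2 * 1.27)

    def test_homogeneity_under_pressure_doubling(self, extractor, rng):
        b = rng.random((42, 44))
        s = rng.random((42, 44))
        f1 = extractor.compute_matrix(b[None], s[None])[0]
        f2 = extractor.compute_matrix(2 * b[None], 2 * s[None])[0]
        for d, v1, v2 in zip(extractor.descriptors, f1, f2):
            if d.kind in ("cop_x", "cop_y", "pressure_ratio", "contact_area_proportion"):
                assert v2 == pytest.approx(v1, rel=1e-12)
            elif d.kind in ("mean_pressure", "peak_pressure", "total_force"):
                assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_matrix_matches_per_feature_naive_recomputation(self, extractor, rng):
        bv = rng.random((42, 44))
        sv = rng.random((42, 44))
        bframe = PressureFrame(MatGeometry.backrest(), bv)
        sframe = PressureFrame(MatGeometry.seatpan(), sv)
        fv = extractor.compute(bframe, sframe)
        frames = {"backrest": bframe, "seatpan": sframe}
        schemes = extractor.scheme
        for d, v in zip(fv.descriptors, fv.values):
            frame = frames[d.side]
            mask = schemes[d.side].area_mask(d.area)
            if d.kind == "cop_x":
                expect = naive_cop(frame, mask)[0]
            elif d.kind == "cop_y":
                expect = naive_cop(frame, mask)[1]
            elif d.kind == "contact_area_proportion":
                expect = naive_contact(frame, mask, 0.0)
            elif d.kind == "pressure_ratio":
                expect = naive_ratio(frame, mask, schemes[d.side].area_mask(d.area2))
            elif d.kind == "mean_pressure":
                expect = naive_stats(frame, mask)[0]
            elif d.kind == "peak_pressure":
                expect = naive_stats(frame, mask)[1]
            else:
                expect = naive_stats(frame, mask)[2]
            assert v == pytest.approx(expect, rel=1e-9), d.name

    def test_translation_covariance_of_global_cop(self, extractor, rng):
        blob = np.zeros((42, 44))
        blob[10:20, 10:20] = rng.random((10, 10)) + 0.1
        shifted = np.roll(blob, 1, axis=1)
        zeros = np.zeros((42, 44))
        f0 = extractor.compute_matrix(blob[None], zeros[None])[0]
        f1 = extractor.compute_matrix(shifted[None], zeros[None])[0]
        names = [d.name for d in extractor.descriptors]
        j = names.index("B_cop_x")
        assert f1[j] - f0[j] == pytest.approx(1.27, rel=1e-9)

    def test_scale_invariance_with_scaled_threshold(self, rng):
        b = rng.random((42, 44))
        s = rng.random((42, 44))
        k = 7.3
        ex1 = FeatureExtractor(contact_threshold=0.4)
        ex2 = FeatureExtractor(contact_threshold=0.4 * k)
        f1 = ex1.compute_matrix(b[None], s[None])[0]
        f2 = ex2.compute_matrix(k * b[None], k * s[None])[0]
        for d, v1, v2 in zip(ex1.descriptors, f1, f2):
            if d.kind in ("cop_x", "cop_y", "pressure_ratio", "contact_area_proportion"):
                assert v2 == pytest.approx(v1, rel=1e-12), d.name


class TestRelativeFeatures:
    def test_identity_and_antisymmetry(self, extractor, rng):
        b1, s1 = rng.random((42, 44)), rng.random((42, 44))
        b2, s2 = rng.random((42, 44)), rng.random((42, 44))
        geo_b, geo_s = MatGeometry.backrest(), MatGeometry.seatpan()
        fa = extractor.compute(PressureFrame(geo_b, b1), PressureFrame(geo_s, s1))
        fb = extractor.compute(PressureFrame(geo_b, b2), PressureFrame(geo_s, s2))
        same = relative_features(fa, fa)
        np.testing.assert_array_equal(same.relative_values, 0.0)
        ab = relative_features(fa, fb)
        ba = relative_features(fb, fa)
        np.testing.assert_allclose(ab.relative_values, -ba.relative_values)

    def test_descriptor_mismatch_rejected(self, extractor, rng):
        fv = extractor.compute(
            PressureFrame(MatGeometry.backrest(), rng.random((42, 44))),
            PressureFrame(MatGeometry.seatpan(), rng.random((42, 44))),
        )
        other = FeatureDescriptor("alien", "cop_x", "backrest", "B")
        import copy

        clone = copy.copy(fv)
        clone.descriptors = [other] * len(fv.descriptors)
        with pytest.raises(ValueError, match="descriptor"):
            relative_features(fv, clone)

    def test_zero_reference_equals_absolute(self, extractor, rng):
        fv = extractor.compute(
            PressureFrame(MatGeometry.backrest(), rng.random((42, 44))),
            PressureFrame(MatGeometry.seatpan(), rng.random((42, 44))),
        )
        from pressurepose.features import FeatureVector

        zero = FeatureVector(fv.descriptors, np.zeros_like(fv.values))
        rel = relative_features(fv, zero)
        np.testing.assert_array_equal(rel.relative_values, fv.values)
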