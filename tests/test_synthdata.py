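"""Tests for the synthetic fundus-like generator."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

import shiftwatch as sw
from shiftwatch.synthdata import (
    QUALITY_BLUR_SIGMA,
    AttributeRecord,
    GeneratorSpec,
    render_image,
    sample_attributes,
)


def _record(**over):
    base = dict(
        patient_id="0",
        sex="female",
        ethnicity="latin_american",
        quality="adequate",
        comorbidity=False,
        dr_grade=0,
    )
    base.update(over)
    return AttributeRecord(**base)


class TestAttributeSampling:
    def test_marginal_recovery_within_three_standard_errors(self, spec32):
        """Empirical frequencies at n=10000 match the configured marginals."""
        n = 10_000
        records = sample_attributes(spec32, n, seed=42)
        df = pd.DataFrame(
            {
                "sex": [r.sex for r in records],
                "ethnicity": [r.ethnicity for r in records],
                "quality": [r.quality for r in records],
                "comorbidity": [r.comorbidity for r in records],
                "dr_grade": [r.dr_grade for r in records],
            }
        )
        for attr, table in spec32.marginals.items():
            freqs = df[attr].value_counts(normalize=True)
            for value, p in table.items():
                se = np.sqrt(p * (1 - p) / n)
                assert abs(freqs.get(value, 0.0) - p) <= max(3 * se, 1e-9), (
                    attr,
                    value,
                )

    def test_expected_female_and_healthy_fractions(self, spec32):
        records = sample_attributes(spec32, 10_000, seed=1)
        female = np.mean([r.sex == "female" for r in records])
        healthy = np.mean([r.dr_grade == 0 for r in records])
        assert female == pytest.approx(0.60, abs=0.02)
        assert healthy == pytest.approx(0.79, abs=0.02)

    def test_same_seed_reproduces_record_sequence(self, spec32):
        a = sample_attributes(spec32, 50, seed=9)
        b = sample_attributes(spec32, 50, seed=9)
        assert a == b

    def test_invalid_marginals_name_the_attribute(self):
        bad = sw.default_marginals()
        bad["sex"] = {"female": 0.7, "male": 0.7, "other": 0.0}
        with pytest.raises(ValueError, match="sex"):
            GeneratorSpec(marginals=bad)

    def test_n_must_be_positive(self, spec32):
        with pytest.raises(ValueError):
            sample_attributes(spec32, 0, seed=0)


class TestRenderer:
    def test_zero_amplitudes_and_noise_give_identical_images(self):
        spec = GeneratorSpec(
            image_size=32,
            effect_amplitudes={k: 0.0 for k in ("sex", "ethnicity", "comorbidity", "dr_grade", "quality")},
            noise_sd=0.0,
        )
        imgs = [
            render_image(_record(sex=s, ethnicity=e, comorbidity=c), spec, seed=i).pixels
            for i, (s, e, c) in enumerate(
                [("female", "white", True), ("male", "african", False), ("other", "asian", True)]
            )
        ]
        np.testing.assert_array_equal(imgs[0], imgs[1])
        np.testing.assert_array_equal(imgs[0], imgs[2])

    def test_comorbidity_difference_is_concentrated_in_haze_region(self):
        """Direct pixel arithmetic: the haze patch dominates the difference."""
        spec = GeneratorSpec(image_size=32, noise_sd=0.0)
        a = render_image(_record(comorbidity=True, quality="excellent"), spec, seed=5).pixels
        b = render_image(_record(comorbidity=False, quality="excellent"), spec, seed=5).pixels
        diff = np.abs(a - b).mean(axis=2)
        assert diff.max() > 0
        # haze centre is at (x, y) = (0.30, -0.25) -> upper-right quadrant rows
        size = spec.image_size
        cy, cx = int((1 - 0.25) * size / 2), int((1 + 0.30) * size / 2)
        near = diff[cy - 4 : cy + 4, cx - 4 : cx + 4].mean()
        far = diff[:8, :8].mean()
        assert near > 5 * (far + 1e-9)

    def test_insufficient_quality_blurs_more_than_adequate(self):
        assert (
            QUALITY_BLUR_SIGMA["insufficient"]
            > QUALITY_BLUR_SIGMA["adequate"]
            > QUALITY_BLUR_SIGMA["good"]
            > QUALITY_BLUR_SIGMA["excellent"]
        )

    def test_renderer_is_deterministic(self, spec32):
        a = render_image(_record(dr_grade=3), spec32, seed=77).pixels
        b = render_image(_record(dr_grade=3), spec32, seed=77).pixels
        np.testing.assert_array_equal(a, b)

    def test_pixels_in_unit_interval_and_square(self, spec32):
        img = render_image(_record(dr_grade=4, quality="excellent"), spec32, seed=3).pixels
        assert img.shape == (spec32.image_size, spec32.image_size, 3)
        assert np.isfinite(img).all()
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_grade_absent_requires_insufficient_quality(self):
        with pytest.raises(ValueError):
            _record(dr_grade=None, quality="good")
        _record(dr_grade=None, quality="insufficient")  # allowed


class TestDatasets:
    def test_generate_is_stable_across_runs(self, spec32):
        a = sw.generate_dataset(spec32, 10, fold="train", seed=8)
        b = sw.generate_dataset(spec32, 10, fold="train", seed=8)
        assert len(a) == 10
        np.testing.assert_array_equal(a.images, b.images)
        pd.testing.assert_frame_equal(a.attrs, b.attrs)

    def test_ood_fold_is_all_insufficient(self, ood_dataset):
        assert (ood_dataset.attrs["quality"] == "insufficient").all()
        assert ood_dataset.attrs["dr_grade"].isna().all()

    def test_round_trip_is_bit_exact(self, spec32, tmp_path):
        ds = sw.generate_dataset(spec32, 6, fold="val", seed=21)
        sw.save_dataset(ds, tmp_path / "ds")
        back = sw.load_dataset(tmp_path / "ds")
        np.testing.assert_array_equal(ds.images, back.images)
        pd.testing.assert_frame_equal(
            ds.attrs, back.attrs[ds.attrs.columns], check_dtype=False
        )

    def test_csv_writes_empty_grade_for_ood(self, spec32, tmp_path):
        ds = sw.generate_dataset(spec32, 3, fold="ood", seed=4)
        out = sw.save_dataset(ds, tmp_path / "ood")
        text = (out / "attributes.csv").read_text().splitlines()
        assert text[0] == "image_id,patient_id,sex,ethnicity,quality,comorbidity,dr_grade,fold"
        assert all(line.split(",")[6] == "" for line in text[1:])


def _linear_separability(Xa, Xb, rng, n=150):
    n = min(n, len(Xa), len(Xb))
    ia = rng.choice(len(Xa), n, replace=False)
    ib = rng.choice(len(Xb), n, replace=False)
    X = np.vstack([Xa[ia].reshape(n, -1), Xb[ib].reshape(n, -1)])
    y = np.repeat([0, 1], n)
    idx = rng.permutation(2 * n)
    cut = int(0.7 * 2 * n)
    clf = LogisticRegression(max_iter=3000)
    clf.fit(X[idx[:cut]], y[idx[:cut]])
    return clf.score(X[idx[cut:]], y[idx[cut:]])


def test_separability_ordering_matches_detection_difficulty(
    dataset, ood_dataset, rng
):
    """OOD quality is easiest to separate, then co-morbidity, then sex."""
    a = dataset.attrs
    adequate = dataset.images[(a["quality"] == "adequate").to_numpy()]
    acc_ood = _linear_separability(ood_dataset.images, adequate, rng)
    acc_com = _linear_separability(
        dataset.images[a["comorbidity"].to_numpy()],
        dataset.images[(~a["comorbidity"]).to_numpy()],
        rng,
    )
    acc_sex = _linear_separability(
        dataset.images[(a["sex"] == "female").to_numpy()],
        dataset.images[(a["sex"] == "male").to_numpy()],
        rng,
    )
    assert acc_ood >= acc_com > acc_sex
    assert acc_sex > 0.55  # sex is weak but not absent
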