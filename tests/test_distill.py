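"""Tests for pseudo-labeling, the distillation loss, and the pretraining loop."""

import sys

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rckd.distill import (DistillConfig, MockTeacher, ExternalCommandTeacher,
                          binarize, kd_loss, resize_for_pretraining,
                          build_student, pretrain)
from rckd.synth import SlideParams, generate_slide


class TestBinarize:
    def test_threshold_is_inclusive(self):
        assert binarize(np.array([[0.5]]), 0.5).tolist() == [[1]]

    def test_elementwise_comparison(self):
        y = np.array([[0.2, 0.7], [0.49, 0.51]])
        assert binarize(y, 0.5).tolist() == [[0, 1], [0, 1]]

    def test_all_zero_map(self):
        assert not binarize(np.zeros((4, 4))).any()

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.array([[1.2]]))

    @given(st.integers(0, 2**31 - 1), st.floats(0.05, 0.95))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_idempotent_under_rethresholding(self, seed, alpha):
        y = np.random.default_rng(seed).uniform(size=(6, 6))
        once = binarize(y, alpha)
        assert np.array_equal(binarize(once, alpha), once)


class TestKDLoss:
    def test_perfect_mimicry_is_zero(self):
        pseudo = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        loss = kd_loss(pseudo.astype(np.float64), pseudo)
        assert float(loss.data) < 1e-9

    def test_uniform_half_probability_equals_ln2(self):
        loss = kd_loss(np.full((8, 8), 0.5), np.random.default_rng(0).integers(0, 2, (8, 8)))
        assert float(loss.data) == pytest.approx(np.log(2), abs=1e-12)

    def test_worked_two_by_two_example(self):
        probs = np.array([[0.9, 0.1], [0.8, 0.6]])
        pseudo = np.array([[1, 0], [1, 1]])
        expected = -np.mean([np.log(0.9), np.log(0.9), np.log(0.8), np.log(0.6)])
        assert float(kd_loss(probs, pseudo).data) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            kd_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_loss_is_nonnegative_on_random_inputs(self, rng):
        for _ in range(50):
            p = rng.uniform(size=(5, 5))
            t = rng.integers(0, 2, (5, 5))
            assert float(kd_loss(p, t).data) >= 0.0


class TestResize:
    def test_downscale_to_training_size(self):
        img = np.random.default_rng(0).integers(0, 255, (64, 48, 3)).astype(np.uint8)
        out = resize_for_pretraining(img, input_size=32)
        assert out.shape == (32, 32, 3)

    def test_identity_resize_preserves_pixels(self):
        img = np.random.default_rng(0).integers(0, 255, (16, 16, 3)).astype(np.uint8)
        out = resize_for_pretraining(img, input_size=16)
        assert np.allclose(out, img)

    def test_constant_image_stays_constant(self):
        img = np.full((40, 40, 3), 127, dtype=np.uint8)
        out = resize_for_pretraining(img, input_size=24)
        assert np.allclose(out, 127)

    def test_mask_resizing_stays_binary(self):
        img = np.zeros((20, 20, 3), dtype=np.uint8)
        mask = np.random.default_rng(1).integers(0, 2, (20, 20)).astype(np.uint8)
        _, m = resize_for_pretraining(img, mask, input_size=13)
        assert set(np.unique(m)) <= {0, 1}


class TestTeachers:
    def test_mock_teacher_returns_ground_truth(self):
        slide = generate_slide(SlideParams(height=32, width=32), seed=7)
        teacher = MockTeacher([slide])
        np.testing.assert_array_equal(teacher.predict(slide.image),
                                      slide.nuclei_mask.astype(np.float64))

    def test_mock_teacher_rejects_unknown_images(self):
        teacher = MockTeacher([])
        with pytest.raises(KeyError):
            teacher.predict(np.zeros((8, 8, 3), dtype=np.uint8))

    def test_external_command_contract_via_16bit_png(self, tmp_path):
        script = tmp_path / "toy_teacher.py"
        script.write_text(
            "import sys\nimport numpy as np\nfrom PIL import Image\n"
            "img = np.asarray(Image.open(sys.argv[1]))\n"
            "out = np.full(img.shape[:2], round(0.75 * 65535), dtype=np.uint16)\n"
            "Image.fromarray(out).save(sys.argv[2])\n")
        teacher = ExternalCommandTeacher([sys.executable, str(script)])
        probs = teacher.predict(np.zeros((10, 12, 3), dtype=np.uint8))
        assert probs.shape == (10, 12)
        assert np.allclose(probs, 0.75, atol=1e-4)


class TestConfigValidation:
    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            DistillConfig(threshold_alpha=1.0)

    def test_warmup_bounded_by_epochs(self):
        with pytest.raises(ValueError):
            DistillConfig(epochs=5, warmup_epochs=6)


@pytest.fixture(scope="module")
def slides():
    params = SlideParams(height=32, width=32, nuclei_density=2.2e-3)
    return [generate_slide(params, 500 + i) for i in range(16)]


class TestPretrain:
    def test_zero_epochs_leaves_weights_untouched(self, tiny_config, slides):
        student = build_student(tiny_config, seed=1)
        before = {n: p.data.copy() for n, p in student.named_parameters()}
        cfg = DistillConfig(input_size=32, batch_size=8, epochs=0, warmup_epochs=0, seed=2)
        backbone, log = pretrain(student, MockTeacher(slides),
                                 [s.image for s in slides], cfg)
        assert log == []
        for n, p in student.named_parameters():
            assert np.array_equal(p.data, before[n])

    def test_loss_decreases_on_learnable_task(self, tiny_config, slides):
        student = build_student(tiny_config, seed=1)
        cfg = DistillConfig(input_size=32, batch_size=8, epochs=6, warmup_epochs=2,
                            peak_lr=1.0, seed=3)
        _, log = pretrain(student, MockTeacher(slides), [s.image for s in slides], cfg)
        assert log[-1]["mean_loss"] < log[0]["mean_loss"]

    def test_same_seed_gives_bitwise_identical_logs(self, tiny_config, slides):
        cfg = DistillConfig(input_size=32, batch_size=8, epochs=2, warmup_epochs=1, seed=9)
        logs = []
        for _ in range(2):
            student = build_student(tiny_config, seed=4)
            _, log = pretrain(student, MockTeacher(slides), [s.image for s in slides], cfg)
            logs.append(log)
        assert logs[0] == logs[1]

    def test_teacher_shape_mismatch_raises(self, tiny_config, slides):
        class BadTeacher:
            def predict(self, image):
                return np.zeros((4, 4))

        student = build_student(tiny_config, seed=1)
        cfg = DistillConfig(input_size=32, batch_size=4, epochs=1, warmup_epochs=1)
        with pytest.raises(ValueError, match="teacher"):
            pretrain(student, BadTeacher(), [slides[0].image], cfg)

    def test_empty_image_set_raises(self, tiny_config):
        student = build_student(tiny_config, seed=1)
        with pytest.raises(ValueError, match="empty"):
            pretrain(student, MockTeacher([]), [], DistillConfig(epochs=1, warmup_epochs=1))

    def test_pretraining_writes_jsonl_log(self, tiny_config, slides, tmp_path):
        student = build_student(tiny_config, seed=1)
        cfg = DistillConfig(input_size=32, batch_size=8, epochs=2, warmup_epochs=1, seed=5)
        log_path = tmp_path / "train.jsonl"
        pretrain(student, MockTeacher(slides), [s.image for s in slides], cfg,
                 log_path=log_path)
        lines = log_path.read_text().strip().splitlines()
        assert len(lines) == 2
        assert '"lr"' in lines[0]
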