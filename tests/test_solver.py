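import numpy as np
import pytest

from resire.containers import ProjectionStack
from resire.model import (
    ReconstructionConfig,
    Resire,
    apply_constraints,
    compute_gradient,
    resire_reconstruct,
    step_size,
)
from resire.projectors import make_radon_operator


class TestStepSize:
    def test_unit_case(self):
        assert step_size(1, 1, 1) == 1.0

    def test_study_geometry(self):
        # 41 projections of a 64^3 grid
        assert step_size(2, 41, 64) == pytest.approx(2 / 2624, rel=1e-12)
        assert step_size(2, 41, 64) == pytest.approx(7.6220e-4, rel=1e-4)

    def test_scaling(self):
        base = step_size(1.0, 10, 20)
        assert step_size(3.0, 10, 20) == pytest.approx(3 * base)
        assert step_size(1.0, 20, 20) == pytest.approx(base / 2)
        assert step_size(1.0, 10, 40) == pytest.approx(base / 2)

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, 0, 1), (1, 1, -2)])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            step_size(*bad)


class TestConstraints:
    def test_positivity_clips_negatives(self):
        cfg = ReconstructionConfig(positivity=True)
        vol = np.array([[[-1.0, 2.0]]])
        assert np.array_equal(apply_constraints(vol, cfg), [[[0.0, 2.0]]])

    def test_no_constraints_is_identity(self):
        cfg = ReconstructionConfig(positivity=False)
        vol = np.array([[[-1.0, 2.0]]])
        assert np.array_equal(apply_constraints(vol, cfg), vol)

    def test_support_mask_zeroes_exterior_only(self):
        x = np.arange(16) - 8
        mask = (x[:, None, None] ** 2 + x[None, :, None] ** 2
                + x[None, None, :] ** 2) <= 25
        cfg = ReconstructionConfig(positivity=False, support=mask)
        vol = np.ones((16, 16, 16))
        out = apply_constraints(vol, cfg)
        assert np.all(out[mask] == 1.0)
        assert np.all(out[~mask] == 0.0)

    def test_mask_shape_mismatch_rejected(self):
        cfg = ReconstructionConfig(support=np.ones((4, 4, 4), dtype=bool))
        with pytest.raises(ValueError):
            apply_constraints(np.zeros((8, 8, 8)), cfg)


class TestGradient:
    def test_zero_residual_gives_zero_gradient(self, rng):
        vol = rng.random((16, 16, 16))
        cfg = ReconstructionConfig(subdivision=2)
        angles = np.array([-40.0, 0.0, 25.0])
        images = np.stack(
            [make_radon_operator(vol.shape, (0, th, 0), 2).forward(vol) for th in angles]
        )
        grad = compute_gradient(vol, ProjectionStack(images, angles), cfg)
        assert np.abs(grad).max() <= 1e-8 * np.abs(vol).max()

    def test_zero_volume_single_zero_tilt_gives_minus_b_slices(self, rng):
        b = rng.random((12, 12))
        stack = ProjectionStack(b[None], [0.0])
        grad = compute_gradient(np.zeros((12, 12, 12)), stack,
                                ReconstructionConfig(subdivision=1))
        for w in range(12):
            assert np.allclose(grad[:, :, w], -b, atol=1e-14)

    def test_matches_central_difference_of_sse(self, rng):
        """<grad, E> against (eps(O+hE) - eps(O-hE)) / 2h."""
        cfg = ReconstructionConfig(subdivision=2)
        vol = rng.random((16, 16, 16))
        E = rng.normal(size=(16, 16, 16))
        angles = np.array([-33.0, 10.0, 58.0])
        images = rng.random((3, 16, 16))
        stack = ProjectionStack(images, angles)
        ops = [make_radon_operator(vol.shape, a, cfg.subdivision) for a in stack.angles]

        def sse(v):
            return 0.5 * sum(
                float(np.sum((op.forward(v) - b) ** 2))
                for op, b in zip(ops, images)
            )

        h = 1e-4
        fd = (sse(vol + h * E) - sse(vol - h * E)) / (2 * h)
        inner = float(np.sum(compute_gradient(vol, stack, cfg) * E))
        assert inner == pytest.approx(fd, rel=1e-4)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            ProjectionStack(np.zeros((0, 4, 4)), np.zeros((0, 3)))


class TestReconstruction:
    def test_zero_images_have_zero_fixed_point(self):
        stack = ProjectionStack(np.zeros((5, 12, 12)), np.linspace(-60, 60, 5))
        cfg = ReconstructionConfig(iterations=10)
        vol, record = resire_reconstruct(stack, cfg)
        assert np.all(vol == 0.0)
        assert np.all(record.sse == 0.0)

    def test_sse_monotone_on_consistent_data(self, small_phantom, small_stack):
        cfg = ReconstructionConfig(t=1.0, iterations=40)
        _, record = resire_reconstruct(small_stack, cfg)
        assert len(record) == 40
        assert np.all(np.diff(record.sse) <= 1e-12 * record.sse[0])

    def test_positivity_keeps_iterates_nonnegative(self, small_stack):
        mins = []
        cfg = ReconstructionConfig(iterations=15, positivity=True)
        Resire(small_stack, config=cfg).fit(
            callback=lambda k, vol, sse, rf: mins.append(vol.min())
        )
        assert all(m >= 0.0 for m in mins)

    def test_duplicating_projections_leaves_update_unchanged(self, small_stack):
        """The 1/(n*N_z) normalization cancels duplication."""
        cfg = ReconstructionConfig(iterations=3, positivity=False)
        vol1, _ = resire_reconstruct(small_stack, cfg)
        doubled = ProjectionStack(
            np.concatenate([small_stack.images, small_stack.images]),
            np.concatenate([small_stack.angles, small_stack.angles]),
        )
        vol2, _ = resire_reconstruct(doubled, cfg)
        assert np.allclose(vol1, vol2, atol=1e-10)

    def test_divergence_raises_naming_iteration(self, small_stack):
        cfg = ReconstructionConfig(t=5e4, iterations=60, positivity=False)
        with pytest.raises(RuntimeError, match="iteration"):
            resire_reconstruct(small_stack, cfg)

    def test_results_summary_and_projection(self, small_stack):
        res = Resire(small_stack, config=ReconstructionConfig(iterations=5)).fit()
        text = res.summary()
        assert "R-factor" in text and "projections (n):      21" in text
        calc = res.project()
        assert calc.shape == small_stack.images.shape

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ReconstructionConfig(iterations=0)
        with pytest.raises(ValueError):
            ReconstructionConfig(t=-1.0)
        with pytest.raises(ValueError):
            ReconstructionConfig(projector="sirt")
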