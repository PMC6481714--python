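import numpy as np
import pytest

from betasyn.afm import (
    AFMError,
    HeightMap,
    despeckle,
    generate_fibril_image,
    height_distribution,
    particle_stats,
    segment_particles,
)


def brute_force_median3(grid):
    # edge-value-repeating reflection, matching the pipeline's convention
    padded = np.pad(grid, 1, mode="symmetric")
    out = np.empty_like(grid, dtype=float)
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            out[i, j] = np.median(padded[i : i + 3, j : j + 3])
    return out


def brute_force_label(mask):
    """8-connected flood fill, independent of scikit-image."""
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for si in range(mask.shape[0]):
        for sj in range(mask.shape[1]):
            if mask[si, sj] and labels[si, sj] == 0:
                current += 1
                stack = [(si, sj)]
                while stack:
                    i, j = stack.pop()
                    if not (0 <= i < mask.shape[0] and 0 <= j < mask.shape[1]):
                        continue
                    if not mask[i, j] or labels[i, j] != 0:
                        continue
                    labels[i, j] = current
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            stack.append((i + di, j + dj))
    return labels


# ---------------------------------------------------------------------------
# generator


def test_generator_is_deterministic():
    a, _ = generate_fibril_image(n_fibrils=4, image_size=128, length=250.0, seed=42)
    b, _ = generate_fibril_image(n_fibrils=4, image_size=128, length=250.0, seed=42)
    assert np.array_equal(a.grid, b.grid)


def test_zero_fibrils_gives_pure_noise():
    hm, truth = generate_fibril_image(n_fibrils=0, image_size=64, noise_sd=0.1,
                                      speckle_fraction=0.0, seed=1)
    assert truth.empty
    assert abs(hm.grid.mean()) < 0.05
    assert hm.grid.max() < 1.0


def test_apex_heights_equal_requested_before_noise():
    hm, truth = generate_fibril_image(
        n_fibrils=3, image_size=256, height=3.5, noise_sd=0.0,
        speckle_fraction=0.0, seed=7,
    )
    assert hm.grid.max() == pytest.approx(3.5, abs=1e-9)
    assert (truth["height"] == 3.5).all()


def test_impossible_placement_raises():
    with pytest.raises(AFMError):
        generate_fibril_image(n_fibrils=60, image_size=64, pixel_size=10.0,
                              length=500.0, seed=0, max_retries=5)


# ---------------------------------------------------------------------------
# despeckle


def test_despeckle_constant_image_unchanged():
    hm = HeightMap(np.full((16, 16), 2.5), pixel_size=10.0)
    assert np.array_equal(despeckle(hm).grid, hm.grid)


def test_despeckle_removes_single_pixel_spike():
    grid = np.zeros((16, 16))
    grid[8, 8] = 50.0
    out = despeckle(HeightMap(grid, pixel_size=10.0))
    assert out.grid.max() == 0.0


def test_despeckle_matches_brute_force_median():
    rng = np.random.default_rng(3)
    grid = rng.uniform(0, 5, (8, 8))
    out = despeckle(HeightMap(grid, pixel_size=10.0))
    assert np.allclose(out.grid, brute_force_median3(grid))


# ---------------------------------------------------------------------------
# segmentation


def test_two_disjoint_ridges_give_two_labels():
    grid = np.zeros((64, 64))
    grid[10:13, 5:60] = 3.0
    grid[40:43, 5:60] = 3.0
    labels = segment_particles(HeightMap(grid, pixel_size=10.0), threshold=1.0)
    assert labels.max() == 2


def test_threshold_above_max_gives_zero_labels():
    grid = np.random.default_rng(0).uniform(0, 1, (32, 32))
    labels = segment_particles(HeightMap(grid, pixel_size=10.0), threshold=5.0)
    assert labels.max() == 0


def test_label_count_matches_brute_force_flood_fill():
    rng = np.random.default_rng(9)
    grid = (rng.random((24, 24)) > 0.7).astype(float) * 3.0
    labels = segment_particles(HeightMap(grid, pixel_size=10.0), threshold=1.0)
    brute = brute_force_label(grid > 1.0)
    assert labels.max() == brute.max()
    # same partition: label images agree up to renumbering
    for value in range(1, brute.max() + 1):
        mask = brute == value
        assert len(np.unique(labels[mask])) == 1


# ---------------------------------------------------------------------------
# particle stats


def test_ridge_axes_recovered_within_ten_percent():
    hm, truth = generate_fibril_image(
        n_fibrils=1, image_size=256, pixel_size=10.0, length=1000.0,
        length_jitter=0.0, width_fwhm=80.0, noise_sd=0.0,
        speckle_fraction=0.0, seed=5,
    )
    labels = segment_particles(hm, threshold=1.75)  # half max
    stats = particle_stats(labels, hm)
    assert len(stats) == 1
    # thresholding at half max makes the mask width equal the FWHM
    assert stats[0].length == pytest.approx(1000.0, rel=0.10)
    assert stats[0].width == pytest.approx(80.0, rel=0.10)
    assert stats[0].major_axis >= stats[0].minor_axis


def test_disc_circularity_near_one():
    yy, xx = np.mgrid[:64, :64]
    grid = ((yy - 32) ** 2 + (xx - 32) ** 2 < 15**2).astype(float) * 3.0
    labels = segment_particles(HeightMap(grid, pixel_size=10.0), threshold=1.0)
    stats = particle_stats(labels, HeightMap(grid, pixel_size=10.0))
    assert stats[0].circularity > 0.9


def test_noiseless_ridge_mask_mean_height_closed_form():
    """Mean in-mask height of a Gaussian ridge profile above a threshold.

    For profile h*exp(-d^2/2s^2) masked at h*exp(-m^2/2s^2), the transverse
    mean is h * sqrt(pi/2) * (s/m) * erf(m/(s*sqrt(2))).
    """
    import math

    hm, _ = generate_fibril_image(
        n_fibrils=1, image_size=256, pixel_size=5.0, length=800.0,
        length_jitter=0.0, width_fwhm=120.0, height=3.5, noise_sd=0.0,
        speckle_fraction=0.0, seed=2,
    )
    sigma = 120.0 / 2.355
    thresh = 1.0
    m = sigma * math.sqrt(2 * math.log(3.5 / thresh))
    expected = 3.5 * math.sqrt(math.pi / 2) * (sigma / m) * math.erf(
        m / (sigma * math.sqrt(2))
    )
    labels = segment_particles(hm, threshold=thresh)
    stats = particle_stats(labels, hm)
    assert stats[0].mean_height == pytest.approx(expected, rel=0.05)


# ---------------------------------------------------------------------------
# full pipeline


@pytest.fixture(scope="module")
def pipeline_run():
    hm, truth = generate_fibril_image(n_fibrils=25, height=3.5, noise_sd=0.1, seed=12)
    smooth = despeckle(hm)
    labels = segment_particles(smooth)
    stats = particle_stats(labels, smooth)
    return truth, smooth, labels, stats


def test_pipeline_recovers_particle_count(pipeline_run):
    truth, _, _, stats = pipeline_run
    assert len(stats) == len(truth) == 25


def test_pipeline_recovers_mean_height_within_tolerance(pipeline_run):
    """25 fibrils at 3.5 nm apex, 0.1 nm noise: mean apex within 0.2 nm."""
    _, _, _, stats = pipeline_run
    summary = height_distribution(stats)
    assert summary["mean"] == pytest.approx(3.5, abs=0.2)
    assert summary["in_reference_band"]


def test_zero_noise_count_exact():
    hm, truth = generate_fibril_image(n_fibrils=10, noise_sd=0.0,
                                      speckle_fraction=0.0, seed=3)
    labels = segment_particles(despeckle(hm))
    stats = particle_stats(labels, hm)
    assert len(stats) == 10


def test_height_recovery_bias_small_across_seeds():
    """Apex-recovery bias < 3% of the set height at 0.1 nm noise."""
    means = []
    for seed in range(5):
        hm, _ = generate_fibril_image(n_fibrils=8, image_size=256, height=3.5,
                                      noise_sd=0.1, seed=seed)
        stats = particle_stats(segment_particles(despeckle(hm)), despeckle(hm))
        means.append(height_distribution(stats)["mean"])
    assert abs(np.mean(means) - 3.5) < 0.03 * 3.5


def test_pipeline_translation_and_rotation_invariance():
    hm, _ = generate_fibril_image(n_fibrils=5, image_size=256, noise_sd=0.05,
                                  seed=8)
    base = segment_particles(despeckle(hm)).max()
    rolled = HeightMap(np.roll(hm.grid, (7, -11), axis=(0, 1)), hm.pixel_size)
    rotated = HeightMap(np.rot90(hm.grid), hm.pixel_size)
    assert segment_particles(despeckle(rolled)).max() == base
    assert segment_particles(despeckle(rotated)).max() == base


def test_empty_label_set_warns():
    with pytest.warns(UserWarning):
        summary = height_distribution([])
    assert summary["n_particles"] == 0


def test_tiff_and_csv_roundtrip(tmp_path):
    hm, _ = generate_fibril_image(n_fibrils=2, image_size=64, length=150.0, seed=0)
    hm.write_tiff(tmp_path / "map.tiff")
    back = HeightMap.read_tiff(tmp_path / "map.tiff", pixel_size=hm.pixel_size)
    assert np.allclose(back.grid, hm.grid, atol=1e-5)
    hm.write_csv(tmp_path / "map.csv")
    back = HeightMap.read_csv(tmp_path / "map.csv", pixel_size=hm.pixel_size)
    assert np.allclose(back.grid, hm.grid, atol=1e-12)
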