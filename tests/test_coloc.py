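import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synaptiq import (
    BoutonPopulation,
    ChannelStack,
    ColocConfig,
    DetectionParams,
    VolumeSpec,
    classify_bouton,
    detect_boutons,
    generate_volume,
    score_bouton,
    summarize_regions,
)
from synaptiq.coloc import BoutonRecord, shell_mask
from synaptiq.errors import (
    ClassificationError,
    DegenerateDataError,
    GeometryError,
    ParameterError,
)

VOXEL = (0.1, 0.1, 0.2)


def make_stack(vgat, marker=None, name="syp_tdt"):
    channels = {"vgat": np.asarray(vgat, dtype=np.uint8)}
    if marker is not None:
        channels[name] = np.asarray(marker, dtype=np.uint8)
    return ChannelStack(channels, voxel_size=VOXEL)


def voi_stack(vgat_voi, marker_voi, name="syp_tdt"):
    """Exactly VOI-sized stack; center voxel admits a full VOI."""
    return make_stack(vgat_voi, marker_voi, name), (2, 7, 7)


def no_mask_config(**kw):
    """Config whose edge-intensity threshold never triggers."""
    return ColocConfig(edge_intensity_k=1e9, **kw)


# --------------------------------------------------------------------------
# detection


def test_constant_volume_yields_no_boutons(default_config):
    vgat = np.full((15, 64, 64), 20, dtype=np.uint8)
    assert detect_boutons(vgat, default_config, VOXEL) == []


def test_volume_smaller_than_voi_is_a_geometry_error(default_config):
    with pytest.raises(GeometryError):
        detect_boutons(np.zeros((3, 10, 10), dtype=np.uint8), default_config,
                       VOXEL)


def test_single_punctum_detected_at_argmax():
    spec = VolumeSpec(shape_xy=(96, 96), seed=2, background_sd=0.0)
    pop = BoutonPopulation(count=1, noise_sd=0.0, peak_sd=0.0)
    stack, truth = generate_volume(spec, pop)
    centroids = detect_boutons(stack["vgat"], ColocConfig(), VOXEL)
    assert len(centroids) == 1
    oracle = np.unravel_index(np.argmax(stack["vgat"]), stack.shape)
    assert all(abs(a - b) <= 1 for a, b in zip(centroids[0], oracle))


def test_two_puncta_three_microns_apart_both_recovered():
    shape = (15, 80, 80)
    vgat = np.zeros(shape, dtype=np.float64)
    zz, yy, xx = np.indices(shape).astype(float)
    for cx in (25.0, 55.0):  # 3 µm apart along x at 0.1 µm/px
        r2 = ((xx - cx) * 0.1) ** 2 + ((yy - 40) * 0.1) ** 2 + ((zz - 7) * 0.2) ** 2
        vgat += 200 * np.exp(-r2 / (2 * 0.3**2))
    vgat = np.clip(np.rint(vgat + 20), 0, 255).astype(np.uint8)
    centroids = detect_boutons(vgat, ColocConfig(), VOXEL)
    assert len(centroids) == 2
    # oracle: per-punctum argmax in disjoint halves
    for half, expected_x in ((slice(0, 40), 25), (slice(40, 80), 55)):
        sub = np.zeros_like(vgat)
        sub[:, :, half] = vgat[:, :, half]
        oz, oy, ox = np.unravel_index(np.argmax(sub), sub.shape)
        match = min(centroids, key=lambda c: abs(c[2] - ox))
        assert all(abs(a - b) <= 1 for a, b in zip(match, (oz, oy, ox)))


# --------------------------------------------------------------------------
# scoring


def test_identical_channels_score_one():
    vgat = (np.arange(15 * 15 * 5).reshape(5, 15, 15) * 7) % 200
    stack, c = voi_stack(vgat, vgat)
    res = score_bouton(stack, c, "syp_tdt", no_mask_config(),
                       background=(20.0, 4.0))
    assert res.score == pytest.approx(1.0, abs=1e-12)


def test_anticorrelated_channels_return_the_floor_exactly():
    vgat = (np.arange(15 * 15 * 5).reshape(5, 15, 15) * 7) % 200
    stack, c = voi_stack(vgat, 200 - vgat)
    res = score_bouton(stack, c, "syp_tdt", no_mask_config(),
                       background=(20.0, 4.0))
    assert res.score == 0.01
    assert res.floored and res.slope < 0


def test_score_matches_closed_form_pearson():
    """vgat=[1,2,3], marker=[1,2,4] tiled over the VOI -> r2 = 81/84."""
    n = 15 * 15 * 5
    vgat = np.resize([1, 2, 3], n).reshape(5, 15, 15)
    marker = np.resize([1, 2, 4], n).reshape(5, 15, 15)
    stack, c = voi_stack(vgat, marker)
    res = score_bouton(stack, c, "syp_tdt", no_mask_config(),
                       background=(300.0, 1.0))
    assert res.score == pytest.approx(81 / 84, abs=1e-12)


def test_zero_vgat_variance_is_degenerate():
    vgat = np.full((5, 15, 15), 50)
    marker = np.arange(5 * 15 * 15).reshape(5, 15, 15) % 200
    stack, c = voi_stack(vgat, marker)
    with pytest.raises(DegenerateDataError):
        score_bouton(stack, c, "syp_tdt", no_mask_config(),
                     background=(50.0, 1.0))


def test_too_few_included_voxels_is_degenerate():
    vgat = np.full((5, 15, 15), 200)
    vgat[2, 7, 7] = 250
    stack, c = voi_stack(vgat, vgat)
    cfg = ColocConfig(edge_intensity_k=0.0)  # every shell voxel excluded
    shell = shell_mask((5, 15, 15), (0.2, 0.1, 0.1), 0.25)
    min_needed = int((~shell).sum()) + 1
    cfg = ColocConfig(edge_intensity_k=0.0, min_included_voxels=min_needed)
    with pytest.raises(DegenerateDataError):
        score_bouton(stack, c, "syp_tdt", cfg, background=(20.0, 4.0))


def test_shell_geometry_at_default_voxel_size():
    """0.25 µm shell = 2 voxels per xy face, 1 section per z face."""
    shell = shell_mask((5, 15, 15), (0.2, 0.1, 0.1), 0.25)
    core = ~shell
    assert core.sum() == 3 * 11 * 11
    assert core[1:4, 2:13, 2:13].all()


@pytest.mark.parametrize("seed", range(5))
def test_score_equals_squared_pearson_for_nonnegative_slope(seed):
    rng = np.random.default_rng(seed)
    vgat = rng.integers(0, 200, size=(5, 15, 15))
    slope_sign = 1 if seed % 2 == 0 else 0
    marker = np.clip(
        slope_sign * 0.5 * vgat + rng.normal(30, 10, vgat.shape), 0, 255
    )
    stack, c = voi_stack(vgat, marker)
    res = score_bouton(stack, c, "syp_tdt", no_mask_config(),
                       background=(300.0, 1.0))
    if res.slope >= 0:
        r = stats.pearsonr(
            stack["vgat"].ravel().astype(float),
            stack["syp_tdt"].ravel().astype(float),
        )[0]
        assert res.score == pytest.approx(r * r, abs=1e-10)


def test_score_scale_invariance_and_negation_flip():
    rng = np.random.default_rng(3)
    vgat = rng.integers(20, 180, size=(5, 15, 15))
    # even-integer marker so a 0.5x + 10 rescale stays exact in 8 bits
    marker = 2 * ((0.4 * vgat).astype(int) + rng.integers(0, 10, vgat.shape))
    stack, c = voi_stack(vgat, marker)
    cfg = no_mask_config()
    base = score_bouton(stack, c, "syp_tdt", cfg, background=(300.0, 1.0))
    # positive affine rescale of the marker: same score to 1e-10
    stack2, _ = voi_stack(vgat, np.clip(0.5 * stack["syp_tdt"] + 10, 0, 255))
    res2 = score_bouton(stack2, c, "syp_tdt", cfg, background=(300.0, 1.0))
    assert res2.score == pytest.approx(base.score, abs=1e-10)
    # negation flips the slope sign and triggers the floor
    stack3, _ = voi_stack(vgat, 255 - stack["syp_tdt"])
    res3 = score_bouton(stack3, c, "syp_tdt", cfg, background=(300.0, 1.0))
    assert res3.floored and res3.score == 0.01


def test_edge_masking_beats_unmasked_with_shell_contamination():
    spec = VolumeSpec(shape_xy=(96, 96), seed=13, background_sd=0.0)
    pop = BoutonPopulation(count=1, noise_sd=0.0, p_glyt2=1.0, peak_sd=0.0)
    stack, truth = generate_volume(spec, pop)
    b = truth[0]
    vz, vy, vx = spec.voxel_zyx
    c = (int(b.centroid_um[2] / vz), int(b.centroid_um[1] / vy),
         int(b.centroid_um[0] / vx))
    # render a contaminating neighbor into the vgat channel only, centered
    # on the shell of the VOI (0.7 µm off-center in x)
    vgat = stack["vgat"].astype(np.float64)
    from synaptiq.synth_imaging import _render_punctum

    neighbor_center = (b.centroid_um[0] + 0.7, b.centroid_um[1], b.centroid_um[2])
    _render_punctum(vgat, neighbor_center, 200.0, 0.2, 0.3, spec.voxel_zyx)
    contaminated = ChannelStack(
        {"vgat": np.clip(np.rint(vgat), 0, 255).astype(np.uint8),
         "syp_tdt": stack["syp_tdt"]},
        voxel_size=spec.voxel_size,
    )
    bg = (spec.background_mean, 2.0)
    masked = score_bouton(contaminated, c, "syp_tdt", ColocConfig(),
                          background=bg)
    unmasked = score_bouton(contaminated, c, "syp_tdt", no_mask_config(),
                            background=bg)
    assert masked.score > unmasked.score


def test_reported_scores_lie_in_valid_range(noisy_volume, default_config):
    from synaptiq import analyze_volume

    stack, _ = noisy_volume
    records = analyze_volume(stack, default_config)
    assert records
    for r in records:
        for v in r.scores.values():
            if v is not None:
                assert 0.0 <= v <= 1.0
                if v < 0.01:
                    # only the exact floor or a genuine ~0 slope case
                    assert v >= 0.0


# --------------------------------------------------------------------------
# classification


@pytest.mark.parametrize(
    "r2,expected",
    [(0.5, "pos"), (0.05, "neg"), (0.25, "unclassified"),
     (0.4, "unclassified"), (0.1, "unclassified")],
)
def test_glyt2_threshold_bands(r2, expected, default_config):
    labels = classify_bouton({"syp_tdt": r2}, default_config)
    assert labels["glyt2"] == expected


def test_syt_and_yfp_thresholds_are_strict(default_config):
    labels = classify_bouton({"syt12": 0.4, "yfp": 0.41}, default_config)
    assert labels["syt12_pos"] is False
    assert labels["yfp_pos"] is True


def test_missing_required_score_raises_naming_channel(default_config):
    with pytest.raises(ClassificationError, match="syp_tdt"):
        classify_bouton({"syt12": 0.5}, default_config, channels=("syp_tdt",))


def test_absent_channel_label_is_missing_not_zero(default_config):
    labels = classify_bouton({"syp_tdt": 0.9}, default_config)
    assert labels["yfp_pos"] is None


# --------------------------------------------------------------------------
# region summaries


def _record(i, glyt2, syt12=False, yfp=False, region="r1"):
    return BoutonRecord(
        id=i, centroid_vox=(0, 0, 0), centroid_um=(0, 0, 0),
        scores={"syp_tdt": 0.9 if glyt2 == "pos" else 0.02,
                "syt12": 0.8 if syt12 else 0.02,
                "yfp": 0.8 if yfp else 0.02},
        n_included={}, labels={"glyt2": glyt2, "syt12_pos": syt12,
                               "yfp_pos": yfp},
        region_label=region,
    )


def test_homogeneous_region_fraction_is_one():
    records = [_record(i, "pos") for i in range(10)]
    summaries = summarize_regions(records)
    by_label = {s.region_label: s for s in summaries}
    assert by_label["r1"].fraction_glyt2_pos == 1.0
    assert by_label["all"].n_boutons == 10


def test_contingency_cells_sum_to_totals():
    records = [_record(0, "pos", syt12=True, yfp=False),
               _record(1, "neg", syt12=False, yfp=True),
               _record(2, "neg", syt12=False, yfp=True),
               _record(3, "pos", syt12=True, yfp=False)]
    s = {x.region_label: x for x in summarize_regions(records)}["all"]
    assert int(s.contingency_yfp_syt.to_numpy().sum()) == 4
    # constructed so no yfp-positive bouton is syt-positive
    if True in s.contingency_yfp_syt.index and True in s.contingency_yfp_syt.columns:
        assert int(s.contingency_yfp_syt.loc[True, True]) == 0


def test_region_label_override_requires_one_per_bouton():
    records = [_record(0, "pos")]
    with pytest.raises(ParameterError):
        summarize_regions(records, region_labels=["a", "b"])
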