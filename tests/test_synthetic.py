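"""Generator contracts: determinism, exact ground truth, mode differences."""

import numpy as np
import pytest
from skimage import measure

from leafseg import (GenerationError, SceneConfig, field_scene, generate_dataset,
                     generate_leaf_image, load_dataset, simple_scene)
from leafseg.synthetic import component_perimeter


def test_seeded_determinism_bitwise():
    cfg = simple_scene(size=64, seed=5)
    a = generate_leaf_image(cfg, 3)
    b = generate_leaf_image(cfg, 3)
    assert np.array_equal(a.image, b.image)
    assert np.array_equal(a.mask, b.mask)
    c = generate_leaf_image(cfg, 4)
    assert not np.array_equal(a.mask, c.mask) or not np.array_equal(a.image, c.image)


def test_no_lesion_config_yields_only_background_and_leaf():
    cfg = simple_scene(size=64, seed=1, lesion_count_range=(0, 0))
    s = generate_leaf_image(cfg, 0)
    assert set(np.unique(s.mask)) == {0, 1}
    assert s.meta["lesions"] == []


def test_round_spot_geometry_matches_rasterized_disk():
    # one disk lesion of radius 20 px: equivalent diameter ~40, area ~pi*400
    cfg = simple_scene(size=256, seed=1, class_set=("background", "leaf", "spot"),
                       morphology={"spot": "round_spot"},
                       lesion_count_range=(1, 1), lesion_radius_range=(20.0, 20.0))
    s = generate_leaf_image(cfg, 0)
    (rec,) = s.meta["lesions"]
    assert abs(rec["equivalent_diameter_px"] - 40.0) <= 1.0
    assert abs(rec["area_px"] - np.pi * 400) <= 0.03 * np.pi * 400
    # perimeter close to the true circumference 2*pi*20
    assert abs(rec["perimeter_px"] - 2 * np.pi * 20) <= 0.03 * 2 * np.pi * 20


def test_mask_and_meta_agree_exactly():
    cfg = field_scene(size=128, seed=9)
    s = generate_leaf_image(cfg, 2)
    for cid in range(2, len(cfg.class_set)):
        labeled = measure.label(s.mask == cid, connectivity=2)
        records = [r for r in s.meta["lesions"] if r["class_id"] == cid]
        assert labeled.max() == len(records)
        # per-lesion areas sum to the class pixel count exactly
        assert sum(r["area_px"] for r in records) == int((s.mask == cid).sum())
        # components match records one-to-one on area and centroid
        props = measure.regionprops(labeled)
        by_area = sorted([(p.area, p.centroid) for p in props])
        rec_sorted = sorted([(r["area_px"], tuple(r["centroid"])) for r in records])
        for (pa, pc), (ra, rc) in zip(by_area, rec_sorted):
            assert pa == ra
            assert np.hypot(pc[0] - rc[0], pc[1] - rc[1]) <= 0.5


def test_lesions_lie_strictly_inside_leaf_tissue():
    cfg = simple_scene(size=96, seed=21)
    for i in range(3):
        s = generate_leaf_image(cfg, i)
        lesion = s.mask >= 2
        assert not (lesion & (s.mask == 0)).any()
        # every lesion pixel was leaf before lesion painting: background untouched
        assert (s.mask[lesion] >= 2).all()


def test_dataset_manifest_and_roundtrip(tmp_path):
    cfg = simple_scene(size=64, seed=2)
    samples, manifest = generate_dataset(cfg, 10, out_dir=tmp_path)
    assert len(manifest) == 10
    loaded = load_dataset(tmp_path)
    assert len(loaded) == 10
    for s, l in zip(samples, loaded):
        assert np.array_equal(s.mask, l.mask)
        assert np.allclose(s.image, l.image)   # 8-bit quantised at generation
    # determinism of the manifest
    _, manifest2 = generate_dataset(cfg, 10)
    assert manifest.equals(manifest2)


def test_lesion_fraction_sampler_hits_requested_range():
    cfg = simple_scene(size=64, seed=77, lesion_area_fraction_range=(0.02, 0.10),
                       lesion_count_range=(1, 2))
    _, manifest = generate_dataset(cfg, 60)
    mean_frac = manifest["lesion_fraction"].mean()
    assert 0.02 <= mean_frac <= 0.10


def test_field_background_more_variable_than_simple():
    var_simple, var_field = [], []
    for i in range(50):
        s = generate_leaf_image(simple_scene(size=48, seed=101,
                                             lesion_count_range=(0, 0)), i)
        f = generate_leaf_image(field_scene(size=48, seed=101,
                                            lesion_count_range=(0, 0)), i)
        var_simple.append(s.image[s.mask == 0].var())
        var_field.append(f.image[f.mask == 0].var())
    assert np.mean(var_field) > np.mean(var_simple)


def test_impossible_placement_raises_generation_error():
    cfg = simple_scene(size=48, seed=0, lesion_radius_range=(40.0, 40.0),
                       class_set=("background", "leaf", "spot"),
                       morphology={"spot": "round_spot"}, lesion_count_range=(1, 1))
    with pytest.raises(GenerationError):
        generate_leaf_image(cfg, 0)


@pytest.mark.parametrize("bad", [
    dict(lesion_area_fraction_range=(0.0, 0.5)),
    dict(lesion_area_fraction_range=(0.6, 0.5)),
    dict(lesion_count_range=(3, 1)),
    dict(mode="studio"),
    dict(class_set=("background",)),
    dict(clutter_density=1.5),
    dict(n_leaves=0),
])
def test_invalid_configs_rejected(bad):
    with pytest.raises(ValueError):
        SceneConfig(**bad).validate()


def test_generate_dataset_rejects_nonpositive_n():
    with pytest.raises(ValueError):
        generate_dataset(simple_scene(size=64), 0)


def test_perimeter_estimator_on_analytic_disk():
    from skimage import draw
    comp = np.zeros((100, 100), bool)
    rr, cc = draw.disk((50, 50), 20, shape=comp.shape)
    comp[rr, cc] = True
    assert abs(component_perimeter(comp) - 2 * np.pi * 20) <= 0.03 * 2 * np.pi * 20
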