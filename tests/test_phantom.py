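import datetime as dt
import json

import numpy as np
import pytest
from scipy import ndimage

from lungcn.banding import split_bands
from lungcn.image_io import load_slice
from lungcn.network import build_network, compute_metrics
from lungcn.phantom import (
    LesionSpec,
    generate_slice,
    grow_lesions,
    honeycomb_cluster,
    honeycomb_lumen_mask,
    write_grid,
    write_manifest,
    write_mask,
)

SPACING = 0.4557


def band_layers(truth):
    return {layer.band.name: layer for layer in split_bands(truth.slice)}


def test_same_seed_is_bit_identical():
    kwargs = dict(
        shape=(48, 48),
        lesions=[LesionSpec("ggo_patch", (24, 24), 5.0, hu_sd=15.0)],
        seed=123,
    )
    a, b = generate_slice(**kwargs), generate_slice(**kwargs)
    assert np.array_equal(a.slice.values, b.slice.values)
    assert all(np.array_equal(x, y) for x, y in zip(a.lesion_masks, b.lesion_masks))


def test_different_seed_changes_noise():
    a = generate_slice(shape=(32, 32), seed=1)
    b = generate_slice(shape=(32, 32), seed=2)
    assert not np.array_equal(a.slice.values, b.slice.values)


def test_noise_free_background_band_membership():
    # default -880 HU parenchyma sits inside the GGO band
    truth = generate_slice(shape=(40, 40), background_hu=(-880, 0), seed=0)
    layers = band_layers(truth)
    assert layers["GGO"].pixel_count == int(truth.background_mask.sum())
    assert layers["E"].pixel_count == 0
    # clean mode: -1000 HU puts the whole field in band E
    clean = generate_slice(shape=(40, 40), background_hu=(-1000, 0), seed=0)
    assert band_layers(clean)["E"].pixel_count == int(clean.background_mask.sum())


def test_consolidation_disk_area_matches_analytic():
    d_mm = 5.0
    truth = generate_slice(
        shape=(64, 64),
        background_hu=(-880, 0),
        lesions=[LesionSpec("consolidation_disk", (32, 32), d_mm)],
        seed=0,
    )
    layers = band_layers(truth)
    r_px = (d_mm / 2) / SPACING
    analytic = np.pi * r_px**2
    boundary = 2 * np.pi * r_px + 4  # 1 px rasterization tolerance on the rim
    assert abs(layers["C"].pixel_count - analytic) <= boundary
    assert layers["C"].pixel_count == int(truth.lesion_masks[0].sum())


def test_soft_tissue_border_outside_lung_field():
    truth = generate_slice(shape=(40, 40), background_hu=(-880, 0), seed=0)
    assert np.all(truth.slice.values[~truth.background_mask] == 40)


def test_lesion_outside_lung_field_warns_and_clips():
    with pytest.warns(UserWarning, match="clipped"):
        truth = generate_slice(
            shape=(40, 40),
            lesions=[LesionSpec("consolidation_disk", (2, 2), 6.0)],
            seed=0,
        )
    assert np.all(truth.lesion_masks[0] <= truth.background_mask)


def test_grow_zero_is_identity_on_masks():
    truth = generate_slice(
        shape=(48, 48),
        lesions=[LesionSpec("ggo_patch", (24, 24), 5.0)],
        seed=5,
    )
    grown = grow_lesions(truth, annual_growth=0.0, t_years=1.0, seed=6)
    assert np.array_equal(grown.lesion_masks[0], truth.lesion_masks[0])
    assert grown.slice.acquisition_date == truth.slice.acquisition_date + dt.timedelta(days=365)


def test_growth_scales_area_quadratically():
    truth = generate_slice(
        shape=(96, 96),
        lesions=[LesionSpec("ggo_patch", (48, 48), 4.0)],
        seed=5,
    )
    grown = grow_lesions(truth, annual_growth=1.0, t_years=1.0, seed=6)
    a0 = truth.lesion_masks[0].sum()
    a1 = grown.lesion_masks[0].sum()
    assert a1 == pytest.approx(4 * a0, rel=0.25)  # rasterization tolerance

    shrunk = grow_lesions(truth, annual_growth=-0.5, t_years=1.0, seed=7)
    assert shrunk.lesions[0].size_mm == pytest.approx(2.0)


def test_growth_rejects_invalid_rate():
    truth = generate_slice(shape=(16, 16), seed=0)
    with pytest.raises(ValueError):
        grow_lesions(truth, annual_growth=-1.0, t_years=1.0, seed=1)


@pytest.mark.parametrize(
    "kind,band",
    [
        ("emphysema_blob", "E"),
        ("ggo_patch", "GGO"),
        ("consolidation_disk", "C"),
        ("reticulation_line", "C"),
        ("nodule_string", "C"),
    ],
)
def test_band_fidelity_under_mild_noise(kind, band):
    """With noise sd <= 10, >= 99 % of lesion pixels land in the intended band."""
    truth = generate_slice(
        shape=(80, 80),
        background_hu=(-880, 10),
        lesions=[LesionSpec(kind, (40, 40), 8.0, hu_sd=10.0)],
        seed=17,
    )
    mask = truth.lesion_masks[0]
    layer = band_layers(truth)[band]
    in_band = np.zeros(truth.slice.shape, dtype=bool)
    in_band[layer.rows, layer.cols] = True
    assert mask.sum() > 0
    assert (in_band & mask).sum() >= 0.99 * mask.sum()


def test_doubling_area_increases_total_count():
    base = generate_slice(
        shape=(96, 96),
        background_hu=(-880, 0),
        lesions=[LesionSpec("consolidation_disk", (48, 48), 4.0)],
        seed=0,
    )
    double_area = generate_slice(
        shape=(96, 96),
        background_hu=(-880, 0),
        lesions=[LesionSpec("consolidation_disk", (48, 48), 4.0 * np.sqrt(2))],
        seed=0,
    )
    m0 = compute_metrics(build_network(band_layers(base)["C"]))
    m1 = compute_metrics(build_network(band_layers(double_area)["C"]))
    assert m1.total_count > m0.total_count


def test_honeycomb_lumina_inside_walls():
    spec = honeycomb_cluster((40, 40), n_cysts=1, cyst_diameter_mm=4.0)
    truth = generate_slice(
        shape=(80, 80), background_hu=(-880, 0), lesions=[spec], seed=0
    )
    layers = band_layers(truth)
    e_px = set(zip(layers["E"].rows.tolist(), layers["E"].cols.tolist()))
    c_px = set(zip(layers["C"].rows.tolist(), layers["C"].cols.tolist()))
    assert e_px and c_px
    # every lumen pixel has a wall pixel further from the centre on its row
    center = (40, 40)
    lumen_r = max(abs(r - center[0]) + abs(c - center[1]) for r, c in e_px)
    wall_r = max(abs(r - center[0]) + abs(c - center[1]) for r, c in c_px)
    assert wall_r > lumen_r


def test_honeycomb_seven_connected_lumina():
    spec = honeycomb_cluster((64, 64), n_cysts=7, cyst_diameter_mm=3.0)
    truth = generate_slice(
        shape=(128, 128), background_hu=(-880, 0), lesions=[spec], seed=0
    )
    lumina = honeycomb_lumen_mask(truth, 0)
    n_components = ndimage.label(lumina, structure=np.ones((3, 3)))[1]
    assert n_components == 7


def test_honeycomb_wall_denser_than_nodule_string():
    """Cyst walls form contiguous curves: higher mean degree than a string of
    separated nodules with a comparable pixel count."""
    wall = generate_slice(
        shape=(96, 96),
        background_hu=(-880, 0),
        lesions=[honeycomb_cluster((48, 48), n_cysts=3, cyst_diameter_mm=5.0)],
        seed=0,
    )
    string = generate_slice(
        shape=(96, 96),
        background_hu=(-880, 0),
        lesions=[LesionSpec("nodule_string", (48, 48), 30.0)],
        seed=0,
    )
    avg_wall = compute_metrics(build_network(band_layers(wall)["C"])).average_count
    avg_string = compute_metrics(build_network(band_layers(string)["C"])).average_count
    assert avg_wall > avg_string


def test_three_mm_ggo_lesion_detectable():
    """A 3 mm circular GGO lesion on an out-of-band background yields a
    non-empty GGO network at the study pixel spacing."""
    truth = generate_slice(
        shape=(64, 64),
        background_hu=(-1000, 0),
        lesions=[LesionSpec("ggo_patch", (32, 32), 3.0)],
        seed=0,
    )
    graph = build_network(band_layers(truth)["GGO"])
    assert graph.edge_count >= 1


def test_lesion_spec_validation():
    with pytest.raises(ValueError):
        LesionSpec("unknown_kind", (0, 0), 1.0)
    with pytest.raises(ValueError):
        LesionSpec("cyst", (0, 0), -1.0)
    with pytest.raises(ValueError):
        LesionSpec("cyst", (0, 0), 1.0, hu_sd=-1)
    with pytest.raises(ValueError):
        honeycomb_cluster((0, 0), n_cysts=0, cyst_diameter_mm=3.0)


def test_outputs_round_trip(tmp_path):
    truth = generate_slice(
        shape=(24, 24),
        lesions=[LesionSpec("ggo_patch", (12, 12), 3.0)],
        seed=9,
    )
    write_grid(truth, tmp_path / "slice.txt")
    write_mask(truth.lesion_masks[0], tmp_path / "mask.txt")
    write_manifest(truth, tmp_path / "manifest.json")

    assert np.array_equal(load_slice(tmp_path / "slice.txt").values, truth.slice.values)
    mask = np.loadtxt(tmp_path / "mask.txt").astype(bool)
    assert np.array_equal(mask, truth.lesion_masks[0])
    manifest = json.loads((tmp_path / "manifest.json").read_text())
    assert manifest["seed"] == 9
    assert manifest["lesions"][0]["kind"] == "ggo_patch"
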