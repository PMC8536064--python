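"""Delivery-score surface: validation, bilinear interpolation, second screen."""

import json

import numpy as np
import pandas as pd
import pytest

from pepscreen import (
    DeliveryScoreSurface,
    SyntheticConfig,
    delivery_score,
    gen_surface,
    load_surface,
    render_map,
    save_surface,
    second_screen,
)
from pepscreen.delivery import SurfaceFormatError


@pytest.fixture
def small_surface():
    return DeliveryScoreSurface(
        hydro_axis=[0.0, 1.0],
        pi_axis=[0.0, 2.0],
        scores=[[10.0, 30.0], [50.0, 70.0]],
    )


def test_surface_round_trip(tmp_path):
    surface = gen_surface(SyntheticConfig(seed=2))
    path = tmp_path / "surface.json"
    save_surface(surface, path)
    back = load_surface(path)
    assert np.array_equal(back.scores, surface.scores)
    assert np.array_equal(back.hydro_axis, surface.hydro_axis)
    assert back.hydro_scale == surface.hydro_scale


def test_surface_rejects_repeated_axis_value():
    with pytest.raises(SurfaceFormatError, match="increasing"):
        DeliveryScoreSurface(
            hydro_axis=[0.0, 0.0], pi_axis=[0.0, 1.0],
            scores=[[1.0, 2.0], [3.0, 4.0]],
        )


def test_load_surface_rejects_ragged_grid(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text(json.dumps({
        "hydro_axis": [0, 1], "pi_axis": [0, 1],
        "scores": [[1, 2], [3]],
    }))
    with pytest.raises(SurfaceFormatError, match="row 1"):
        load_surface(path)


def test_surface_rejects_shape_mismatch():
    with pytest.raises(SurfaceFormatError, match="shape"):
        DeliveryScoreSurface(
            hydro_axis=[0.0, 1.0, 2.0], pi_axis=[0.0, 1.0],
            scores=[[1.0, 2.0], [3.0, 4.0]],
        )


def test_interpolation_identity_at_nodes(small_surface):
    for i, h in enumerate(small_surface.hydro_axis):
        for j, p in enumerate(small_surface.pi_axis):
            assert delivery_score(small_surface, h, p) == pytest.approx(
                small_surface.scores[i, j]
            )


def test_interpolation_cell_midpoint_is_corner_mean(small_surface):
    assert delivery_score(small_surface, 0.5, 1.0) == pytest.approx(
        (10 + 30 + 50 + 70) / 4
    )


def _bilinear_oracle(surface, h, p):
    """Independent textbook bilinear formula."""
    hx, px, z = surface.hydro_axis, surface.pi_axis, surface.scores
    i = np.searchsorted(hx, h, side="right") - 1
    i = min(max(i, 0), len(hx) - 2)
    j = np.searchsorted(px, p, side="right") - 1
    j = min(max(j, 0), len(px) - 2)
    t = (h - hx[i]) / (hx[i + 1] - hx[i])
    u = (p - px[j]) / (px[j + 1] - px[j])
    return (
        z[i, j] * (1 - t) * (1 - u)
        + z[i + 1, j] * t * (1 - u)
        + z[i, j + 1] * (1 - t) * u
        + z[i + 1, j + 1] * t * u
    )


def test_interpolation_matches_brute_force_bilinear():
    surface = gen_surface(SyntheticConfig(seed=6))
    rng = np.random.default_rng(0)
    h = rng.uniform(surface.hydro_axis[0], surface.hydro_axis[-1], 1000)
    p = rng.uniform(surface.pi_axis[0], surface.pi_axis[-1], 1000)
    got = delivery_score(surface, h, p)
    want = np.array([_bilinear_oracle(surface, hi, pi) for hi, pi in zip(h, p)])
    assert np.allclose(got, want, atol=1e-9)


def test_interpolation_bounded_by_enclosing_nodes(small_surface):
    rng = np.random.default_rng(1)
    for _ in range(100):
        h, p = rng.uniform(0, 1), rng.uniform(0, 2)
        v = delivery_score(small_surface, h, p)
        assert 10.0 - 1e-12 <= v <= 70.0 + 1e-12


def test_out_of_hull_queries_clamp_to_corners(small_surface):
    assert delivery_score(small_surface, -100, -100) == pytest.approx(10.0)
    assert delivery_score(small_surface, 100, 100) == pytest.approx(70.0)
    assert delivery_score(small_surface, -100, 100) == pytest.approx(30.0)


def test_nonfinite_coordinates_rejected(small_surface):
    with pytest.raises(ValueError):
        delivery_score(small_surface, float("nan"), 1.0)


def _candidates(hydros, pis):
    return pd.DataFrame({
        "peptide": [f"P{i}" for i in range(len(hydros))],
        "mean_hydrophobicity": hydros,
        "mean_pi": pis,
    })


def test_second_screen_threshold_is_strict():
    flat = DeliveryScoreSurface(
        hydro_axis=[0, 1], pi_axis=[0, 1], scores=[[50.0, 50.0], [50.0, 50.0]]
    )
    out = second_screen(_candidates([0.5], [0.5]), flat, threshold=50.0)
    assert len(out) == 0


@pytest.mark.parametrize("level,expected", [(60.0, 3), (40.0, 0)])
def test_second_screen_constant_surfaces(level, expected):
    flat = DeliveryScoreSurface(
        hydro_axis=[0, 1], pi_axis=[0, 1], scores=[[level] * 2] * 2
    )
    out = second_screen(_candidates([0.1, 0.5, 0.9], [0.2, 0.5, 0.8]), flat)
    assert len(out) == expected


def test_second_screen_monotone_in_threshold():
    surface = gen_surface(SyntheticConfig(seed=10))
    rng = np.random.default_rng(3)
    cand = _candidates(rng.uniform(-4, 4, 200), rng.uniform(3, 10, 200))
    low = second_screen(cand, surface, threshold=30.0)
    high = second_screen(cand, surface, threshold=70.0)
    assert set(high["peptide"]) <= set(low["peptide"])


def test_second_screen_selects_low_pi_under_corner_peaked_surface():
    """A surface peaked at high hydrophobicity / low pI pulls the finalist
    pool toward lower pI than the candidate pool."""
    surface = gen_surface(SyntheticConfig(seed=4))
    rng = np.random.default_rng(5)
    cand = _candidates(rng.uniform(-4, 4, 500), rng.uniform(3, 10, 500))
    finalists = second_screen(cand, surface, threshold=50.0)
    assert 0 < len(finalists) < len(cand)
    assert finalists["mean_pi"].mean() < cand["mean_pi"].mean()


def test_render_map_writes_image(tmp_path):
    surface = gen_surface(SyntheticConfig(seed=1))
    peptides = pd.DataFrame({
        "peptide": ["ACDEFG"] * 10,
        "mean_hydrophobicity": np.linspace(-2, 2, 10),
        "mean_pi": np.linspace(4, 8, 10),
    })
    path = tmp_path / "map.png"
    render_map(surface, peptides, 6, path)
    assert path.stat().st_size > 0

    empty = tmp_path / "empty.png"
    render_map(surface, peptides.iloc[0:0], 6, empty)
    assert empty.stat().st_size > 0


def test_render_map_rejects_mixed_lengths(tmp_path):
    surface = gen_surface(SyntheticConfig(seed=1))
    peptides = pd.DataFrame({
        "peptide": ["ACDE", "ACDEFG"],
        "mean_hydrophobicity": [0.0, 0.0],
        "mean_pi": [6.0, 6.0],
    })
    with pytest.raises(ValueError):
        render_map(surface, peptides, 4, tmp_path / "bad.png")
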