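"""Stimulus geometry: tessellation, projection and cue-conflict construction."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

from cuefusion import (GeometryError, InvalidSpecificationError, PlaneSpec,
                       ViewingGeometry, make_dot_pattern, make_stimulus_pair,
                       make_texture_tiles, pair_centers,
                       project_conflict_stimulus, project_stereo)
from cuefusion.geometry import backproject_to_plane, plane_points_3d


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_project(point3d, eye, distance):
    """Brute-force ray/screen-plane intersection: solve E + s(P-E), z = 0."""
    p = np.asarray(point3d, dtype=float)
    e = np.asarray(eye, dtype=float)
    s = np.roots([p[2] - e[2], e[2]])  # e_z + s (p_z - e_z) = 0
    s = float(s[0])
    hit = e + s * (p - e)
    assert abs(hit[2]) < 1e-12
    return hit[:2]


def oracle_triangulate(left_xy, right_xy, geom):
    """Least-squares intersection of the two eye rays through screen points."""
    def ray(eye, screen):
        d = np.array([screen[0] - eye[0], screen[1] - eye[1], -eye[2]])
        return eye, d / np.linalg.norm(d)

    e1, d1 = ray(geom.left_eye, left_xy)
    e2, d2 = ray(geom.right_eye, right_xy)
    # solve min |e1 + t1 d1 - (e2 + t2 d2)|^2
    A = np.column_stack([d1, -d2])
    t = np.linalg.lstsq(A, e2 - e1, rcond=None)[0]
    p1, p2 = e1 + t[0] * d1, e2 + t[1] * d2
    return (p1 + p2) / 2


# ---------------------------------------------------------------------------
# texture tiles
# ---------------------------------------------------------------------------

def test_zero_jitter_tiles_are_unit_squares():
    disc = PlaneSpec()
    pat = make_texture_tiles(disc, seed=0, jitter_range=0.0)
    # a generator well inside the disc owns an exact 1 cm^2 square cell
    interior = [t for g, t in zip(pat.generators, pat.tiles)
                if g[0] ** 2 + g[1] ** 2 < 4 ** 2]
    assert interior
    for tile in interior:
        assert len(tile) == 4
        ext = tile.max(axis=0) - tile.min(axis=0)
        np.testing.assert_allclose(ext, [1.0, 1.0], atol=1e-9)


def test_generator_count_matches_ellipse_enumeration():
    disc = PlaneSpec(length_ratio=1.25)
    a, b = disc.semi_axes
    pat = make_texture_tiles(disc, seed=0, jitter_range=0.0)
    inside = sum(1 for g in pat.generators if g[0]**2 / a**2 + g[1]**2 / b**2 <= 1)
    # brute-force enumeration of integer grid nodes inside the ellipse
    brute = sum(1 for u in range(-20, 21) for v in range(-20, 21)
                if u**2 / a**2 + v**2 / b**2 <= 1)
    assert inside == brute
    assert abs(brute - math.pi * a * b) / (math.pi * a * b) < 0.05


def test_tiles_partition_disc_area():
    disc = PlaneSpec()
    pat = make_texture_tiles(disc, seed=3)
    from shapely.geometry import Polygon
    total = sum(Polygon(t).area for t in pat.tiles)
    a, b = disc.semi_axes
    # the disc outline is a fine polygonal approximation of the ellipse,
    # so the summed tile area matches pi*a*b to the chord deficit only
    assert abs(total - math.pi * a * b) < 5e-4 * math.pi * a * b


def test_texture_determinism_and_jitter_bound():
    disc = PlaneSpec()
    p1 = make_texture_tiles(disc, seed=42)
    p2 = make_texture_tiles(disc, seed=42)
    assert len(p1.tiles) == len(p2.tiles)
    for t1, t2 in zip(p1.tiles, p2.tiles):
        np.testing.assert_array_equal(t1, t2)
    # every generator lies within +/-jitter of its grid node per axis
    off = p1.generators - np.round(p1.generators)
    assert np.all(np.abs(off) <= p1.jitter_range + 1e-12)


def test_degenerate_disc_rejected():
    with pytest.raises(InvalidSpecificationError):
        PlaneSpec(width=0.0)


# ---------------------------------------------------------------------------
# dot patterns
# ---------------------------------------------------------------------------

def test_zero_jitter_dots_are_grid_nodes(geom):
    disc = PlaneSpec()
    pat = make_dot_pattern(disc, geom, seed=0, jitter_range=0.0)
    np.testing.assert_allclose(pat.dots, np.round(pat.dots), atol=1e-9)
    assert len(pat.dots) > 50


def test_dot_determinism(geom):
    disc = PlaneSpec()
    d1 = make_dot_pattern(disc, geom, seed=9)
    d2 = make_dot_pattern(disc, geom, seed=9)
    np.testing.assert_array_equal(d1.dots, d2.dots)


def test_dot_screen_density_uniform(geom):
    """Pooled over 100 seeds, dot counts in equal-area central bins do not
    reject uniformity (the screen image carries no texture gradient)."""
    disc = PlaneSpec()
    edges = np.linspace(-4, 4, 5)  # 4x4 bins of 2x2 cm well inside the disc
    counts = np.zeros((4, 4))
    for seed in range(100):
        pat = make_dot_pattern(disc, geom, seed=seed)
        h, _, _ = np.histogram2d(pat.dots[:, 0], pat.dots[:, 1], bins=[edges, edges])
        counts += h
    stat, p = chisquare(counts.ravel())
    assert p > 0.01


# ---------------------------------------------------------------------------
# stereo projection
# ---------------------------------------------------------------------------

def test_screen_plane_points_have_zero_disparity(geom, rng):
    pts = np.column_stack([rng.uniform(-10, 10, 20), rng.uniform(-10, 10, 20),
                           np.zeros(20)])
    proj = project_stereo(pts, geom)
    np.testing.assert_allclose(proj.left_eye, proj.right_eye, atol=1e-12)
    np.testing.assert_allclose(proj.left_eye, pts[:, :2], atol=1e-12)


@pytest.mark.parametrize("depth", [2.0, 10.0, -10.0, 40.0])
def test_on_axis_disparity_matches_ray_oracle(geom, depth):
    pt = np.array([[0.0, 0.0, depth]])
    proj = project_stereo(pt, geom)
    left = oracle_project(pt[0], geom.left_eye, geom.viewing_distance)
    right = oracle_project(pt[0], geom.right_eye, geom.viewing_distance)
    np.testing.assert_allclose(proj.left_eye[0], left, atol=1e-9)
    np.testing.assert_allclose(proj.right_eye[0], right, atol=1e-9)
    # closed-form horizontal disparity i*d/(D-d)
    i, D = geom.interocular_distance, geom.viewing_distance
    expected = i * depth / (D - depth)
    assert abs((proj.left_eye[0, 0] - proj.right_eye[0, 0]) - expected) < 1e-9


def test_depth_sign_flip_flips_disparity(geom, rng):
    pts = np.column_stack([rng.uniform(-10, 10, 30), rng.uniform(-10, 10, 30),
                           rng.uniform(1, 20, 30)])
    d_pos = project_stereo(pts, geom)
    pts_neg = pts * np.array([1, 1, -1])
    d_neg = project_stereo(pts_neg, geom)
    disp_pos = d_pos.left_eye[:, 0] - d_pos.right_eye[:, 0]
    disp_neg = d_neg.left_eye[:, 0] - d_neg.right_eye[:, 0]
    assert np.all(np.sign(disp_pos) == -np.sign(disp_neg))


def test_point_behind_eye_raises(geom):
    with pytest.raises(GeometryError):
        project_stereo(np.array([[0.0, 0.0, 200.0]]), geom)


# ---------------------------------------------------------------------------
# cue-conflict construction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("slant", [-30.0, 0.0, 25.0, 57.5])
@pytest.mark.parametrize("seed", [0, 7])
def test_zero_conflict_equals_direct_projection(geom, slant, seed):
    """Equal texture and disparity slants reduce to plain stereo projection."""
    disc = PlaneSpec(slant_texture=slant, slant_disparity=slant)
    pat = make_texture_tiles(disc, seed=seed)
    conflict = project_conflict_stimulus(disc, pat, geom)
    uv = np.concatenate(pat.tiles)
    direct = project_stereo(plane_points_3d(uv, disc, slant), geom,
                            conflict.element_sizes)
    assert np.max(np.abs(conflict.left_eye - direct.left_eye)) < 1e-9
    assert np.max(np.abs(conflict.right_eye - direct.right_eye)) < 1e-9


def test_monocular_image_invariant_to_disparity_slant(geom):
    """The cyclopean image (midpoint of the two eyes' views) depends only on
    the texture-specified slant."""
    base = PlaneSpec(slant_texture=45.0, slant_disparity=45.0)
    alt = PlaneSpec(slant_texture=45.0, slant_disparity=20.0)
    pat = make_texture_tiles(base, seed=5)
    pa = project_conflict_stimulus(base, pat, geom)
    pb = project_conflict_stimulus(alt, pat, geom)
    cyc_a = (pa.left_eye + pa.right_eye) / 2
    cyc_b = (pb.left_eye + pb.right_eye) / 2
    assert np.max(np.abs(cyc_a - cyc_b)) < 1e-9


@pytest.mark.parametrize("slant_disp", [20.0, 45.0, 57.5])
def test_triangulated_depths_recover_disparity_slant(geom, slant_disp):
    """Triangulating left/right dots recovers the disparity-specified plane."""
    disc = PlaneSpec(slant_texture=45.0, slant_disparity=slant_disp)
    pat = make_dot_pattern(disc, geom, seed=11)
    proj = project_conflict_stimulus(disc, pat, geom)
    world = np.array([oracle_triangulate(l, r, geom)
                      for l, r in zip(proj.left_eye, proj.right_eye)])
    # plane slanted about the x-axis satisfies z = z0 + y tan(slant)
    A = np.column_stack([np.ones(len(world)), world[:, 1]])
    coef, *_ = np.linalg.lstsq(A, world[:, 2], rcond=None)
    resid = world[:, 2] - A @ coef
    assert np.max(np.abs(resid)) < 1e-6
    recovered = math.degrees(math.atan(coef[1]))
    assert abs(recovered - slant_disp) < 0.01
    assert abs(coef[0] - disc.depth_offset) < 1e-6


def test_texture_foreshortening_follows_cosine():
    """The projected extent of a central probe along the slant axis shrinks
    by cos(slant) relative to the frontoparallel case."""
    geom = ViewingGeometry()
    probe = np.array([[0.0, -0.5], [0.0, 0.5]])
    extents = {}
    for slant in (0.0, 30.0, 60.0):
        disc = PlaneSpec(slant_texture=slant, slant_disparity=slant,
                         depth_offset=1e-9)
        w = plane_points_3d(probe, disc, slant)
        scr = np.array([oracle_project(p, geom.cyclopean_eye,
                                       geom.viewing_distance) for p in w])
        extents[slant] = scr[1, 1] - scr[0, 1]
    for slant in (30.0, 60.0):
        ratio = extents[slant] / extents[0.0]
        assert abs(ratio - math.cos(math.radians(slant))) < 0.01


def test_backprojection_parallel_ray_raises(geom):
    disc = PlaneSpec(slant_disparity=89.0, depth_offset=0.0)
    # a screen point whose cyclopean ray runs (nearly) along the plane
    ray_slope = math.degrees(math.atan2(geom.viewing_distance, 0.0))
    steep = PlaneSpec(slant_disparity=0.0, depth_offset=0.0)
    with pytest.raises(GeometryError):
        # plane rotated to contain the viewing axis: force denominator ~ 0
        backproject_to_plane(np.array([[0.0, geom.viewing_distance * 1e13, 0.0]]),
                             disc, 89.999999999, geom)


# ---------------------------------------------------------------------------
# pair layout / export
# ---------------------------------------------------------------------------

def test_pair_spans_display_width(geom):
    xl, xr = pair_centers(geom)
    span = (xr + 8) - (xl - 8)
    expected = 2 * geom.viewing_distance * math.tan(math.radians(geom.display_width / 2))
    assert abs(span - expected) < 1e-9


def test_stimulus_pair_roles_and_conflict(geom, rng):
    discs = make_stimulus_pair("T+D-", "different", geom, rng)
    assert {d["role"] for d in discs} == {"standard", "comparison"}
    cmp_spec = next(d["spec"] for d in discs if d["role"] == "comparison")
    assert cmp_spec.slant_texture == 45.0 + 12.5
    assert cmp_spec.slant_disparity == 45.0 - 12.5
    std_spec = next(d["spec"] for d in discs if d["role"] == "standard")
    assert std_spec.slant_texture == std_spec.slant_disparity == 45.0
    assert {d["spec"].side for d in discs} == {"left", "right"}
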