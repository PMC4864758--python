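"""Slanted-disc stimulus geometry and two-eye projection.

Stimuli are pairs of elliptical discs slanted in depth, defined by a texture
of Voronoi tiles (carrying a foreshortening gradient) or by dots of uniform
screen density (carrying only binocular disparity).  Cue-conflict stimuli are
constructed by reprojection: the one-eye (cyclopean) image is rendered from a
plane at the texture-specified slant, and each image point is then assigned
the depth of a plane at the disparity-specified slant along its cyclopean
ray, so the texture gradient and the disparity field signal different slants.

Coordinate convention (right-handed, all lengths in cm): origin at the screen
centre, x rightward, y upward, z toward the viewer.  The eyes sit at
z = viewing_distance, x = +/- interocular_distance / 2, and the screen is the
plane z = 0.  Disc slant is a rotation of the plane about its horizontal axis,
in degrees from frontoparallel; positive slant tips the top of the disc
toward the viewer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

from .exceptions import GeometryError, InvalidSpecificationError

__all__ = [
    "ViewingGeometry",
    "PlaneSpec",
    "TexturePattern",
    "DotPattern",
    "StereoProjection",
    "make_texture_tiles",
    "make_dot_pattern",
    "project_stereo",
    "project_conflict_stimulus",
    "pair_centers",
    "make_stimulus_pair",
    "stimulus_pair_to_json",
    "projection_to_svg",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ViewingGeometry:
    """Observer-screen layout.

    Parameters
    ----------
    viewing_distance : float
        Eye-to-screen distance in cm.
    interocular_distance : float
        Eye separation in cm; scales all disparities.
    display_width : float
        Total horizontal extent of the stimulus pair in degrees of visual
        angle.
    """

    viewing_distance: float = 175.0
    interocular_distance: float = 6.2
    display_width: float = 13.0

    def __post_init__(self):
        if self.viewing_distance <= 0:
            raise InvalidSpecificationError("viewing_distance must be > 0")
        if self.interocular_distance <= 0:
            raise InvalidSpecificationError("interocular_distance must be > 0")
        if not 0 < self.display_width < 90:
            raise InvalidSpecificationError("display_width must be in (0, 90) deg")

    @property
    def left_eye(self) -> np.ndarray:
        return np.array([-self.interocular_distance / 2, 0.0, self.viewing_distance])

    @property
    def right_eye(self) -> np.ndarray:
        return np.array([+self.interocular_distance / 2, 0.0, self.viewing_distance])

    @property
    def cyclopean_eye(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.viewing_distance])


@dataclass(frozen=True)
class PlaneSpec:
    """One slanted disc: an ellipse of the given width whose texture-specified
    and disparity-specified slants may differ (cue conflict)."""

    width: float = 16.0
    length_ratio: float = 1.0
    slant_texture: float = 45.0
    slant_disparity: float = 45.0
    depth_offset: float = 10.0
    side: str = "left"
    center_x: float = 0.0

    def __post_init__(self):
        if self.width <= 0:
            raise InvalidSpecificationError("disc width must be > 0")
        if not 1.0 <= self.length_ratio <= 1.5:
            raise InvalidSpecificationError("length_ratio must be in [1, 1.5]")
        for s in (self.slant_texture, self.slant_disparity):
            if not -90 < s < 90:
                raise InvalidSpecificationError("slants must be in (-90, 90) deg")
        if self.side not in ("left", "right"):
            raise InvalidSpecificationError("side must be 'left' or 'right'")

    @property
    def semi_axes(self) -> tuple[float, float]:
        """(horizontal, in-plane vertical) semi-axes of the disc outline, cm."""
        return self.width / 2, self.width / 2 * self.length_ratio


@dataclass(frozen=True)
class TexturePattern:
    """Voronoi tiles in the plane's own 2D frame, clipped to the disc."""

    tiles: list  # list of (k_i, 2) float arrays, vertices in plane cm
    generators: np.ndarray  # (n, 2) jittered grid nodes, one per tile
    grid_spacing: float = 1.0
    jitter_range: float = 0.225


@dataclass(frozen=True)
class DotPattern:
    """Dots at uniform density in the screen frame (no texture gradient)."""

    dots: np.ndarray  # (n, 2) screen coordinates, cm
    outline: np.ndarray  # (m, 2) screen outline of the disc, cm
    grid_spacing: float = 1.0
    jitter_range: float = 1.5


@dataclass(frozen=True)
class StereoProjection:
    """Left- and right-eye screen coordinates sharing one element topology.

    ``element_sizes`` gives the vertex count of each polygon in order; it is
    ``None`` for dot stimuli, where every row is an independent dot.
    """

    left_eye: np.ndarray
    right_eye: np.ndarray
    element_sizes: tuple | None = None

    def elements(self, eye: str = "left"):
        pts = self.left_eye if eye == "left" else self.right_eye
        if self.element_sizes is None:
            return [pts]
        out, i = [], 0
        for k in self.element_sizes:
            out.append(pts[i:i + k])
            i += k
        return out


# --------------------------------------------------------------------------
# patterns
# --------------------------------------------------------------------------

def _ellipse_polygon(a: float, b: float, n: int = 256) -> Polygon:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polygon(np.column_stack([a * np.cos(th), b * np.sin(th)]))


def _jittered_grid(xlim, ylim, spacing, jitter, rng):
    xs = np.arange(math.floor(xlim[0] / spacing), math.ceil(xlim[1] / spacing) + 1) * spacing
    ys = np.arange(math.floor(ylim[0] / spacing), math.ceil(ylim[1] / spacing) + 1) * spacing
    gx, gy = np.meshgrid(xs, ys)
    nodes = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    if jitter > 0:
        nodes = nodes + rng.uniform(-jitter, jitter, size=nodes.shape)
    return nodes


def make_texture_tiles(disc: PlaneSpec, seed: int, *, grid_spacing: float = 1.0,
                       jitter_range: float = 0.225) -> TexturePattern:
    """Voronoi tiles around a jittered cm grid, clipped to the disc ellipse.

    The jitter is uniform on [-jitter_range, +jitter_range] per axis; with
    zero jitter the interior tiles are exact unit squares.  Deterministic for
    a fixed (disc, seed).
    """
    a, b = disc.semi_axes
    rng = np.random.default_rng(seed)
    margin = 2 * grid_spacing + jitter_range
    nodes = _jittered_grid((-a - margin, a + margin), (-b - margin, b + margin),
                           grid_spacing, jitter_range, rng)
    ellipse = _ellipse_polygon(a, b)
    cells = shapely.voronoi_polygons(shapely.multipoints(nodes), ordered=True)
    tiles, gens = [], []
    for node, cell in zip(nodes, cells.geoms):
        clipped = cell.intersection(ellipse)
        if clipped.is_empty or clipped.area < 1e-12:
            continue
        if clipped.geom_type == "MultiPolygon":  # rare sliver split at boundary
            clipped = max(clipped.geoms, key=lambda g: g.area)
        tiles.append(np.asarray(clipped.exterior.coords[:-1], dtype=float))
        gens.append(node)
    return TexturePattern(tiles=tiles, generators=np.asarray(gens),
                          grid_spacing=grid_spacing, jitter_range=jitter_range)


def make_dot_pattern(disc: PlaneSpec, geometry: ViewingGeometry, seed: int, *,
                     grid_spacing: float = 1.0, jitter_range: float = 1.5) -> DotPattern:
    """Dots on a jittered cm grid laid out directly in the screen frame.

    Because the dots are generated in image coordinates and only later
    assigned depths by back-projection (see :func:`project_conflict_stimulus`),
    their projected density is statistically uniform and carries no slant
    information; only their disparities do.  The disc outline is the cyclopean
    projection of the ellipse at the texture-specified slant so that the
    monocular image is independent of the disparity manipulation.
    """
    rng = np.random.default_rng(seed)
    a, b = disc.semi_axes
    th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    rim_uv = np.column_stack([a * np.cos(th), b * np.sin(th)])
    rim3d = plane_points_3d(rim_uv, disc, disc.slant_texture)
    outline = _project_from_eye(rim3d, geometry.cyclopean_eye, geometry.viewing_distance)
    poly = Polygon(outline)
    xmin, ymin, xmax, ymax = poly.bounds
    pad = grid_spacing + jitter_range
    dots = _jittered_grid((xmin - pad, xmax + pad), (ymin - pad, ymax + pad),
                          grid_spacing, jitter_range, rng)
    inside = shapely.contains_xy(poly, dots[:, 0], dots[:, 1])
    return DotPattern(dots=dots[inside], outline=outline,
                      grid_spacing=grid_spacing, jitter_range=jitter_range)


# --------------------------------------------------------------------------
# projection
# --------------------------------------------------------------------------

def plane_points_3d(uv: np.ndarray, disc: PlaneSpec, slant_deg: float) -> np.ndarray:
    """Lift plane-frame 2D points onto the disc's plane at the given slant."""
    uv = np.atleast_2d(np.asarray(uv, dtype=float))
    s = math.radians(slant_deg)
    return np.column_stack([
        disc.center_x + uv[:, 0],
        uv[:, 1] * math.cos(s),
        disc.depth_offset + uv[:, 1] * math.sin(s),
    ])


def _project_from_eye(points3d: np.ndarray, eye: np.ndarray, distance: float) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points3d, dtype=float))
    z = pts[:, 2]
    if np.any(z >= distance - 1e-9):
        raise GeometryError("point at or behind an eye")
    t = distance / (distance - z)
    sx = eye[0] + t * (pts[:, 0] - eye[0])
    sy = t * pts[:, 1]
    return np.column_stack([sx, sy])


def project_stereo(points_3d: np.ndarray, geometry: ViewingGeometry,
                   element_sizes: tuple | None = None) -> StereoProjection:
    """Pinhole projection of 3D points onto the screen plane from both eyes.

    Points on the screen plane (z = 0) project to identical left/right
    coordinates; points off the plane acquire horizontal disparity
    proportional to the interocular distance.
    """
    left = _project_from_eye(points_3d, geometry.left_eye, geometry.viewing_distance)
    right = _project_from_eye(points_3d, geometry.right_eye, geometry.viewing_distance)
    return StereoProjection(left_eye=left, right_eye=right, element_sizes=element_sizes)


def backproject_to_plane(screen_pts: np.ndarray, disc: PlaneSpec, slant_deg: float,
                         geometry: ViewingGeometry) -> np.ndarray:
    """Intersect cyclopean rays through screen points with the disc's plane.

    The plane passes through (center_x, 0, depth_offset) with normal
    (0, -sin s, cos s).  Raises :class:`GeometryError` when a ray is parallel
    to the plane or the intersection lies at or behind the eyes.
    """
    screen = np.atleast_2d(np.asarray(screen_pts, dtype=float))
    eye = geometry.cyclopean_eye
    s = math.radians(slant_deg)
    normal = np.array([0.0, -math.sin(s), math.cos(s)])
    center = np.array([disc.center_x, 0.0, disc.depth_offset])
    direction = np.column_stack([
        screen[:, 0] - eye[0], screen[:, 1] - eye[1], np.full(len(screen), -eye[2])])
    denom = direction @ normal
    if np.any(np.abs(denom) < 1e-12):
        raise GeometryError("cyclopean ray parallel to the disparity plane")
    t = (normal @ (center - eye)) / denom
    pts = eye + t[:, None] * direction
    if np.any(pts[:, 2] >= geometry.viewing_distance - 1e-9):
        raise GeometryError("back-projected point at or behind the eyes")
    return pts


def project_conflict_stimulus(spec: PlaneSpec, texture, geometry: ViewingGeometry
                              ) -> StereoProjection:
    """Two-eye projection of a (possibly cue-conflict) disc.

    The cyclopean image is rendered from the plane at ``slant_texture`` (for
    tiles) or taken directly from the screen-frame dots; each image point is
    then given the depth of the plane at ``slant_disparity`` along its
    cyclopean ray, and projected to both eyes.  With equal slants this reduces
    exactly to :func:`project_stereo` of the physical plane.
    """
    if isinstance(texture, TexturePattern):
        sizes = tuple(len(t) for t in texture.tiles)
        uv = np.concatenate(texture.tiles, axis=0) if texture.tiles else np.empty((0, 2))
        world_tex = plane_points_3d(uv, spec, spec.slant_texture)
        screen = _project_from_eye(world_tex, geometry.cyclopean_eye,
                                   geometry.viewing_distance)
    elif isinstance(texture, DotPattern):
        sizes = None
        screen = texture.dots
    else:
        raise InvalidSpecificationError(f"unknown pattern type {type(texture)!r}")
    world = backproject_to_plane(screen, spec, spec.slant_disparity, geometry)
    return project_stereo(world, geometry, element_sizes=sizes)


# --------------------------------------------------------------------------
# stimulus-pair layout and export
# --------------------------------------------------------------------------

def pair_centers(geometry: ViewingGeometry, disc_width: float = 16.0
                 ) -> tuple[float, float]:
    """Horizontal disc centres (cm) such that the pair spans display_width."""
    span = 2 * geometry.viewing_distance * math.tan(math.radians(geometry.display_width) / 2)
    if span < 2 * disc_width:
        raise InvalidSpecificationError(
            "display_width too small for two discs of this width")
    x0 = span / 2 - disc_width / 2
    return -x0, x0


#: deltas (texture, disparity) applied to the comparison disc on "different"
#: trials, degrees; None marks a cue that is absent from the stimulus.
CONDITION_DELTAS = {
    "T+": (+12.5, None),
    "T-": (-12.5, None),
    "D+": (None, +12.5),
    "D-": (None, -12.5),
    "T+D+": (+12.5, +12.5),
    "T+D-": (+12.5, -12.5),
}


def make_stimulus_pair(condition: str, truth: str, geometry: ViewingGeometry,
                       rng: np.random.Generator, *, standard_slant: float = 45.0,
                       disc_width: float = 16.0, depth_magnitude: float = 10.0):
    """Build the standard/comparison disc pair for one trial.

    Returns a list of two dicts with keys ``role``, ``spec``, ``pattern``,
    ``projection``.  The standard disc is placed on a random side; each disc
    draws its own length ratio and +/- depth offset.  Texture conditions use
    tile patterns, disparity-only conditions use uniform-density dot patterns.
    """
    if condition not in CONDITION_DELTAS:
        raise InvalidSpecificationError(f"unknown condition {condition!r}")
    if truth not in ("same", "different"):
        raise InvalidSpecificationError("truth must be 'same' or 'different'")
    d_tex, d_disp = CONDITION_DELTAS[condition]
    use_dots = d_tex is None
    x_left, x_right = pair_centers(geometry, disc_width)
    std_side = rng.choice(["left", "right"])
    discs = []
    for role in ("standard", "comparison"):
        tex = standard_slant
        disp = standard_slant
        if role == "comparison" and truth == "different":
            tex = standard_slant + (d_tex or 0.0)
            disp = standard_slant + (d_disp or 0.0)
            if d_tex is None:
                tex = disp  # physical outline follows the disparity slant
        elif d_tex is None:
            tex = disp
        side = std_side if role == "standard" else ("right" if std_side == "left" else "left")
        spec = PlaneSpec(
            width=disc_width,
            length_ratio=float(rng.uniform(1.0, 1.5)),
            slant_texture=tex, slant_disparity=disp,
            depth_offset=float(rng.choice([+1.0, -1.0])) * depth_magnitude,
            side=side, center_x=x_left if side == "left" else x_right)
        seed = int(rng.integers(0, 2**31 - 1))
        if use_dots:
            pattern = make_dot_pattern(spec, geometry, seed)
        else:
            pattern = make_texture_tiles(spec, seed)
        proj = project_conflict_stimulus(spec, pattern, geometry)
        discs.append({"role": role, "spec": spec, "pattern": pattern,
                      "projection": proj})
    return discs


def stimulus_pair_to_json(condition: str, truth: str, discs: list) -> str:
    """Serialize a stimulus pair (specs plus per-eye vertex arrays) to JSON."""
    doc = {"condition": condition, "truth": truth, "discs": []}
    for d in discs:
        spec, proj = d["spec"], d["projection"]
        doc["discs"].append({
            "role": d["role"],
            "spec": {
                "width_cm": spec.width, "length_ratio": spec.length_ratio,
                "slant_texture_deg": spec.slant_texture,
                "slant_disparity_deg": spec.slant_disparity,
                "depth_offset_cm": spec.depth_offset,
                "side": spec.side, "center_x_cm": spec.center_x,
            },
            "element_sizes": list(proj.element_sizes) if proj.element_sizes else None,
            "left_eye": proj.left_eye.round(6).tolist(),
            "right_eye": proj.right_eye.round(6).tolist(),
        })
    return json.dumps(doc)


def projection_to_svg(discs: list, eye: str = "left", scale: float = 10.0) -> str:
    """Minimal SVG rendering of one eye's view of a stimulus pair."""
    allpts = np.concatenate([d["projection"].left_eye for d in discs] +
                            [d["projection"].right_eye for d in discs])
    xmin, ymin = allpts.min(axis=0) - 2
    xmax, ymax = allpts.max(axis=0) + 2
    w, h = (xmax - xmin) * scale, (ymax - ymin) * scale

    def sx(x):
        return (x - xmin) * scale

    def sy(y):
        return (ymax - y) * scale  # flip: SVG y grows downward

    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.0f}" '
             f'height="{h:.0f}" viewBox="0 0 {w:.1f} {h:.1f}">',
             f'<rect width="{w:.1f}" height="{h:.1f}" fill="black"/>']
    for d in discs:
        proj = d["projection"]
        if proj.element_sizes is None:
            pts = proj.left_eye if eye == "left" else proj.right_eye
            for x, y in pts:
                parts.append(f'<circle cx="{sx(x):.2f}" cy="{sy(y):.2f}" '
                             f'r="{0.12 * scale:.2f}" fill="white"/>')
        else:
            for k, poly in enumerate(d["projection"].elements(eye)):
                coords = " ".join(f"{sx(x):.2f},{sy(y):.2f}" for x, y in poly)
                hue = (k * 47) % 360
                parts.append(f'<polygon points="{coords}" '
                             f'fill="hsl({hue},60%,55%)" stroke="black" '
                             f'stroke-width="0.5"/>')
    parts.append("</svg>")
    return "\n".join(parts)
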