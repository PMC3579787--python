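"""Synthetic brightfield worm phantoms with analytic ground truth.

A phantom is a tube of varying radius swept along a smooth backbone curve,
rendered dark on a bright, unevenly illuminated background — the situation a
stereomicroscope produces for nematodes crawling on clean agar.  Because the
backbone and the radius profile are known analytically, length, mid-body
width and the solid-of-revolution volume of the rendered object are known
exactly, which makes phantoms usable as ground truth for the measurement
pipeline.

Conventions
-----------
Control points are ``(x, y)`` in pixel units with ``x`` the column and ``y``
the row; the image origin is the top-left pixel center.  The radius profile
``r(u)`` is parameterized by normalized arclength ``u in [0, 1]`` and must
vanish at both tips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomError",
    "resample_backbone",
    "true_volume",
    "render_phantom",
    "tapered_radius_profile",
    "wavy_backbone",
    "adult_spec",
    "l1_spec",
]

#: spacing (px) of the dense backbone polyline used for arclength,
#: rasterization and self-intersection checks
_DENSE_STEP = 0.25


class PhantomError(ValueError):
    """Invalid phantom specification or impossible geometry."""


def tapered_radius_profile(mid_radius_px: float, blunt: float = 0.3) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth worm-like radius profile ``r(u) = r_mid * (4u(1-u))**blunt``.

    ``blunt`` < 0.5 gives a nearly constant mid-body with short tapered
    tips, resembling a larval or adult nematode; ``blunt = 0.5`` is an
    ellipse profile.  ``r(0) = r(1) = 0`` by construction.
    """
    if mid_radius_px < 0:
        raise PhantomError("mid_radius_px must be >= 0")

    def r(u):
        u = np.asarray(u, dtype=float)
        return mid_radius_px * np.clip(4.0 * u * (1.0 - u), 0.0, None) ** blunt

    return r


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic worm image."""

    backbone_control_points: Sequence[tuple[float, float]]
    radius_profile: Callable[[np.ndarray], np.ndarray]
    image_size: tuple[int, int]  # (width, height) px
    background_level: float = 200.0
    foreground_level: float = 60.0
    illumination_gradient: float = 0.0  # peak-to-peak intensity of a ramp
    noise_sd: float = 0.0
    scale: float = 1.0  # µm per px
    seed: int = 0

    def __post_init__(self):
        if len(self.backbone_control_points) < 2:
            raise PhantomError("need at least 2 backbone control points")
        if not self.foreground_level < self.background_level:
            raise PhantomError("foreground_level must be darker than background_level")
        if self.scale <= 0:
            raise PhantomError("scale must be > 0 µm/px")


@dataclass
class PhantomTruth:
    """Analytic ground truth for one rendered phantom."""

    true_length_px: float
    true_mid_width_px: float
    true_volume_px3: float
    true_mask: np.ndarray
    scale_um_per_px: float
    length_um: float = field(init=False)
    mid_width_um: float = field(init=False)
    volume_um3: float = field(init=False)
    volume_pl: float = field(init=False)

    def __post_init__(self):
        s = self.scale_um_per_px
        self.length_um = self.true_length_px * s
        self.mid_width_um = self.true_mid_width_px * s
        self.volume_um3 = self.true_volume_px3 * s**3
        self.volume_pl = self.volume_um3 / 1000.0  # 1 pl = 1000 µm³


def resample_backbone(control_points, step: float):
    """Resample a control polygon to an arclength-parameterized polyline.

    A natural cubic spline is drawn through the control points
    (chord-length parameterization) and evaluated on a dense grid; points
    are then re-interpolated so that consecutive output points are ``step``
    apart in arclength (the final point is the exact curve end).

    Returns
    -------
    points : (n, 2) float array of (x, y)
    arclength : float
        Total backbone arclength in px.
    """
    pts = np.asarray(control_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise PhantomError("need >= 2 control points of shape (n, 2)")
    if step <= 0:
        raise PhantomError("step must be > 0")

    chord = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(pts, axis=0).T))])
    if chord[-1] == 0:
        raise PhantomError("control points are all coincident")
    if pts.shape[0] == 2:
        # spline through 2 points degenerates; use the straight segment
        def ev(t):
            f = (t / chord[-1])[:, None]
            return pts[0] + f * (pts[1] - pts[0])
    else:
        sx = CubicSpline(chord, pts[:, 0], bc_type="natural")
        sy = CubicSpline(chord, pts[:, 1], bc_type="natural")

        def ev(t):
            return np.column_stack([sx(t), sy(t)])

    # dense polyline for arclength (0.25 px nominal spacing)
    n_dense = max(int(np.ceil(chord[-1] / _DENSE_STEP)) * 2, 8)
    t_dense = np.linspace(0.0, chord[-1], n_dense + 1)
    dense = ev(t_dense)
    seg = np.hypot(*np.diff(dense, axis=0).T)
    s_dense = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(s_dense[-1])

    s_targets = np.arange(0.0, total, step)
    if total - s_targets[-1] > 1e-9:
        s_targets = np.concatenate([s_targets, [total]])
    else:
        s_targets[-1] = total
    t_targets = np.interp(s_targets, s_dense, t_dense)
    return ev(t_targets), total


def true_volume(radius_profile, length_px: float) -> float:
    """Volume of the solid of revolution ``∫₀ᴸ π r(s)² ds`` by quadrature.

    ``radius_profile`` is either a callable ``r(u)`` on [0, 1] or a sampled
    ``(u, r)`` pair of arrays (linearly interpolated).  Relative quadrature
    error is far below 1e-6 for smooth profiles.
    """
    if length_px <= 0:
        raise PhantomError("length must be > 0")
    r = _as_profile_callable(radius_profile)
    u = np.linspace(0.0, 1.0, 200_001)
    ru = np.asarray(r(u), dtype=float)
    if np.any(ru < -1e-12):
        raise PhantomError("radius profile is negative somewhere on [0, 1]")
    from scipy.integrate import simpson

    return float(np.pi * length_px * simpson(ru**2, x=u))


def _as_profile_callable(radius_profile):
    if callable(radius_profile):
        return radius_profile
    u_s, r_s = (np.asarray(a, dtype=float) for a in radius_profile)
    return lambda u: np.interp(u, u_s, r_s)


def render_phantom(spec: PhantomSpec):
    """Rasterize a phantom: returns ``(image, truth)``.

    A pixel belongs to the worm iff its center lies within ``r(u*)`` of the
    backbone, where ``u*`` is the nearest backbone parameter found by dense
    sampling at 0.25 px.  Ground truth (arclength, mid width, quadrature
    volume, exact mask) is computed before noise; rendering is
    deterministic for a fixed seed.
    """
    width, height = spec.image_size
    r_fun = _as_profile_callable(spec.radius_profile)

    dense, total = resample_backbone(spec.backbone_control_points, _DENSE_STEP)
    s_dense = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(dense, axis=0).T))])
    u_dense = s_dense / s_dense[-1]
    r_dense = np.asarray(r_fun(u_dense), dtype=float)
    if np.any(r_dense < -1e-12):
        raise PhantomError("radius profile is negative somewhere on [0, 1]")
    r_dense = np.clip(r_dense, 0.0, None)
    r_max = float(r_dense.max())
    if r_max <= 0:
        raise PhantomError("radius profile is identically zero")

    tree = cKDTree(dense)
    _check_self_intersection(tree, dense, s_dense, u_dense, r_max)

    x, y = dense[:, 0], dense[:, 1]
    if (x.min() - r_max < 10 or y.min() - r_max < 10
            or x.max() + r_max > width - 1 - 10 or y.max() + r_max > height - 1 - 10):
        raise PhantomError(
            "image_size too small: worm plus 10 px margin does not fit "
            f"(tube bbox x [{x.min() - r_max:.0f}, {x.max() + r_max:.0f}], "
            f"y [{y.min() - r_max:.0f}, {y.max() + r_max:.0f}] in {width}x{height})"
        )

    mask = np.zeros((height, width), dtype=bool)
    r0 = max(int(np.floor(y.min() - r_max - 2)), 0)
    r1 = min(int(np.ceil(y.max() + r_max + 2)), height - 1)
    c0 = max(int(np.floor(x.min() - r_max - 2)), 0)
    c1 = min(int(np.ceil(x.max() + r_max + 2)), width - 1)
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    centers = np.column_stack([cc.ravel(), rr.ravel()]).astype(float)  # (x, y)
    dist, idx = tree.query(centers, workers=-1)
    inside = dist <= r_dense[idx]
    mask[rr.ravel()[inside], cc.ravel()[inside]] = True

    truth = PhantomTruth(
        true_length_px=float(s_dense[-1]),
        true_mid_width_px=2.0 * float(np.asarray(r_fun(0.5), dtype=float)),
        true_volume_px3=true_volume(r_fun, float(s_dense[-1])),
        true_mask=mask.copy(),
        scale_um_per_px=spec.scale,
    )

    img = np.full((height, width), float(spec.background_level))
    if spec.illumination_gradient:
        # tilted-plane shading along the image diagonal, peak-to-peak G
        g_r, g_c = np.mgrid[0:height, 0:width]
        ramp = (g_r / max(height - 1, 1) + g_c / max(width - 1, 1)) / 2.0
        img += spec.illumination_gradient * (ramp - 0.5)
    img[mask] = spec.foreground_level
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, truth


def _check_self_intersection(tree, dense, s_dense, u_dense, r_max):
    """Reject backbones that pass within 2·r_max of themselves."""
    pairs = tree.query_pairs(r=2.0 * r_max, output_type="ndarray")
    if len(pairs) == 0:
        return
    arc_sep = np.abs(s_dense[pairs[:, 0]] - s_dense[pairs[:, 1]])
    # nearby-in-arclength pairs are trivially close in space; only distant
    # stretches of backbone approaching each other indicate a tangled tube
    bad = arc_sep > 4.0 * r_max
    if np.any(bad):
        i, j = pairs[bad][0]
        raise PhantomError(
            "backbone self-intersects within tube diameter: parameters "
            f"u={u_dense[i]:.3f} and u={u_dense[j]:.3f} are "
            f"{np.hypot(*(dense[i] - dense[j])):.1f} px apart (< 2·max r = {2 * r_max:.1f})"
        )


def wavy_backbone(length_px: float, amplitude_px: float = 40.0,
                  n_waves: float = 1.5, n_points: int = 11,
                  origin: tuple[float, float] = (0.0, 0.0),
                  phase: float = 0.0):
    """Sinusoidal control points rescaled so the spline arclength is ``length_px``.

    Emulates the gentle sinusoidal posture of a crawling nematode.
    """
    xs = np.linspace(0.0, length_px, n_points)
    ys = amplitude_px * np.sin(2.0 * np.pi * n_waves * xs / length_px + phase)
    pts = np.column_stack([xs, ys])
    _, arclen = resample_backbone(pts, 1.0)
    pts *= length_px / arclen
    return pts + np.asarray(origin, dtype=float)


def _centered_spec(length_px, mid_radius_px, scale, seed, noise_sd,
                   illumination_gradient, amplitude_px, n_waves, phase, blunt):
    pts = wavy_backbone(length_px, amplitude_px=amplitude_px,
                        n_waves=n_waves, phase=phase)
    margin = mid_radius_px + 14
    pts[:, 0] -= pts[:, 0].min() - margin
    pts[:, 1] -= pts[:, 1].min() - margin
    w = int(np.ceil(pts[:, 0].max() + margin))
    h = int(np.ceil(pts[:, 1].max() + margin))
    return PhantomSpec(
        backbone_control_points=pts,
        radius_profile=tapered_radius_profile(mid_radius_px, blunt=blunt),
        image_size=(w, h),
        noise_sd=noise_sd,
        illumination_gradient=illumination_gradient,
        scale=scale,
        seed=seed,
    )


def adult_spec(seed: int = 0, noise_sd: float = 3.0,
               illumination_gradient: float = 30.0,
               length_px: float | None = None,
               mid_radius_px: float | None = None,
               scale: float = 1.5,
               amplitude_px: float = 45.0, n_waves: float = 1.5,
               phase: float = 0.0, blunt: float = 0.3) -> PhantomSpec:
    """Phantom at young-adult (48 h) proportions: ~720 µm long, ~30 µm mid radius.

    At the default 1.5 µm/px that is a 480 px backbone with a 20 px mid
    radius, comparable to the worms in the repeated-measurement experiment.
    """
    if length_px is None:
        length_px = 720.0 / scale
    if mid_radius_px is None:
        mid_radius_px = 30.0 / scale
    return _centered_spec(length_px, mid_radius_px, scale, seed, noise_sd,
                          illumination_gradient, amplitude_px, n_waves, phase, blunt)


def l1_spec(seed: int = 0, noise_sd: float = 3.0,
            illumination_gradient: float = 30.0,
            scale: float = 0.5, amplitude_px: float = 35.0,
            n_waves: float = 1.5, phase: float = 0.0,
            blunt: float = 0.3) -> PhantomSpec:
    """Phantom at arrested-L1 proportions: ~205 µm long, ~10 µm mid radius."""
    return _centered_spec(205.0 / scale, 10.0 / scale, scale, seed, noise_sd,
                          illumination_gradient, amplitude_px, n_waves, phase, blunt)
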