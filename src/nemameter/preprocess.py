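"""Illumination correction by rolling-ball background subtraction.

Brightfield images of worms on agar have a bright but uneven background.
Treating intensity as a height field, a ball of a given radius rolled under
the surface traces out the background; subtracting it flattens smooth
shading while leaving objects narrower than the ball untouched, so a single
global threshold suffices downstream.

With ``light_background`` (the brightfield default) the image is inverted
before estimation and the output is kept in that inverted convention:
dark worms on bright agar come out as bright objects on a dark, flat
background, which is what the segmentation stage expects.  The estimated
background is replaced by its global mean before subtraction, so the
overall intensity level is preserved rather than pushed to zero.
"""

from __future__ import annotations

import numpy as np
from skimage import restoration

from .image_io import IntensityImage

__all__ = ["subtract_background", "estimate_background", "invert"]


def invert(image: IntensityImage) -> IntensityImage:
    """Photographic negative: p ↦ 255 − p."""
    return IntensityImage(255 - image.pixels, scale=image.scale)


def estimate_background(image: IntensityImage, ball_radius_px: float) -> np.ndarray:
    """Rolling-ball (Sternberg) background of a dark-background image.

    Equivalent to a grayscale opening with a spherical structuring
    element: the surface traced by the top of a ball of the given radius
    rolled under the intensity landscape.
    """
    if ball_radius_px < 1:
        raise ValueError("ball_radius_px must be >= 1")
    h, w = image.pixels.shape
    if ball_radius_px > max(h, w):
        raise ValueError(
            f"ball radius {ball_radius_px} exceeds image extent {h}x{w}")
    return restoration.rolling_ball(image.pixels, radius=ball_radius_px)


def subtract_background(image: IntensityImage, ball_radius_px: float = 50,
                        light_background: bool = True) -> IntensityImage:
    """Flatten uneven illumination; output has bright objects on dark ground.

    The background estimate is subtracted and its global mean added back
    ("background set to a constant average intensity"), clipping to
    [0, 255].
    """
    work = invert(image) if light_background else image
    bg = estimate_background(work, ball_radius_px).astype(float)
    out = work.pixels.astype(float) - bg + bg.mean()
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return IntensityImage(out, scale=image.scale)
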