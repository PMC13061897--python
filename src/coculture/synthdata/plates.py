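"""Synthetic Petri-dish images: a bright rim plus colony disks."""

from __future__ import annotations

import numpy as np

from .design import ColonyDisk


def gen_plate_image(
    width: int = 600,
    height: int = 600,
    colonies: list[tuple[float, float, float, float]] = (),
    plate_diameter_px: float = 560.0,
    background: float = 30.0,
    rim_intensity: float = 220.0,
    rim_thickness: float = 3.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[ColonyDisk], list[bool]]:
    """Render a grayscale plate image.

    ``colonies`` is a list of (cx, cy, radius_px, intensity). Colonies are
    filled disks brighter than background; the plate rim is a circle of
    known pixel diameter centred in the image (the anchor for mm
    conversion). Returns (image uint8, truth sorted by area descending,
    overlap flags aligned with the truth list).
    """
    rng = np.random.default_rng([seed, 301])
    img = np.full((height, width), float(background))
    yy, xx = np.mgrid[0:height, 0:width]

    cx0, cy0 = (width - 1) / 2.0, (height - 1) / 2.0
    r_plate = plate_diameter_px / 2.0
    dist = np.hypot(xx - cx0, yy - cy0)
    img[np.abs(dist - r_plate) <= rim_thickness / 2.0] = rim_intensity

    disks: list[ColonyDisk] = []
    for cx, cy, radius, intensity in colonies:
        if radius < 1:
            raise ValueError("colony radius must be >= 1 px")
        if np.hypot(cx - cx0, cy - cy0) + radius > r_plate:
            raise ValueError("colony extends beyond plate boundary")
        img[np.hypot(xx - cx, yy - cy) <= radius] = intensity
        disks.append(ColonyDisk(cx=float(cx), cy=float(cy), radius=float(radius)))

    order = np.argsort([-d.area_px for d in disks], kind="stable")
    disks = [disks[i] for i in order]
    overlap = [
        any(
            np.hypot(d.cx - o.cx, d.cy - o.cy) < d.radius + o.radius
            for o in disks
            if o is not d
        )
        for d in disks
    ]

    img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), disks, overlap
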