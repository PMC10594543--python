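"""Geometry constants of the wide-field video-capillaroscope.

The instrument images a 7.4 mm x 5.5 mm skin patch onto a 4000 x 3000 px
sensor at 30 frames per second, so a single pixel sees 1.85 um of skin.
Stabilization crops a 50 px margin (3900 x 2900 px analysed field), and
annotation works on 1300 x 1000 px sub-crops.
"""

from __future__ import annotations

SENSOR_WIDTH_PX = 4000
SENSOR_HEIGHT_PX = 3000
FOV_WIDTH_MM = 7.4
FOV_HEIGHT_MM = 5.5
FRAME_RATE_FPS = 30.0
N_ANALYSIS_FRAMES = 150  # 5 s at 30 fps

STABILIZATION_MARGIN_PX = 50
STABILIZED_WIDTH_PX = SENSOR_WIDTH_PX - 2 * STABILIZATION_MARGIN_PX    # 3900
STABILIZED_HEIGHT_PX = SENSOR_HEIGHT_PX - 2 * STABILIZATION_MARGIN_PX  # 2900

ANNOTATION_CROP_WIDTH_PX = 1300
ANNOTATION_CROP_HEIGHT_PX = 1000


def pixel_pitch_um(fov_width_mm: float = FOV_WIDTH_MM,
                   width_px: int = SENSOR_WIDTH_PX) -> float:
    """Physical extent of one pixel in micrometres (7.4 mm / 4000 px = 1.85)."""
    if width_px <= 0:
        raise ValueError("width_px must be positive")
    return fov_width_mm * 1000.0 / width_px


UM_PER_PX = pixel_pitch_um()  # 1.85


def extent_mm(n_px: int, um_per_px: float = UM_PER_PX) -> float:
    """Physical extent in millimetres of ``n_px`` pixels at the given pitch."""
    return n_px * um_per_px / 1000.0


def area_um2(area_px: float, um_per_px: float = UM_PER_PX) -> float:
    """Convert a pixel area to um^2 (area_px * um_per_px^2)."""
    return area_px * um_per_px ** 2
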