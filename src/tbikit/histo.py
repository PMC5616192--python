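"""Immunohistochemistry quantification on 8-bit grayscale sections.

Two measurements, per the bright-field DAB convention (stained = dark):

* percent area — fraction of ROI pixels with intensity below a
  per-marker threshold, x100 (used for IBA-1, GFAP and APP);
* optical density — mean over ROI pixels of log10(255 / I) with I
  floored at 1, the ImageJ-style calibrated OD (used for MBP).

To emulate a thicker imaging slab, two serial sections are measured per
region and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HistoMeasure", "percent_area", "optical_density",
           "serial_section_measure", "MARKER_MEASURES", "DEFAULT_THRESHOLD"]

#: Which measurement each marker uses.
MARKER_MEASURES: dict[str, str] = {
    "IBA-1": "percent_area",
    "GFAP": "percent_area",
    "APP": "percent_area",
    "MBP": "optical_density",
}

#: Stain-intensity threshold used when a marker-specific one is not given.
DEFAULT_THRESHOLD = 128


@dataclass
class HistoMeasure:
    roi: str
    marker: str
    value: float      # percent area (%) or optical density (dimensionless)
    measure: str      # "percent_area" | "optical_density"
    n_sections: int


def _roi_pixels(img: np.ndarray, roi_mask: np.ndarray | None) -> np.ndarray:
    img = np.asarray(img)
    if roi_mask is None:
        return img.reshape(-1)
    roi_mask = np.asarray(roi_mask, bool)
    if roi_mask.shape != img.shape:
        raise ValueError("mask shape does not match image shape")
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    return img[roi_mask]


def percent_area(img: np.ndarray, roi_mask: np.ndarray | None = None,
                 threshold: int = DEFAULT_THRESHOLD) -> float:
    """Percentage of ROI pixels with intensity strictly below ``threshold``."""
    px = _roi_pixels(img, roi_mask)
    return 100.0 * float(np.count_nonzero(px < threshold)) / px.size


def optical_density(img: np.ndarray, roi_mask: np.ndarray | None = None) -> float:
    """Mean log10(255 / max(I, 1)) over the ROI pixels."""
    px = _roi_pixels(img, roi_mask).astype(float)
    return float(np.mean(np.log10(255.0 / np.maximum(px, 1.0))))


def serial_section_measure(
    sections,
    marker: str,
    roi: str = "",
    threshold: int = DEFAULT_THRESHOLD,
) -> HistoMeasure:
    """Average the per-section measurement over two serial sections.

    ``sections`` is a sequence of two (image, roi_mask) pairs (mask may
    be None for whole-image measurement).  The measurement is percent
    area for IBA-1/GFAP/APP and optical density for MBP.
    """
    if marker not in MARKER_MEASURES:
        raise ValueError(f"unknown marker {marker!r}; expected one of "
                         f"{sorted(MARKER_MEASURES)}")
    if len(sections) != 2:
        raise ValueError("exactly two serial sections are required")
    measure = MARKER_MEASURES[marker]
    vals = []
    for img, mask in sections:
        if measure == "percent_area":
            vals.append(percent_area(img, mask, threshold))
        else:
            vals.append(optical_density(img, mask))
    return HistoMeasure(roi=roi, marker=marker, value=float(np.mean(vals)),
                        measure=measure, n_sections=2)
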