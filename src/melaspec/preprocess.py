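"""Denoising, normalization and lesion-minus-normal intensity correction.

The preprocessing chain for each scan is:

1. **Median filter** (default 3x3, reflection padding) to remove impulse
   noise picked up by the CCD during acquisition.
2. **Min-max normalization** per image: ``I' = (I - min) / (max - min)``,
   mapping the darkest pixel of each scan to 0 and the brightest to 1.  A
   constant scan is rejected — the transform is undefined and a flat CCD
   frame indicates acquisition failure.
3. **Corrected intensity** per polarization: the two normalized lesion-spot
   scans are averaged and the normalized normal-spot scan is subtracted,

       I-bar = (I'_lesion1 + I'_lesion2) / 2 - I'_normal.

   Subtracting the subject's own normal skin removes baseline effects such
   as skin tone, age or device gain that are common to all six scans; the
   result is signed and kept signed.

Order matters: filtering precedes normalization so that impulse outliers do
not distort the per-image min/max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import DegenerateScanError, ValidationError
from .scan_io import SampleRecord, SpectralScan

__all__ = [
    "NormalizedScan", "CorrectedImage",
    "median_filter", "minmax_normalize", "corrected_intensity",
    "preprocess_sample",
]


@dataclass
class NormalizedScan:
    """A min-max normalized scan: values in [0, 1], min 0 and max 1 attained."""

    intensities: np.ndarray
    polarization: str
    spot_role: str
    source: str = ""  # provenance: originating scan identity


@dataclass
class CorrectedImage:
    """The signed lesion-minus-normal corrected intensity matrix (one
    polarization of one sample); values lie in [-1, 1]."""

    values: np.ndarray
    polarization: str
    sample_id: str = ""


def _as_window(window) -> tuple[int, int]:
    if np.isscalar(window):
        window = (int(window), int(window))
    w = tuple(int(x) for x in window)
    if len(w) != 2:
        raise ValidationError(f"window must have one extent per axis, got {window!r}")
    for x in w:
        if x < 1 or x % 2 == 0:
            raise ValidationError(
                f"window extents must be odd and >= 1, got {window!r}")
    return w


def median_filter(scan: SpectralScan, window=3) -> SpectralScan:
    """Median-filter a scan with an odd window per axis.

    Borders are handled by reflection padding (the edge pixel is included in
    the mirror); the output shape equals the input shape.
    """
    w = _as_window(window)
    if w[0] > scan.shape[0] or w[1] > scan.shape[1]:
        raise ValidationError(
            f"window {w} exceeds scan dimensions {scan.shape}")
    out = ndimage.median_filter(scan.intensities.astype(float), size=w,
                                mode="reflect")
    return SpectralScan(out, polarization=scan.polarization,
                        spot_role=scan.spot_role)


def minmax_normalize(scan: SpectralScan, source: str = "") -> NormalizedScan:
    """Rescale a scan to [0, 1]: ``(I - min) / (max - min)`` elementwise.

    Raises :class:`DegenerateScanError` on a constant image (max == min).
    """
    arr = scan.intensities.astype(float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise DegenerateScanError(
            f"constant scan (all values {lo}): min-max normalization undefined")
    return NormalizedScan((arr - lo) / (hi - lo),
                          polarization=scan.polarization,
                          spot_role=scan.spot_role, source=source)


def corrected_intensity(s1: NormalizedScan, s2: NormalizedScan,
                        s3: NormalizedScan, sample_id: str = "") -> CorrectedImage:
    """Average the two lesion-spot scans and subtract the normal-spot scan.

    All three scans must share shape and polarization; ``s1``/``s2`` are the
    lesion spots and ``s3`` the normal spot.  Negative values are preserved.
    """
    pols = {s1.polarization, s2.polarization, s3.polarization}
    if len(pols) != 1:
        raise ValidationError(f"mixed polarizations in correction: {sorted(pols)}")
    shapes = {s1.intensities.shape, s2.intensities.shape, s3.intensities.shape}
    if len(shapes) != 1:
        raise ValidationError(f"mismatched scan shapes in correction: {sorted(shapes)}")
    values = (s1.intensities + s2.intensities) / 2.0 - s3.intensities
    return CorrectedImage(values, polarization=s1.polarization,
                          sample_id=sample_id)


def preprocess_sample(sample: SampleRecord, window=3
                      ) -> tuple[CorrectedImage, CorrectedImage]:
    """Full preprocessing of one six-scan sample.

    Each scan is median-filtered then normalized; the corrected intensity is
    computed separately for the P scans (p1, p2, p3) and the V scans
    (v1, v2, v3).  Returns ``(corrected_P, corrected_V)``.
    """
    normalized = {}
    for slot, scan in sample.scans.items():
        try:
            filtered = median_filter(scan, window)
            normalized[slot] = minmax_normalize(
                filtered, source=f"{sample.sample_id}/{slot}")
        except (ValidationError, DegenerateScanError) as exc:
            raise type(exc)(f"scan {slot} of sample {sample.sample_id}: {exc}") from exc
    corr_p = corrected_intensity(normalized["p1"], normalized["p2"],
                                 normalized["p3"], sample_id=sample.sample_id)
    corr_v = corrected_intensity(normalized["v1"], normalized["v2"],
                                 normalized["v3"], sample_id=sample.sample_id)
    return corr_p, corr_v
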