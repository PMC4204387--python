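"""Synthetic cohorts of six-scan spectroscopic skin samples.

No public dataset of paired polarized/unpolarized spectral skin scans exists,
so this module generates labelled cohorts whose class-conditional intensity
structure matches what the downstream analysis assumes:

* each scan is a 32x512 CCD frame whose bright detector line sits at a fixed
  row (row 15 by default, 1-based) with a smooth spectral profile along the
  columns and a dark vignetted margin at the detector edges;
* all six scans of a sample share the same per-subject baseline — a
  multiplicative gain drawn per subject plus a common skin-tone offset — so
  that the lesion-minus-normal correction demonstrably removes it;
* benign lesion spots carry a small diffuse shift: after per-image min-max
  normalization the bulk of their pixels concentrates in [0.2, 0.4];
* melanoma lesion spots add a broad, positively skewed intensity excess
  scaled by ``effect_size``, spreading normalized values over [0, 1] with
  most pixels bright;
* isolated impulse (salt-and-pepper) pixels are injected at ``noise_rate``,
  the noise type the median-filter stage of the pipeline removes.

At ``effect_size = 0`` melanoma and benign lesion scans are drawn from the
identical distribution, so labels carry no signal — the calibration case for
the evaluation harness.  The same seed always reproduces the cohort
bit-for-bit (scans are emitted at float32 precision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .scan_io import (
    BENIGN, CODE_TO_LABEL, MELANOMA, SCAN_SLOTS,
    Manifest, SampleRecord, SpectralScan, write_manifest, write_scan,
)

# Fixed generator constants (normalized-intensity space, see docs/methods.md):
_DARK_LEVEL = 0.08        # detector dark offset, arbitrary raw units
_RAW_SCALE = 1000.0       # arbitrary positive CCD count scale
_NORMAL_BULK = 0.28       # diffuse skin level of normal-spot scans
_BENIGN_GAP = 0.01        # benign lesion minus normal skin, diffuse level
_SKIN_TONE_SD = 0.03      # per-subject offset shared by all six scans
_SPOT_LEVEL_SD = 0.025    # per-scan diffuse-level heterogeneity (probe spot)
_TEXTURE_SD = 0.03        # median per-pixel texture amplitude
_TEXTURE_AMP_LOG_SD = 0.3   # log-scale spread of the per-scan amplitude
_TEXTURE_DF_RANGE = (3.0, 20.0)  # per-scan tail weight of the texture
_SPECK_MEAN_COUNT = 35.0    # mean bright micro-speck count per lesion scan
_SPECK_COUNT_LOG_SD = 0.8   # log-scale spread of the per-scan speck rate
_SPECK_AMPLITUDE = 0.55     # peak height of one speck
_SPECK_SIGMA = 1.3          # spatial extent (pixels) of one speck
_MEL_SHIFT = 0.12         # melanoma location shift at effect_size = 1
_MEL_SPREAD = 0.55        # span of the skewed melanoma intensity excess


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    The defaults emulate the clinical study cohort this pipeline targets:
    187 samples (19 melanoma, 168 benign) of 32x512 scans with the bright
    detector line at row 15 (1-based).

    Parameters
    ----------
    effect_size
        Non-negative scale of the melanoma-vs-benign distributional shift.
        0 means no class signal; 1 is the nominal, well-separated regime.
    noise_rate
        Per-pixel probability of an impulse (salt or pepper) outlier.
    subject_shift_sd
        Log-scale SD of the per-subject multiplicative gain shared by all
        six scans of a sample.
    """

    n_melanoma: int = 19
    n_benign: int = 168
    n_rows: int = 32
    n_cols: int = 512
    peak_row: int = 15            # 1-based row of the bright detector line
    effect_size: float = 1.0
    noise_rate: float = 0.002
    subject_shift_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_melanoma < 0:
            raise ValidationError(f"n_melanoma must be >= 0, got {self.n_melanoma}")
        if self.n_benign < 0:
            raise ValidationError(f"n_benign must be >= 0, got {self.n_benign}")
        if self.n_melanoma + self.n_benign < 1:
            raise ValidationError("cohort must contain at least one sample "
                                  "(n_melanoma + n_benign >= 1)")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError(
                f"n_rows and n_cols must be >= 1, got {self.n_rows}x{self.n_cols}")
        if not 1 <= self.peak_row <= self.n_rows:
            raise ValidationError(
                f"peak_row must be in [1, {self.n_rows}], got {self.peak_row}")
        if not self.effect_size >= 0:
            raise ValidationError(f"effect_size must be >= 0, got {self.effect_size}")
        if not 0 <= self.noise_rate <= 1:
            raise ValidationError(f"noise_rate must be in [0, 1], got {self.noise_rate}")
        if not self.subject_shift_sd >= 0:
            raise ValidationError(
                f"subject_shift_sd must be >= 0, got {self.subject_shift_sd}")


def _detector_profiles(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ridge row profile, spectral column profile and edge-vignetting envelope."""
    i = np.arange(1, spec.n_rows + 1, dtype=float)          # 1-based rows
    j = np.arange(1, spec.n_cols + 1, dtype=float)
    ridge = np.exp(-0.5 * ((i - spec.peak_row) / 1.1) ** 2)  # bright line
    # Smooth spectral response along the columns: a broad bump on a pedestal.
    col = 0.75 + 0.25 * np.exp(-0.5 * ((j - 0.45 * spec.n_cols) /
                                       (0.22 * spec.n_cols)) ** 2)
    # Illumination reaches only the inner detector rows; the outermost rows
    # read near dark level, which anchors the per-image minimum.  The
    # transition is sharp (about one row wide).
    margin = max(1.2, 0.05 * spec.n_rows)
    env = (1.0 / (1.0 + np.exp(-(i - (1 + margin)) / 0.25))
           * 1.0 / (1.0 + np.exp(-((spec.n_rows - margin) - i) / 0.25)))
    return ridge, col, env


def _speck_field(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    """Bright micro-specks on lesion tissue (pigment granules / speckle).

    Each speck is a small Gaussian bump wide enough to survive the 3x3
    median-filter stage — unlike the single-pixel impulse noise.  The
    per-scan speck rate varies between acquisitions, which makes the
    spatial-spread statistics of a scan vary independently of its diffuse
    level and fine-texture amplitude.
    """
    shape = (spec.n_rows, spec.n_cols)
    count = rng.poisson(_SPECK_MEAN_COUNT * np.exp(rng.normal(0.0, _SPECK_COUNT_LOG_SD)))
    field = np.zeros(shape)
    if count == 0:
        return field
    rows = rng.uniform(2.0, spec.n_rows - 3.0, size=count)
    cols = rng.uniform(0.0, spec.n_cols - 1.0, size=count)
    amps = _SPECK_AMPLITUDE * rng.uniform(0.7, 1.3, size=count)
    ii = np.arange(spec.n_rows, dtype=float)[:, None]
    jj = np.arange(spec.n_cols, dtype=float)[None, :]
    for r, c, a in zip(rows, cols, amps):
        # evaluate each bump only on its local window to keep this cheap
        r0, r1 = max(0, int(r) - 4), min(spec.n_rows, int(r) + 5)
        c0, c1 = max(0, int(c) - 4), min(spec.n_cols, int(c) + 5)
        field[r0:r1, c0:c1] += a * np.exp(
            -0.5 * (((ii[r0:r1] - r) ** 2 + (jj[:, c0:c1] - c) ** 2)
                    / _SPECK_SIGMA ** 2))
    return field


def _lesion_excess(rng: np.random.Generator, spec: CohortSpec,
                   shape: tuple[int, int]) -> np.ndarray:
    """Positively skewed per-pixel melanoma excess, scaled by effect_size."""
    if spec.effect_size == 0:
        return np.zeros(shape)
    skewed = rng.beta(2.2, 1.3, size=shape)  # broad, high-heavy in [0, 1]
    return spec.effect_size * (_MEL_SHIFT + _MEL_SPREAD * skewed)


def _make_scan(rng: np.random.Generator, spec: CohortSpec, *, gain: float,
               tone: float, lesion: bool, melanoma: bool,
               profiles: tuple[np.ndarray, np.ndarray, np.ndarray],
               polarization: str, spot_role: str) -> SpectralScan:
    ridge, col, env = profiles
    shape = (spec.n_rows, spec.n_cols)

    # Per-scan heterogeneity: each acquisition has its own diffuse level
    # (probe-spot tissue variation), texture amplitude (speckle strength)
    # and texture tail weight (standardized Student-t pixels).
    level = rng.normal(0.0, _SPOT_LEVEL_SD)
    amp = _TEXTURE_SD * np.exp(rng.normal(0.0, _TEXTURE_AMP_LOG_SD))
    df = rng.uniform(*_TEXTURE_DF_RANGE)
    texture = amp * rng.standard_t(df, size=shape) / np.sqrt(df / (df - 2.0))

    bulk = _NORMAL_BULK + tone + level + texture
    if lesion:
        bulk = bulk + _BENIGN_GAP + _speck_field(rng, spec)
        if melanoma:
            bulk = bulk + _lesion_excess(rng, spec, shape)

    # Normalized-space target: bright ridge plus vignetted diffuse field.
    target = np.clip(ridge[:, None] * col[None, :] + env[:, None] * bulk, 0.0, 1.0)
    raw = _RAW_SCALE * gain * (_DARK_LEVEL + target)

    if spec.noise_rate > 0:
        hit = rng.random(size=shape) < spec.noise_rate
        salt = rng.random(size=shape) < 0.5
        raw = np.where(hit & salt, _RAW_SCALE * gain * (_DARK_LEVEL + 1.15), raw)
        raw = np.where(hit & ~salt, 0.0, raw)

    return SpectralScan(raw.astype("<f4"), polarization=polarization,
                        spot_role=spot_role)


def generate_sample(rng: np.random.Generator, spec: CohortSpec,
                    sample_id: str, label: int) -> SampleRecord:
    """Draw one six-scan sample.  The subject gain and skin-tone offset are
    drawn once and shared by all six scans."""
    profiles = _detector_profiles(spec)
    gain = math.exp(rng.normal(0.0, spec.subject_shift_sd))
    tone = rng.normal(0.0, _SKIN_TONE_SD)
    melanoma = label == MELANOMA
    scans = {}
    for slot in SCAN_SLOTS:
        pol = "P" if slot.startswith("p") else "V"
        role = {"1": "lesion1", "2": "lesion2", "3": "normal"}[slot[1]]
        scans[slot] = _make_scan(
            rng, spec, gain=gain, tone=tone,
            lesion=role != "normal", melanoma=melanoma,
            profiles=profiles, polarization=pol, spot_role=role)
    return SampleRecord(sample_id=sample_id, scans=scans, label=label)


def generate_cohort(spec: CohortSpec) -> list[SampleRecord]:
    """Generate ``n_melanoma + n_benign`` labelled samples.

    Melanoma samples come first (``mel-000`` ...), then benign
    (``ben-000`` ...).  Identical specs (including seed) produce bit-identical
    cohorts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cohort = [generate_sample(rng, spec, f"mel-{k:03d}", MELANOMA)
              for k in range(spec.n_melanoma)]
    cohort += [generate_sample(rng, spec, f"ben-{k:03d}", BENIGN)
               for k in range(spec.n_benign)]
    return cohort


def write_cohort(cohort: list[SampleRecord], directory: str | Path,
                 layout: str = "raw_f32le") -> Manifest:
    """Write every scan of the cohort plus a manifest CSV into ``directory``.

    Returns the manifest; scan paths in it are relative to the directory.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = ".csv" if layout == "text" else ".f32"
    rows = []
    for rec in cohort:
        row = {"sample_id": rec.sample_id, "label": CODE_TO_LABEL[rec.label]}
        for slot in SCAN_SLOTS:
            fname = f"{rec.sample_id}_{slot}{ext}"
            write_scan(rec.scans[slot], directory / fname, layout=layout)
            row[slot] = fname
        rows.append(row)
    manifest = Manifest(rows=rows)
    write_manifest(manifest, directory / "manifest.csv")
    return manifest


def zero_effect(spec: CohortSpec) -> CohortSpec:
    """The matched no-signal control of a cohort spec."""
    return replace(spec, effect_size=0.0)
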