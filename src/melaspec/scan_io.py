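"""Reading and writing spectral scans, sample manifests, feature tables and models.

A spectral scan is a 32x512 matrix of non-negative CCD intensities; rows are
detector lines and columns are spectral channels.  Two on-disk layouts are
supported:

``raw_f32le``
    Headerless little-endian 32-bit floats, row-major, exactly
    ``n_rows * n_cols`` values.  File extension ``.f32`` by convention.
``text``
    ``n_rows`` lines of ``n_cols`` comma-separated numbers.  Extension
    ``.csv``.

All pixel indices in documentation and error messages are 1-based, matching
the convention of the acquisition protocol; storage order is row-major with
pixel (1, 1) stored first.

A *sample* is six scans of one skin site: P-polarized and V-polarized scans of
two lesion spots plus one nearby normal-skin spot (p1, p2, p3, v1, v2, v3).
Cohorts are described by a manifest CSV with header
``sample_id,label,p1,p2,p3,v1,v2,v3`` where the scan columns hold file paths
and ``label`` is ``melanoma``, ``benign`` or ``unknown``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .exceptions import FormatError, ValidationError

#: Integer class codes: melanoma is the positive (cancer) class.
MELANOMA = 1
BENIGN = -1
UNKNOWN = 0

LABEL_TO_CODE = {"melanoma": MELANOMA, "benign": BENIGN, "unknown": UNKNOWN}
CODE_TO_LABEL = {v: k for k, v in LABEL_TO_CODE.items()}

#: The six scan slots of a sample, in canonical order.
SCAN_SLOTS = ("p1", "p2", "p3", "v1", "v2", "v3")

#: Canonical feature-table column order (see :mod:`melaspec.features`).
FEATURE_COLUMNS = (
    "p_mean", "p_sd", "p_mad", "p_l1", "p_l2",
    "v_mean", "v_sd", "v_mad", "v_l1", "v_l2",
)

MANIFEST_COLUMNS = ("sample_id", "label") + SCAN_SLOTS

_SLOT_META = {
    "p1": ("P", "lesion1"), "p2": ("P", "lesion2"), "p3": ("P", "normal"),
    "v1": ("V", "lesion1"), "v2": ("V", "lesion2"), "v3": ("V", "normal"),
}


@dataclass
class SpectralScan:
    """One CCD intensity matrix with its polarization and probe-spot role.

    Parameters
    ----------
    intensities
        ``(n_rows, n_cols)`` array of finite, non-negative intensities.
    polarization
        ``"P"`` (parallel-polarized) or ``"V"`` (cross-polarized).
    spot_role
        ``"lesion1"``, ``"lesion2"`` or ``"normal"``.
    """

    intensities: np.ndarray
    polarization: str = "P"
    spot_role: str = "lesion1"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 2 or arr.size == 0:
            raise ValidationError(
                f"scan must be a non-empty 2-D matrix, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("scan contains non-finite intensities")
        if np.any(arr < 0):
            raise ValidationError("scan contains negative intensities")
        if self.polarization not in ("P", "V"):
            raise ValidationError(
                f"polarization must be 'P' or 'V', got {self.polarization!r}")
        if self.spot_role not in ("lesion1", "lesion2", "normal"):
            raise ValidationError(f"unknown spot_role {self.spot_role!r}")
        self.intensities = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass
class SampleRecord:
    """Six spectral scans of one skin sample plus its class label.

    ``scans`` maps the slot names ``p1, p2, p3, v1, v2, v3`` to
    :class:`SpectralScan` objects; slots 1-2 probe lesion spots and slot 3
    probes nearby normal skin.  ``label`` is +1 (melanoma), -1 (benign) or
    0 (unknown, for diagnosis of new subjects).
    """

    sample_id: str
    scans: dict[str, SpectralScan]
    label: int = UNKNOWN

    def __post_init__(self) -> None:
        missing = [s for s in SCAN_SLOTS if s not in self.scans]
        if missing:
            raise ValidationError(f"sample {self.sample_id}: missing scan slot(s) {missing}")
        shapes = {s: self.scans[s].shape for s in SCAN_SLOTS}
        if len(set(shapes.values())) != 1:
            raise ValidationError(
                f"sample {self.sample_id}: inconsistent scan shapes {shapes}")
        if self.label not in (MELANOMA, BENIGN, UNKNOWN):
            raise ValidationError(
                f"sample {self.sample_id}: label must be +1, -1 or 0, got {self.label}")
        for slot in SCAN_SLOTS:
            pol, role = _SLOT_META[slot]
            scan = self.scans[slot]
            if scan.polarization != pol or scan.spot_role != role:
                raise ValidationError(
                    f"sample {self.sample_id}: slot {slot} expects "
                    f"({pol}, {role}), got ({scan.polarization}, {scan.spot_role})")


@dataclass
class Manifest:
    """Rows of (sample_id, label string, six scan-file paths)."""

    rows: list[dict[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r["sample_id"] for r in self.rows]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample_id(s) in manifest: {dupes}")
        for r in self.rows:
            if r["label"] not in LABEL_TO_CODE:
                raise ValidationError(
                    f"sample {r['sample_id']}: label must be one of "
                    f"{sorted(LABEL_TO_CODE)}, got {r['label']!r}")

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# scan files

def write_scan(scan: SpectralScan, path: str | Path, layout: str = "raw_f32le") -> None:
    """Write a scan to ``path`` in the given layout.

    Values are stored as 32-bit floats (``raw_f32le``) or their shortest
    round-tripping decimal representation (``text``); reading the file back
    with :func:`read_scan` reproduces the matrix exactly at that precision.
    """
    path = Path(path)
    data = np.ascontiguousarray(scan.intensities, dtype="<f4")
    if layout == "raw_f32le":
        path.write_bytes(data.tobytes())
    elif layout == "text":
        lines = [",".join(np.format_float_positional(v, trim="-") for v in row)
                 for row in data]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValidationError(f"unknown scan layout {layout!r}")


def read_scan(path: str | Path, layout: str = "raw_f32le",
              n_rows: int = 32, n_cols: int = 512,
              polarization: str = "P", spot_role: str = "lesion1") -> SpectralScan:
    """Read a scan file written by :func:`write_scan`.

    For the raw layout the expected shape must be declared (default 32x512);
    the text layout is validated against it.  Raises :class:`FormatError` if
    the byte count or line structure does not match.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"scan file not found: {path}")
    if layout == "raw_f32le":
        raw = path.read_bytes()
        expected = 4 * n_rows * n_cols
        if len(raw) != expected:
            raise FormatError(
                f"{path}: expected {n_rows}x{n_cols} float32 values "
                f"({expected} bytes), found {len(raw)} bytes")
        arr = np.frombuffer(raw, dtype="<f4").reshape(n_rows, n_cols)
    elif layout == "text":
        rows = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            try:
                rows.append([float(tok) for tok in line.split(",")])
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: non-numeric value ({exc})") from exc
        arr = np.array(rows, dtype="<f4")
        if arr.ndim != 2 or arr.shape != (n_rows, n_cols):
            found = "ragged" if arr.ndim != 2 else f"{arr.shape[0]}x{arr.shape[1]}"
            raise FormatError(
                f"{path}: expected a {n_rows}x{n_cols} matrix, found {found}")
    else:
        raise ValidationError(f"unknown scan layout {layout!r}")
    return SpectralScan(arr.copy(), polarization=polarization, spot_role=spot_role)


def _layout_for(path: str | Path) -> str:
    return "text" if str(path).endswith(".csv") else "raw_f32le"


# ---------------------------------------------------------------------------
# manifests

def write_manifest(manifest: Manifest, path: str | Path) -> None:
    """Write a manifest CSV with the canonical header."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        for row in manifest.rows:
            writer.writerow(row)


def read_manifest(path: str | Path, n_rows: int = 32, n_cols: int = 512) -> list[SampleRecord]:
    """Load a manifest CSV and its referenced scan files into SampleRecords.

    Records are returned in manifest row order.  Scan paths are resolved
    relative to the manifest's directory.  A missing column, missing file or
    duplicate sample_id raises an error naming the offender.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"manifest not found: {path}")
    base = path.parent
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing_cols = [c for c in MANIFEST_COLUMNS if c not in header]
        if missing_cols:
            raise FormatError(f"{path}: manifest missing column(s) {missing_cols}")
        rows = list(reader)
    manifest = Manifest(rows=[{c: r[c] for c in MANIFEST_COLUMNS} for r in rows])

    records = []
    for row in manifest.rows:
        scans = {}
        for slot in SCAN_SLOTS:
            scan_path = base / row[slot]
            if not scan_path.exists():
                raise FormatError(
                    f"sample {row['sample_id']}: scan file for slot {slot} "
                    f"not found: {scan_path}")
            pol, role = _SLOT_META[slot]
            scans[slot] = read_scan(scan_path, layout=_layout_for(scan_path),
                                    n_rows=n_rows, n_cols=n_cols,
                                    polarization=pol, spot_role=role)
        records.append(SampleRecord(sample_id=row["sample_id"], scans=scans,
                                    label=LABEL_TO_CODE[row["label"]]))
    return records


# ---------------------------------------------------------------------------
# model files

def write_model_file(payload: dict, path: str | Path) -> None:
    """Write a trained-model payload as self-describing text (YAML key/value +
    nested arrays).  Floats round-trip exactly via their shortest repr."""
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_model_file(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"model file not found: {path}")
    payload = yaml.safe_load(path.read_text())
    if not isinstance(payload, dict) or "kind" not in payload:
        raise FormatError(f"{path}: not a melaspec model file (no 'kind' key)")
    return payload


def iter_shapes(records: Iterable[SampleRecord]) -> tuple[int, int]:
    """Common (n_rows, n_cols) of a cohort; raises if inconsistent."""
    shapes = {rec.scans["p1"].shape for rec in records}
    if len(shapes) > 1:
        raise ValidationError(f"cohort mixes scan shapes: {sorted(shapes)}")
    return shapes.pop()
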