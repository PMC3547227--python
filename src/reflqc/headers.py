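"""Instrument image-header parsing, auditing and pixel-value codecs.

Two text header dialects are supported, mirroring the metadata conventions
of an R-AXIS IV image plate and a Bruker PLATINUM CCD detector:

* **raxis** — key-value lines such as ``a3fPhi 0.0 0.0 1.0`` (spindle start,
  offset and rotation range per frame), ``a3fCircle 0.0 0.0 0.0`` (goniometer
  omega, chi and swing theta), beam centre ``a2fXray1``/``a2fXray2``,
  ``nIP_num`` (number of image plates), ``ImhCompression`` (overflow scale
  ratio R for stored pixel values >= 32768) and ``a4cSpindle`` (spindle
  orientation, frequently left empty by the instrument).
* **bruker** — keyword records ``ANGLES`` (Eulerian starting angles
  2theta, omega, phi, chi), ``AXIS`` (scan axis number, 3 = phi),
  ``NPIXELB`` (bytes per stored pixel), ``NEXP`` (second field: baseline
  offset), ``CCDPARM`` (first numeric field: detector gain in ADU/photon),
  ``CENTER`` (beam centre), and ``CORRECT``/``WARFIL``/``DARK`` correction
  provenance references.

The headers here are line-oriented ASCII fixtures: the binary layouts of
the real instrument formats are deliberately not reproduced, but every
field carries the semantics of its real counterpart.  Pixel codecs
implement the two overflow schemes: the R-AXIS scaled 16-bit scheme
(stored v >= 32768 decodes to (v - 32768) * R) and the Bruker 8-bit +
overflow-table scheme (stored 255 is a sentinel pointing at the next
unused wide-integer table entry, then a baseline offset is subtracted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "Dialect",
    "ScanAxis",
    "SpindleSense",
    "OverflowScheme",
    "ImageMetadata",
    "AuditFinding",
    "EncodedImage",
    "HeaderParseError",
    "parse_raxis_header",
    "parse_bruker_header",
    "parse_header",
    "decode_pixels",
    "encode_pixels",
    "audit_metadata",
]

RAXIS_OVERFLOW_PIVOT = 32768
BRUKER_SENTINEL = 255
DEFAULT_GAIN = 1.0
DEFAULT_RAXIS_OVERFLOW_RATIO = 8


class HeaderParseError(ValueError):
    """Malformed or incomplete header blob."""


class Dialect(str, Enum):
    raxis = "raxis"
    bruker = "bruker"


class ScanAxis(str, Enum):
    phi = "phi"
    omega = "omega"


class SpindleSense(str, Enum):
    cw = "cw"
    ccw = "ccw"
    unknown = "unknown"


class OverflowScheme(str, Enum):
    raxis_scaled = "raxis_scaled"
    bruker_table = "bruker_table"


@dataclass
class ImageMetadata:
    """Unified instrument/scan/detector description from either dialect."""

    dialect: Dialect
    n_fast: int
    n_slow: int
    pixel_size: float  # micrometres
    beam_center: tuple[float, float]  # (fast, slow) pixels
    scan_axis: ScanAxis
    start_angles: dict[str, float]  # axis name -> degrees
    rotation_per_frame: float  # degrees
    gain: float = DEFAULT_GAIN  # ADU per photon
    overflow_scheme: OverflowScheme = OverflowScheme.raxis_scaled
    baseline_offset: int = 0  # ADU
    overflow_ratio: int = DEFAULT_RAXIS_OVERFLOW_RATIO  # R-AXIS scale ratio R
    correction_refs: dict[str, str] = field(default_factory=dict)
    spindle_sense: SpindleSense = SpindleSense.unknown
    axis_convention: Optional[str] = None  # fast/slow pixel-coordinate convention
    goniometer_model: Optional[str] = None
    missing_fields: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_fast <= 0 or self.n_slow <= 0:
            raise ValueError("pixel counts must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if self.rotation_per_frame <= 0:
            raise ValueError("rotation per frame must be positive")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


@dataclass(frozen=True)
class AuditFinding:
    field: str
    severity: str  # "warning" | "info"
    note: str


@dataclass
class EncodedImage:
    raw: bytes
    overflow_table: list[int]
    lossy: bool = False


def _tokenize(blob: str) -> dict[str, list[str]]:
    records: dict[str, list[str]] = {}
    for line in blob.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        # accept both "KEY: values" (colon in the first token) and "KEY values"
        first = line.split(None, 1)[0]
        if ":" in first:
            key, _, rest = line.partition(":")
            records[key.strip()] = rest.split()
        else:
            parts = line.split()
            records[parts[0]] = parts[1:]
    return records


def _floats(records: dict, key: str, n: int) -> list[float]:
    if key not in records:
        raise HeaderParseError(f"mandatory key {key!r} absent from header")
    vals = records[key]
    if len(vals) < n:
        raise HeaderParseError(f"key {key!r}: expected {n} numeric fields, got {len(vals)}")
    try:
        return [float(v) for v in vals[:n]]
    except ValueError as exc:
        raise HeaderParseError(f"key {key!r}: malformed numeric field ({exc})") from None


def parse_raxis_header(blob: str) -> ImageMetadata:
    """Parse an R-AXIS-dialect text header into :class:`ImageMetadata`.

    Defaults applied for absent optional fields are recorded in
    ``missing_fields``: gain (default 1.0), spindle orientation
    (``a4cSpindle`` empty or absent) and the fast/slow pixel-coordinate
    convention (never provided by the instrument's native header).
    """
    rec = _tokenize(blob)
    missing: list[str] = []

    phi = _floats(rec, "a3fPhi", 3)  # (start, offset, rotation range per frame)
    circle = _floats(rec, "a3fCircle", 3)  # omega, chi, swing theta
    npix = _floats(rec, "nPixels", 2)
    psize = _floats(rec, "fPixelSize", 1)[0]
    bx = _floats(rec, "a2fXray1", 1)[0]
    by = _floats(rec, "a2fXray2", 1)[0]

    start_angles = {
        "phi": phi[0],
        "omega": circle[0],
        "chi": circle[1],
        "theta": circle[2],
    }
    if phi[2] <= 0:
        raise HeaderParseError("a3fPhi: rotation range per frame must be positive")

    if "fGain" in rec and rec["fGain"]:
        gain = _floats(rec, "fGain", 1)[0]
    else:
        gain = DEFAULT_GAIN
        missing.append("gain")

    spindle = SpindleSense.unknown
    if rec.get("a4cSpindle"):
        token = rec["a4cSpindle"][0].lower()
        if token in ("cw", "clockwise"):
            spindle = SpindleSense.cw
        elif token in ("ccw", "anticlockwise", "counterclockwise"):
            spindle = SpindleSense.ccw
    if spindle is SpindleSense.unknown:
        missing.append("spindle orientation")

    axis_conv = " ".join(rec["a4cAxes"]) if rec.get("a4cAxes") else None
    if axis_conv is None:
        missing.append("fast/slow convention")
    gonio = " ".join(rec["a4cGonio"]) if rec.get("a4cGonio") else None
    if gonio is None:
        # the native instrument header never records the axis layout; the
        # fixture dialect allows an optional a4cGonio record to supply it
        missing.append("goniometer axis layout")

    ratio = DEFAULT_RAXIS_OVERFLOW_RATIO
    if rec.get("ImhCompression"):
        try:
            ratio = int(float(rec["ImhCompression"][0]))
        except ValueError:
            raise HeaderParseError("ImhCompression: malformed numeric field") from None

    return ImageMetadata(
        dialect=Dialect.raxis,
        n_fast=int(npix[0]),
        n_slow=int(npix[1]),
        pixel_size=psize,
        beam_center=(bx, by),
        scan_axis=ScanAxis.phi,
        start_angles=start_angles,
        rotation_per_frame=phi[2],
        gain=gain,
        overflow_scheme=OverflowScheme.raxis_scaled,
        baseline_offset=0,
        overflow_ratio=ratio,
        spindle_sense=spindle,
        axis_convention=axis_conv,
        goniometer_model=gonio,
        missing_fields=missing,
    )


_BRUKER_AXES = {2: ScanAxis.omega, 3: ScanAxis.phi}


def parse_bruker_header(blob: str) -> ImageMetadata:
    """Parse a Bruker-dialect text header into :class:`ImageMetadata`.

    ANGLES maps in order to (two_theta, omega, phi, chi); AXIS selects the
    scan axis (3 = phi, 2 = omega); the detector gain is the first numeric
    field of CCDPARM; the baseline offset is the second field of NEXP.
    """
    rec = _tokenize(blob)
    missing: list[str] = []

    if "NPIXELB" not in rec:
        raise HeaderParseError("mandatory key 'NPIXELB' absent (pixel depth unrecoverable)")
    angles = _floats(rec, "ANGLES", 4)
    axis_no = int(_floats(rec, "AXIS", 1)[0])
    if axis_no not in _BRUKER_AXES:
        raise HeaderParseError(f"AXIS: {axis_no} outside the documented set {sorted(_BRUKER_AXES)}")
    nrows = int(_floats(rec, "NROWS", 1)[0])
    ncols = int(_floats(rec, "NCOLS", 1)[0])
    psize = _floats(rec, "PIXSIZE", 1)[0]
    cx, cy = _floats(rec, "CENTER", 2)

    nexp = _floats(rec, "NEXP", 2) if "NEXP" in rec else None
    baseline = int(nexp[1]) if nexp is not None else 0
    if nexp is None:
        missing.append("baseline offset")

    if "CCDPARM" in rec and rec["CCDPARM"]:
        gain = _floats(rec, "CCDPARM", 1)[0]
    else:
        gain = DEFAULT_GAIN
        missing.append("gain")

    increment = _floats(rec, "INCREME", 1)[0] if "INCREME" in rec else 0.5

    corr: dict[str, str] = {}
    for key, slot in (("CORRECT", "flood_field"), ("WARFIL", "distortion"), ("DARK", "dark")):
        if rec.get(key):
            corr[slot] = rec[key][0]
        else:
            missing.append(f"{slot} reference")

    gonio = rec["MACH3"][0] if rec.get("MACH3") else None
    if gonio is None:
        missing.append("goniometer axis layout")
    spindle = SpindleSense.unknown
    if rec.get("SENSE"):
        token = rec["SENSE"][0].lower()
        if token in ("cw", "clockwise"):
            spindle = SpindleSense.cw
        elif token in ("ccw", "anticlockwise", "counterclockwise"):
            spindle = SpindleSense.ccw
    if spindle is SpindleSense.unknown:
        # the native format relies on a-priori knowledge of the rotation
        # senses; the fixture dialect allows an optional SENSE record
        missing.append("spindle orientation")

    return ImageMetadata(
        dialect=Dialect.bruker,
        n_fast=ncols,
        n_slow=nrows,
        pixel_size=psize,
        beam_center=(cx, cy),
        scan_axis=_BRUKER_AXES[axis_no],
        start_angles={
            "two_theta": angles[0],
            "omega": angles[1],
            "phi": angles[2],
            "chi": angles[3],
        },
        rotation_per_frame=increment,
        gain=gain,
        overflow_scheme=OverflowScheme.bruker_table,
        baseline_offset=baseline,
        correction_refs=corr,
        spindle_sense=spindle,
        axis_convention="fast=x slow=y",  # defined by the dialect itself
        goniometer_model=gonio,
        missing_fields=missing,
    )


def parse_header(blob: str, dialect: str | Dialect) -> ImageMetadata:
    d = Dialect(dialect)
    return parse_raxis_header(blob) if d is Dialect.raxis else parse_bruker_header(blob)


# ---------------------------------------------------------------------------
# pixel codecs


def decode_pixels(
    raw: bytes,
    md: ImageMetadata,
    overflow_table: list[int] | None = None,
) -> np.ndarray:
    """Decode a stored pixel buffer to intensities in ADU.

    Bruker: one byte per pixel; a stored 255 is replaced by the next unused
    overflow-table entry in raster order; the baseline offset is then
    subtracted from every pixel.  R-AXIS: two bytes (little-endian) per
    pixel; stored values >= 32768 decode to (value - 32768) * R.
    """
    n = md.n_fast * md.n_slow
    if md.overflow_scheme is OverflowScheme.bruker_table:
        if len(raw) != n:
            raise ValueError(f"bruker buffer: expected {n} bytes, got {len(raw)}")
        vals = np.frombuffer(raw, dtype=np.uint8).astype(np.int64)
        sentinel = vals == BRUKER_SENTINEL
        n_over = int(sentinel.sum())
        table = overflow_table or []
        if n_over > len(table):
            raise ValueError(
                f"{n_over} overflow sentinels but only {len(table)} table entries"
            )
        vals[sentinel] = np.asarray(table[:n_over], dtype=np.int64)
        return vals - md.baseline_offset
    # raxis
    if len(raw) % 2:
        raise ValueError("raxis buffer has odd byte count")
    if len(raw) != 2 * n:
        raise ValueError(f"raxis buffer: expected {2 * n} bytes, got {len(raw)}")
    vals = np.frombuffer(raw, dtype="<u2").astype(np.int64)
    over = vals >= RAXIS_OVERFLOW_PIVOT
    vals[over] = (vals[over] - RAXIS_OVERFLOW_PIVOT) * md.overflow_ratio
    return vals


def encode_pixels(intensities: np.ndarray, md: ImageMetadata) -> EncodedImage:
    """Inverse of :func:`decode_pixels`, for fixture generation.

    R-AXIS values >= 32768 that are not on the (v - 32768) * R grid are
    encoded to the nearest grid point and the result is flagged lossy.
    """
    x = np.asarray(intensities).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("intensities must be finite")
    x = np.round(x).astype(np.int64)

    if md.overflow_scheme is OverflowScheme.bruker_table:
        stored = x + md.baseline_offset
        if stored.min() < 0:
            raise ValueError("value below the representable range (baseline underflow)")
        if stored.max() >= 2**32:
            raise ValueError("value exceeds the representable bruker range (2^32)")
        over = stored >= BRUKER_SENTINEL
        table = [int(v) for v in stored[over]]
        out = stored.copy()
        out[over] = BRUKER_SENTINEL
        return EncodedImage(out.astype(np.uint8).tobytes(), table, lossy=False)

    # raxis
    if x.min() < 0:
        raise ValueError("raxis intensities must be non-negative")
    r = md.overflow_ratio
    max_repr = (2**16 - 1 - RAXIS_OVERFLOW_PIVOT) * r
    if x.max() > max_repr:
        raise ValueError(f"value exceeds the representable raxis range ({max_repr})")
    over = x >= RAXIS_OVERFLOW_PIVOT
    stored = x.copy()
    q = np.round(x[over] / r).astype(np.int64)
    lossy = bool(np.any(q * r != x[over]))
    stored[over] = q + RAXIS_OVERFLOW_PIVOT
    return EncodedImage(stored.astype("<u2").tobytes(), [], lossy=lossy)


# ---------------------------------------------------------------------------
# metadata audit

_AUDIT_RULES: list[tuple[str, str, str]] = [
    ("spindle orientation", "warning",
     "rotation sense of the spindle axis not recorded; must be known a priori"),
    ("fast/slow convention", "warning",
     "fastest/slowest running pixel coordinates not given; eight interpretations possible"),
    ("gain", "warning",
     "detector gain absent; default 1.0 ADU/photon assumed, biasing Poisson sigmas"),
    ("goniometer axis layout", "warning",
     "goniometer axis layout not described in the header"),
    ("baseline offset", "warning",
     "baseline offset absent; stored negative values cannot be recovered"),
    ("flood_field reference", "info",
     "no flood-field correction provenance; non-uniformity correction unverifiable"),
    ("distortion reference", "info",
     "no spatial-distortion (unwarp) provenance"),
    ("dark reference", "info",
     "no dark-current correction provenance"),
]


def audit_metadata(md: ImageMetadata) -> list[AuditFinding]:
    """Report needed-but-absent metadata as audit findings.

    One finding per defaulted or unrecorded item in ``md.missing_fields``,
    covering spindle/rotation sense, the fast/slow pixel-coordinate
    convention, gain, goniometer axis layout and correction provenance.
    Empty iff everything the downstream processing needs is present.
    Monotone: removing a header field never shrinks the findings list.
    """
    present = set(md.missing_fields)
    return [
        AuditFinding(fieldname, severity, note)
        for fieldname, severity, note in _AUDIT_RULES
        if fieldname in present
    ]
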