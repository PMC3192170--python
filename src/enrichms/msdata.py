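"""Targeted MS/MS run model, I/O, XIC extraction and peak integration.

A :class:`Run` is a time-ordered list of centroided product-ion scans, each
acquired against a precursor target from the inclusion list.  Extracted ion
chromatograms (XICs) are built per product ion by summing peak intensities
within a +/-0.5 Da window (the assay's product-ion mass tolerance), and
chromatographic peaks are integrated with the trapezoidal rule.

Two on-disk formats are supported: mzML (read and write; retention times
converted to minutes on read) and a plain tabular TSV with one row per
centroid peak, which round-trips bit-exactly.
"""

from __future__ import annotations

import base64
import json
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SpectrumScan",
    "Run",
    "XIC",
    "PeakBounds",
    "IntegratedPeak",
    "read_run",
    "write_run",
    "extract_product_xic",
    "detect_peak",
    "integrate",
]


@dataclass
class SpectrumScan:
    """One centroided product-ion scan against a precursor target."""

    retention_time: float  # minutes
    precursor_target_mz: float
    peaks: list[tuple[float, float]]  # (mz, intensity), sorted by mz

    def __post_init__(self) -> None:
        self.retention_time = float(self.retention_time)
        self.precursor_target_mz = float(self.precursor_target_mz)
        if self.retention_time < 0:
            raise ValueError("retention_time must be >= 0")
        self.peaks = sorted(
            ((float(mz), float(i)) for mz, i in self.peaks), key=lambda p: p[0]
        )
        if any(intensity < 0 for _, intensity in self.peaks):
            raise ValueError("peak intensities must be >= 0")


@dataclass
class Run:
    """A single targeted LC-MS/MS injection."""

    scans: list[SpectrumScan] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [s.retention_time for s in self.scans]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("scans must be strictly increasing in retention time")

    def __len__(self) -> int:
        return len(self.scans)


@dataclass
class XIC:
    """Extracted ion chromatogram for one product ion."""

    target_mz: float
    tolerance: float
    times: np.ndarray  # minutes, increasing
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class PeakBounds:
    """Detected chromatographic peak boundaries; ``found`` is False for an
    all-zero XIC (no-peak result rather than an exception)."""

    left_bound: float
    right_bound: float
    apex_time: float
    found: bool = True


@dataclass(frozen=True)
class IntegratedPeak:
    area: float  # intensity * minutes
    apex_time: float
    left_bound: float
    right_bound: float

    def __post_init__(self) -> None:
        if not self.left_bound <= self.apex_time <= self.right_bound:
            raise ValueError("apex_time must lie within bounds")
        if self.area < 0:
            raise ValueError("area must be >= 0")


# ---------------------------------------------------------------------------
# Tabular format: TSV, one row per centroid peak; '#meta' comment line
# carries the run metadata as JSON.  Floats are written with repr so the
# round trip is bit-exact.

_TABULAR_HEADER = "scan_index\trt_min\tprecursor_mz\tpeak_mz\tintensity"


def write_run_tabular(run: Run, path: str | Path) -> None:
    with open(path, "w") as handle:
        if run.metadata:
            handle.write(f"#meta {json.dumps(run.metadata, sort_keys=True)}\n")
        handle.write(_TABULAR_HEADER + "\n")
        for index, scan in enumerate(run.scans):
            rt, prec = float(scan.retention_time), float(scan.precursor_target_mz)
            if not scan.peaks:
                handle.write(f"{index}\t{rt!r}\t{prec!r}\t\t\n")
                continue
            for mz, intensity in scan.peaks:
                handle.write(
                    f"{index}\t{rt!r}\t{prec!r}\t{float(mz)!r}\t{float(intensity)!r}\n"
                )


def read_run_tabular(path: str | Path) -> Run:
    metadata: dict = {}
    scans: dict[int, SpectrumScan] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#meta "):
                metadata = json.loads(line[len("#meta ") :])
                continue
            if line.startswith("#") or line == _TABULAR_HEADER:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}: malformed row at line {line_no}")
            index = int(fields[0])
            if index not in scans:
                scans[index] = SpectrumScan(
                    retention_time=float(fields[1]),
                    precursor_target_mz=float(fields[2]),
                    peaks=[],
                )
            if fields[3]:
                scans[index].peaks.append((float(fields[3]), float(fields[4])))
    ordered = [scans[i] for i in sorted(scans)]
    for scan in ordered:
        scan.peaks.sort(key=lambda p: p[0])
    return Run(scans=ordered, metadata=metadata)


# ---------------------------------------------------------------------------
# mzML: read and written directly over lxml.  The reader covers the common
# encoding subset (32-/64-bit float arrays, no compression or zlib; scan
# start time in minutes or seconds); the writer emits 64-bit float,
# uncompressed arrays.  Retention times are stored in minutes and converted
# from seconds on read when the file declares seconds.

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{count}" defaultDataProcessingRef="dp">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _encode_array(values: Sequence[float]) -> str:
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode("ascii")


def _binary_array_xml(values: Sequence[float], accession: str, name: str) -> str:
    encoded = _encode_array(values)
    return (
        f'          <binaryDataArray encodedLength="{len(encoded)}">\n'
        f'            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        f'            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        f'            <cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>\n'
        f"            <binary>{encoded}</binary>\n"
        f"          </binaryDataArray>\n"
    )


def write_run_mzml(run: Run, path: str | Path) -> None:
    run_id = str(run.metadata.get("replicate_id", "run"))
    parts = [_MZML_HEADER.format(run_id=run_id, count=len(run.scans))]
    for index, scan in enumerate(run.scans):
        mzs = [p[0] for p in scan.peaks]
        intensities = [p[1] for p in scan.peaks]
        parts.append(
            f'      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{len(mzs)}">\n'
            f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>\n'
            f'        <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>\n'
            f'        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
            f"        <scanList count=\"1\">\n"
            f'          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>\n'
            f"          <scan>\n"
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{scan.retention_time!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>\n'
            f"          </scan>\n"
            f"        </scanList>\n"
            f"        <precursorList count=\"1\">\n"
            f"          <precursor>\n"
            f"            <selectedIonList count=\"1\">\n"
            f"              <selectedIon>\n"
            f'                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{scan.precursor_target_mz!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
            f"              </selectedIon>\n"
            f"            </selectedIonList>\n"
            f"          </precursor>\n"
            f"        </precursorList>\n"
            f'        <binaryDataArrayList count="2">\n'
            + _binary_array_xml(mzs, "MS:1000514", "m/z array")
            + _binary_array_xml(intensities, "MS:1000515", "intensity array")
            + "        </binaryDataArrayList>\n"
            + "      </spectrum>\n"
        )
    parts.append(_MZML_FOOTER)
    Path(path).write_text("".join(parts))


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _cv_params(element) -> dict[str, tuple[str, dict]]:
    """name -> (value, attributes) for the direct cvParam children."""
    params = {}
    for cv in element.findall(f"{_MZML_NS}cvParam"):
        params[cv.get("name")] = (cv.get("value", ""), dict(cv.attrib))
    return params


def _decode_binary_array(array_element) -> list[float]:
    params = _cv_params(array_element)
    binary = array_element.find(f"{_MZML_NS}binary")
    raw = base64.b64decode((binary.text or "").encode("ascii"))
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    elif "no compression" not in params and len(params) > 2:
        unknown = set(params) - {"64-bit float", "32-bit float", "m/z array",
                                 "intensity array", "no compression"}
        if unknown:
            raise ValueError(f"unsupported binary encoding: {sorted(unknown)}")
    width = "f" if "32-bit float" in params else "d"
    size = struct.calcsize(width)
    return list(struct.unpack(f"<{len(raw) // size}{width}", raw))


def read_run_mzml(path: str | Path) -> Run:
    from lxml import etree

    tree = etree.parse(str(path))
    scans: list[SpectrumScan] = []
    for index, spectrum in enumerate(tree.iter(f"{_MZML_NS}spectrum")):
        spectrum_id = spectrum.get("id", f"index={index}")
        try:
            scan = spectrum.find(
                f"{_MZML_NS}scanList/{_MZML_NS}scan"
            )
            rt_value, rt_attrs = _cv_params(scan)["scan start time"]
            rt_min = float(rt_value)
            if rt_attrs.get("unitName", "minute").startswith("second"):
                rt_min /= 60.0
            ion = spectrum.find(
                f"{_MZML_NS}precursorList/{_MZML_NS}precursor/"
                f"{_MZML_NS}selectedIonList/{_MZML_NS}selectedIon"
            )
            precursor = float(_cv_params(ion)["selected ion m/z"][0])
            mzs: list[float] = []
            intensities: list[float] = []
            for array in spectrum.findall(
                f"{_MZML_NS}binaryDataArrayList/{_MZML_NS}binaryDataArray"
            ):
                params = _cv_params(array)
                values = _decode_binary_array(array)
                if "m/z array" in params:
                    mzs = values
                elif "intensity array" in params:
                    intensities = values
            if len(mzs) != len(intensities):
                raise ValueError("m/z and intensity arrays differ in length")
        except (KeyError, AttributeError, TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: malformed spectrum {spectrum_id!r}: {exc}"
            ) from exc
        scans.append(
            SpectrumScan(
                retention_time=rt_min,
                precursor_target_mz=precursor,
                peaks=list(zip(mzs, intensities)),
            )
        )
    return Run(scans=scans)


def read_run(path: str | Path, format: str | None = None) -> Run:
    """Read a targeted run; format inferred from the extension when not
    given ('mzML' or 'tabular')."""
    if format is None:
        format = "mzML" if str(path).lower().endswith(".mzml") else "tabular"
    if format.lower() == "mzml":
        return read_run_mzml(path)
    if format.lower() == "tabular":
        return read_run_tabular(path)
    raise ValueError(f"unknown run format {format!r}")


def write_run(run: Run, path: str | Path, format: str | None = None) -> None:
    if format is None:
        format = "mzML" if str(path).lower().endswith(".mzml") else "tabular"
    if format.lower() == "mzml":
        write_run_mzml(run, path)
    elif format.lower() == "tabular":
        write_run_tabular(run, path)
    else:
        raise ValueError(f"unknown run format {format!r}")


# ---------------------------------------------------------------------------
# XIC extraction and peak integration


def extract_product_xic(
    run: Run,
    precursor_target: float,
    fragment_mz: float,
    tolerance: float = 0.5,
    precursor_tolerance: float = 1.5,
) -> XIC:
    """Extract a product-ion chromatogram.

    Over scans whose precursor target lies within +/-``precursor_tolerance``
    of ``precursor_target``, sums peak intensities with
    ``|mz - fragment_mz| <= tolerance`` (boundary inclusive); scans with no
    matching peak contribute an intensity of 0.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    times, intensities = [], []
    for scan in run.scans:
        if abs(scan.precursor_target_mz - precursor_target) > precursor_tolerance:
            continue
        total = sum(
            intensity
            for mz, intensity in scan.peaks
            if abs(mz - fragment_mz) <= tolerance
        )
        times.append(scan.retention_time)
        intensities.append(total)
    return XIC(
        target_mz=fragment_mz,
        tolerance=tolerance,
        times=np.array(times),
        intensities=np.array(intensities),
    )


def detect_peak(
    xic: XIC, boundary_fraction: float = 0.01, valley_fraction: float = 0.05
) -> PeakBounds:
    """Locate the chromatographic peak in an XIC.

    The apex is the global intensity maximum.  Bounds extend outward from
    the apex until intensity falls below ``boundary_fraction`` of the apex
    or a local minimum below ``valley_fraction`` of the apex is reached,
    clipped to the XIC time range.  An all-zero XIC yields a flagged
    no-peak result.
    """
    if len(xic) < 3:
        raise ValueError("XIC must have at least 3 points")
    y = xic.intensities
    apex_idx = int(np.argmax(y))
    apex = y[apex_idx]
    if apex <= 0:
        t0, t1 = float(xic.times[0]), float(xic.times[-1])
        return PeakBounds(t0, t1, t0, found=False)
    floor = boundary_fraction * apex
    valley = valley_fraction * apex

    def is_local_min(i: int) -> bool:
        left = y[i - 1] if i > 0 else np.inf
        right = y[i + 1] if i < len(y) - 1 else np.inf
        return y[i] <= left and y[i] <= right

    left_idx = apex_idx
    while left_idx > 0:
        nxt = left_idx - 1
        if y[nxt] < floor or (is_local_min(nxt) and y[nxt] < valley):
            left_idx = nxt
            break
        left_idx = nxt
    right_idx = apex_idx
    while right_idx < len(y) - 1:
        nxt = right_idx + 1
        if y[nxt] < floor or (is_local_min(nxt) and y[nxt] < valley):
            right_idx = nxt
            break
        right_idx = nxt
    return PeakBounds(
        left_bound=float(xic.times[left_idx]),
        right_bound=float(xic.times[right_idx]),
        apex_time=float(xic.times[apex_idx]),
    )


def integrate(xic: XIC, bounds: PeakBounds | tuple[float, float]) -> IntegratedPeak:
    """Trapezoidal peak area of an XIC over ``bounds``.

    Bounds must lie within the XIC time range; only XIC points inside
    ``[left, right]`` contribute.
    """
    if isinstance(bounds, PeakBounds):
        left, right = bounds.left_bound, bounds.right_bound
    else:
        left, right = bounds
    if left > right:
        raise ValueError("inverted integration bounds")
    if len(xic) == 0:
        return IntegratedPeak(0.0, left, left, right)
    if left < xic.times[0] - 1e-12 or right > xic.times[-1] + 1e-12:
        raise ValueError("bounds outside XIC time range")
    mask = (xic.times >= left) & (xic.times <= right)
    t, y = xic.times[mask], xic.intensities[mask]
    area = float(np.trapezoid(y, t)) if len(t) >= 2 else 0.0
    apex_time = float(t[np.argmax(y)]) if len(t) else left
    return IntegratedPeak(
        area=max(area, 0.0), apex_time=apex_time, left_bound=left, right_bound=right
    )


def union_bounds(a: PeakBounds, b: PeakBounds) -> PeakBounds:
    """Union of two peak-bound intervals (co-eluting species share an
    integration window); apex taken from the first found peak."""
    if not a.found:
        return b
    if not b.found:
        return a
    return PeakBounds(
        left_bound=min(a.left_bound, b.left_bound),
        right_bound=max(a.right_bound, b.right_bound),
        apex_time=a.apex_time,
    )
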