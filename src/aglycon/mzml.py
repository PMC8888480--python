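"""Read-only MS2 extraction from mzML 1.1 files.

Only the subset of mzML needed here is interpreted: per-spectrum cvParams
for MS level and scan start time (seconds or minutes), the first selected
ion of the first precursor, and the m/z / intensity binary arrays (32- or
64-bit floats, plain or zlib-compressed).  Profile data, chromatograms and
indexed wrappers are ignored.
"""

from __future__ import annotations

import base64
import logging
import struct
import zlib
from pathlib import Path

import numpy as np
from lxml import etree

from .spectra import FragmentPeak, Spectrum

logger = logging.getLogger(__name__)

# PSI-MS controlled-vocabulary accessions
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CHARGE = "MS:1000041"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_COLLISION_ENERGY = "MS:1000045"


def _cv_params(elem) -> list:
    return [c for c in elem.iter("{*}cvParam")]


def _decode_array(bda) -> np.ndarray:
    dtype = "<f8"
    compressed = False
    for cv in _cv_params(bda):
        acc = cv.get("accession")
        if acc == _ACC_F32:
            dtype = "<f4"
        elif acc == _ACC_ZLIB:
            compressed = True
    binary = bda.find("{*}binary")
    if binary is None or not (binary.text or "").strip():
        return np.array([], dtype=float)
    raw = base64.b64decode(binary.text)
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(elem, path: Path) -> Spectrum | None:
    """Return a Spectrum for MS2 scans, None for any other MS level."""
    ms_level = None
    for cv in elem.iterchildren("{*}cvParam"):
        if cv.get("accession") == _ACC_MS_LEVEL:
            ms_level = int(cv.get("value"))
    if ms_level != 2:
        return None

    rt_min = None
    scan_list = elem.find("{*}scanList")
    if scan_list is not None:
        for cv in _cv_params(scan_list):
            if cv.get("accession") == _ACC_SCAN_START:
                value = float(cv.get("value"))
                unit = (cv.get("unitName") or "").lower()
                rt_min = value if unit.startswith("minute") else value / 60.0

    precursor_mz = None
    charge = 1
    collision_energy = None
    prec_list = elem.find("{*}precursorList")
    if prec_list is not None:
        for cv in _cv_params(prec_list):
            acc = cv.get("accession")
            if acc == _ACC_SELECTED_MZ:
                precursor_mz = float(cv.get("value"))
            elif acc == _ACC_CHARGE:
                charge = int(cv.get("value"))
            elif acc == _ACC_COLLISION_ENERGY:
                collision_energy = f"{cv.get('value')} eV"
    if precursor_mz is None:
        logger.warning("%s: MS2 scan %r without selected ion m/z skipped", path, elem.get("id"))
        return None

    mz = intensity = None
    for bda in elem.iter("{*}binaryDataArray"):
        accessions = {cv.get("accession") for cv in _cv_params(bda)}
        if _ACC_MZ_ARRAY in accessions:
            mz = _decode_array(bda)
        elif _ACC_INT_ARRAY in accessions:
            intensity = _decode_array(bda)
    if mz is None or intensity is None:
        logger.warning("%s: MS2 scan %r lacks peak arrays, skipped", path, elem.get("id"))
        return None

    return Spectrum(
        precursor_mz=precursor_mz,
        peaks=tuple(FragmentPeak(float(m), float(i)) for m, i in zip(mz, intensity)),
        precursor_charge=max(charge, 1),
        rt=rt_min,
        collision_energy=collision_energy,
        source_id=f"{path.name}:{elem.get('id', '')}",
    )


def read_mzml_ms2(path: str | Path) -> list[Spectrum]:
    """Extract all MS-level-2 spectra from an mzML file.

    Scan start times are converted to minutes.  A file without MS2 scans
    yields an empty list (with a warning); malformed XML raises
    ``ValueError``.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    try:
        for _, elem in etree.iterparse(str(path), events=("end",), tag="{*}spectrum"):
            s = _parse_spectrum(elem, path)
            if s is not None:
                spectra.append(s)
            elem.clear(keep_tail=True)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{path}: not readable as mzML: {exc}") from exc
    if not spectra:
        logger.warning("%s: no MS2 spectra found", path)
    return spectra
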