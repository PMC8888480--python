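"""Core domain types for centroided MS/MS spectra and spectral libraries.

The containers here are deliberately small: a :class:`FragmentPeak` is an
(m/z, intensity) pair, a :class:`Spectrum` is a precursor plus an ordered
peak list, and a :class:`SpectralLibrary` groups reference spectra by
compound.  File I/O covers the three text formats the workflow touches:
MGF (read/write, via :mod:`pyteomics.mgf`), NIST-style MSP libraries
(read/write, via :mod:`matchms`) and mzML (read-only MS2 extraction, in
:mod:`aglycon.mzml`).

Conventions
-----------
* retention time is stored in **minutes**; MGF files use RTINSECONDS and
  are converted on the way in/out,
* peaks are always sorted by ascending m/z; duplicate peaks closer than
  ``PEAK_MERGE_TOL`` are merged (summed intensity at the
  intensity-weighted mean m/z),
* base-peak normalisation puts the most intense peak at 100 (percent
  scale); the intensity cut-off factor of a library search is defined
  relative to that base peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

#: peaks closer than this (Th) are considered duplicates and merged
PEAK_MERGE_TOL = 1e-4
#: upper bound on plausible fragment m/z for the supported instruments (Th)
MZ_UPPER_BOUND = 5000.0
#: precursor m/z agreement required between spectra of one library compound (Th)
PRECURSOR_GROUP_TOL = 0.01


class FragmentPeak(NamedTuple):
    """One centroided fragment peak: m/z in Thomson, intensity in arbitrary units."""

    mz: float
    intensity: float


def _merge_close_peaks(peaks: list[FragmentPeak]) -> tuple[FragmentPeak, ...]:
    """Sort peaks by m/z and merge runs closer than ``PEAK_MERGE_TOL``."""
    if not peaks:
        return ()
    peaks = sorted(peaks, key=lambda p: p.mz)
    merged: list[FragmentPeak] = [peaks[0]]
    for p in peaks[1:]:
        last = merged[-1]
        if p.mz - last.mz < PEAK_MERGE_TOL:
            total = last.intensity + p.intensity
            if total > 0:
                mz = (last.mz * last.intensity + p.mz * p.intensity) / total
            else:
                mz = 0.5 * (last.mz + p.mz)
            merged[-1] = FragmentPeak(mz, total)
        else:
            merged.append(p)
    return tuple(merged)


@dataclass
class Spectrum:
    """A single product-ion (MS2) spectrum.

    Parameters
    ----------
    precursor_mz : float
        Selected precursor m/z in Thomson.
    peaks : sequence of FragmentPeak
        Centroided peak list; sorted and de-duplicated on construction.
    precursor_charge : int
        Charge state, default 1 (positive mode, singly protonated).
    rt : float, optional
        Retention time in minutes.
    collision_energy : str, optional
        Free-form collision-energy tag, e.g. ``"20 eV"`` or ``"NCE35"``.
    source_id : str
        Provenance string (file + scan identifier).
    """

    precursor_mz: float
    peaks: tuple[FragmentPeak, ...]
    precursor_charge: int = 1
    rt: float | None = None
    collision_energy: str | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor m/z must be positive, got {self.precursor_mz}")
        if self.precursor_charge < 1:
            raise ValueError(f"precursor charge must be >= 1, got {self.precursor_charge}")
        if self.rt is not None and self.rt < 0:
            raise ValueError(f"retention time must be non-negative, got {self.rt}")
        peaks = [FragmentPeak(float(p[0]), float(p[1])) for p in self.peaks]
        for p in peaks:
            if p.mz <= 0:
                raise ValueError(f"fragment m/z must be positive, got {p.mz}")
            if p.mz >= MZ_UPPER_BOUND:
                raise ValueError(f"fragment m/z {p.mz} beyond instrument range ({MZ_UPPER_BOUND})")
            if p.intensity < 0:
                raise ValueError(f"intensity must be non-negative, got {p.intensity}")
        self.peaks = _merge_close_peaks(peaks)

    # -- convenience views -------------------------------------------------
    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    @property
    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)

    def __len__(self) -> int:
        return len(self.peaks)


def normalize_spectrum(s: Spectrum, cutoff_factor: float = 0.0) -> Spectrum:
    """Rescale so the base peak has intensity 100 and drop low peaks.

    Peaks whose rescaled intensity falls below ``100 * cutoff_factor`` are
    removed.  Idempotent: applying it twice equals applying it once.
    """
    if not 0 <= cutoff_factor < 1:
        raise ValueError(f"cutoff_factor must be in [0, 1), got {cutoff_factor}")
    if not s.peaks:
        raise ValueError(f"cannot normalize empty spectrum {s.source_id!r}")
    base = s.base_peak_intensity
    if base == 0:
        raise ValueError(f"cannot normalize all-zero spectrum {s.source_id!r}")
    scale = 100.0 / base
    threshold = 100.0 * cutoff_factor
    peaks = tuple(
        FragmentPeak(p.mz, p.intensity * scale)
        for p in s.peaks
        if p.intensity * scale >= threshold
    )
    return replace(s, peaks=peaks)


@dataclass
class CompoundEntry:
    """All reference spectra of one library compound (typically one per collision energy)."""

    name: str
    precursor_mz: float
    spectra: list[Spectrum]
    formula: str | None = None
    rt: float | None = None

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError(f"compound {self.name!r} has no spectra")
        for s in self.spectra:
            if abs(s.precursor_mz - self.precursor_mz) > PRECURSOR_GROUP_TOL:
                raise ValueError(
                    f"compound {self.name!r}: spectrum precursor {s.precursor_mz} "
                    f"deviates from entry precursor {self.precursor_mz} by more than "
                    f"{PRECURSOR_GROUP_TOL} Th"
                )


@dataclass
class SpectralLibrary:
    """A set of compound entries with unique names."""

    entries: list[CompoundEntry] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate compound names in library: {dupes}")

    def get(self, name: str) -> CompoundEntry | None:
        for e in self.entries:
            if e.name == name:
                return e
        return None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[CompoundEntry]:
        return iter(self.entries)


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    PEPMASS (first value) maps to ``precursor_mz``, CHARGE to
    ``precursor_charge`` (default 1+), RTINSECONDS is converted to minutes,
    TITLE to ``source_id``.  A block without PEPMASS is an error.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    with _mgf.read(str(path), use_index=False) as reader:
        for i, block in enumerate(reader):
            params = block.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise ValueError(f"{path}: MGF block {i} has no PEPMASS")
            charge_list = params.get("charge")
            charge = int(charge_list[0]) if charge_list else 1
            if charge < 0:
                # paper workflow is positive mode; keep magnitude, flag upstream
                logger.warning("%s: block %d has negative charge %d", path, i, charge)
                charge = abs(charge)
            rt_s = params.get("rtinseconds")
            rt = float(rt_s) / 60.0 if rt_s is not None else None
            ce = params.get("collision_energy")
            title = params.get("title", f"{path.name}:scan={i}")
            peaks = tuple(
                FragmentPeak(float(mz), float(it))
                for mz, it in zip(block["m/z array"], block["intensity array"])
            )
            spectra.append(
                Spectrum(
                    precursor_mz=float(pepmass[0]),
                    peaks=peaks,
                    precursor_charge=max(charge, 1),
                    rt=rt,
                    collision_energy=str(ce) if ce is not None else None,
                    source_id=str(title),
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; round-trips precursor m/z, RT and peaks to 1e-4."""
    records = []
    for s in spectra:
        params: dict = {
            "title": s.source_id,
            "pepmass": (s.precursor_mz, None),
            "charge": f"{s.precursor_charge}+",
        }
        if s.rt is not None:
            params["rtinseconds"] = s.rt * 60.0
        if s.collision_energy is not None:
            params["collision_energy"] = s.collision_energy
        records.append(
            {
                "m/z array": np.array([p.mz for p in s.peaks]),
                "intensity array": np.array([p.intensity for p in s.peaks]),
                "params": params,
            }
        )
    with open(path, "w") as fh:
        _mgf.write(records, output=fh)


# ---------------------------------------------------------------------------
# MSP
# ---------------------------------------------------------------------------

def read_msp_library(path: str | Path) -> SpectralLibrary:
    """Read a NIST-style MSP file into a :class:`SpectralLibrary`.

    Records are grouped by compound name; several records under the same
    name become the multiple (per collision energy) reference spectra of
    one :class:`CompoundEntry`.  Records without peaks are skipped with a
    warning; two records sharing a name but disagreeing in precursor m/z
    by more than ``PRECURSOR_GROUP_TOL`` are an error.
    """
    from matchms.importing import load_from_msp

    path = Path(path)
    grouped: dict[str, list[Spectrum]] = {}
    meta: dict[str, dict] = {}
    for rec in load_from_msp(str(path), metadata_harmonization=True):
        if rec is None:
            continue
        md = rec.metadata
        name = md.get("compound_name") or md.get("name")
        if name is None:
            logger.warning("%s: MSP record without a name skipped", path)
            continue
        if rec.peaks is None or len(rec.peaks.mz) == 0:
            logger.warning("%s: MSP record %r has no peaks, skipped", path, name)
            continue
        prec = md.get("precursor_mz")
        if prec is None:
            logger.warning("%s: MSP record %r has no precursor m/z, skipped", path, name)
            continue
        prec = float(prec)
        if name in grouped:
            first = grouped[name][0].precursor_mz
            if abs(prec - first) > PRECURSOR_GROUP_TOL:
                raise ValueError(
                    f"{path}: records named {name!r} disagree in precursor m/z "
                    f"({first} vs {prec})"
                )
        rt = md.get("retention_time")
        ce = md.get("collision_energy")
        spectrum = Spectrum(
            precursor_mz=prec,
            peaks=tuple(
                FragmentPeak(float(mz), float(it))
                for mz, it in zip(rec.peaks.mz, rec.peaks.intensities)
            ),
            rt=float(rt) if rt is not None else None,
            collision_energy=str(ce) if ce is not None else None,
            source_id=f"{path.name}:{name}",
        )
        grouped.setdefault(name, []).append(spectrum)
        entry_meta = meta.setdefault(name, {})
        if md.get("formula"):
            entry_meta["formula"] = str(md["formula"])
    entries = [
        CompoundEntry(
            name=name,
            precursor_mz=specs[0].precursor_mz,
            spectra=specs,
            formula=meta[name].get("formula"),
            rt=next((s.rt for s in specs if s.rt is not None), None),
        )
        for name, specs in grouped.items()
    ]
    return SpectralLibrary(entries=entries, metadata={"source": str(path)})


def write_msp_library(library: SpectralLibrary, path: str | Path) -> None:
    """Write a library as MSP, one record per reference spectrum."""
    from matchms import Spectrum as MatchmsSpectrum
    from matchms.exporting import save_as_msp

    records = []
    for entry in library:
        for s in entry.spectra:
            md = {"compound_name": entry.name, "precursor_mz": s.precursor_mz}
            if entry.formula:
                md["formula"] = entry.formula
            if s.rt is not None:
                md["retention_time"] = s.rt
            if s.collision_energy is not None:
                md["collision_energy"] = s.collision_energy
            records.append(
                MatchmsSpectrum(
                    mz=np.array([p.mz for p in s.peaks]),
                    intensities=np.array([p.intensity for p in s.peaks]),
                    metadata=md,
                    metadata_harmonization=False,
                )
            )
    Path(path).unlink(missing_ok=True)
    save_as_msp(records, str(path))
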