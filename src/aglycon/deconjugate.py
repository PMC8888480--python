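"""Step 2 — transform a flagged glucuronide spectrum into an aglycone pseudo-spectrum.

The precursor is reassigned to the predicted aglycone m/z (glucuronide
precursor minus the applied loss), fragments above the new precursor are
truncated away, and — when a glucuronic acid fragment (GlucA-NL) is also
present — that fragment is removed as well, since it has no counterpart
in the aglycone reference spectrum and would depress the match.  Removed
peaks are kept in an audit field so deviating-fragmentation cases can be
reviewed in head-to-tail plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .masses import GLUCA_NL, GLUC_NL, NeutralLossDef
from .screen import DEFAULT_NL_TOL
from .spectra import FragmentPeak, Spectrum

#: tolerance for the truncation boundary (Th); the aglycone pseudo-molecular
#: ion sits exactly at the new precursor and must survive truncation
DEFAULT_TRUNCATION_TOL = 0.01


class DeconjugationError(ValueError):
    """Raised when deconjugation leaves no usable spectrum."""


@dataclass
class DeconjugatedSpectrum(Spectrum):
    """An in silico-deconjugated spectrum plus its audit trail."""

    parent_precursor_mz: float = 0.0
    applied_loss: NeutralLossDef | None = None
    removed_peaks: tuple[FragmentPeak, ...] = ()


def truncate_peaks(
    peaks: tuple[FragmentPeak, ...],
    max_mz: float,
    tol: float = DEFAULT_TRUNCATION_TOL,
) -> tuple[tuple[FragmentPeak, ...], tuple[FragmentPeak, ...]]:
    """Split peaks into (retained, removed) at ``max_mz + tol`` inclusive."""
    retained = tuple(p for p in peaks if p.mz <= max_mz + tol)
    removed = tuple(p for p in peaks if p.mz > max_mz + tol)
    return retained, removed


def deconjugate_spectrum(
    s: Spectrum,
    loss: NeutralLossDef = GLUC_NL,
    tol: float = DEFAULT_TRUNCATION_TOL,
    secondary_loss: NeutralLossDef | None = GLUCA_NL,
    secondary_tol: float = DEFAULT_NL_TOL,
) -> DeconjugatedSpectrum:
    """Build the aglycone pseudo-spectrum of a flagged glucuronide spectrum.

    The new precursor is ``s.precursor_mz - loss.delta_mz``; peaks above
    it (beyond ``tol``) are truncated, and any peak within
    ``secondary_tol`` of ``s.precursor_mz - secondary_loss.delta_mz`` is
    removed too.  The result is renormalised to base peak 100.  A spectrum
    left empty raises :class:`DeconjugationError` so unusable
    deconjugations are reported rather than silently dropped.
    """
    if not s.peaks:
        raise DeconjugationError(f"spectrum {s.source_id!r} has no peaks")
    new_precursor = s.precursor_mz - loss.delta_mz
    if new_precursor <= 0:
        raise DeconjugationError(
            f"precursor {s.precursor_mz} minus {loss.label} is non-physical"
        )
    retained, removed = truncate_peaks(s.peaks, new_precursor, tol)
    if secondary_loss is not None:
        secondary_target = s.precursor_mz - secondary_loss.delta_mz
        still_retained = tuple(
            p for p in retained if abs(p.mz - secondary_target) > secondary_tol
        )
        removed = removed + tuple(
            p for p in retained if abs(p.mz - secondary_target) <= secondary_tol
        )
        retained = still_retained
    if not retained:
        raise DeconjugationError(
            f"spectrum {s.source_id!r}: no peaks left after truncation at "
            f"{new_precursor:.4f}"
        )
    base = max(p.intensity for p in retained)
    if base <= 0:
        raise DeconjugationError(f"spectrum {s.source_id!r}: zero-intensity residue")
    scale = 100.0 / base
    return DeconjugatedSpectrum(
        precursor_mz=new_precursor,
        peaks=tuple(FragmentPeak(p.mz, p.intensity * scale) for p in retained),
        precursor_charge=s.precursor_charge,
        rt=s.rt,
        collision_energy=s.collision_energy,
        source_id=s.source_id,
        parent_precursor_mz=s.precursor_mz,
        applied_loss=loss,
        removed_peaks=removed,
    )
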