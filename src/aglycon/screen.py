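"""Step 1 — neutral-loss screening of data-dependent MS/MS spectra.

A spectrum is flagged when it contains a fragment at
``precursor_mz - loss.delta_mz`` within an absolute mass window
(default +/- 0.001 Th).  The loss is defined relative to the precursor
only, never between fragment pairs, because the glucuronide moiety is
cleaved from the precursor ion.  The primary loss (Gluc-NL) flags a
spectrum; secondary losses (GlucA-NL) are annotated on already-flagged
spectra and, by default, do not flag on their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .masses import NeutralLossDef
from .spectra import Spectrum

logger = logging.getLogger(__name__)

#: absolute screening window, Th
DEFAULT_NL_TOL = 0.001


@dataclass
class NeutralLossHit:
    """A spectrum flagged for one neutral loss.

    ``mass_error`` is observed minus expected fragment m/z (signed, Th);
    ``secondary`` maps loss labels to hits for additional losses found in
    the same spectrum.
    """

    spectrum: Spectrum
    loss: NeutralLossDef
    fragment_mz: float
    fragment_rel_intensity: float
    mass_error: float
    secondary: dict[str, "NeutralLossHit"] = field(default_factory=dict)


def find_neutral_loss(
    s: Spectrum,
    loss: NeutralLossDef,
    tol: float = DEFAULT_NL_TOL,
    min_rel_intensity: float = 0.0,
    charge: int = 1,
) -> NeutralLossHit | None:
    """Find the fragment matching ``precursor - loss`` within ``tol``.

    Among in-window candidates at or above ``min_rel_intensity`` (percent
    of base peak) the one with the smallest absolute mass error wins; ties
    go to the higher intensity.  Returns None when no candidate exists.
    For ``charge`` > 1 the loss delta is divided by the charge (the m/z
    shift of a neutral loss on a multiply charged ion).
    """
    if tol <= 0:
        raise ValueError(f"tolerance must be positive, got {tol}")
    if not s.peaks:
        logger.debug("empty spectrum %r in neutral-loss search", s.source_id)
        return None
    target = s.precursor_mz - loss.delta_mz / max(charge, 1)
    base = s.base_peak_intensity
    best: tuple[float, float, float] | None = None  # (|err|, -intensity, mz)
    for p in s.peaks:
        err = p.mz - target
        if abs(err) > tol:
            continue
        rel = 100.0 * p.intensity / base if base > 0 else 0.0
        if rel < min_rel_intensity:
            continue
        key = (abs(err), -p.intensity, p.mz)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    _, neg_int, frag_mz = best
    return NeutralLossHit(
        spectrum=s,
        loss=loss,
        fragment_mz=frag_mz,
        fragment_rel_intensity=100.0 * (-neg_int) / base if base > 0 else 0.0,
        mass_error=frag_mz - target,
    )


def screen_dataset(
    spectra: list[Spectrum],
    losses: list[NeutralLossDef],
    tol: float = DEFAULT_NL_TOL,
    min_rel_intensity: float = 0.0,
    flag_on_any: bool = False,
    allow_multiply_charged: bool = False,
) -> list[NeutralLossHit]:
    """Screen a dataset; one hit per flagged spectrum.

    The first entry of ``losses`` is the primary loss; further losses are
    recorded in ``hit.secondary`` when present.  With ``flag_on_any`` a
    secondary loss alone also flags (strict-OR mode).  Multiply charged
    precursors are skipped unless ``allow_multiply_charged``, in which
    case the loss delta is divided by the charge.
    """
    if not losses:
        raise ValueError("at least one neutral loss is required")
    hits: list[NeutralLossHit] = []
    for s in spectra:
        charge = s.precursor_charge
        if charge > 1 and not allow_multiply_charged:
            logger.info("skipping multiply charged spectrum %r", s.source_id)
            continue
        per_loss = [
            find_neutral_loss(s, loss, tol, min_rel_intensity, charge=charge)
            for loss in losses
        ]
        primary = per_loss[0]
        if primary is None and flag_on_any:
            primary = next((h for h in per_loss[1:] if h is not None), None)
        if primary is None:
            continue
        for h in per_loss[1:]:
            if h is not None and h is not primary:
                primary.secondary[h.loss.label] = h
        hits.append(primary)
    return hits


def hits_to_frame(hits: list[NeutralLossHit]) -> pd.DataFrame:
    """Tabulate hits for TSV export."""
    rows = [
        {
            "source_id": h.spectrum.source_id,
            "precursor_mz": h.spectrum.precursor_mz,
            "rt": h.spectrum.rt,
            "loss": h.loss.label,
            "fragment_mz": h.fragment_mz,
            "mass_error": h.mass_error,
            "rel_intensity": h.fragment_rel_intensity,
            "secondary_losses": ";".join(sorted(h.secondary)) or "",
        }
        for h in hits
    ]
    columns = [
        "source_id", "precursor_mz", "rt", "loss", "fragment_mz",
        "mass_error", "rel_intensity", "secondary_losses",
    ]
    return pd.DataFrame(rows, columns=columns)
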