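"""Step 3 — spectral library search with MP/AMP and cosine dot-product scoring.

Matching fragments are found by greedy one-to-one assignment within an
absolute m/z window (default +/- 0.01 Th), smallest mass error first.
Per reference spectrum a match probability (MP, 0-100) is computed; the
compound-level average match probability (AMP) is the arithmetic mean of
the MPs over all reference spectra of that compound.  The MP used here is
an MSforID-inspired composite,

    MP = 100 * (2 n_m / (n_s + n_r))
             * sqrt( (I_m,s / I_s) * (I_m,r / I_r) ),

i.e. a Dice factor on matched peak counts times the geometric mean of the
matched-intensity fractions of both spectra.  It is 0 with no matches,
100 at identity, symmetric, and invariant to uniform intensity rescaling.
The cosine (dot-product) score is computed over the aligned intensity
vectors, with unmatched peaks of either spectrum contributing
zero-partner entries.

A candidate annotation is accepted when the precursor mass error is
within +/- 0.01 Th of the predicted aglycone m/z and its AMP exceeds 5.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .spectra import CompoundEntry, SpectralLibrary, Spectrum, normalize_spectrum

#: fragment-match window, Th
DEFAULT_MATCH_TOL = 0.01
#: precursor acceptance window, Th
DEFAULT_PRECURSOR_TOL = 0.01
#: relative intensity cut-off applied before scoring
DEFAULT_INTENSITY_CUTOFF = 0.01
#: minimum AMP for an accepted annotation (strictly greater than)
DEFAULT_AMP_THRESHOLD = 5.0


@dataclass(frozen=True)
class FragmentMatch:
    """One matched fragment pair; intensities in percent of base peak."""

    sample_mz: float
    reference_mz: float
    sample_intensity: float
    reference_intensity: float
    mz_error: float


@dataclass
class SearchResult:
    """Scores of one library candidate against one deconjugated spectrum."""

    compound: CompoundEntry
    mp_values: list[float]
    amp: float
    dot_product: float
    matches: list[list[FragmentMatch]]
    precursor_error: float
    accepted: bool
    sample_source_id: str = ""
    collision_energy: str | None = None


def match_fragments(
    sample: Spectrum, reference: Spectrum, tol: float = DEFAULT_MATCH_TOL
) -> list[FragmentMatch]:
    """Greedy one-to-one fragment assignment within ``tol``.

    Candidate pairs are ranked by absolute mass error ascending (ties by
    larger intensity product) and accepted if neither peak is already
    used.
    """
    candidates = []
    for i, sp in enumerate(sample.peaks):
        for j, rp in enumerate(reference.peaks):
            err = sp.mz - rp.mz
            if abs(err) <= tol:
                candidates.append((abs(err), -sp.intensity * rp.intensity, i, j, err))
    candidates.sort()
    used_s: set[int] = set()
    used_r: set[int] = set()
    matches: list[FragmentMatch] = []
    for _, _, i, j, err in candidates:
        if i in used_s or j in used_r:
            continue
        used_s.add(i)
        used_r.add(j)
        sp, rp = sample.peaks[i], reference.peaks[j]
        matches.append(FragmentMatch(sp.mz, rp.mz, sp.intensity, rp.intensity, err))
    matches.sort(key=lambda m: m.sample_mz)
    return matches


def match_probability(
    sample: Spectrum, reference: Spectrum, tol: float = DEFAULT_MATCH_TOL
) -> float:
    """Reference-spectrum-specific match probability in [0, 100]."""
    if not reference.peaks:
        raise ValueError("reference spectrum has no peaks")
    if not sample.peaks:
        return 0.0
    matches = match_fragments(sample, reference, tol)
    if not matches:
        return 0.0
    n_m = len(matches)
    n_s, n_r = len(sample.peaks), len(reference.peaks)
    total_s = sum(p.intensity for p in sample.peaks)
    total_r = sum(p.intensity for p in reference.peaks)
    matched_s = sum(m.sample_intensity for m in matches)
    matched_r = sum(m.reference_intensity for m in matches)
    count_factor = 2.0 * n_m / (n_s + n_r)
    intensity_factor = math.sqrt((matched_s / total_s) * (matched_r / total_r))
    return 100.0 * count_factor * intensity_factor


def amp(
    sample: Spectrum, compound: CompoundEntry, tol: float = DEFAULT_MATCH_TOL
) -> float:
    """Average match probability: mean MP over the compound's reference spectra."""
    mps = [match_probability(sample, ref, tol) for ref in compound.spectra]
    return sum(mps) / len(mps)


def dot_product(
    sample: Spectrum, reference: Spectrum, tol: float = DEFAULT_MATCH_TOL
) -> float:
    """Cosine similarity over aligned intensity vectors, in [0, 1]."""
    matches = match_fragments(sample, reference, tol)
    if not matches:
        return 0.0
    num = sum(m.sample_intensity * m.reference_intensity for m in matches)
    norm_s = math.sqrt(sum(p.intensity**2 for p in sample.peaks))
    norm_r = math.sqrt(sum(p.intensity**2 for p in reference.peaks))
    if norm_s == 0 or norm_r == 0:
        return 0.0
    return num / (norm_s * norm_r)


def search(
    sample: Spectrum,
    library: SpectralLibrary,
    precursor_tol: float = DEFAULT_PRECURSOR_TOL,
    match_tol: float = DEFAULT_MATCH_TOL,
    intensity_cutoff: float = DEFAULT_INTENSITY_CUTOFF,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
) -> list[SearchResult]:
    """Score a (deconjugated) spectrum against all candidates in the precursor window.

    Candidates are library entries whose precursor m/z lies within
    ``precursor_tol`` of the sample precursor.  Results are ranked by AMP
    descending (ties: dot product descending, then name).  The compound
    with the highest AMP is the best library match; ``accepted`` requires
    AMP strictly greater than ``amp_threshold``.  An empty candidate list
    yields an empty result list, not an error.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    sample_n = normalize_spectrum(sample, intensity_cutoff)
    results: list[SearchResult] = []
    for entry in library:
        prec_err = sample.precursor_mz - entry.precursor_mz
        if abs(prec_err) > precursor_tol:
            continue
        refs = [normalize_spectrum(r, intensity_cutoff) for r in entry.spectra]
        mps = [match_probability(sample_n, r, match_tol) for r in refs]
        amp_value = sum(mps) / len(mps)
        dots = [dot_product(sample_n, r, match_tol) for r in refs]
        matches = [match_fragments(sample_n, r, match_tol) for r in refs]
        results.append(
            SearchResult(
                compound=entry,
                mp_values=mps,
                amp=amp_value,
                dot_product=max(dots),
                matches=matches,
                precursor_error=prec_err,
                accepted=abs(prec_err) <= precursor_tol and amp_value > amp_threshold,
                sample_source_id=sample.source_id,
                collision_energy=sample.collision_energy,
            )
        )
    results.sort(key=lambda r: (-r.amp, -r.dot_product, r.compound.name))
    return results


def results_to_frame(results: list[SearchResult]) -> pd.DataFrame:
    """Tabulate ranked search results for TSV export."""
    rows = [
        {
            "rank": rank,
            "source_id": r.sample_source_id,
            "compound": r.compound.name,
            "amp": r.amp,
            "dot_product": r.dot_product,
            "n_matched": max((len(m) for m in r.matches), default=0),
            "precursor_error": r.precursor_error,
            "collision_energy": r.collision_energy,
            "accepted": r.accepted,
        }
        for rank, r in enumerate(results, start=1)
    ]
    columns = [
        "rank", "source_id", "compound", "amp", "dot_product",
        "n_matched", "precursor_error", "collision_energy", "accepted",
    ]
    return pd.DataFrame(rows, columns=columns)


def head_to_tail_table(
    sample: Spectrum, reference: Spectrum, tol: float = DEFAULT_MATCH_TOL
) -> pd.DataFrame:
    """Paired peak table for head-to-tail plotting.

    One row per peak of either spectrum; matched pairs share a row, with
    NaN in the missing column for unmatched peaks.
    """
    matches = match_fragments(sample, reference, tol)
    matched_s = {m.sample_mz for m in matches}
    matched_r = {m.reference_mz for m in matches}
    rows = [
        {
            "sample_mz": m.sample_mz,
            "sample_intensity": m.sample_intensity,
            "reference_mz": m.reference_mz,
            "reference_intensity": m.reference_intensity,
            "matched": True,
        }
        for m in matches
    ]
    for p in sample.peaks:
        if p.mz not in matched_s:
            rows.append(
                {
                    "sample_mz": p.mz,
                    "sample_intensity": p.intensity,
                    "reference_mz": float("nan"),
                    "reference_intensity": float("nan"),
                    "matched": False,
                }
            )
    for p in reference.peaks:
        if p.mz not in matched_r:
            rows.append(
                {
                    "sample_mz": float("nan"),
                    "sample_intensity": float("nan"),
                    "reference_mz": p.mz,
                    "reference_intensity": p.intensity,
                    "matched": False,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "sample_mz", "sample_intensity",
            "reference_mz", "reference_intensity", "matched",
        ],
    )
    return frame.sort_values(
        by=["sample_mz", "reference_mz"], na_position="last"
    ).reset_index(drop=True)
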