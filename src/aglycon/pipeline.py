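"""End-to-end orchestration: screen -> deconjugate -> library search -> RT filter.

This is the glue the command-line interface and the test harness share.
Each flagged spectrum yields one report row with its best library match;
spectra whose deconjugation or search fails are reported with a status
instead of being silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .deconjugate import DeconjugationError, deconjugate_spectrum
from .masses import NeutralLossDef, default_losses
from .rt import RtModel, RtPair, fit_rt_model, rt_consistency
from .screen import DEFAULT_NL_TOL, screen_dataset
from .search import (
    DEFAULT_AMP_THRESHOLD,
    DEFAULT_INTENSITY_CUTOFF,
    DEFAULT_MATCH_TOL,
    DEFAULT_PRECURSOR_TOL,
    search,
)
from .spectra import SpectralLibrary, Spectrum

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "source_id", "parent_precursor_mz", "deconjugated_precursor_mz", "rt",
    "best_match", "amp", "dot_product", "n_matched", "precursor_error",
    "rt_flag", "accepted", "status",
]


@dataclass
class PipelineParams:
    """All tunable parameters of the four-step workflow with their defaults."""

    nl_tol: float = DEFAULT_NL_TOL
    search_tol: float = DEFAULT_MATCH_TOL
    precursor_tol: float = DEFAULT_PRECURSOR_TOL
    intensity_cutoff: float = DEFAULT_INTENSITY_CUTOFF
    amp_threshold: float = DEFAULT_AMP_THRESHOLD
    min_rel_intensity: float = 0.0
    rt_band_k: float = 3.0
    losses: list[NeutralLossDef] = field(default_factory=default_losses)

    def __post_init__(self) -> None:
        for name in ("nl_tol", "search_tol", "precursor_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def run_pipeline(
    spectra: list[Spectrum],
    library: SpectralLibrary,
    rt_pairs: list[RtPair] | None = None,
    rt_model: RtModel | None = None,
    params: PipelineParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full workflow and return (report, summary).

    The report has one row per flagged spectrum.  The RT-consistency flag
    requires either a pre-fitted ``rt_model`` or ``rt_pairs`` to fit one,
    plus a library RT for the matched aglycone; otherwise it is
    ``"unknown"``.  The summary collects counts and the effective
    parameters.
    """
    params = params or PipelineParams()
    if rt_model is None and rt_pairs is not None:
        rt_model = fit_rt_model(rt_pairs)

    hits = screen_dataset(
        spectra, params.losses, tol=params.nl_tol,
        min_rel_intensity=params.min_rel_intensity,
    )
    rows: list[dict] = []
    n_searched = 0
    for hit in hits:
        s = hit.spectrum
        row = {
            "source_id": s.source_id,
            "parent_precursor_mz": s.precursor_mz,
            "deconjugated_precursor_mz": float("nan"),
            "rt": s.rt,
            "best_match": "",
            "amp": float("nan"),
            "dot_product": float("nan"),
            "n_matched": 0,
            "precursor_error": float("nan"),
            "rt_flag": "unknown",
            "accepted": False,
            "status": "ok",
        }
        try:
            secondary = params.losses[1] if len(params.losses) > 1 else None
            deconv = deconjugate_spectrum(
                s, hit.loss, tol=params.search_tol,
                secondary_loss=secondary, secondary_tol=params.nl_tol,
            )
        except DeconjugationError as exc:
            logger.warning("deconjugation failed for %r: %s", s.source_id, exc)
            row["status"] = f"deconjugation_failed: {exc}"
            rows.append(row)
            continue
        row["deconjugated_precursor_mz"] = deconv.precursor_mz

        results = search(
            deconv, library,
            precursor_tol=params.precursor_tol, match_tol=params.search_tol,
            intensity_cutoff=params.intensity_cutoff,
            amp_threshold=params.amp_threshold,
        )
        n_searched += 1
        if not results:
            row["status"] = "no_candidate_in_precursor_window"
            rows.append(row)
            continue
        best = results[0]
        row.update(
            best_match=best.compound.name,
            amp=best.amp,
            dot_product=best.dot_product,
            n_matched=max((len(m) for m in best.matches), default=0),
            precursor_error=best.precursor_error,
            accepted=best.accepted,
        )
        if rt_model is not None and s.rt is not None:
            row["rt_flag"] = rt_consistency(
                s.rt, best.compound.rt, rt_model, k=params.rt_band_k
            )
        rows.append(row)

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    summary = {
        "n_spectra": len(spectra),
        "n_flagged": len(hits),
        "n_searched": n_searched,
        "n_accepted": int(report["accepted"].sum()) if len(report) else 0,
        "parameters": {
            "nl_tol": params.nl_tol,
            "search_tol": params.search_tol,
            "precursor_tol": params.precursor_tol,
            "intensity_cutoff": params.intensity_cutoff,
            "amp_threshold": params.amp_threshold,
            "min_rel_intensity": params.min_rel_intensity,
            "rt_band_k": params.rt_band_k,
            "losses": [loss.label for loss in params.losses],
        },
    }
    if rt_model is not None:
        summary["rt_model"] = {
            "slope": rt_model.slope,
            "intercept": rt_model.intercept,
            "r_squared": rt_model.r_squared,
            "residual_sd": rt_model.residual_sd,
            "mean_shift": rt_model.mean_shift,
            "n": rt_model.n,
        }
    return report, summary
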