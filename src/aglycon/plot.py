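"""Head-to-tail spectral comparison plots (sample up, reference down)."""

from __future__ import annotations

from .search import DEFAULT_MATCH_TOL, head_to_tail_table
from .spectra import Spectrum, normalize_spectrum


def head_to_tail(
    sample: Spectrum,
    reference: Spectrum,
    tol: float = DEFAULT_MATCH_TOL,
    ax=None,
):
    """Mirrored stem plot of a sample spectrum against a reference.

    Matched peaks are drawn in colour, unmatched peaks in grey; the
    sample points up, the reference down.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    table = head_to_tail_table(
        normalize_spectrum(sample), normalize_spectrum(reference), tol
    )
    for row in table.itertuples():
        colour = "tab:red" if row.matched else "0.6"
        if row.sample_mz == row.sample_mz:  # not NaN
            ax.vlines(row.sample_mz, 0, row.sample_intensity, color=colour)
        if row.reference_mz == row.reference_mz:
            ax.vlines(row.reference_mz, 0, -row.reference_intensity,
                      color="tab:blue" if row.matched else "0.6")
    ax.axhline(0, color="black", linewidth=0.8)
    ax.set_xlabel("m/z")
    ax.set_ylabel("relative intensity (%)")
    ax.set_ylim(-110, 110)
    ax.set_title(f"{sample.source_id}  vs  {reference.source_id}")
    return ax
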