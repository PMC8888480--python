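"""Seeded generator of aglycone libraries and derived glucuronide MS/MS datasets.

The generator emulates the statistical structure the deconjugation
workflow relies on, so every stage can be exercised without instrument
data:

* an aglycone reference library — per compound a random [M+H]+ precursor,
  one or two reference spectra (two collision-energy tags) whose peaks
  lie below the precursor, and a surviving molecular-ion peak at the
  precursor m/z itself;
* derived glucuronide MS/MS spectra — precursor shifted up by the
  anhydroglucuronic acid mass, a subset of the aglycone fragments with
  multiplicative (log-normal) intensity noise, the diagnostic
  neutral-loss fragment at the aglycone precursor m/z, an optional
  glucuronic acid (GlucA) fragment 18.0106 below it, and, for a
  configurable fraction of compounds, interference fragments absent from
  the reference — emulating conjugates whose fragmentation deviates from
  the aglycone (ether-bond cleavage, [Gluc+NH]-type losses);
* decoy aglycone-only spectra constructed to avoid every registered
  neutral-loss window;
* an aglycone/glucuronide retention-time table following a linear model
  with a negative mean shift (glucuronides elute earlier on reversed
  phase).

Fragment m/z values are drawn on a 0.05 Th grid before jitter.  Because
both losses (176.0321, 194.0426) are more than 0.007 Th away from any
multiple of 0.05, no grid peak can fall inside a +/- 0.001 Th screening
window of a grid precursor by accident; decoys therefore carry zero
neutral-loss hits by construction, and the only in-window fragments of a
glucuronide spectrum are the ones placed deliberately.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .masses import GLUCA_NL, GLUC_NL
from .rt import RtPair
from .spectra import CompoundEntry, FragmentPeak, SpectralLibrary, Spectrum

#: grid spacing for fragment m/z before jitter (Th)
MZ_GRID = 0.05


@dataclass(frozen=True)
class FixtureConfig:
    """Conditions for the synthetic library and dataset.

    Defaults describe a routine positive-mode LC-HRMS screen: scan range
    75-1000 Th, sub-mTh mass accuracy, 20% multiplicative intensity
    noise, a 15-min gradient, and glucuronides eluting about one minute
    before their aglycones (slope 0.95, intercept -0.8 min, residual sd
    0.1 min).
    """

    n_compounds: int = 50
    n_glucuronides: int = 25
    n_decoys: int = 25
    peaks_per_spectrum: tuple[int, int] = (5, 12)
    mz_range: tuple[float, float] = (75.0, 1000.0)
    mz_noise_sd: float = 0.0002
    intensity_noise_cv: float = 0.2
    fragment_keep_prob: float = 0.9
    fraction_with_gluca: float = 0.5
    fraction_with_interference: float = 0.0
    rt_window: tuple[float, float] = (1.0, 14.0)
    rt_slope: float = 0.95
    rt_intercept: float = -0.8
    rt_residual_sd: float = 0.1
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("fragment_keep_prob", "fraction_with_gluca", "fraction_with_interference"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.mz_range[0] <= 0 or self.mz_range[1] <= self.mz_range[0]:
            raise ValueError(f"invalid mz_range {self.mz_range}")
        if self.peaks_per_spectrum[0] < 2 or self.peaks_per_spectrum[1] < self.peaks_per_spectrum[0]:
            raise ValueError(f"invalid peaks_per_spectrum {self.peaks_per_spectrum}")
        if self.n_glucuronides + self.n_decoys > self.n_compounds:
            raise ValueError("n_glucuronides + n_decoys exceeds n_compounds")
        if self.mz_noise_sd < 0 or self.intensity_noise_cv < 0 or self.rt_residual_sd < 0:
            raise ValueError("noise parameters must be non-negative")

    def noiseless(self) -> "FixtureConfig":
        """The same conditions with every stochastic distortion switched off."""
        return replace(
            self,
            mz_noise_sd=0.0,
            intensity_noise_cv=0.0,
            fragment_keep_prob=1.0,
            fraction_with_interference=0.0,
            rt_residual_sd=0.0,
        )


def _grid_mz(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    """Distinct m/z values on the MZ_GRID within [lo, hi]."""
    lo_idx = int(np.ceil(lo / MZ_GRID))
    hi_idx = int(np.floor(hi / MZ_GRID))
    if hi_idx - lo_idx + 1 < size:
        raise ValueError(f"m/z range [{lo}, {hi}] too narrow for {size} grid peaks")
    idx = rng.choice(np.arange(lo_idx, hi_idx + 1), size=size, replace=False)
    return np.sort(idx) * MZ_GRID


def make_aglycone_library(cfg: FixtureConfig) -> SpectralLibrary:
    """Generate the reference library of unconjugated compounds.

    Each compound gets a precursor on the m/z grid, a retention time
    uniform over the gradient window, and one or two reference spectra
    (collision-energy tags ``20 eV`` and ``40 eV``) sharing a fragment
    set that always includes the surviving [M+H]+ peak at the precursor.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.mz_range
    # keep the glucuronide precursor (aglycone + 176.03) inside the scan range
    prec_lo = max(lo + 80.0, 150.0)
    prec_hi = hi - GLUC_NL.delta_mz - 1.0
    entries: list[CompoundEntry] = []
    for i in range(cfg.n_compounds):
        name = f"compound_{i:03d}"
        precursor = float(np.round(rng.uniform(prec_lo, prec_hi) / MZ_GRID) * MZ_GRID)
        rt = float(rng.uniform(*cfg.rt_window))
        n_peaks = int(rng.integers(cfg.peaks_per_spectrum[0], cfg.peaks_per_spectrum[1] + 1))
        frag_mz = _grid_mz(rng, lo, precursor - 2 * MZ_GRID, n_peaks - 1)
        all_mz = np.append(frag_mz, precursor)
        n_spectra = int(rng.integers(1, 3))
        spectra = []
        for k, ce in enumerate(("20 eV", "40 eV")[:n_spectra]):
            intensities = rng.uniform(5.0, 100.0, size=len(all_mz))
            intensities[-1] = rng.uniform(40.0, 100.0)  # molecular ion well visible
            intensities *= 100.0 / intensities.max()
            spectra.append(
                Spectrum(
                    precursor_mz=precursor,
                    peaks=tuple(FragmentPeak(float(m), float(it)) for m, it in zip(all_mz, intensities)),
                    rt=rt,
                    collision_energy=ce,
                    source_id=f"lib:{name}:{ce}",
                )
            )
        entries.append(CompoundEntry(name=name, precursor_mz=precursor, spectra=spectra, rt=rt))
    return SpectralLibrary(entries=entries, metadata={"generator_seed": cfg.seed})


def _perturb_intensity(rng: np.random.Generator, intensity: float, cv: float) -> float:
    if cv <= 0:
        return intensity
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return float(intensity * rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def make_glucuronide_dataset(
    library: SpectralLibrary, cfg: FixtureConfig
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Derive glucuronide MS/MS spectra and decoys from the aglycone library.

    The first ``n_glucuronides`` library compounds become glucuronides,
    the next ``n_decoys`` become aglycone-only decoy spectra.  Returns the
    spectra plus a ground-truth table (one row per spectrum: kind,
    compound, parent precursor, deviation flags).
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    rng = np.random.default_rng(cfg.seed + 1)
    spectra: list[Spectrum] = []
    truth_rows: list[dict] = []

    gluc_entries = library.entries[: cfg.n_glucuronides]
    decoy_entries = library.entries[cfg.n_glucuronides : cfg.n_glucuronides + cfg.n_decoys]

    for entry in gluc_entries:
        ref = entry.spectra[0]
        parent_prec = entry.precursor_mz + GLUC_NL.delta_mz
        peaks: list[FragmentPeak] = []
        # aglycone fragment subset (the [M+H]+ peak becomes the NL fragment)
        kept = 0
        for p in ref.peaks:
            if p.mz != entry.precursor_mz and rng.random() > cfg.fragment_keep_prob:
                continue
            mz = p.mz + (rng.normal(0.0, cfg.mz_noise_sd) if cfg.mz_noise_sd > 0 else 0.0)
            peaks.append(FragmentPeak(mz, _perturb_intensity(rng, p.intensity, cfg.intensity_noise_cv)))
            kept += 1
        if kept < 2:  # keep the spectrum searchable
            for p in ref.peaks[:2]:
                peaks.append(FragmentPeak(p.mz, p.intensity))

        has_gluca = bool(rng.random() < cfg.fraction_with_gluca)
        if has_gluca:
            gluca_mz = parent_prec - GLUCA_NL.delta_mz
            gluca_mz += rng.normal(0.0, cfg.mz_noise_sd) if cfg.mz_noise_sd > 0 else 0.0
            peaks.append(FragmentPeak(gluca_mz, float(rng.uniform(10.0, 60.0))))

        n_interference = 0
        if rng.random() < cfg.fraction_with_interference:
            n_interference = int(rng.integers(1, 3))
            ref_mz = np.array([p.mz for p in ref.peaks])
            placed = 0
            while placed < n_interference:
                mz = float(_grid_mz(rng, cfg.mz_range[0], entry.precursor_mz - 2 * MZ_GRID, 1)[0])
                if np.min(np.abs(ref_mz - mz)) < 0.02:
                    continue
                jitter = rng.normal(0.0, cfg.mz_noise_sd) if cfg.mz_noise_sd > 0 else 0.0
                peaks.append(FragmentPeak(mz + jitter, float(rng.uniform(50.0, 100.0))))
                placed += 1

        rt = cfg.rt_slope * entry.rt + cfg.rt_intercept
        if cfg.rt_residual_sd > 0:
            rt += rng.normal(0.0, cfg.rt_residual_sd)
        spectra.append(
            Spectrum(
                precursor_mz=parent_prec,
                peaks=tuple(peaks),
                rt=max(rt, 0.0),
                collision_energy=ref.collision_energy,
                source_id=f"sim:gluc:{entry.name}",
            )
        )
        truth_rows.append(
            {
                "source_id": f"sim:gluc:{entry.name}",
                "kind": "glucuronide",
                "compound": entry.name,
                "parent_precursor_mz": parent_prec,
                "aglycone_precursor_mz": entry.precursor_mz,
                "rt": spectra[-1].rt,
                "has_gluca": has_gluca,
                "n_interference": n_interference,
            }
        )

    for entry in decoy_entries:
        ref = entry.spectra[0]
        peaks = [
            FragmentPeak(
                p.mz + (rng.normal(0.0, cfg.mz_noise_sd) if cfg.mz_noise_sd > 0 else 0.0),
                _perturb_intensity(rng, p.intensity, cfg.intensity_noise_cv),
            )
            for p in ref.peaks
        ]
        spectra.append(
            Spectrum(
                precursor_mz=entry.precursor_mz,
                peaks=tuple(peaks),
                rt=entry.rt,
                collision_energy=ref.collision_energy,
                source_id=f"sim:decoy:{entry.name}",
            )
        )
        truth_rows.append(
            {
                "source_id": f"sim:decoy:{entry.name}",
                "kind": "decoy",
                "compound": entry.name,
                "parent_precursor_mz": entry.precursor_mz,
                "aglycone_precursor_mz": entry.precursor_mz,
                "rt": entry.rt,
                "has_gluca": False,
                "n_interference": 0,
            }
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "source_id", "kind", "compound", "parent_precursor_mz",
            "aglycone_precursor_mz", "rt", "has_gluca", "n_interference",
        ],
    )
    return spectra, truth


def make_rt_table(
    library: SpectralLibrary, cfg: FixtureConfig, n: int | None = None
) -> list[RtPair]:
    """Aglycone/glucuronide RT pairs following the configured linear model."""
    rng = np.random.default_rng(cfg.seed + 2)
    entries = library.entries if n is None else library.entries[:n]
    pairs = []
    for entry in entries:
        x = entry.rt if entry.rt is not None else float(rng.uniform(*cfg.rt_window))
        y = cfg.rt_slope * x + cfg.rt_intercept
        if cfg.rt_residual_sd > 0:
            y += rng.normal(0.0, cfg.rt_residual_sd)
        pairs.append(RtPair(entry.name, x, max(y, 0.0)))
    return pairs
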