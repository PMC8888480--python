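"""Monoisotopic mass arithmetic for neutral-loss formulas.

Glucuronidation adds a glucuronic acid moiety to the parent compound
(the aglycone).  Under collision-induced dissociation the conjugate
predominantly ejects anhydroglucuronic acid (C6H8O6, 176.0321 Da,
"Gluc-NL"); benzylic or acylic conjugates can instead lose the full
glucuronic acid (C6H10O7, 194.0426 Da, "GlucA-NL").  Both deltas are
computed from elemental monoisotopic masses at full precision — the
four-decimal figures above are rounded displays — because screening
windows of +/- 0.001 Th leave no room for rounded constants.

All arithmetic is performed in m/z space assuming singly protonated
positive-mode ions; multiply charged precursors are excluded from
screening by default (see :mod:`aglycon.screen`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from pyteomics import mass as _mass

#: lowest plausible aglycone fragment m/z (Th); smaller results are rejected
MIN_AGLYCONE_MZ = 50.0


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass of a neutral elemental formula in Da.

    The empty formula has mass 0.  Unknown element symbols and negative
    counts raise ``ValueError``.
    """
    if formula == "":
        return 0.0
    try:
        composition = _mass.Composition(formula=formula)
    except Exception as exc:  # pyteomics raises PyteomicsError
        raise ValueError(f"cannot parse formula {formula!r}: {exc}") from exc
    for element, count in composition.items():
        if count < 0:
            raise ValueError(f"negative count for {element} in {formula!r}")
        if element not in _mass.nist_mass:
            raise ValueError(f"unknown element {element!r} in {formula!r}")
    return float(_mass.calculate_mass(composition=composition))


@dataclass(frozen=True)
class NeutralLossDef:
    """A registered neutral loss: label, neutral formula and its monoisotopic mass."""

    label: str
    formula: str
    delta_mz: float = field(default=0.0)

    def __post_init__(self) -> None:
        computed = monoisotopic_mass(self.formula)
        if computed <= 0:
            raise ValueError(f"neutral loss {self.label!r} has non-positive mass")
        if self.delta_mz == 0.0:
            object.__setattr__(self, "delta_mz", computed)
        elif abs(self.delta_mz - computed) > 1e-4:
            raise ValueError(
                f"delta_mz {self.delta_mz} inconsistent with formula "
                f"{self.formula!r} ({computed:.6f})"
            )

    @classmethod
    def from_formula(cls, label: str, formula: str) -> "NeutralLossDef":
        return cls(label=label, formula=formula)


#: loss of anhydroglucuronic acid — the glucuronide-diagnostic neutral loss
GLUC_NL = NeutralLossDef.from_formula("Gluc-NL", "C6H8O6")
#: loss of intact glucuronic acid (Gluc-NL + H2O), seen for benzylic/acylic conjugates
GLUCA_NL = NeutralLossDef.from_formula("GlucA-NL", "C6H10O7")


def default_losses() -> list[NeutralLossDef]:
    """The shipped loss registry: Gluc-NL (primary) and GlucA-NL (secondary)."""
    return [GLUC_NL, GLUCA_NL]


def load_loss_registry(path: str | Path) -> list[NeutralLossDef]:
    """Read a loss registry from a text file of ``label = formula`` lines.

    Blank lines and ``#`` comments are ignored; ``label<TAB>formula`` is
    accepted too.  The first entry is treated as the primary loss.
    """
    losses: list[NeutralLossDef] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            label, formula = (part.strip() for part in line.split("=", 1))
        else:
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: cannot parse loss definition {raw!r}")
            label, formula = parts
        losses.append(NeutralLossDef.from_formula(label, formula))
    if not losses:
        raise ValueError(f"{path}: loss registry is empty")
    return losses


def aglycone_precursor(
    glucuronide_precursor_mz: float,
    loss: NeutralLossDef = GLUC_NL,
    min_fragment_mz: float = MIN_AGLYCONE_MZ,
) -> float:
    """Predicted aglycone [M+H]+ m/z: glucuronide precursor minus the loss.

    Assumes charge 1.  Results at or below ``min_fragment_mz`` are
    non-physical aglycones and raise ``ValueError``.
    """
    result = glucuronide_precursor_mz - loss.delta_mz
    if result <= min_fragment_mz:
        raise ValueError(
            f"aglycone m/z {result:.4f} from precursor {glucuronide_precursor_mz:.4f} "
            f"minus {loss.label} is below the plausible bound {min_fragment_mz}"
        )
    return result
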