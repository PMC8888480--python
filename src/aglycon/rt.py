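"""Step 4 — retention-time correlation between aglycones and their glucuronides.

On reversed-phase chromatography a glucuronide elutes close to, and
typically about one minute earlier than, its aglycone.  A simple linear
model, glucuronide RT regressed on aglycone RT, captures this well
enough to exclude false-positive annotations: an observed glucuronide RT
far from the prediction is implausible.  The fit is ordinary least
squares from the closed-form normal equations; the consistency band is
``k`` residual standard deviations (default k = 3), a documented
convention rather than a hard rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class RtPair:
    """Observed retention times (minutes) of one aglycone/glucuronide pair."""

    compound: str
    rt_aglycone: float
    rt_glucuronide: float

    def __post_init__(self) -> None:
        if self.rt_aglycone < 0 or self.rt_glucuronide < 0:
            raise ValueError(f"negative retention time for {self.compound!r}")


@dataclass(frozen=True)
class RtModel:
    """Fitted linear RT model: rt_glucuronide = slope * rt_aglycone + intercept."""

    slope: float
    intercept: float
    r_squared: float
    mean_shift: float
    n: int
    residual_sd: float

    def predict(self, rt_aglycone: float) -> float:
        return self.slope * rt_aglycone + self.intercept


def fit_rt_model(pairs: list[RtPair]) -> RtModel:
    """Ordinary least squares of glucuronide RT on aglycone RT.

    Requires at least 3 pairs and non-degenerate aglycone RTs.  R^2 is
    1 - SS_res / SS_tot; ``mean_shift`` is the mean of
    (rt_glucuronide - rt_aglycone); ``residual_sd`` uses n - 2 degrees of
    freedom.
    """
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need at least 3 RT pairs, got {n}")
    x = [p.rt_aglycone for p in pairs]
    y = [p.rt_glucuronide for p in pairs]
    xbar = sum(x) / n
    ybar = sum(y) / n
    sxx = sum((xi - xbar) ** 2 for xi in x)
    if sxx == 0:
        raise ValueError("aglycone retention times are all identical")
    sxy = sum((xi - xbar) * (yi - ybar) for xi, yi in zip(x, y))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    residuals = [yi - (slope * xi + intercept) for xi, yi in zip(x, y)]
    ss_res = sum(r * r for r in residuals)
    ss_tot = sum((yi - ybar) ** 2 for yi in y)
    if ss_tot == 0:
        r_squared = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r_squared = 1.0 - ss_res / ss_tot
    return RtModel(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        mean_shift=sum(yi - xi for xi, yi in zip(x, y)) / n,
        n=n,
        residual_sd=math.sqrt(ss_res / (n - 2)),
    )


def rt_consistency(
    observed_rt: float,
    aglycone_rt: float | None,
    model: RtModel,
    k: float = 3.0,
) -> str:
    """Flag an observed glucuronide RT against the model prediction.

    Returns ``"consistent"`` when |observed - predicted| <= k * residual
    sd, ``"inconsistent"`` otherwise, and ``"unknown"`` when the aglycone
    RT is not available.
    """
    if aglycone_rt is None:
        return "unknown"
    predicted = model.predict(aglycone_rt)
    return "consistent" if abs(observed_rt - predicted) <= k * model.residual_sd else "inconsistent"


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_rt_model(model: RtModel, path: str | Path) -> None:
    """Persist the model as a small key=value text file."""
    lines = [
        f"slope = {model.slope!r}",
        f"intercept = {model.intercept!r}",
        f"r_squared = {model.r_squared!r}",
        f"mean_shift = {model.mean_shift!r}",
        f"n = {model.n}",
        f"residual_sd = {model.residual_sd!r}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_rt_model(path: str | Path) -> RtModel:
    values: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        values[key.strip()] = float(value.strip())
    return RtModel(
        slope=values["slope"],
        intercept=values["intercept"],
        r_squared=values["r_squared"],
        mean_shift=values["mean_shift"],
        n=int(values["n"]),
        residual_sd=values["residual_sd"],
    )


def read_rt_pairs(path: str | Path) -> list[RtPair]:
    """Read aglycone/glucuronide RT pairs from a TSV with columns
    compound, rt_aglycone, rt_glucuronide."""
    frame = pd.read_csv(path, sep="\t")
    required = {"compound", "rt_aglycone", "rt_glucuronide"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        RtPair(str(row.compound), float(row.rt_aglycone), float(row.rt_glucuronide))
        for row in frame.itertuples()
    ]


def write_rt_pairs(pairs: list[RtPair], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "compound": p.compound,
                "rt_aglycone": p.rt_aglycone,
                "rt_glucuronide": p.rt_glucuronide,
            }
            for p in pairs
        ]
    ).to_csv(path, sep="\t", index=False)
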