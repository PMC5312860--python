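"""Binomial capture-probability estimates from per-run outcomes.

Each simulation condition contributes n replicate runs; the capture
probability is estimated at two bounds, following how the observed outcomes
bracket the true entry probability:

* **upper** ("highest possible probability of entry") — runs where either
  capture or possible capture is observed,
* **lower** ("lowest possible probability of entry") — runs where capture
  is observed.

Uncertainty is the plain binomial standard error sqrt(p(1−p)/n) — no
continuity correction.  Probabilities are stored as fractions and rendered
as percentages in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .classify import CaptureOutcome

__all__ = ["CaptureProbability", "capture_probability", "probability_table"]


@dataclass(frozen=True)
class CaptureProbability:
    height: float
    translation: float
    orientation: str
    bound: str        # "lower" | "upper"
    p: float          # fraction
    se: float         # fraction
    n: int

    def __post_init__(self) -> None:
        if self.bound not in ("lower", "upper"):
            raise ValueError("bound must be 'lower' or 'upper'")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def percent(self) -> float:
        return 100.0 * self.p

    @property
    def se_percent(self) -> float:
        return 100.0 * self.se


def _labels(outcomes) -> list[str]:
    out = []
    for o in outcomes:
        out.append(o.label if isinstance(o, CaptureOutcome) else str(o))
    return out


def capture_probability(outcomes, bound: str,
                        condition: tuple[float, float, str] = (0.0, 0.0, "up"),
                        ) -> CaptureProbability:
    """Binomial proportion (and SE) of one condition's outcomes at one bound.

    ``outcomes`` is a sequence of CaptureOutcomes or bare labels, all from
    the same condition; ``condition`` is (height, translation, orientation)
    metadata carried through to the result.
    """
    labels = _labels(outcomes)
    n = len(labels)
    if n == 0:
        raise ValueError("cannot estimate a probability from zero runs")
    unknown = set(labels) - {"captured", "possible", "failed"}
    if unknown:
        raise ValueError(f"unknown outcome labels: {sorted(unknown)}")
    if bound == "lower":
        k = sum(lab == "captured" for lab in labels)
    elif bound == "upper":
        k = sum(lab in ("captured", "possible") for lab in labels)
    else:
        raise ValueError("bound must be 'lower' or 'upper'")
    p = k / n
    se = math.sqrt(p * (1.0 - p) / n)
    height, translation, orientation = condition
    return CaptureProbability(
        height=height, translation=translation, orientation=orientation,
        bound=bound, p=p, se=se, n=n,
    )


def probability_table(outcome_df: pd.DataFrame,
                      displacement_height: float = 3.0) -> pd.DataFrame:
    """Capture probabilities for every condition at both bounds.

    ``outcome_df`` needs columns height, translation, orientation, label.
    Rows are tagged by study: the distance study (translation = 0) and the
    displacement study (lateral offsets at the displacement height), ready
    for the regression module.  Output probabilities are percentages.
    """
    required = {"height", "translation", "orientation", "label"}
    missing = required - set(outcome_df.columns)
    if missing:
        raise ValueError(f"outcome table missing columns: {sorted(missing)}")
    rows = []
    grouped = outcome_df.groupby(
        ["height", "translation", "orientation"], sort=True
    )
    for (height, translation, orientation), grp in grouped:
        for bound in ("lower", "upper"):
            cp = capture_probability(
                grp["label"].tolist(), bound,
                condition=(height, translation, orientation),
            )
            rows.append(
                {
                    "height": height,
                    "translation": translation,
                    "orientation": orientation,
                    "bound": bound,
                    "study": "distance" if translation == 0 else "displacement",
                    "p_percent": cp.percent,
                    "se_percent": cp.se_percent,
                    "n": cp.n,
                }
            )
    return pd.DataFrame(rows)
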