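"""Parameter-recovery protocols on Bernoulli-tier synthetic outcomes.

These helpers run the full estimation chain under a *known* linear truth
model: draw per-run possible-capture outcomes, aggregate them into
per-condition empirical percentages, and fit the capture model exactly as
it would be fitted to real study data.  They are the standard way to ask
whether the height/translation coefficients are recoverable at a given
replication level.
"""

from __future__ import annotations

import numpy as np

from .io import ConditionSpec
from .model import (CaptureModelResults, fit_combined_model,
                    fit_height_model, remove_height_effect)
from .synthetic import sample_outcomes

__all__ = ["recover_height_model", "recover_combined_model"]

DEFAULT_HEIGHTS = (1.0, 1.5, 2.0, 3.0, 4.0)
DEFAULT_TRANSLATIONS = (0.0, 0.5, 1.0, 1.5, 2.0)


def _proportion_points(outcomes, by: str) -> list[tuple[float, float]]:
    return [
        (float(value), 100.0 * grp["possible_capture"].mean())
        for value, grp in outcomes.groupby(by)
    ]


def recover_height_model(
    truth: CaptureModelResults,
    heights=DEFAULT_HEIGHTS,
    replicates: int = 2000,
    seed: int = 0,
    orientation: str = "down",
) -> CaptureModelResults:
    """Height-only recovery: sample outcomes on the height grid and refit."""
    grid = [
        ConditionSpec(height=h, translation=0.0, orientation=orientation,
                      replicate=r)
        for h in heights for r in range(1, replicates + 1)
    ]
    outcomes = sample_outcomes(truth, grid, seed=seed)
    return fit_height_model(_proportion_points(outcomes, "height"),
                            orientation=orientation)


def recover_combined_model(
    truth: CaptureModelResults,
    heights=DEFAULT_HEIGHTS,
    translations=DEFAULT_TRANSLATIONS,
    series_height: float = 3.0,
    replicates: int = 2000,
    seed: int = 0,
    orientation: str = "down",
) -> CaptureModelResults:
    """Full two-covariate recovery via the remove-height-effect procedure.

    The height series (on axis) and the translation series (at the series
    height, including its t = 0 anchor) are sampled independently; the
    height line is fitted first, the translation series is anchored to its
    prediction, and the combined model is fitted.
    """
    child = np.random.SeedSequence(seed).spawn(2)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in child]
    height_grid = [
        ConditionSpec(height=h, translation=0.0, orientation=orientation,
                      replicate=r)
        for h in heights for r in range(1, replicates + 1)
    ]
    translation_grid = [
        ConditionSpec(height=series_height, translation=t,
                      orientation=orientation, replicate=r)
        for t in translations for r in range(1, replicates + 1)
    ]
    height_pts = _proportion_points(
        sample_outcomes(truth, height_grid, seed=seeds[0]), "height"
    )
    translation_pts = _proportion_points(
        sample_outcomes(truth, translation_grid, seed=seeds[1]), "translation"
    )
    height_fit = fit_height_model(height_pts, orientation=orientation)
    adjusted = remove_height_effect(translation_pts, height_fit,
                                    series_height)
    return fit_combined_model(height_pts, adjusted, orientation=orientation,
                              series_height=series_height)
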