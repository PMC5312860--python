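"""Linear capture-probability models in release height and lateral offset.

The central quantity is the possible-capture probability (percent) of a
mononucleotide released at height ``h`` (nm above the K8 ring, on the pore
axis) and lateral translation ``t`` (nm off-axis):

    p(h, t) = intercept − height_slope · h − translation_slope · t

fitted in two stages, mirroring how the release-point studies are designed:

1. the *height line* — ordinary least squares on the on-axis series
   (translation 0) gives the intercept and height slope;
2. the *translation slope* — the lateral-offset series (measured at one
   fixed series height, 3.0 nm by default) first has the height effect
   removed by shifting all its probabilities by a single constant so that
   its t = 0 point equals the height line's prediction at the series
   height; the slope is then least-squares fitted with the intercept pinned
   to that prediction (equivalently, a regression through the origin of the
   anchored residuals on t).

The module follows the statsmodels convention: build a :class:`CaptureModel`
from data, call :meth:`~CaptureModel.fit`, and work with the returned
:class:`CaptureModelResults` (parameters, standard errors, ``predict``,
``summary``).  The spec-level helpers ``fit_height_model``,
``remove_height_effect``, ``fit_combined_model`` and ``predict`` are thin
wrappers over the same machinery.

Predictions are raw linear values — never clamped to [0, 100]; a
``UserWarning`` flags predictions outside that range.  Units are percent
and nm throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CaptureModel",
    "CaptureModelResults",
    "fit_height_model",
    "remove_height_effect",
    "fit_combined_model",
    "predict",
]

_T0_TOL = 1e-9


class ModelError(ValueError):
    """Raised for under-determined or inconsistent model inputs."""


@dataclass(frozen=True)
class CaptureModelResults:
    """Fitted (or externally specified) linear capture-probability model.

    Attributes
    ----------
    intercept : float
        Possible-capture probability (%) at height 0, translation 0.
    height_slope, translation_slope : float
        Percent lost per nm of release height / lateral translation (both
        stored positive; the model subtracts them).
    bse : dict
        Standard errors of the parameters, where estimable.
    nobs, rss : float
        Number of fitted points and residual sum of squares.
    """

    intercept: float
    height_slope: float
    translation_slope: float = 0.0
    orientation: str | None = None
    series_height: float | None = None
    nobs: int = 0
    rss: float = float("nan")
    bse: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("intercept", "height_slope", "translation_slope"):
            if not np.isfinite(getattr(self, name)):
                raise ModelError(f"{name} is not finite")

    @classmethod
    def from_coefficients(cls, intercept: float, height_slope: float,
                          translation_slope: float = 0.0,
                          orientation: str | None = None,
                          ) -> "CaptureModelResults":
        """A model specified directly by its coefficients (no fit)."""
        return cls(
            intercept=float(intercept),
            height_slope=float(height_slope),
            translation_slope=float(translation_slope),
            orientation=orientation,
        )

    @property
    def params(self) -> dict:
        return {
            "intercept": self.intercept,
            "height_slope": self.height_slope,
            "translation_slope": self.translation_slope,
        }

    def predict(self, height: float, translation: float = 0.0,
                warn: bool = True) -> float:
        """Predicted possible-capture probability (%) — raw linear value.

        Raises on negative height or translation; warns (``UserWarning``)
        when the prediction falls outside [0, 100].
        """
        if height < 0:
            raise ModelError("height must be >= 0")
        if translation < 0:
            raise ModelError("translation must be >= 0")
        value = (
            self.intercept
            - self.height_slope * height
            - self.translation_slope * translation
        )
        if warn and not 0.0 <= value <= 100.0:
            warnings.warn(
                f"predicted probability {value:.1f}% lies outside [0, 100]; "
                "the linear model is being evaluated beyond its valid range",
                UserWarning,
                stacklevel=2,
            )
        return float(value)

    def summary(self) -> str:
        lines = [
            "Linear capture-probability model",
            "=" * 48,
            f"orientation:        {self.orientation or '-'}",
            f"n observations:     {self.nobs}",
            f"residual SS:        {self.rss:.6g}",
            "-" * 48,
            f"{'parameter':<20}{'estimate':>12}{'std err':>12}",
            "-" * 48,
        ]
        for name, value in self.params.items():
            se = self.bse.get(name)
            se_str = f"{se:12.4f}" if se is not None and np.isfinite(se) else f"{'':>12}"
            lines.append(f"{name:<20}{value:12.4f}{se_str}")
        lines.append("-" * 48)
        lines.append(
            "model: p(%) = intercept - height_slope*h - translation_slope*t"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "orientation": self.orientation,
            "intercept": self.intercept,
            "height_slope": self.height_slope,
            "translation_slope": self.translation_slope,
            "series_height": self.series_height,
            "nobs": self.nobs,
            "rss": self.rss,
            "bse": dict(self.bse),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CaptureModelResults":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            intercept=d["intercept"],
            height_slope=d["height_slope"],
            translation_slope=d.get("translation_slope", 0.0),
            orientation=d.get("orientation"),
            series_height=d.get("series_height"),
            nobs=d.get("nobs", 0),
            rss=d.get("rss", float("nan")),
            bse=d.get("bse", {}),
        )


class CaptureModel:
    """Capture-probability model builder.

    Parameters
    ----------
    height_points : sequence of (height nm, probability %)
        The on-axis release series.
    translation_points : sequence of (translation nm, probability %), optional
        The lateral-offset series, measured at ``series_height``.  Must
        include a t = 0 point (the anchor for height-effect removal).
    orientation : str, optional
        "up" or "down"; carried through to the results.
    series_height : float
        Release height (nm) of the translation series; default 3.0.
    """

    def __init__(self, height_points, translation_points=None,
                 orientation: str | None = None, series_height: float = 3.0):
        self.height_points = [(float(h), float(p)) for h, p in height_points]
        self.translation_points = (
            None if translation_points is None
            else [(float(t), float(p)) for t, p in translation_points]
        )
        self.orientation = orientation
        self.series_height = float(series_height)
        if len({h for h, _ in self.height_points}) < 2:
            raise ModelError(
                "need at least 2 distinct heights to fit the height line"
            )

    @classmethod
    def from_table(cls, table: pd.DataFrame, orientation: str,
                   bound: str = "upper",
                   series_height: float = 3.0) -> "CaptureModel":
        """Build from a :func:`nanocapture.stats.probability_table` frame.

        The height series is the distance-study rows (translation 0); the
        translation series is the displacement-study rows at the series
        height, plus the on-axis point at that height as its t = 0 anchor.
        """
        sel = table[(table["orientation"] == orientation)
                    & (table["bound"] == bound)]
        if sel.empty:
            raise ModelError(
                f"no rows for orientation={orientation!r}, bound={bound!r}"
            )
        hrows = sel[sel["translation"] == 0].sort_values("height")
        height_points = list(zip(hrows["height"], hrows["p_percent"]))
        trows = sel[(sel["height"] == series_height)].sort_values("translation")
        translation_points = (
            list(zip(trows["translation"], trows["p_percent"]))
            if len(trows) > 1 else None
        )
        return cls(height_points, translation_points,
                   orientation=orientation, series_height=series_height)

    def fit(self, weights=None, anchor_intercept: bool = True
            ) -> CaptureModelResults:
        """Least-squares fit; weighted (e.g. 1/SE²) if ``weights`` given.

        ``anchor_intercept=False`` frees the translation line's intercept
        instead of pinning it to the height-line prediction (sensitivity
        option; the anchored fit is the default procedure).
        """
        hres = _ols_height(self.height_points, weights=weights)
        intercept, height_slope, h_bse, h_rss = hres
        result = dict(
            intercept=intercept, height_slope=height_slope,
            translation_slope=0.0,
            orientation=self.orientation, series_height=self.series_height,
            nobs=len(self.height_points), rss=h_rss,
            bse={"intercept": h_bse[0], "height_slope": h_bse[1]},
        )
        if self.translation_points is not None:
            base = CaptureModelResults(**result)
            adjusted = remove_height_effect(
                self.translation_points, base, self.series_height
            )
            slope, t_se, t_rss = _translation_slope(
                adjusted, base.predict(self.series_height, warn=False),
                anchor_intercept=anchor_intercept,
            )
            result["translation_slope"] = slope
            result["bse"]["translation_slope"] = t_se
            result["nobs"] += len(adjusted)
            result["rss"] += t_rss
        return CaptureModelResults(**result)


def _ols_height(points, weights=None):
    h = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(h)) < 2:
        raise ModelError("need at least 2 distinct heights")
    X = sm.add_constant(h)
    model = sm.OLS(y, X) if weights is None else sm.WLS(y, X, weights=weights)
    try:
        res = model.fit()
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ModelError(f"singular height design: {exc}") from exc
    intercept = float(res.params[0])
    slope = float(-res.params[1])  # stored positive: p = a − slope·h
    bse = (float(res.bse[0]), float(res.bse[1]))
    return intercept, slope, bse, float(res.ssr)


def _translation_slope(adjusted_points, anchor, anchor_intercept=True):
    t = np.array([p[0] for p in adjusted_points], dtype=float)
    y = np.array([p[1] for p in adjusted_points], dtype=float)
    if anchor_intercept:
        # p_adj = anchor − s·t  ⇔  (anchor − p_adj) = s·t : OLS through origin
        res = sm.OLS(anchor - y, t[:, None]).fit()
        return float(res.params[0]), float(res.bse[0]), float(res.ssr)
    res = sm.OLS(y, sm.add_constant(t)).fit()
    return float(-res.params[1]), float(res.bse[1]), float(res.ssr)


# ---------------------------------------------------------------------------
# Spec-level operation wrappers
# ---------------------------------------------------------------------------

def fit_height_model(points, orientation: str | None = None,
                     weights=None) -> CaptureModelResults:
    """OLS line p(%) = intercept − height_slope·h for an on-axis series."""
    model = CaptureModel(points, orientation=orientation)
    return model.fit(weights=weights)


def remove_height_effect(translation_points, height_model: CaptureModelResults,
                         series_height: float = 3.0) -> list[tuple[float, float]]:
    """Shift a translation series so its t = 0 point matches the height line.

    Every probability moves by the single constant Δ = prediction(series
    height) − observed(t = 0); afterwards the t = 0 point equals the
    height-model prediction exactly.  Raises if the series has no t = 0
    anchor point.
    """
    pts = [(float(t), float(p)) for t, p in translation_points]
    anchors = [p for t, p in pts if abs(t) <= _T0_TOL]
    if not anchors:
        raise ModelError(
            "translation series has no t=0 point; the height-effect "
            "anchor is undefined"
        )
    prediction = height_model.predict(series_height, warn=False)
    delta = prediction - anchors[0]
    return [(t, p + delta) for t, p in pts]


def fit_combined_model(height_points, adjusted_translation_points,
                       orientation: str | None = None,
                       series_height: float = 3.0,
                       anchor_intercept: bool = True) -> CaptureModelResults:
    """Two-covariate model from a height series and an *adjusted* series.

    The intercept and height slope come from the height-only fit; the
    translation slope from least squares on the adjusted lateral series
    with the intercept pinned at the height-line prediction for the series
    height (freed when ``anchor_intercept=False``).
    """
    hres = fit_height_model(height_points, orientation=orientation)
    anchor = hres.predict(series_height, warn=False)
    slope, t_se, t_rss = _translation_slope(
        [(float(t), float(p)) for t, p in adjusted_translation_points],
        anchor, anchor_intercept=anchor_intercept,
    )
    bse = dict(hres.bse)
    bse["translation_slope"] = t_se
    return CaptureModelResults(
        intercept=hres.intercept,
        height_slope=hres.height_slope,
        translation_slope=slope,
        orientation=orientation,
        series_height=series_height,
        nobs=hres.nobs + len(adjusted_translation_points),
        rss=hres.rss + t_rss,
        bse=bse,
    )


def predict(fit: CaptureModelResults, height: float,
            translation: float = 0.0) -> float:
    """Evaluate a fitted model (module-level convenience)."""
    return fit.predict(height, translation)
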