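"""Multi-set centering and scaling strategies for cytometry data.

After transformation, each marker column is centered (a location vector
``m`` subtracted) and scaled (divided by a dispersion vector ``s``).
The strategies differ in *which cells* define ``m`` and ``s``:

``standard_pooled``
    All cells of all samples concatenated into one matrix; the pooled
    mean and pooled standard deviation.  This is what concatenating
    pipelines (Citrus, flowSOM) do implicitly.  Because every cell
    carries equal weight, samples with many cells dominate the
    statistics.

``multiset_whole``
    Sample-weighted: the location is the unweighted average of the
    per-sample locations; the scale is the square root of the average of
    the per-sample (within-sample) variances.  Every sample contributes
    equally no matter how many cells it holds, which creates a common
    reference point instead of one anchored in the largest sample.

``control_based``
    As ``multiset_whole`` but averaging over the control samples
    (``group_id == 0``) only; responder cells are expressed relative to
    the control reference, which emphasizes response-specific shifts and
    shape changes.

``per_sample``
    Each sample centered/scaled by its own statistics; removes
    sample-specific technical offsets (laser drift, handling delays) at
    the cost of erasing any group-level mean difference.

Locations are means or medians; dispersions are standard deviations or
normal-consistent MADs (median absolute deviation times 1.4826).  The
robust pair is the appropriate choice when very few cells were measured.
The within-sample variance entering ``multiset_whole``/``control_based``
/``per_sample`` scaling is always taken about each sample's own
location, whatever centering preceded it; the scaling formulas adapt
unchanged to any centering choice.

:class:`Preprocessor` / :class:`PreprocessModel` wrap the strategy
functions in a strict fit/apply split: all global statistics are fitted
on training samples only and can then be applied to held-out data,
which makes leakage-free cross-validation of the whole pipeline
possible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import median_abs_deviation

from .datamodel import MarkerPanel, MultiSet, PanelMismatchError, concatenate
from .transform import TransformSpec, apply_transform

__all__ = [
    "CenterSpec",
    "ScaleSpec",
    "Preprocessor",
    "PreprocessModel",
    "ConfigurationError",
    "ZeroVarianceError",
    "center_standard",
    "center_multiset_whole",
    "center_control",
    "center_per_sample",
    "scale_standard",
    "scale_multiset_whole",
    "scale_control",
    "scale_per_sample",
    "fit_preprocess",
    "apply_preprocess",
    "preprocess",
    "CENTER_STRATEGIES",
    "SCALE_STRATEGIES",
]

CENTER_STRATEGIES = ("standard_pooled", "multiset_whole", "control_based",
                     "per_sample")
SCALE_STRATEGIES = ("standard_pooled", "multiset_whole", "control_based",
                    "per_sample", "none")

#: MAD multiplier making the estimator consistent for the standard
#: deviation under normality (1 / Phi^-1(3/4) ~= 1.4826).
MAD_SCALE = 1.482602218505602

_LOW_CELL_THRESHOLD = 100


class ConfigurationError(ValueError):
    """Strategy cannot run on this data (e.g. control-based without controls)."""


class ZeroVarianceError(ValueError):
    """A marker with zero dispersion cannot be scaled."""


@dataclass(frozen=True)
class CenterSpec:
    strategy: str = "multiset_whole"
    estimator: str = "mean"

    def __post_init__(self) -> None:
        if self.strategy not in CENTER_STRATEGIES:
            raise ValueError(
                f"unknown centering strategy {self.strategy!r}; "
                f"choose from {CENTER_STRATEGIES}"
            )
        if self.estimator not in ("mean", "median"):
            raise ValueError(f"center estimator must be mean or median, "
                             f"got {self.estimator!r}")


@dataclass(frozen=True)
class ScaleSpec:
    strategy: str = "multiset_whole"
    estimator: str = "sd"
    ddof: int = 1

    def __post_init__(self) -> None:
        if self.strategy not in SCALE_STRATEGIES:
            raise ValueError(
                f"unknown scaling strategy {self.strategy!r}; "
                f"choose from {SCALE_STRATEGIES}"
            )
        if self.estimator not in ("sd", "mad"):
            raise ValueError(f"scale estimator must be sd or mad, "
                             f"got {self.estimator!r}")
        if self.ddof not in (0, 1):
            raise ValueError(f"ddof must be 0 or 1, got {self.ddof}")


# ---------------------------------------------------------------------------
# location / dispersion primitives
# ---------------------------------------------------------------------------

def _location(x: np.ndarray, estimator: str) -> np.ndarray:
    if estimator == "mean":
        return x.mean(axis=0)
    return np.median(x, axis=0)


def _within_sample_variance(x: np.ndarray, estimator: str, ddof: int,
                            sample_id: str) -> np.ndarray:
    """Per-marker variance of one sample about its own location."""
    if estimator == "sd":
        if x.shape[0] <= ddof:
            raise ZeroVarianceError(
                f"sample {sample_id!r} has {x.shape[0]} cell(s); variance "
                f"with ddof={ddof} is undefined"
            )
        return x.var(axis=0, ddof=ddof)
    mad = median_abs_deviation(x, axis=0, scale=1.0) * MAD_SCALE
    return mad ** 2


def _pooled_dispersion(x: np.ndarray, estimator: str, ddof: int) -> np.ndarray:
    if estimator == "sd":
        return x.std(axis=0, ddof=ddof)
    return median_abs_deviation(x, axis=0, scale=1.0) * MAD_SCALE


def _check_positive_scale(s: np.ndarray, panel: MarkerPanel,
                          context: str) -> None:
    bad = np.flatnonzero(~(s > 0) | ~np.isfinite(s))
    if bad.size:
        names = [panel.names[j] for j in bad]
        raise ZeroVarianceError(
            f"zero/undefined dispersion for marker(s) {names} ({context}); "
            f"cannot scale a degenerate marker"
        )


def _subtract(ms: MultiSet, m: np.ndarray) -> MultiSet:
    return ms.with_blocks([s.data - m for s in ms.samples])


def _divide(ms: MultiSet, s: np.ndarray) -> MultiSet:
    return ms.with_blocks([smp.data / s for smp in ms.samples])


# ---------------------------------------------------------------------------
# centering strategies
# ---------------------------------------------------------------------------

def center_standard(ms: MultiSet, estimator: str = "mean"
                    ) -> tuple[MultiSet, np.ndarray]:
    """Center on the pooled (cell-weighted) grand location.

    Every cell weighs equally, so the grand mean is pulled toward the
    samples with the most cells.
    """
    x, _ = concatenate(ms)
    m = _location(x, estimator)
    return _subtract(ms, m), m


def _sample_locations(ms: MultiSet, estimator: str) -> np.ndarray:
    return np.stack([_location(s.data, estimator) for s in ms.samples])


def center_multiset_whole(ms: MultiSet, estimator: str = "mean"
                          ) -> tuple[MultiSet, np.ndarray]:
    """Center on the unweighted average of per-sample locations.

    Each sample contributes equally to the overall location regardless
    of its cell count.
    """
    m = _sample_locations(ms, estimator).mean(axis=0)
    return _subtract(ms, m), m


def center_control(ms: MultiSet, estimator: str = "mean"
                   ) -> tuple[MultiSet, np.ndarray]:
    """Center every group on the control-group reference location."""
    controls = ms.controls
    if not controls:
        raise ConfigurationError(
            "control-based centering needs at least one sample with "
            "group_id == 0"
        )
    m0 = np.stack([_location(s.data, estimator) for s in controls]).mean(axis=0)
    return _subtract(ms, m0), m0


def center_per_sample(ms: MultiSet, estimator: str = "mean") -> MultiSet:
    """Subtract each sample's own location (removes per-sample offsets)."""
    blocks = [s.data - _location(s.data, estimator) for s in ms.samples]
    return ms.with_blocks(blocks)


# ---------------------------------------------------------------------------
# scaling strategies
# ---------------------------------------------------------------------------

def scale_standard(ms: MultiSet, estimator: str = "sd", ddof: int = 1
                   ) -> tuple[MultiSet, np.ndarray]:
    """Divide by the pooled dispersion of the concatenated matrix."""
    x, _ = concatenate(ms)
    s = _pooled_dispersion(x, estimator, ddof)
    _check_positive_scale(s, ms.panel, "pooled over all cells")
    return _divide(ms, s), s


def _average_within_variance(samples, estimator: str, ddof: int) -> np.ndarray:
    variances = np.stack([
        _within_sample_variance(s.data, estimator, ddof, s.sample_id)
        for s in samples
    ])
    return variances.mean(axis=0)


def scale_multiset_whole(ms: MultiSet, estimator: str = "sd", ddof: int = 1
                         ) -> tuple[MultiSet, np.ndarray]:
    """Divide by sqrt(average within-sample variance) over all samples."""
    s = np.sqrt(_average_within_variance(ms.samples, estimator, ddof))
    _check_positive_scale(s, ms.panel, "averaged over all samples")
    return _divide(ms, s), s


def scale_control(ms: MultiSet, estimator: str = "sd", ddof: int = 1
                  ) -> tuple[MultiSet, np.ndarray]:
    """Divide by sqrt(average within-sample variance) over controls only."""
    controls = ms.controls
    if not controls:
        raise ConfigurationError(
            "control-based scaling needs at least one sample with "
            "group_id == 0"
        )
    s0 = np.sqrt(_average_within_variance(controls, estimator, ddof))
    _check_positive_scale(s0, ms.panel, "averaged over control samples")
    return _divide(ms, s0), s0


def scale_per_sample(ms: MultiSet, estimator: str = "sd", ddof: int = 1
                     ) -> MultiSet:
    """Divide each sample by its own dispersion vector."""
    blocks = []
    for smp in ms.samples:
        v = _within_sample_variance(smp.data, estimator, ddof, smp.sample_id)
        s = np.sqrt(v)
        bad = np.flatnonzero(~(s > 0) | ~np.isfinite(s))
        if bad.size:
            names = [ms.panel.names[j] for j in bad]
            raise ZeroVarianceError(
                f"sample {smp.sample_id!r}: zero dispersion for marker(s) "
                f"{names}"
            )
        blocks.append(smp.data / s)
    return ms.with_blocks(blocks)


# ---------------------------------------------------------------------------
# fit / apply model
# ---------------------------------------------------------------------------

@dataclass
class PreprocessModel:
    """Fitted transform + centering + scaling parameters.

    Location and scale vectors are stored for the global strategies and
    absent (``None``) for per-sample strategies, whose statistics are by
    definition recomputed on whatever data the model is applied to.
    """

    panel: MarkerPanel
    transform: TransformSpec
    center: CenterSpec
    scale: ScaleSpec
    location: np.ndarray | None
    scale_values: np.ndarray | None
    fitted_on: list[tuple[str, int]] = field(default_factory=list)
    n_controls_fitted: int = 0
    mad_scale: float = MAD_SCALE

    def __post_init__(self) -> None:
        if self.scale_values is not None and not (self.scale_values > 0).all():
            raise ZeroVarianceError("fitted scale vector has non-positive entries")
        if (self.center.strategy == "control_based"
                or self.scale.strategy == "control_based"):
            if self.n_controls_fitted < 1:
                raise ConfigurationError(
                    "control-based model fitted without any control sample"
                )

    # -- application ---------------------------------------------------
    def apply(self, ms: MultiSet) -> MultiSet:
        """Transform, center and scale ``ms`` with the fitted parameters.

        Global strategies use the stored training vectors unchanged;
        per-sample strategies recompute per-sample statistics on ``ms``.
        """
        if ms.panel.names != self.panel.names:
            raise PanelMismatchError(
                f"panel mismatch: model {list(self.panel.names)} vs data "
                f"{list(ms.panel.names)}"
            )
        out = apply_transform(ms, self.transform)
        if self.center.strategy == "per_sample":
            out = center_per_sample(out, self.center.estimator)
        else:
            out = _subtract(out, self.location)
        if self.scale.strategy == "per_sample":
            out = scale_per_sample(out, self.scale.estimator, self.scale.ddof)
        elif self.scale.strategy != "none":
            out = _divide(out, self.scale_values)
        return out

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "panel": list(self.panel.names),
            "transform": {"kind": self.transform.kind,
                          "cofactor": self.transform.cofactor,
                          "log_base": "natural (asinh identity)"
                          if self.transform.kind == "arcsinh" else "10"},
            "center": {"strategy": self.center.strategy,
                       "estimator": self.center.estimator},
            "scale": {"strategy": self.scale.strategy,
                      "estimator": self.scale.estimator,
                      "ddof": self.scale.ddof,
                      "mad_scale": self.mad_scale},
            "location": None if self.location is None
            else [float(v) for v in self.location],
            "scale_values": None if self.scale_values is None
            else [float(v) for v in self.scale_values],
            "fitted_on": [[sid, gid] for sid, gid in self.fitted_on],
            "n_controls_fitted": self.n_controls_fitted,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessModel":
        return cls(
            panel=MarkerPanel(tuple(d["panel"])),
            transform=TransformSpec(d["transform"]["kind"],
                                    d["transform"]["cofactor"]),
            center=CenterSpec(d["center"]["strategy"], d["center"]["estimator"]),
            scale=ScaleSpec(d["scale"]["strategy"], d["scale"]["estimator"],
                            d["scale"]["ddof"]),
            location=None if d["location"] is None
            else np.asarray(d["location"], dtype=float),
            scale_values=None if d["scale_values"] is None
            else np.asarray(d["scale_values"], dtype=float),
            fitted_on=[(sid, int(gid)) for sid, gid in d["fitted_on"]],
            n_controls_fitted=int(d["n_controls_fitted"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "PreprocessModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def summary(self) -> str:
        lines = [
            "Multi-set preprocessing model",
            f"  transform : {self.transform.kind}"
            + (f" (cofactor {self.transform.cofactor:g})"
               if self.transform.kind == "arcsinh" else ""),
            f"  centering : {self.center.strategy} ({self.center.estimator})",
            f"  scaling   : {self.scale.strategy} ({self.scale.estimator}, "
            f"ddof={self.scale.ddof})",
            f"  fitted on : {len(self.fitted_on)} sample(s), "
            f"{self.n_controls_fitted} control(s)",
        ]
        if self.location is not None or self.scale_values is not None:
            lines.append(f"  {'marker':<16}{'location':>12}{'scale':>12}")
            for j, name in enumerate(self.panel.names):
                loc = (f"{self.location[j]:12.5g}"
                       if self.location is not None else f"{'-':>12}")
                sc = (f"{self.scale_values[j]:12.5g}"
                      if self.scale_values is not None else f"{'-':>12}")
                lines.append(f"  {name:<16}{loc}{sc}")
        return "\n".join(lines)


class Preprocessor:
    """Model object: configure a preprocessing pipeline on training data.

    ``Preprocessor(ms, ...).fit()`` computes all global location/scale
    vectors from ``ms`` only and returns a :class:`PreprocessModel`
    results object whose :meth:`~PreprocessModel.apply` can be used on
    the training set or on held-out samples without leakage.
    """

    def __init__(self, ms: MultiSet,
                 transform: TransformSpec | None = None,
                 center: CenterSpec | None = None,
                 scale: ScaleSpec | None = None):
        self.ms = ms
        self.transform = transform or TransformSpec()
        self.center = center or CenterSpec()
        self.scale = scale or ScaleSpec()

    def fit(self) -> PreprocessModel:
        ms, center, scale = self.ms, self.center, self.scale
        if (center.strategy == "control_based"
                or scale.strategy == "control_based") and ms.n_controls == 0:
            raise ConfigurationError(
                "control-based preprocessing needs at least one control "
                "sample (group_id == 0) in the training data"
            )
        small = ms.n_cells.min()
        if small < _LOW_CELL_THRESHOLD and (center.estimator == "mean"
                                            or scale.estimator == "sd"):
            warnings.warn(
                f"smallest sample has only {small} cells; median/MAD "
                f"estimators are more reliable at very low cell counts",
                stacklevel=2,
            )
        if center.strategy == "multiset_whole" and scale.strategy == "per_sample":
            warnings.warn(
                "centering on the whole set combined with scaling per "
                "sample tends to give unpredictable downstream models",
                stacklevel=2,
            )

        t = apply_transform(ms, self.transform)

        location = None
        if center.strategy == "standard_pooled":
            centered, location = center_standard(t, center.estimator)
        elif center.strategy == "multiset_whole":
            centered, location = center_multiset_whole(t, center.estimator)
        elif center.strategy == "control_based":
            centered, location = center_control(t, center.estimator)
        else:
            centered = center_per_sample(t, center.estimator)

        scale_values = None
        if scale.strategy == "standard_pooled":
            _, scale_values = scale_standard(centered, scale.estimator,
                                             scale.ddof)
        elif scale.strategy == "multiset_whole":
            _, scale_values = scale_multiset_whole(centered, scale.estimator,
                                                   scale.ddof)
        elif scale.strategy == "control_based":
            _, scale_values = scale_control(centered, scale.estimator,
                                            scale.ddof)
        elif scale.strategy == "per_sample":
            # validate feasibility on the training data (zero-dispersion
            # markers, single-cell samples) without storing anything
            scale_per_sample(centered, scale.estimator, scale.ddof)

        return PreprocessModel(
            panel=ms.panel,
            transform=self.transform,
            center=center,
            scale=scale,
            location=location,
            scale_values=scale_values,
            fitted_on=[s.key for s in ms.samples],
            n_controls_fitted=ms.n_controls,
        )


def fit_preprocess(train: MultiSet, transform: TransformSpec | None = None,
                   center: CenterSpec | None = None,
                   scale: ScaleSpec | None = None) -> PreprocessModel:
    """Functional alias for ``Preprocessor(train, ...).fit()``."""
    return Preprocessor(train, transform, center, scale).fit()


def apply_preprocess(model: PreprocessModel, ms: MultiSet) -> MultiSet:
    """Functional alias for ``model.apply(ms)``."""
    return model.apply(ms)


def preprocess(ms: MultiSet, transform: TransformSpec | None = None,
               center: CenterSpec | None = None,
               scale: ScaleSpec | None = None
               ) -> tuple[MultiSet, PreprocessModel]:
    """One-shot fit-and-apply on the same data."""
    model = fit_preprocess(ms, transform, center, scale)
    return model.apply(ms), model
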