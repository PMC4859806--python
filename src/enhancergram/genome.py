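"""Ensemble enhancer prediction over tiled genomic windows.

Long genomic regions are tiled into overlapping 500-bp windows, each window
is scanned for Dorsal/Twist/Snail (and E-box) sites, and every model in a
fitted panel predicts the window's 17-point DV expression profile.  Windows
are summarized by the pointwise mean and standard deviation across the
panel, by performance-weighted averages (weights proportional to 1 - RMSE,
or to the Akaike relative likelihood exp(-dAIC/2)), and by a pattern call:
mesodermal (ventral expression surviving at the Snail-repressed points),
neuroectodermal (a lateral stripe repressed ventrally), inactive, or
ambiguous.  Predicted enhancers are graded against measurements with the
4- and 5-point scoring scales used for out-of-sample enhancer evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .engine import GradientSet, N_POINTS, Profile, predict_expression_fast
from .fitting import FitResult
from .motifs import ScoreMatrix, SiteMap, build_sitemap
from .schemes import ParameterVector, get_model

__all__ = [
    "tile",
    "panel_predict",
    "aggregate",
    "classify_profile",
    "score_neuroectodermal",
    "score_mesodermal",
    "EnsemblePrediction",
    "EnhancerScore",
    "PanelMember",
    "ClassifierConfig",
]

DEFAULT_WINDOW = 500
DEFAULT_STEP = 250

# point indices (0-based) delimiting the embryonic domains along the
# 17-point axis: the Snail gradient collapses between points 6 and 7
MESODERM_POINTS = slice(0, 5)
NEUROECTODERM_POINTS = slice(5, 13)
SNAIL_CHECK_POINT = 3  # "nucleus 4": 4th of the 17 points, 1-based


def tile(length: int, window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP
         ) -> list[tuple[int, int]]:
    """Fully contained overlapping windows [k*step, k*step + window)."""
    if step >= window:
        raise ValueError("step must be smaller than window (overlap required)")
    if length < window:
        warnings.warn(
            f"sequence of {length} bp is shorter than the {window} bp window; "
            f"returning one full-sequence window", stacklevel=2,
        )
        return [(0, length)]
    return [(k * step, k * step + window)
            for k in range((length - window) // step + 1)]


@dataclass(frozen=True)
class PanelMember:
    """One fitted model usable for ensemble prediction."""

    model: str
    theta: ParameterVector
    rmse: float
    aic: float

    @classmethod
    def from_fit(cls, res: FitResult) -> "PanelMember":
        return cls(res.model, res.theta, res.best_rmse, res.aic)


@dataclass
class ClassifierConfig:
    """Pattern-call thresholds (derived from the scoring-scale boundaries)."""

    inactive_max: float = 0.1
    mesoderm_factor: float = 0.5  # point-4 value >= factor * max -> ventral signal
    neuro_factor: float = 0.3  # point-4 value < factor * max -> repressed ventrally


@dataclass
class EnsemblePrediction:
    window: tuple[str, int, int]
    per_model: dict[str, Profile]
    mean: Profile = field(init=False)
    sd: Profile = field(init=False)
    weighted: dict[str, Profile] = field(init=False)
    pattern: str = field(init=False)
    sitemap: SiteMap | None = None
    _panel: list[PanelMember] | None = None

    def __post_init__(self):
        stack = np.vstack([p.values for p in self.per_model.values()])
        self.mean = Profile(stack.mean(axis=0))
        self.sd = Profile(stack.std(axis=0))
        self.weighted = {}
        if self._panel is not None:
            self.weighted = {
                "rmse_weighted": aggregate(self, "rmse"),
                "aic_weighted": aggregate(self, "aic"),
            }
        self.pattern = classify_profile(self.mean)

    @property
    def peak(self) -> float:
        return float(self.mean.values.max())


def aggregate(e: EnsemblePrediction, weighting: str = "uniform") -> Profile:
    """Panel average profile under uniform, (1 - RMSE), or AIC weighting."""
    stack = np.vstack([e.per_model[m].values for m in e.per_model])
    if weighting == "uniform":
        return Profile(stack.mean(axis=0))
    if e._panel is None:
        raise ValueError("weighted aggregation requires panel metadata")
    members = {m.model: m for m in e._panel}
    order = list(e.per_model)
    if weighting == "rmse":
        w = []
        for mid in order:
            v = 1.0 - members[mid].rmse
            if v < 0:
                warnings.warn(
                    f"model {mid} has RMSE >= 1; weight floored at 0", stacklevel=2
                )
                v = 0.0
            w.append(v)
        w = np.asarray(w)
    elif weighting == "aic":
        aics = np.array([members[mid].aic for mid in order])
        w = np.exp(-(aics - aics.min()) / 2.0)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if w.sum() == 0:
        w = np.ones_like(w)
    w = w / w.sum()
    return Profile(w @ stack)


def panel_predict(seq_id: str, seq: str, windows: list[tuple[int, int]],
                  panel: list[PanelMember],
                  matrices: dict[str, tuple[ScoreMatrix, float]],
                  gradients: GradientSet, bhlh: str | None = None
                  ) -> list[EnsemblePrediction]:
    """Scan each window, build its SiteMap, and predict with every model.

    E-box (bHLH) annotation is disabled by default in genome scans: literal
    CANNTG hexamers occur every ~130 bp in random sequence and would place
    activator sites in essentially every window.
    """
    out = []
    for start, end in windows:
        sm = build_sitemap(f"{seq_id}:{start}-{end}", seq[start:end],
                           matrices, bhlh=bhlh)
        per_model = {}
        for member in panel:
            spec = get_model(member.model)
            prof = predict_expression_fast(sm, member.theta, gradients, spec)
            per_model[member.model] = prof
        out.append(EnsemblePrediction((seq_id, start, end), per_model,
                                      sitemap=sm, _panel=panel))
    return out


def classify_profile(p: Profile, cfg: ClassifierConfig | None = None) -> str:
    """Call a 17-point profile mesodermal / neuroectodermal / inactive / ambiguous."""
    cfg = cfg or ClassifierConfig()
    v = p.values
    peak = float(v.max())
    if peak < cfg.inactive_max:
        return "inactive"
    argmax = int(v.argmax())
    ventral = v[SNAIL_CHECK_POINT]
    if ventral >= cfg.mesoderm_factor * peak and argmax < MESODERM_POINTS.stop:
        return "mesodermal"
    if (ventral < cfg.neuro_factor * peak
            and NEUROECTODERM_POINTS.start <= argmax < NEUROECTODERM_POINTS.stop):
        return "neuroectodermal"
    return "ambiguous"


@dataclass(frozen=True)
class EnhancerScore:
    """Graded agreement between predicted and measured profiles.

    Lower scores represent better fits.  Neuroectodermal enhancers are
    graded on two 4-point scales (Snail repression at nucleus 4, peak
    activation agreement); mesodermal enhancers on a 5-point activation and
    a 4-point Snail scale.
    """

    role: str  # neuroectodermal | mesodermal
    snail_score: int
    activation_score: int


def score_neuroectodermal(predicted: Profile, measured: Profile) -> EnhancerScore:
    """Grade a neuroectodermal enhancer prediction.

    Snail repression is read at nucleus 4 of the predicted profile
    (grades: <0.1 complete, 0.1-0.3 moderate, 0.3-0.5 weak, 0.5-1 very
    weak); activation from the peak-expression difference (grades at 0.2,
    0.5, 0.7).
    """
    ventral = float(predicted.values[SNAIL_CHECK_POINT])
    snail = _grade(ventral, [0.1, 0.3, 0.5])
    peak_diff = abs(float(predicted.values.max()) - float(measured.values.max()))
    activation = _grade(peak_diff, [0.2, 0.5, 0.7])
    return EnhancerScore("neuroectodermal", snail, activation)


def score_mesodermal(predicted: Profile, measured: Profile) -> EnhancerScore:
    """Grade a mesodermal enhancer prediction.

    Snail grade: 1 if mesoderm activation exceeds 1.5x the peak
    neurectoderm expression (no Snail activity), 2 if comparable, 3 if
    below, 4 if mesoderm expression is under 0.1 absolute.  Activation:
    peak-difference bands (0.2, 0.4, 0.7) when the prediction is
    mesoderm-dominant, else grade 4 (low dorsal signal) or 5 (high dorsal
    signal at the dorsal-most points).
    """
    v = predicted.values
    meso = float(v[MESODERM_POINTS].max())
    neuro = float(v[NEUROECTODERM_POINTS].max())
    if meso < 0.1:
        snail = 4
    elif neuro > 0 and meso > 1.5 * neuro:
        snail = 1
    elif neuro == 0 and meso >= 0.1:
        snail = 1
    elif meso >= 0.9 * neuro:
        snail = 2
    else:
        snail = 3
    meso_dominant = meso >= neuro
    if meso_dominant:
        peak_diff = abs(meso - float(measured.values[MESODERM_POINTS].max()))
        activation = _grade(peak_diff, [0.2, 0.4, 0.7])
        activation = min(activation, 3)
    else:
        dorsal_tail = float(v[13:].max())
        activation = 4 if dorsal_tail < 0.3 else 5
    return EnhancerScore("mesodermal", snail, activation)


def _grade(value: float, edges: list[float]) -> int:
    return int(np.searchsorted(np.asarray(edges), value, side="right")) + 1
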