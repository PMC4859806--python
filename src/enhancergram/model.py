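"""Model/Results interface over the thermodynamic engine and fitting stack.

`EnhancerModel` binds one model formulation (a cooperativity x quenching
scheme pair) to a perturbation dataset and the TF concentration gradients;
``fit()`` runs the restart-based CMA-ES estimation and returns an
`EnhancerResults` carrying the estimated parameters, per-run and
per-construct diagnostics, AIC, and prediction methods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import GradientSet, Profile, load_gradients, predict_expression_fast
from .fitting import FitConfig, FitResult, _Objective, fit as _fit
from .motifs import SiteMap
from .schemes import ModelSpec, ParameterVector, get_model

__all__ = ["EnhancerModel", "EnhancerResults"]


class EnhancerModel:
    """A thermodynamic enhancer model bound to a perturbation dataset.

    Parameters
    ----------
    data
        Object exposing ``entries() -> [(construct_id, SiteMap, Profile)]``
        (e.g. `simulate.PerturbationDataset`).
    spec
        A `ModelSpec` or model id string such as ``"C14Q5"``.
    gradients
        TF concentration gradients; the packaged 17-point fixture by default.
    """

    def __init__(self, data, spec: ModelSpec | str,
                 gradients: GradientSet | None = None):
        self.spec = get_model(spec) if isinstance(spec, str) else spec
        self.data = data
        self.gradients = gradients or load_gradients()
        self._objective = _Objective(self.spec, data, self.gradients)

    @property
    def n_params(self) -> int:
        return self.spec.n_params

    @property
    def n_points(self) -> int:
        return self._objective.n_points

    def rmse(self, theta) -> float:
        """Objective value at a parameter point."""
        theta = theta.values if isinstance(theta, ParameterVector) else np.asarray(theta)
        return self._objective.rmse(theta)

    def predict(self, theta, sitemap: SiteMap | None = None):
        """Predicted profiles for all constructs, or for one site map."""
        thv = theta.values if isinstance(theta, ParameterVector) else np.asarray(theta)
        if sitemap is not None:
            return predict_expression_fast(sitemap, thv, self.gradients, self.spec)
        return {cid: Profile(v, construct_id=cid)
                for cid, v in self._objective.predictions(thv).items()}

    def fit(self, cfg: FitConfig | None = None, **kwargs) -> "EnhancerResults":
        """Estimate parameters; ``kwargs`` override `FitConfig` fields."""
        if cfg is None:
            cfg = FitConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either cfg or keyword overrides, not both")
        res = _fit(self.spec, self.data, self.gradients, cfg)
        return EnhancerResults(self, res)


class EnhancerResults:
    """Estimation results for one `EnhancerModel`."""

    def __init__(self, model: EnhancerModel, fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result

    # -- point estimates and diagnostics --------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(
            self.fit_result.theta.values,
            index=list(self.model.spec.slot_names),
            name=self.model.spec.id,
        )

    @property
    def rmse(self) -> float:
        return self.fit_result.best_rmse

    @property
    def aic(self) -> float:
        return self.fit_result.aic

    @property
    def stable(self) -> bool:
        return self.fit_result.stable

    @property
    def per_construct_rmse(self) -> pd.Series:
        d = self.fit_result.per_construct_rmse
        return pd.Series(d, name="rmse").sort_index(key=lambda ix: ix.astype(int))

    @property
    def run_rmses(self) -> list[float]:
        return [r["rmse"] for r in self.fit_result.runs]

    def predict(self, sitemap: SiteMap | None = None):
        return self.model.predict(self.fit_result.theta, sitemap)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        spec = self.model.spec
        lines = [
            f"Thermodynamic enhancer model {spec.id}",
            "=" * 52,
            f"{'Constructs:':<24}{len(self.model.data.entries())}",
            f"{'Fitted points:':<24}{self.model.n_points}",
            f"{'Parameters:':<24}{spec.n_params}",
            f"{'Restarts:':<24}{len(self.fit_result.runs)}",
            f"{'Best RMSE:':<24}{self.rmse:.4f}",
            f"{'AIC:':<24}{self.aic:.1f}",
            f"{'Stable (>=3 runs +/-5%):':<24}{self.stable}",
            "-" * 52,
            f"{'parameter':<22}{'estimate':>12}  {'run spread':>14}",
        ]
        thetas = np.array([r["theta"] for r in self.fit_result.runs])
        spread = thetas.max(axis=0) - thetas.min(axis=0)
        for name, val, sp in zip(spec.slot_names, self.fit_result.theta.values, spread):
            lines.append(f"{name:<22}{val:>12.4g}  {sp:>14.3g}")
        lines.append("=" * 52)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<EnhancerResults {self.model.spec.id} "
                f"rmse={self.rmse:.4f} aic={self.aic:.1f}>")
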