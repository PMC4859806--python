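"""Cross-validation schemes and variance-based sensitivity analysis.

Systematic cross-validation leaves out one mutation class at a time
(Dorsal, Twist, Dorsal+Twist, Snail, bHLH knockout constructs, using the
published class memberships); random five-fold cross-validation splits the
38 constructs into seeded partitions of sizes 8, 8, 8, 7, 7.  Constructs 1
and 22 belong to no systematic class and are always kept in training.

Sensitivity analysis perturbs parameters around the fitted point
(independent +/-20% log-uniform factors by default) and decomposes the
variance of the resulting RMSE with Saltelli/Jansen estimators: the
first-order index measures what a parameter explains on its own, the
second-order (total minus first) what it explains only jointly with others.
Parameters whose slots are never exercised by the construct set (empty
distance bins) are excluded before normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import GradientSet
from .fitting import FitConfig, FitResult, _Objective, fit
from .schemes import KIND_QFRAC, KIND_SCALING, ModelSpec, ParameterVector

__all__ = [
    "PartitionScheme",
    "systematic_partitions",
    "random_partitions",
    "cross_validate",
    "CVReport",
    "sensitivity",
    "SensitivityReport",
    "sobol_indices",
]


@dataclass(frozen=True)
class PartitionScheme:
    name: str
    folds: dict[str, tuple[int, ...]]
    kind: str  # systematic | random
    seed: int | None = None

    def __post_init__(self):
        all_ids: list[int] = []
        for ids in self.folds.values():
            all_ids.extend(ids)
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("folds must be disjoint")


def systematic_partitions() -> PartitionScheme:
    """The five published mutation-class folds."""
    from .simulate import CLASS_LISTS

    return PartitionScheme("systematic", dict(CLASS_LISTS), "systematic")


def random_partitions(seed: int, ids=None) -> PartitionScheme:
    """Seeded shuffle of the registry into folds of sizes 8, 8, 8, 7, 7.

    For a registry of a different size the fold sizes are rescaled
    proportionally: n // 5 each, with the remainder distributed one by one
    to the leading folds.
    """
    ids = list(ids) if ids is not None else list(range(1, 39))
    n = len(ids)
    if n == 38:
        sizes = [8, 8, 8, 7, 7]
    else:
        base, rem = divmod(n, 5)
        sizes = [base + (1 if i < rem else 0) for i in range(5)]
    rng = np.random.default_rng(seed)
    shuffled = list(np.array(ids)[rng.permutation(n)])
    folds = {}
    pos = 0
    for i, size in enumerate(sizes, start=1):
        folds[f"fold{i}"] = tuple(int(x) for x in shuffled[pos: pos + size])
        pos += size
    return PartitionScheme(f"random_seed{seed}", folds, "random", seed)


@dataclass
class CVReport:
    model: str
    partition: str
    fold_results: dict[str, dict]  # fold -> {rmse_heldout, rmse_all, fit, per_construct}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fold, res in self.fold_results.items():
            for cid, r in res["per_construct"].items():
                rows.append({
                    "model": self.model, "fold": fold, "construct": cid,
                    "rmse": r,
                    "held_out": int(cid) in res["held_out_ids"],
                })
        return pd.DataFrame(rows)

    def heldout_rmse(self, fold: str) -> float:
        return self.fold_results[fold]["rmse_heldout"]


def cross_validate(spec: ModelSpec, data, partitions: PartitionScheme,
                   gradients: GradientSet, cfg: FitConfig | None = None,
                   min_train: int = 5) -> CVReport:
    """Fit on each fold's complement; report held-out and overall RMSE."""
    import warnings

    all_ids = set(data.ids())
    fold_results = {}
    for fold_name, fold_ids in partitions.folds.items():
        held = set(fold_ids) & all_ids
        train_ids = all_ids - held
        if len(train_ids) < min_train:
            warnings.warn(
                f"fold {fold_name} leaves only {len(train_ids)} training "
                f"constructs", stacklevel=2,
            )
        train = data.subset(train_ids)
        res = fit(spec, train, gradients, cfg)
        theta = res.theta.values
        full_obj = _Objective(spec, data, gradients)
        per_construct = full_obj.per_construct(theta)
        if held:
            held_obj = _Objective(spec, data.subset(held), gradients)
            rmse_heldout = held_obj.rmse(theta)
        else:
            rmse_heldout = full_obj.rmse(theta)
        fold_results[fold_name] = {
            "rmse_heldout": rmse_heldout,
            "rmse_all": full_obj.rmse(theta),
            "held_out_ids": sorted(int(i) for i in held),
            "per_construct": per_construct,
            "fit": res,
        }
    return CVReport(spec.id, partitions.name, fold_results)


# ----------------------------------------------------------------------
# sensitivity analysis
# ----------------------------------------------------------------------

@dataclass
class SensitivityReport:
    model: str
    first_order: dict[str, float]
    second_order: dict[str, float]
    excluded: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "model": self.model,
            "first_order": self.first_order,
            "second_order": self.second_order,
            "excluded": self.excluded,
        }


def sobol_indices(func, sampler, k: int, n: int, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Jansen estimators of first-order and total-order Sobol indices.

    ``sampler(rng, n, k)`` draws an (n, k) input matrix; ``func`` maps one
    row to a scalar.  Returns (first_order, total_order), each length k,
    unnormalized (fractions of output variance).
    """
    A = sampler(rng, n, k)
    B = sampler(rng, n, k)
    yA = np.array([func(row) for row in A])
    yB = np.array([func(row) for row in B])
    var = np.var(np.concatenate([yA, yB]))
    first = np.zeros(k)
    total = np.zeros(k)
    if var == 0:
        return first, total
    for i in range(k):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        yABi = np.array([func(row) for row in ABi])
        first[i] = 1.0 - np.mean((yB - yABi) ** 2) / (2 * var)
        total[i] = np.mean((yA - yABi) ** 2) / (2 * var)
    return first, total


def _informative_slots(obj: _Objective, theta: np.ndarray, spec: ModelSpec
                       ) -> np.ndarray:
    """A slot is informative iff changing it alone changes some prediction."""
    base = obj.predictions(theta)
    keep = np.zeros(spec.n_params, dtype=bool)
    for i, kind in enumerate(spec.slot_kinds):
        probe = theta.copy()
        probe[i] = 0.25 if kind == KIND_QFRAC else max(theta[i] * 2.0, 0.5)
        if np.isclose(probe[i], theta[i]):
            probe[i] = 0.75 if kind == KIND_QFRAC else theta[i] + 1.0
        alt = obj.predictions(probe)
        keep[i] = any(not np.array_equal(base[c], alt[c]) for c in base)
    return keep


def sensitivity(spec: ModelSpec, fit_result: FitResult, data,
                gradients: GradientSet, rel: float = 0.2, n: int = 2048,
                seed: int = 0) -> SensitivityReport:
    """First- and second-order relative sensitivities of the fitted model.

    Perturbs each included parameter by an independent log-uniform factor in
    [1-rel, 1+rel] around its fitted value (n seeded Saltelli samples) and
    decomposes the variance of the model RMSE.  Indices are clipped at 0 and
    each order is normalized to sum 1 over the reported parameters.
    """
    import warnings

    obj = _Objective(spec, data, gradients)
    theta0 = fit_result.theta.values
    keep = _informative_slots(obj, theta0, spec)
    idx = np.nonzero(keep)[0]
    excluded = [spec.slot_names[i] for i in range(spec.n_params) if not keep[i]]
    k = len(idx)
    rng = np.random.default_rng(seed)
    lo, hi = np.log(1 - rel), np.log(1 + rel)
    bounds = np.array(spec.bounds)

    def sampler(rng, n, k):
        return np.exp(rng.uniform(lo, hi, size=(n, k)))

    def func(mult_row):
        theta = theta0.copy()
        theta[idx] = np.clip(theta0[idx] * mult_row, bounds[idx, 0], bounds[idx, 1])
        return obj.rmse(theta)

    first, total = sobol_indices(func, sampler, k, n, rng)
    if np.all(first == 0) and np.all(total == 0):
        warnings.warn("zero output variance; all sensitivities are 0", stacklevel=2)
    first = np.maximum(first, 0.0)
    second = np.maximum(total - first, 0.0)
    names = [spec.slot_names[i] for i in idx]
    return SensitivityReport(
        spec.id,
        dict(zip(names, _normalize(first))),
        dict(zip(names, _normalize(second))),
        excluded,
    )


def _normalize(v: np.ndarray) -> list[float]:
    s = v.sum()
    return [float(x) for x in (v / s if s > 0 else v)]
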