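"""Cooperativity and quenching scheme definitions and the 120-model factory.

Each thermodynamic model formulation combines one of 15 cooperativity
schemes (C1-C15) with one of 8 quenching schemes (Q1-Q8).  Cooperativity
multiplies the statistical weight of two adjacently bound factors as a
function of their center-to-center distance ``d`` (bp); quenching gives the
fraction of time a bound Snail repressor inactivates an adjacently bound
activator at distance ``d``.

Scheme inventory
----------------
Cooperativity: C1 linear ``a + b*d``, C2 logistic ``2a/(1+exp(d/b))``,
C3 gaussian ``a*exp(-d^2/b)`` (each with one (a, b) pair shared by the
homotypic classes DD/TT/SS and a separate pair for heterotypic DT);
C4-C9 binned with shared homotypic bins plus DT bins; C10-C15 the same bin
edges but one bin set per interaction class (DD, TT, DT, SS).

Quenching: Q1 a fixed, zero-parameter non-monotonic lookup curve (a packaged
stand-in for a previously published short-range-repression profile);
Q2 linear decay, Q3 logistic, Q4 gaussian (amplitude fixed at a=1, one free
``b`` per repressed activator class Snail->Dorsal and Snail->Twist);
Q5-Q8 binned fractions per repressed class.

All parameter layouts start with the three TF scaling factors
(Dorsal, Twist, Snail).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "CoopScheme",
    "QuenchScheme",
    "ModelSpec",
    "ParameterVector",
    "get_model",
    "list_models",
    "parameter_layout",
    "cooperativity_factor",
    "quench_fraction",
    "COOP_IDS",
    "QUENCH_IDS",
    "CLS_DD",
    "CLS_TT",
    "CLS_DT",
    "CLS_SS",
    "CLS_NONE",
    "QCLS_SD",
    "QCLS_ST",
    "QCLS_NONE",
]

# interaction-class codes used by the engine's vectorized pair matrices
CLS_NONE = -1  # activator-repressor adjacency: no cooperativity class
CLS_DD = 0
CLS_TT = 1
CLS_DT = 2
CLS_SS = 3

QCLS_NONE = -1
QCLS_SD = 0  # Snail quenching Dorsal
QCLS_ST = 1  # Snail quenching Twist

_COOP_EDGES = {
    "C4": [25], "C10": [25],
    "C5": [50], "C11": [50],
    "C6": [75], "C12": [75],
    "C7": [50, 100], "C13": [50, 100],
    "C8": [60, 120], "C14": [60, 120],
    "C9": [70, 140], "C15": [70, 140],
}

_QUENCH_EDGES = {
    "Q5": [25, 50, 75],
    "Q6": [35, 70, 105],
    "Q7": [45, 90, 135],
    "Q8": [10, 20, 30, 40, 50, 60, 70, 80, 90],
}

_CONTINUOUS_FORMS = {"C1": "linear", "C2": "logistic", "C3": "gaussian"}
_QCONTINUOUS_FORMS = {"Q2": "linear", "Q3": "logistic", "Q4": "gaussian"}

COOP_IDS = tuple(f"C{i}" for i in range(1, 16))
QUENCH_IDS = tuple(f"Q{j}" for j in range(1, 9))


@dataclass(frozen=True)
class CoopScheme:
    id: str
    form: str  # linear | logistic | gaussian | binned | protein_binned
    bin_edges: tuple[int, ...] = ()
    per_protein: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) + 1 if self.bin_edges else 0

    @property
    def n_params(self) -> int:
        if self.form in ("linear", "logistic", "gaussian"):
            return 4  # homotypic (a,b) + DT (a,b)
        n_classes = 4 if self.per_protein else 2
        return n_classes * self.n_bins


@dataclass(frozen=True)
class QuenchScheme:
    id: str
    form: str  # fixed_msb | linear | logistic | gaussian | binned
    bin_edges: tuple[int, ...] = ()

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) + 1 if self.bin_edges else 0

    @property
    def n_params(self) -> int:
        if self.form == "fixed_msb":
            return 0
        if self.form in ("linear", "logistic", "gaussian"):
            return 2  # one b per repressed class (SD, ST); a fixed at 1
        return 2 * self.n_bins


def coop_scheme(cid: str) -> CoopScheme:
    if cid in _CONTINUOUS_FORMS:
        return CoopScheme(cid, _CONTINUOUS_FORMS[cid])
    if cid in _COOP_EDGES:
        per_protein = int(cid[1:]) >= 10
        return CoopScheme(
            cid,
            "protein_binned" if per_protein else "binned",
            tuple(_COOP_EDGES[cid]),
            per_protein,
        )
    raise KeyError(f"unknown cooperativity scheme {cid!r}")


def quench_scheme(qid: str) -> QuenchScheme:
    if qid == "Q1":
        return QuenchScheme(qid, "fixed_msb")
    if qid in _QCONTINUOUS_FORMS:
        return QuenchScheme(qid, _QCONTINUOUS_FORMS[qid])
    if qid in _QUENCH_EDGES:
        return QuenchScheme(qid, "binned", tuple(_QUENCH_EDGES[qid]))
    raise KeyError(f"unknown quenching scheme {qid!r}")


# slot kinds decide fitting transforms and bounds
KIND_SCALING = "scaling"
KIND_COOP = "coop"
KIND_QFRAC = "quench_fraction"
KIND_B = "shape_b"

_BOUNDS = {
    KIND_SCALING: (1e-9, 1000.0),
    KIND_COOP: (0.0, 1000.0),
    KIND_QFRAC: (0.0, 1.0),
    KIND_B: (1e-9, 1000.0),
}


def _load_msb_curve() -> dict:
    with resources.files("enhancergram.data").joinpath("q1_msb.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class ModelSpec:
    """One of the 120 model formulations: layout of named parameter slots."""

    coop: CoopScheme
    quench: QuenchScheme
    slot_names: tuple[str, ...] = field(init=False)
    slot_kinds: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        names: list[str] = ["scale_Dorsal", "scale_Twist", "scale_Snail"]
        kinds: list[str] = [KIND_SCALING] * 3
        c = self.coop
        if c.form in ("linear", "logistic", "gaussian"):
            for grp in ("homo", "DT"):
                names += [f"coop_{grp}_a", f"coop_{grp}_b"]
                kinds += [KIND_COOP, KIND_B]
        else:
            groups = ("DD", "TT", "DT", "SS") if c.per_protein else ("homo", "DT")
            for grp in groups:
                for b in range(1, c.n_bins + 1):
                    names.append(f"coop_{grp}_bin{b}")
                    kinds.append(KIND_COOP)
        q = self.quench
        if q.form in ("linear", "logistic", "gaussian"):
            names += ["quench_SD_b", "quench_ST_b"]
            kinds += [KIND_B, KIND_B]
        elif q.form == "binned":
            for grp in ("SD", "ST"):
                for b in range(1, q.n_bins + 1):
                    names.append(f"quench_{grp}_bin{b}")
                    kinds.append(KIND_QFRAC)
        object.__setattr__(self, "slot_names", tuple(names))
        object.__setattr__(self, "slot_kinds", tuple(kinds))

    @property
    def id(self) -> str:
        return f"{self.coop.id}{self.quench.id}"

    @property
    def n_params(self) -> int:
        return len(self.slot_names)

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [_BOUNDS[k] for k in self.slot_kinds]

    def slot(self, name: str) -> int:
        return self.slot_names.index(name)

    # ------------------------------------------------------------------
    # vectorized factor evaluation used by the engine
    # ------------------------------------------------------------------
    def coop_factors(self, theta: np.ndarray, d: np.ndarray, cls: np.ndarray) -> np.ndarray:
        """Cooperativity factor for each pair.

        ``d``: integer center-to-center distances; ``cls``: interaction-class
        codes (CLS_*).  Pairs with ``cls == CLS_NONE`` get factor 1.
        """
        d = np.asarray(d, dtype=float)
        cls = np.asarray(cls)
        out = np.ones_like(d, dtype=float)
        mask = cls != CLS_NONE
        if not mask.any():
            return out
        c = self.coop
        if c.form in ("linear", "logistic", "gaussian"):
            # group 0 = homotypic (DD, TT, SS), group 1 = DT
            grp = np.where(cls == CLS_DT, 1, 0)
            a = theta[3 + 2 * grp]
            b = theta[4 + 2 * grp]
            if c.form == "linear":
                vals = a + b * d
            elif c.form == "logistic":
                vals = 2.0 * a / (1.0 + np.exp(d / b))
            else:
                vals = a * np.exp(-(d ** 2) / b)
            out[mask] = vals[mask]
        else:
            edges = np.asarray(c.bin_edges)
            binidx = np.searchsorted(edges, d, side="left")
            if c.per_protein:
                grp = cls.copy()  # DD=0, TT=1, DT=2, SS=3 match slot order
            else:
                grp = np.where(cls == CLS_DT, 1, 0)
            slot = 3 + grp * c.n_bins + binidx
            out[mask] = theta[slot[mask]]
        return out

    def quench_fractions(self, theta: np.ndarray, d: np.ndarray, qcls: np.ndarray,
                         literal_linear: bool = False) -> np.ndarray:
        """Quench fraction in [0, 1] for each Snail->activator pair.

        ``qcls``: QCLS_SD / QCLS_ST / QCLS_NONE.  Non-quenching pairs get 0.
        """
        d = np.asarray(d, dtype=float)
        if np.any(d < 0):
            raise ValueError("negative repressor-activator distance")
        qcls = np.asarray(qcls)
        out = np.zeros_like(d, dtype=float)
        mask = qcls != QCLS_NONE
        if not mask.any():
            return out
        q = self.quench
        q0 = 3 + self.coop.n_params
        if q.form == "fixed_msb":
            curve = _MSB_CURVE
            table = np.asarray(list(curve["values"]) + [curve["beyond"]], dtype=float)
            idx = np.minimum((d // curve["bin_width"]).astype(int), len(table) - 1)
            out[mask] = table[idx][mask]
        elif q.form in ("linear", "logistic", "gaussian"):
            b = theta[q0 + np.where(qcls == QCLS_ST, 1, 0)]
            if q.form == "linear":
                if literal_linear:
                    # the printed increasing form f(d) = a + b*d with a = 1
                    vals = np.clip(1.0 + b * d, 0.0, 1.0)
                else:
                    vals = np.maximum(0.0, 1.0 - b * d)
            elif q.form == "logistic":
                vals = 2.0 / (1.0 + np.exp(d / b))
            else:
                vals = np.exp(-(d ** 2) / b)
            out[mask] = vals[mask]
        else:
            edges = np.asarray(q.bin_edges)
            binidx = np.searchsorted(edges, d, side="left")
            grp = np.where(qcls == QCLS_ST, 1, 0)
            slot = q0 + grp * q.n_bins + binidx
            out[mask] = np.clip(theta[slot[mask]], 0.0, 1.0)
        return np.clip(out, 0.0, 1.0)

    # ------------------------------------------------------------------
    def to_json(self) -> dict:
        return {
            "id": self.id,
            "coop": self.coop.id,
            "quench": self.quench.id,
            "slots": list(self.slot_names),
            "n_params": self.n_params,
        }


_MSB_CURVE = _load_msb_curve()


@dataclass
class ParameterVector:
    """Values aligned to a ModelSpec layout, with per-slot bounds."""

    spec: ModelSpec
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_params,):
            raise ValueError(
                f"expected {self.spec.n_params} parameters for {self.spec.id}, "
                f"got {self.values.shape}"
            )

    def validate(self) -> None:
        for v, (lo, hi), name in zip(self.values, self.spec.bounds, self.spec.slot_names):
            if not (lo <= v <= hi) or not math.isfinite(v):
                raise ValueError(f"parameter {name}={v} outside bounds [{lo}, {hi}]")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.spec.slot(name)])

    def replace(self, **updates: float) -> "ParameterVector":
        vals = self.values.copy()
        for name, v in updates.items():
            vals[self.spec.slot(name)] = v
        return ParameterVector(self.spec, vals)

    def to_json(self) -> dict:
        return {
            "model": self.spec.id,
            "values": dict(zip(self.spec.slot_names, map(float, self.values))),
        }

    @classmethod
    def from_json(cls, payload: dict) -> "ParameterVector":
        spec = get_model(payload["model"])
        vals = [payload["values"][n] for n in spec.slot_names]
        return cls(spec, np.asarray(vals))


def parameter_layout(cid: str, qid: str) -> ModelSpec:
    """Build the ModelSpec for one cooperativity/quenching combination."""
    return ModelSpec(coop_scheme(cid), quench_scheme(qid))


def get_model(model_id: str) -> ModelSpec:
    """Look up a ModelSpec by its combined id, e.g. ``"C14Q5"``."""
    if "Q" not in model_id or not model_id.startswith("C"):
        raise KeyError(f"unknown model id {model_id!r}")
    cid, qid = model_id.split("Q")
    return parameter_layout(cid, f"Q{qid}")


def list_models() -> list[ModelSpec]:
    """All 120 formulations: the Cartesian product C1-C15 x Q1-Q8."""
    return [parameter_layout(c, q) for c in COOP_IDS for q in QUENCH_IDS]


def cooperativity_factor(spec: ModelSpec, theta, tfA: str, tfB: str, d: float) -> float:
    """Scalar cooperativity factor for one adjacently bound pair."""
    theta = np.asarray(theta, dtype=float)
    cls = pair_class(tfA, tfB)
    return float(spec.coop_factors(theta, np.array([float(d)]), np.array([cls]))[0])


def quench_fraction(spec: ModelSpec, theta, repressed_tf: str, d: float) -> float:
    """Scalar quench fraction for Snail repressing ``repressed_tf`` at distance d."""
    theta = np.asarray(theta, dtype=float)
    if repressed_tf in ("Dorsal",):
        qcls = QCLS_SD
    elif repressed_tf in ("Twist", "bHLH"):
        qcls = QCLS_ST
    else:
        raise ValueError(f"{repressed_tf!r} is not a repressed activator class")
    return float(spec.quench_fractions(theta, np.array([float(d)]), np.array([qcls]))[0])


_ACTIVATORS = {"Dorsal", "Twist", "bHLH"}


def pair_class(tfA: str, tfB: str) -> int:
    """Cooperativity interaction class of a pair of TFs.

    bHLH E-box sites are treated as Twist-class activators.  Activator and
    repressor adjacency carries no cooperativity class (code CLS_NONE).
    """
    a, b = sorted((tfA, tfB))
    a = "Twist" if a == "bHLH" else a
    b = "Twist" if b == "bHLH" else b
    if a == "Dorsal" and b == "Dorsal":
        return CLS_DD
    if a == "Twist" and b == "Twist":
        return CLS_TT
    if a == "Dorsal" and b == "Twist":
        return CLS_DT
    if a == "Snail" and b == "Snail":
        return CLS_SS
    return CLS_NONE


def quench_class(tfA: str, tfB: str) -> int:
    """Quench-pair class: which activator a Snail site would repress."""
    pair = {tfA, tfB}
    if "Snail" not in pair:
        return QCLS_NONE
    other = (pair - {"Snail"}) or {"Snail"}
    tf = next(iter(other))
    if tf == "Dorsal":
        return QCLS_SD
    if tf in ("Twist", "bHLH"):
        return QCLS_ST
    return QCLS_NONE
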