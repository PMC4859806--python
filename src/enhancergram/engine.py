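"""Thermodynamic-equilibrium expression prediction along the DV axis.

The enhancer is treated as a statistical-mechanical ensemble over binding
configurations: every subset of sites with no overlapping pair is a state.
A configuration's Boltzmann weight is the product of single-site occupancy
terms (TF scaling factor x normalized site affinity x TF concentration)
and cooperativity factors between adjacently bound sites (adjacent = no
other bound site between them).  Expression at a DV position equals the
ensemble probability of an "active" configuration: at least one bound
activator escaping quenching by its adjacently bound Snail repressors.

The quenching algebra used throughout: an activator bound next to
repressors r (at center-to-center distance d_r) survives with probability
``p_i = prod_r (1 - f(d_r))``; a configuration is inactive with probability
``prod_i (1 - p_i)`` over its bound activators, so
``P_active = 1 - prod_i (1 - p_i)`` (independent-quenching products,
at-least-one-active survivor).  Configurations without bound activators are
never active.

Two evaluation paths are provided: explicit enumeration over all valid
configurations (`predict_expression`, capped at 22 sites) and an O(m^2)
left-to-right transfer recursion over the most recently bound site
(`predict_expression_fast`) that is exact for any site count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterator

import numpy as np
import pandas as pd

from . import schemes
from .motifs import SiteMap
from .schemes import ModelSpec, ParameterVector

__all__ = [
    "N_POINTS",
    "TFGradient",
    "GradientSet",
    "Profile",
    "Configuration",
    "valid_configurations",
    "configuration_weight",
    "predict_expression",
    "predict_expression_fast",
    "CompiledMap",
    "load_gradients",
]

N_POINTS = 17  # DV positions: 0-40% egg height, one point per 2.5%
ENUMERATION_CAP = 22

_ACTIVATORS = {"Dorsal", "Twist", "bHLH"}
# bHLH E-box sites are modeled as Twist-class activators: they share the
# Twist scaling factor, concentration gradient and interaction classes.
_SCALING_TF = {"Dorsal": "Dorsal", "Twist": "Twist", "bHLH": "Twist", "Snail": "Snail"}


@dataclass(frozen=True)
class TFGradient:
    """Relative nuclear concentration of one TF at the 17 DV points."""

    tf: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_POINTS,):
            raise ValueError(f"gradient for {self.tf} must have {N_POINTS} points")
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"gradient for {self.tf} must lie in [0, 1]")
        object.__setattr__(self, "values", v)


class GradientSet:
    """The per-TF concentration gradients needed by the engine."""

    def __init__(self, gradients: dict[str, TFGradient]):
        self._g = dict(gradients)

    def conc(self, tf: str) -> np.ndarray:
        key = _SCALING_TF.get(tf, tf)
        if key not in self._g:
            raise KeyError(f"no concentration gradient for TF {tf!r}")
        return self._g[key].values

    def __contains__(self, tf: str) -> bool:
        return _SCALING_TF.get(tf, tf) in self._g

    def tfs(self) -> list[str]:
        return list(self._g)


def load_gradients(path=None) -> GradientSet:
    """Load the packaged 17-point Dorsal/Twist/Snail gradient fixture,
    or a TSV with columns point/<TF names>."""
    if path is None:
        src = resources.files("enhancergram.data").joinpath("gradients.tsv")
        with src.open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    grads = {
        col: TFGradient(col, df[col].to_numpy(float))
        for col in df.columns
        if col != "point"
    }
    return GradientSet(grads)


@dataclass
class Profile:
    """A 17-point expression profile (normalized units, wild-type peak ~1)."""

    values: np.ndarray
    stderr: np.ndarray | None = None
    construct_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_POINTS,):
            raise ValueError(f"profile must have {N_POINTS} points")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
            if self.stderr.shape != (N_POINTS,) or np.any(self.stderr < 0):
                raise ValueError("stderr must be 17 nonnegative values")

    def __len__(self) -> int:
        return N_POINTS


@dataclass(frozen=True)
class Configuration:
    """One binding state: the set of bound site indices."""

    bound: frozenset[int]

    def __len__(self) -> int:
        return len(self.bound)


def _center_distance(a, b) -> int:
    # center-to-center distance, rounded half-up to integer bp
    return int(math.floor(abs(a.center - b.center) + 0.5))


class CompiledMap:
    """Per-(SiteMap, ModelSpec) precomputation for repeated evaluation.

    Sites are ordered by (start, end); along that order non-overlap is
    transitive, so the transfer recursion only needs to forbid transitions
    between directly overlapping pairs.
    """

    def __init__(self, sitemap: SiteMap, spec: ModelSpec, gradients: GradientSet,
                 literal_linear_quench: bool = False):
        self.sitemap = sitemap
        self.spec = spec
        self.literal_linear_quench = literal_linear_quench
        sites = sitemap.sites
        m = len(sites)
        self.m = m
        self.is_act = np.array([s.tf in _ACTIVATORS for s in sites], dtype=bool)
        self.affinity = np.array([s.affinity for s in sites], dtype=float)
        self.scale_slot = np.array(
            [spec.slot(f"scale_{_SCALING_TF[s.tf]}") for s in sites], dtype=int
        )
        # concentration of the binding TF at each DV point: (m, 17)
        self.conc = (
            np.vstack([gradients.conc(s.tf) for s in sites])
            if m else np.zeros((0, N_POINTS))
        )
        self.dmat = np.zeros((m, m), dtype=int)
        self.cls = np.full((m, m), schemes.CLS_NONE, dtype=int)
        self.qcls = np.full((m, m), schemes.QCLS_NONE, dtype=int)
        self.compatible = np.ones((m, m), dtype=bool)
        overlaps = sitemap.overlap_pairs
        for i in range(m):
            for j in range(m):
                if i == j:
                    self.compatible[i, j] = False
                    continue
                self.dmat[i, j] = _center_distance(sites[i], sites[j])
                self.cls[i, j] = schemes.pair_class(sites[i].tf, sites[j].tf)
                if self.is_act[i] != self.is_act[j]:
                    self.qcls[i, j] = schemes.quench_class(sites[i].tf, sites[j].tf)
                if (i, j) in overlaps:
                    self.compatible[i, j] = False

    # ------------------------------------------------------------------
    def site_weights(self, theta: np.ndarray) -> np.ndarray:
        """Per-site statistical weight at each DV point: (m, 17)."""
        if np.any(theta < 0):
            raise ValueError("parameters must be nonnegative")
        return (theta[self.scale_slot] * self.affinity)[:, None] * self.conc

    def pair_factors(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(omega, f): cooperativity factors and quench fractions, (m, m)."""
        omega = self.spec.coop_factors(theta, self.dmat, self.cls)
        f = self.spec.quench_fractions(theta, self.dmat, self.qcls,
                                       literal_linear=self.literal_linear_quench)
        return omega, f

    # ------------------------------------------------------------------
    def predict_fast(self, theta: np.ndarray) -> np.ndarray:
        """Expression at the 17 DV points via the transfer recursion."""
        m = self.m
        if m == 0:
            return np.zeros(N_POINTS)
        w = self.site_weights(theta)
        omega, f = self.pair_factors(theta)
        act = self.is_act
        # Z[k]: sum of W over chains whose last bound site is k.
        # U[k], V[k]: same sums times the partially assembled inactive
        # product; a chain ending in activator k contributes U[k] + V[k]*b
        # once k's right-hand quench fraction b is known (0 at chain end).
        Z = np.zeros((m, N_POINTS))
        U = np.zeros((m, N_POINTS))
        V = np.zeros((m, N_POINTS))
        for k in range(m):
            if k > 0:
                t = omega[:k, k] * self.compatible[:k, k]
                zin = t @ Z[:k]
                # complete predecessors' pending inactive factors: the right
                # quench fraction b of activator j becomes known once the
                # next bound site k is fixed (nonzero only if k is a repressor)
                b = np.where(act[:k] & (not act[k]), f[:k, k], 0.0)
                C = U[:k] + b[:, None] * V[:k]
            else:
                t = np.zeros(0)
                zin = np.zeros(N_POINTS)
                C = np.zeros((0, N_POINTS))
            Z[k] = w[k] * (1.0 + zin)
            if act[k]:
                # left quench fraction a of k, from a repressor predecessor;
                # the empty prefix has no left neighbor (a = 0)
                a = np.where(~act[:k], f[:k, k], 0.0)
                U[k] = w[k] * ((t * a) @ C)
                V[k] = w[k] * (((t * (1.0 - a)) @ C) + 1.0)
            else:
                U[k] = w[k] * ((t @ C) + 1.0)
                V[k] = 0.0
        sum_w = 1.0 + Z.sum(axis=0)
        sum_wq = 1.0 + U.sum(axis=0)
        e = 1.0 - sum_wq / sum_w
        return np.clip(e, 0.0, 1.0)


def valid_configurations(sitemap: SiteMap, cap: int = ENUMERATION_CAP) -> Iterator[Configuration]:
    """All subsets of sites with no overlapping pair, including the empty set."""
    m = len(sitemap)
    if m > cap:
        raise ValueError(
            f"site map has {m} sites, above the enumeration cap {cap}; use "
            f"predict_expression_fast or raise the cap"
        )
    conflict = np.zeros(m, dtype=np.int64)
    for (i, j) in sitemap.overlap_pairs:
        conflict[i] |= 1 << j

    def rec(idx: int, mask: int):
        if idx == m:
            yield Configuration(frozenset(i for i in range(m) if mask >> i & 1))
            return
        yield from rec(idx + 1, mask)  # idx unbound
        if not (conflict[idx] & mask):
            yield from rec(idx + 1, mask | (1 << idx))

    yield from rec(0, 0)


def _config_weight_and_active(cm: CompiledMap, bound: list[int], w: np.ndarray,
                              omega: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(W, P_active) across the 17 DV points for one configuration."""
    if not bound:
        return np.ones(N_POINTS), np.zeros(N_POINTS)
    W = np.ones(N_POINTS)
    for i in bound:
        W = W * w[i]
    for a, b in zip(bound[:-1], bound[1:]):
        W = W * omega[a, b]
    inactive = np.ones(N_POINTS)
    for pos, i in enumerate(bound):
        if not cm.is_act[i]:
            continue
        survive = np.ones(N_POINTS)
        for nb in (bound[pos - 1] if pos > 0 else None,
                   bound[pos + 1] if pos + 1 < len(bound) else None):
            if nb is not None and not cm.is_act[nb]:
                survive = survive * (1.0 - f[i, nb])
        inactive = inactive * (1.0 - survive)
    return W, 1.0 - inactive


def configuration_weight(config: Configuration, theta, conc: dict[str, float],
                         sitemap: SiteMap, spec: ModelSpec) -> float:
    """Boltzmann weight of one configuration at a single DV point.

    ``conc`` maps TF name -> concentration at that point.  W(empty) = 1.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("parameters must be nonnegative")
    sites = sitemap.sites
    bound = sorted(config.bound)
    w = 1.0
    for i in bound:
        s = sites[i]
        scale = theta[spec.slot(f"scale_{_SCALING_TF[s.tf]}")]
        w *= scale * s.affinity * conc[_SCALING_TF[s.tf]]
    for i, j in zip(bound[:-1], bound[1:]):
        d = _center_distance(sites[i], sites[j])
        cls = schemes.pair_class(sites[i].tf, sites[j].tf)
        w *= spec.coop_factors(theta, np.array([float(d)]), np.array([cls]))[0]
    return float(w)


def _as_theta(theta, spec: ModelSpec) -> np.ndarray:
    if isinstance(theta, ParameterVector):
        if theta.spec.id != spec.id:
            raise ValueError("parameter vector does not match the model spec")
        return theta.values
    return np.asarray(theta, dtype=float)


def predict_expression(sitemap: SiteMap, theta, gradients: GradientSet,
                       spec: ModelSpec, cap: int = ENUMERATION_CAP,
                       literal_linear_quench: bool = False) -> Profile:
    """Expression profile by explicit enumeration over all configurations."""
    theta = _as_theta(theta, spec)
    for s in sitemap.sites:
        if s.tf not in gradients:
            raise KeyError(f"missing concentration gradient for TF {s.tf!r}")
    if len(sitemap) == 0:
        return Profile(np.zeros(N_POINTS), construct_id=sitemap.sequence_id)
    cm = CompiledMap(sitemap, spec, gradients, literal_linear_quench)
    w = cm.site_weights(theta)
    omega, f = cm.pair_factors(theta)
    num = np.zeros(N_POINTS)
    den = np.zeros(N_POINTS)
    for config in valid_configurations(sitemap, cap=cap):
        bound = sorted(config.bound)
        W, pact = _config_weight_and_active(cm, bound, w, omega, f)
        num += W * pact
        den += W
    return Profile(np.clip(num / den, 0.0, 1.0), construct_id=sitemap.sequence_id)


def predict_expression_fast(sitemap: SiteMap, theta, gradients: GradientSet,
                            spec: ModelSpec,
                            literal_linear_quench: bool = False) -> Profile:
    """Expression profile via the transfer recursion (any site count)."""
    theta = _as_theta(theta, spec)
    for s in sitemap.sites:
        if s.tf not in gradients:
            raise KeyError(f"missing concentration gradient for TF {s.tf!r}")
    cm = CompiledMap(sitemap, spec, gradients, literal_linear_quench)
    return Profile(cm.predict_fast(theta), construct_id=sitemap.sequence_id)
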