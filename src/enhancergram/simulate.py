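"""Synthetic inputs with the statistical structure the analysis assumes.

This module generates everything the pipeline consumes: the 38-construct
site-knockout perturbation design, the packaged TF concentration gradients,
noisy multi-embryo expression profiles drawn from a known ground-truth
model, the raw-pixel-profile preprocessing path (quadratic background
subtraction, wild-type peak normalization, 6-pixel block averaging), and
random genomes with planted enhancer elements for scan-back experiments.

The default wild-type site layout places the experimentally characterized
site sequences (4 Dorsal, 2 Twist, 4 Snail, 2 E-box) on a 318-bp enhancer
with the known Snail4/Twist2 overlap.  The positions themselves are a
documented, clearly-labelled stand-in: real coordinates can be supplied via
configuration.  Knockout constructs delete sites from the site map; the
sequence-level mutation path (`motifs.mutate_sites`) is available when a
real enhancer sequence is configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import GradientSet, N_POINTS, Profile, TFGradient, load_gradients, predict_expression_fast
from .motifs import BindingSite, SiteMap
from .schemes import ModelSpec, ParameterVector

__all__ = [
    "ConstructSpec",
    "PerturbationDataset",
    "gradient_fixtures",
    "construct_registry",
    "build_wildtype_sitemap",
    "wildtype_sequence",
    "simulate_dataset",
    "demo_truth",
    "simulate_raw_profile",
    "preprocess_raw",
    "discretize_profile",
    "plant_enhancers",
    "DEFAULT_SITE_LAYOUT",
    "CLASS_LISTS",
]

# systematic cross-validation classes: the printed construct id lists
CLASS_LISTS = {
    "dorsal": (2, 3, 6, 7, 8, 11, 12, 15, 16),
    "twist": (4, 5, 17),
    "dorsal_twist": (9, 10, 13, 14, 18, 19, 20, 21),
    "snail": tuple(range(23, 34)),
    "bhlh": tuple(range(34, 39)),
}

# (name, tf, start, wild-type sequence, relative affinity)
# Positions are a synthetic stand-in layout over the 318-bp enhancer; the
# Snail4 site overlaps Twist2 (shared CACATGTT core).
DEFAULT_SITE_LAYOUT = [
    ("Snail1", "Snail", 5, "CAACTTGCGG", 0.90),
    ("Dorsal1", "Dorsal", 22, "GGGAAAAACAC", 0.95),
    ("Twist1", "Twist", 48, "CGCATATGTT", 0.90),
    ("Snail2", "Snail", 70, "CACCTTGCTG", 0.85),
    ("Dorsal2", "Dorsal", 95, "CGGAATTTCCT", 0.85),
    ("bHLH1", "bHLH", 120, "CATTTG", 0.70),
    ("Snail3", "Snail", 140, "CCACTTGCGCT", 0.80),
    ("Dorsal3", "Dorsal", 165, "GGGAAATTCCC", 0.90),
    ("Dorsal4", "Dorsal", 195, "GGGAAAGGCCA", 0.75),
    ("Twist2", "Twist", 225, "AGCACATGTT", 0.85),
    ("Snail4", "Snail", 226, "GCACATGTTT", 0.90),
    ("bHLH2", "bHLH", 250, "CAAGTG", 0.70),
]

ENHANCER_LENGTH = 318

SITE_NAMES = tuple(name for name, *_ in DEFAULT_SITE_LAYOUT)

# inferred knockout compositions per construct (single, pairwise and
# multiple knockouts within each printed class; exact compositions beyond
# the class lists are not published)
_KNOCKOUTS: dict[int, tuple[str, ...]] = {
    1: (),
    2: ("Dorsal1",), 3: ("Dorsal2",), 6: ("Dorsal3",), 7: ("Dorsal4",),
    8: ("Dorsal1", "Dorsal2"), 11: ("Dorsal1", "Dorsal3"),
    12: ("Dorsal2", "Dorsal4"), 15: ("Dorsal3", "Dorsal4"),
    16: ("Dorsal1", "Dorsal2", "Dorsal3", "Dorsal4"),
    4: ("Twist1",), 5: ("Twist2",), 17: ("Twist1", "Twist2"),
    9: ("Dorsal1", "Twist1"), 10: ("Dorsal2", "Twist2"),
    13: ("Dorsal3", "Twist1"), 14: ("Dorsal4", "Twist2"),
    18: ("Dorsal1", "Dorsal2", "Twist1"), 19: ("Dorsal3", "Dorsal4", "Twist2"),
    20: ("Dorsal1", "Twist1", "Twist2"),
    21: ("Dorsal1", "Dorsal2", "Dorsal3", "Dorsal4", "Twist1", "Twist2"),
    22: (),
    23: ("Snail1",), 24: ("Snail2",), 25: ("Snail3",), 26: ("Snail4",),
    27: ("Snail1", "Snail2"), 28: ("Snail2", "Snail3"),
    29: ("Snail3", "Snail4"), 30: ("Snail1", "Snail3"),
    31: ("Snail2", "Snail4"), 32: ("Snail1", "Snail2", "Snail3"),
    33: ("Snail1", "Snail2", "Snail3", "Snail4"),
    34: ("bHLH1", "bHLH2"),
    35: ("bHLH1", "bHLH2", "Dorsal1"),
    36: ("bHLH1", "bHLH2", "Twist1"),
    37: ("bHLH1", "bHLH2", "Snail1"),
    38: ("bHLH1", "bHLH2", "Dorsal1", "Twist1"),
}


@dataclass(frozen=True)
class ConstructSpec:
    """One reporter construct: which sites are knocked out."""

    id: int
    label: str
    knocked_out: frozenset[str]
    cls: str  # wildtype_activators | dorsal | twist | dorsal_twist | snail | bhlh | other
    inferred: bool = True  # composition inferred from the class lists


def _class_of(cid: int) -> str:
    for cls, ids in CLASS_LISTS.items():
        if cid in ids:
            return cls
    return "other"


def construct_registry() -> list[ConstructSpec]:
    """The 38-construct perturbation design, classed per the CV lists."""
    out = []
    for cid in range(1, 39):
        ko = _KNOCKOUTS[cid]
        label = "wild type" if not ko else "+".join(n for n in ko) + " KO"
        out.append(ConstructSpec(cid, label, frozenset(ko), _class_of(cid),
                                 inferred=cid not in (1,)))
    return out


def gradient_fixtures() -> tuple[TFGradient, TFGradient, TFGradient]:
    """The printed 17-point Dorsal, Twist and Snail concentration arrays."""
    g = load_gradients()
    return tuple(TFGradient(tf, g.conc(tf)) for tf in ("Dorsal", "Twist", "Snail"))


def build_wildtype_sitemap(layout=None, length: int = ENHANCER_LENGTH) -> SiteMap:
    """Wild-type SiteMap from a (name, tf, start, sequence, affinity) layout."""
    layout = layout or DEFAULT_SITE_LAYOUT
    sites = []
    seen: dict[tuple[str, int], str] = {}
    for name, tf, start, seq, affinity in layout:
        key = (tf, start)
        if key in seen:
            raise ValueError(f"duplicate {tf} site at position {start}")
        seen[key] = name
        sites.append(BindingSite(tf, start, start + len(seq), "+",
                                 score=0.0, affinity=affinity, name=name))
    return SiteMap("rho_wt", length, sites)


def wildtype_sequence(layout=None, length: int = ENHANCER_LENGTH,
                      seed: int = 318) -> str:
    """A synthetic 318-bp enhancer embedding the wild-type site sequences."""
    layout = layout or DEFAULT_SITE_LAYOUT
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=length))
    for _, _, start, sub, _ in layout:
        seq[start: start + len(sub)] = list(sub)
    return "".join(seq)


@dataclass
class PerturbationDataset:
    """Constructs with site maps and measured (or simulated) profiles."""

    constructs: list[tuple[ConstructSpec, SiteMap, Profile]]
    n_embryos: int
    provenance: dict = field(default_factory=dict)

    def entries(self) -> list[tuple[str, SiteMap, Profile]]:
        return [(str(spec.id), sm, prof) for spec, sm, prof in self.constructs]

    def ids(self) -> list[int]:
        return [spec.id for spec, _, _ in self.constructs]

    def subset(self, ids) -> "PerturbationDataset":
        ids = {int(i) for i in ids}
        kept = [c for c in self.constructs if c[0].id in ids]
        return PerturbationDataset(kept, self.n_embryos, self.provenance)

    def profile(self, cid: int) -> Profile:
        for spec, _, prof in self.constructs:
            if spec.id == cid:
                return prof
        raise KeyError(cid)


def simulate_dataset(truth: ParameterVector, registry=None,
                     noise_sd: float = 0.02, n_embryos: int = 10,
                     seed: int = 0, gradients: GradientSet | None = None,
                     wildtype: SiteMap | None = None) -> PerturbationDataset:
    """Simulate the perturbation dataset from a ground-truth model.

    For each construct the knocked-out sites are deleted from the wild-type
    site map, the 17-point profile is predicted under ``truth``, and
    ``n_embryos`` noisy replicates (additive Gaussian, truncated at 0) are
    averaged; the standard error of the embryo mean is recorded.
    """
    if noise_sd < 0 or n_embryos < 1:
        raise ValueError("noise_sd must be >= 0 and n_embryos >= 1")
    registry = registry or construct_registry()
    gradients = gradients or load_gradients()
    wildtype = wildtype or build_wildtype_sitemap()
    rng = np.random.default_rng(seed)
    rows = []
    for cspec in registry:
        sm = wildtype.without(cspec.knocked_out)
        sm = SiteMap(f"construct_{cspec.id}", sm.length, sm.sites)
        truth_prof = predict_expression_fast(sm, truth, gradients, truth.spec)
        embryos = np.maximum(
            0.0,
            truth_prof.values + rng.normal(0.0, noise_sd, size=(n_embryos, N_POINTS))
            if noise_sd > 0 else np.tile(truth_prof.values, (n_embryos, 1)),
        )
        mean = embryos.mean(axis=0)
        if n_embryos > 1:
            stderr = embryos.std(axis=0, ddof=1) / np.sqrt(n_embryos)
        else:
            stderr = np.zeros(N_POINTS)
        rows.append((cspec, sm, Profile(mean, stderr, construct_id=str(cspec.id))))
    return PerturbationDataset(
        rows, n_embryos,
        provenance={
            "truth_model": truth.spec.id,
            "theta": truth.to_json()["values"],
            "noise_sd": noise_sd,
            "n_embryos": n_embryos,
            "seed": seed,
        },
    )


def demo_truth(spec: ModelSpec) -> ParameterVector:
    """A plausible ground-truth parameter point for any model formulation.

    Used as the default generating model for synthetic datasets: strong
    activator binding with modest distance-limited cooperativity, strong
    Snail binding, and quenching that decays over roughly 100 bp.  Under
    these values the wild-type construct produces a lateral
    (neuroectodermal) stripe: ventral repression by Snail, a peak where the
    Snail gradient collapses, and decay dorsally with the activators.
    """
    vals = []
    for name, kind in zip(spec.slot_names, spec.slot_kinds):
        if name in ("scale_Dorsal", "scale_Twist"):
            vals.append(0.75)
        elif name == "scale_Snail":
            vals.append(40.0)
        elif name.startswith("coop") and name.endswith("_a"):
            vals.append(8.0)
        elif name.startswith("coop") and name.endswith("_b"):
            # decay scale for the continuous forms; slope for the linear one
            form = spec.coop.form
            vals.append({"linear": 1e-4, "logistic": 70.0, "gaussian": 5000.0}[form])
        elif name.startswith("coop"):  # binned factor: strong at short range,
            b = int(name.rsplit("bin", 1)[1])  # distance-independent beyond
            vals.append({1: 8.0}.get(b, 3.0))
        elif name.endswith("_b"):  # quenching shape parameter
            form = spec.quench.form
            vals.append({"linear": 0.004, "logistic": 100.0, "gaussian": 20000.0}[form])
        else:  # quench-fraction bin: near-complete at short range, decaying
            b = int(name.rsplit("bin", 1)[1])  # towards the ~100 bp horizon
            nb = spec.quench.n_bins
            frac = (b - 0.5) / nb
            vals.append(float(np.clip(1.0 - 0.015 * np.exp(1.2 * frac), 0.02, 0.98)))
    return ParameterVector(spec, np.asarray(vals))


# ----------------------------------------------------------------------
# raw-profile simulation and preprocessing
# ----------------------------------------------------------------------

SIGNAL_PIXELS = 102  # 0-40% of the DV axis
FLANK_PIXELS = 102  # signal-free dorsal-ectoderm flank used for background fit
PIXELS_PER_POINT = 6


def discretize_profile(pixels: np.ndarray) -> np.ndarray:
    """17 points by averaging every 6 pixels of a 102-pixel profile."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.shape != (SIGNAL_PIXELS,):
        raise ValueError(f"expected {SIGNAL_PIXELS} pixels, got {pixels.shape}")
    return pixels.reshape(N_POINTS, PIXELS_PER_POINT).mean(axis=1)


def simulate_raw_profile(profile17, parabola=(0.0, 0.0, 0.0),
                         session_scale: float = 1.0, noise_sd: float = 0.0,
                         seed: int = 0) -> np.ndarray:
    """Forward-simulate a raw fluorescence trace from a 17-point profile.

    The signal region (102 px) is the profile upsampled 6x; a signal-free
    dorsal-ectoderm flank of equal width follows (keeping the background fit
    an interpolation-scale problem rather than a long extrapolation).  A quadratic background (coefficients
    ``parabola`` = (c0, c1, c2) over the pixel coordinate) and a session
    intensity scale emulate imaging conditions.
    """
    vals = np.asarray(profile17, dtype=float)
    if vals.shape != (N_POINTS,):
        raise ValueError(f"expected a {N_POINTS}-point profile")
    rng = np.random.default_rng(seed)
    signal = np.concatenate([np.repeat(vals, PIXELS_PER_POINT),
                             np.zeros(FLANK_PIXELS)])
    x = np.arange(SIGNAL_PIXELS + FLANK_PIXELS, dtype=float)
    c0, c1, c2 = parabola
    background = c0 + c1 * x + c2 * x ** 2
    raw = session_scale * signal + background
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, size=raw.shape)
    return raw


def preprocess_raw(raw: np.ndarray, wildtype_raw: np.ndarray | None = None
                   ) -> tuple[Profile, int]:
    """Background-subtract, normalize and discretize one raw trace.

    A quadratic is fitted to the signal-free dorsal flank and subtracted
    everywhere; negative residuals are clipped at zero (count returned).
    If a same-session wild-type trace is given, intensities are divided by
    its peak (mean of corrected values above the 95th percentile); without
    a reference the trace is assumed to be on the unit intensity scale.
    """
    raw = np.asarray(raw, dtype=float)
    total = SIGNAL_PIXELS + FLANK_PIXELS
    if raw.shape != (total,):
        raise ValueError(f"expected {total} pixels")
    corrected = _subtract_background(raw)
    n_clipped = int(np.sum(corrected < 0))
    corrected = np.maximum(corrected, 0.0)
    if wildtype_raw is not None:
        wt = np.maximum(_subtract_background(np.asarray(wildtype_raw, float)), 0.0)
        sig = wt[:SIGNAL_PIXELS]
        peak = sig[sig >= np.percentile(sig, 95)].mean()
        if peak > 0:
            corrected = corrected / peak
    return Profile(discretize_profile(corrected[:SIGNAL_PIXELS])), n_clipped


def _subtract_background(raw: np.ndarray) -> np.ndarray:
    x = np.arange(len(raw), dtype=float)
    flank = slice(SIGNAL_PIXELS, None)
    coef = np.polynomial.polynomial.polyfit(x[flank], raw[flank], 2)
    return raw - np.polynomial.polynomial.polyval(x, coef)


# ----------------------------------------------------------------------
# planted genomes
# ----------------------------------------------------------------------

def plant_enhancers(genome_length: int, elements: list[tuple[str, str]],
                    seed: int = 0, positions: list[int] | None = None
                    ) -> tuple[str, list[dict]]:
    """Random background genome with enhancer sequences written in.

    ``elements`` is a list of (sequence, expected_pattern).  Positions are
    drawn evenly spaced with seeded jitter unless given, then nudged so each
    element lies wholly inside at least one window of the default 500/250
    genome tiling (an element straddling every window boundary would have no
    fully containing analysis window).  Returns the genome string and truth
    records usable as BED rows.
    """
    rng = np.random.default_rng(seed)
    genome = rng.choice(list("ACGT"), size=genome_length)
    if positions is None:
        if not elements:
            return "".join(genome), []
        slot = genome_length // (len(elements) + 1)
        positions = []
        for i, (seq, _) in enumerate(elements, start=1):
            jitter = int(rng.integers(-slot // 4, slot // 4 + 1))
            pos = max(0, min(genome_length - len(seq), i * slot + jitter))
            frame_room = 500 - len(seq)
            if frame_room > 0 and pos % 250 > frame_room:
                pos -= pos % 250 - frame_room
            positions.append(max(0, pos))
    occupied: list[tuple[int, int]] = []
    truth = []
    for (seq, pattern), start in zip(elements, positions):
        end = start + len(seq)
        if end > genome_length or any(s < end and start < e for s, e in occupied):
            raise ValueError(f"no room to place element at {start}-{end}")
        occupied.append((start, end))
        genome[start:end] = list(seq)
        truth.append({"start": int(start), "end": int(end), "pattern": pattern})
    return "".join(genome), truth
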