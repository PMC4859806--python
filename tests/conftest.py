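import numpy as np
import pytest

from enhancergram.engine import load_gradients
from enhancergram.motifs import BindingSite, SiteMap
from enhancergram.schemes import get_model, list_models
from enhancergram.simulate import build_wildtype_sitemap, demo_truth


@pytest.fixture(scope="session")
def gradients():
    return load_gradients()


@pytest.fixture(scope="session")
def wildtype_map():
    return build_wildtype_sitemap()


@pytest.fixture(scope="session")
def all_models():
    return list_models()


@pytest.fixture
def c5q5():
    return get_model("C5Q5")


@pytest.fixture
def truth_c5q5(c5q5):
    return demo_truth(c5q5)


TFS = ["Dorsal", "Twist", "Snail", "bHLH"]


def random_sitemap(rng, n_sites, length=318, allow_overlap=True):
    """Random annotated site map; sites may overlap unless disabled."""
    sites = []
    if allow_overlap:
        starts = sorted(int(s) for s in rng.integers(0, length - 12, size=n_sites))
        for i, start in enumerate(starts):
            L = int(rng.integers(6, 12))
            sites.append(BindingSite(TFS[rng.integers(0, 4)], start, start + L, "+",
                                     5.0, float(rng.uniform(0.3, 1.0)), name=f"s{i}"))
    else:
        cur = 0
        for i in range(n_sites):
            start = cur + int(rng.integers(2, 20))
            L = int(rng.integers(6, 12))
            cur = start + L
            sites.append(BindingSite(TFS[rng.integers(0, 4)], start, start + L, "+",
                                     5.0, float(rng.uniform(0.3, 1.0)), name=f"s{i}"))
        length = max(length, cur + 5)
    return SiteMap("random", length, sites)


def random_theta(rng, spec, coop_low=0.0, coop_high=5.0, monotone_quench=False):
    """Random in-bounds parameter vector for a model spec."""
    th = np.empty(spec.n_params)
    for i, kind in enumerate(spec.slot_kinds):
        if kind == "scaling":
            th[i] = rng.uniform(0.1, 20.0)
        elif kind == "coop":
            th[i] = rng.uniform(coop_low, coop_high)
        elif kind == "shape_b":
            th[i] = rng.uniform(1.0, 200.0)
        else:
            th[i] = rng.uniform(0.0, 1.0)
    if monotone_quench:
        for grp in ("SD", "ST"):
            idx = [i for i, n in enumerate(spec.slot_names)
                   if n.startswith(f"quench_{grp}_bin")]
            if idx:
                th[idx] = sorted(th[idx], reverse=True)
    return th
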