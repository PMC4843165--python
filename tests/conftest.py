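import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def template_484():
    from sharkvis.pigments import VisualPigmentTemplate, template_absorbance

    return template_absorbance(VisualPigmentTemplate(484.0, "A1"))


@pytest.fixture(scope="session")
def blue_water():
    from sharkvis.light import water_type

    return water_type("blue")


@pytest.fixture(scope="session")
def blue_green_water():
    from sharkvis.light import water_type

    return water_type("blue-green")


@pytest.fixture(scope="session")
def patch_pair():
    from sharkvis.synth import gen_patch_pair

    return gen_patch_pair("C_ventriosum")


def random_binary_tree(rng: np.random.Generator, n_tips: int):
    """A random rooted binary tree over tips t1..tn, as a newick string."""
    nodes = [f"t{i}" for i in range(1, n_tips + 1)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"
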