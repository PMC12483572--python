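import numpy as np
import pytest

from kinstruct import KinshipSystem, load_inventory

G1 = "G+1"
G0 = "G0"


@pytest.fixture(scope="session")
def default_inventory():
    return load_inventory("default")


@pytest.fixture(scope="session")
def experiment_inventory():
    return load_inventory("experiment16")


@pytest.fixture(scope="session")
def funcle_inventory():
    """Two-parent toy: father and father's brother, each with one child."""
    return load_inventory(
        {
            "name": "funcle",
            "kin_types": [
                {"code": "F", "generation": G1, "referent_gender": "male"},
                {"code": "FB", "generation": G1, "referent_gender": "male"},
                {"code": "B", "generation": G0, "referent_gender": "male"},
                {"code": "FBS", "generation": G0, "referent_gender": "male"},
            ],
            "links": [["F", "B"], ["FB", "FBS"]],
        }
    )


@pytest.fixture
def funcle_system():
    """Merged parent term with unmerged child terms: 1 bit of asymmetry."""
    return KinshipSystem(
        "funcle", {"F": "funcle", "FB": "funcle", "B": "brother", "FBS": "cousin"}
    )


@pytest.fixture(scope="session")
def quad_inventory():
    """Four independent parent-child chains plus no shared parents."""
    kin_types = []
    links = []
    for i in range(4):
        kin_types.append({"code": f"P{i}", "generation": G1})
        kin_types.append({"code": f"C{i}", "generation": G0})
        links.append([f"P{i}", f"C{i}"])
    return load_inventory({"name": "quad", "kin_types": kin_types, "links": links})


@pytest.fixture
def bijective_quad_system():
    """One-to-one term matching over the quad inventory: H_sym = 0."""
    assignment = {}
    for i in range(4):
        assignment[f"P{i}"] = f"parent_{i}"
        assignment[f"C{i}"] = f"child_{i}"
    return KinshipSystem("bijective", assignment)


def one_term_system(inventory, g1_form="pa", g0_form="kin"):
    """A single shared term in each generation over a full inventory."""
    assignment = {}
    for code in inventory.codes:
        assignment[code] = g1_form if inventory[code].generation == G1 else g0_form
    return KinshipSystem("one_term", assignment)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_small_system(rng, inventory, n_g1_forms=3, n_g0_forms=3, missing=0.0):
    """A random partial assignment over an inventory, for oracle comparisons."""
    assignment = {}
    for code in inventory.codes:
        if rng.random() < missing:
            continue
        if inventory[code].generation == G1:
            assignment[code] = f"p{rng.integers(n_g1_forms)}"
        else:
            assignment[code] = f"c{rng.integers(n_g0_forms)}"
    return KinshipSystem("random_small", assignment)
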