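import numpy as np
import pytest

from netkin.compiler import build_aggregation, compile_network
from netkin.estimator import Condition
from netkin.fixtures import (
    FixtureSpec,
    make_network,
    make_truth_and_data,
    _measured_layers,
)
from netkin.network import (
    Biomolecule,
    Effect,
    Interaction,
    InteractionNetwork,
    Mechanism,
    infer_active_modes,
)
from netkin.ode import build


def make_net(edge_specs, genes=None):
    """Shorthand network builder: edge_specs = [(src, tgt, mech, effect), ...]."""
    edges = [
        Interaction(source=s, target=t, mechanism=Mechanism(m),
                    effect=Effect(e) if e else None)
        for s, t, m, e in edge_specs
    ]
    if genes is None:
        genes = sorted({g for e in edges for g in (e.source, e.target)})
    return InteractionNetwork(nodes=[Biomolecule(g) for g in genes], edges=edges)


@pytest.fixture(scope="session")
def small_fixture():
    """4-gene noise-free fixture: network, truth K, dataset, system, ode."""
    spec = FixtureSpec(seed=1, cv={"protein": 0.0, "phospho": 0.0, "rna": 0.0})
    net = make_network(spec)
    K_true, ds, sys_, ode = make_truth_and_data(net, spec)
    return {"spec": spec, "net": net, "K_true": K_true, "dataset": ds,
            "system": sys_, "ode": ode}


@pytest.fixture(scope="session")
def small_agg(small_fixture):
    sys_ = small_fixture["system"]
    return build_aggregation(sys_, _measured_layers(sys_))


def random_reaction_system(rng, n_elements=None, n_reactions=None):
    """Random small reaction system exercising arities 0-2, reversibility
    and catalysts; used as input for oracle-equivalence checks."""
    from netkin.compiler import Element, Form, Reaction, ReactionSystem

    n = n_elements or rng.integers(3, 10)
    m = n_reactions or rng.integers(2, 15)
    elements = [Element(index=i, form=Form.PROTEIN, gene=f"E{i}") for i in range(n)]
    reactions = []
    names = []
    slot = 0
    for j in range(m):
        kind = rng.integers(0, 5)
        if kind == 0:       # synthesis
            reactants, products = (), (int(rng.integers(0, n)),)
        elif kind == 1:     # degradation
            reactants, products = (int(rng.integers(0, n)),), ()
        elif kind == 2:     # conversion / binding
            reactants = tuple(int(x) for x in rng.integers(0, n, rng.integers(1, 3)))
            products = tuple(int(x) for x in rng.integers(0, n, rng.integers(1, 3)))
        elif kind == 3:     # catalysis (enzyme on both sides)
            e, s, p = (int(x) for x in rng.integers(0, n, 3))
            reactants, products = (e, s), (e, p)
        else:               # reversible binding
            reactants = tuple(int(x) for x in rng.integers(0, n, 2))
            products = (int(rng.integers(0, n)),)
        reversible = kind == 4 or (kind == 2 and rng.random() < 0.5)
        kf = slot; slot += 1
        names.append(f"kF[{j}]")
        kb = None
        if reversible:
            kb = slot; slot += 1
            names.append(f"kB[{j}]")
        reactions.append(Reaction(reactants=reactants, products=products,
                                  kf_index=kf, kb_index=kb, origin=f"rand:{j}"))
    return ReactionSystem(elements=elements, reactions=reactions,
                          n_parameters=slot, parameter_names=names)
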