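"""Synthetic study generator: toy networks, ground-truth kinetics and noisy
triplicate multi-layer time courses.

Emulates the experimental design the pipeline targets — cells sampled at
0, 2, 6, 24 and 48 h in three biological replicates across protein,
phosphoprotein and RNA layers, under a control condition and drug-like
perturbations — without any download.  Trajectories come from simulating a
known ("true") parameter set on a generated network; replicates are drawn
lognormal around the model value with a configurable coefficient of
variation, which keeps concentrations positive.  The phospho layer is
emitted as relative intensities (a random per-biomolecule scale factor)
so the mean-normalized scoring branch is exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compiler import Form, ReactionSystem, build_aggregation, compile_network
from .estimator import Condition
from .network import (
    Biomolecule,
    Effect,
    Interaction,
    InteractionNetwork,
    Mechanism,
    infer_active_modes,
)
from .objective import ExperimentalDataset
from .ode import OdeSystem, SimulationError, build

#: sampling times (hours) mirroring the targeted experimental design
DEFAULT_TIMES = (0.0, 2.0, 6.0, 24.0, 48.0)

DEFAULT_MECHANISMS = {
    "phosphorylation": 2,
    "dephosphorylation": 1,
    "ubiquitination": 1,
    "binding": 1,
    "transcriptional_regulation": 1,
}

MEDIUM_MECHANISMS = {
    "phosphorylation": 4,
    "dephosphorylation": 2,
    "ubiquitination": 1,
    "binding": 2,
    "transcriptional_regulation": 2,
}


@dataclass
class FixtureSpec:
    n_genes: int = 4
    mechanisms: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MECHANISMS))
    k_low: float = 10.0 ** -1.5
    k_high: float = 10.0 ** 0.5
    cv: dict[str, float] = field(
        default_factory=lambda: {"protein": 0.1, "phospho": 0.1, "rna": 0.1})
    times: tuple[float, ...] = DEFAULT_TIMES
    n_replicates: int = 3
    conditions: list[Condition] = field(
        default_factory=lambda: [Condition("control")])
    seed: int = 0
    baseline_low: float = 5.0
    baseline_high: float = 50.0
    cell_volume_ul: float = 8.0
    phospho_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least two genes")
        if any(c <= 0 for c in self.mechanisms.values()):
            raise ValueError("mechanism counts must be positive")
        if list(self.times) != sorted(set(self.times)):
            raise ValueError("time grid must be strictly increasing")


def medium_spec(seed: int = 0, conditions: list[Condition] | None = None) -> FixtureSpec:
    """The ~10-gene / ~60-parameter configuration used for recovery studies."""
    return FixtureSpec(
        n_genes=10, mechanisms=dict(MEDIUM_MECHANISMS), seed=seed,
        conditions=conditions or [Condition("control")],
    )


def make_network(spec: FixtureSpec) -> InteractionNetwork:
    """Generate a connected toy network with the requested mechanism mix.

    Guarantees a shared-substrate motif (a kinase and a phosphatase acting
    on the same target, so the compiled system shares that target's
    phospho element) and at least one transcriptional edge when requested,
    so DNA/RNA bookkeeping is exercised.  Reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i}" for i in range(spec.n_genes)]
    n_edges = sum(spec.mechanisms.values())
    if n_edges > spec.n_genes * (spec.n_genes - 1):
        raise ValueError("more edges requested than ordered gene pairs")

    wanted: list[str] = []
    for mech, count in sorted(spec.mechanisms.items()):
        wanted.extend([mech] * count)
    rng.shuffle(wanted)
    # shared-substrate motif first: two modification edges on one target
    mods = [m for m in ("phosphorylation", "dephosphorylation")
            if m in spec.mechanisms]

    edges: list[Interaction] = []
    used: set[tuple] = set()

    def add(mech: str, src: str, tgt: str) -> bool:
        key = (mech, src, tgt) if mech != "binding" else (mech, frozenset((src, tgt)))
        if src == tgt or key in used:
            return False
        used.add(key)
        effect = Effect.ACTIVATION if rng.random() < 0.7 else Effect.INHIBITION
        edges.append(Interaction(source=src, target=tgt,
                                 mechanism=Mechanism(mech), effect=effect,
                                 evidence="synthetic"))
        return True

    remaining = list(wanted)
    if len(mods) >= 2 and spec.n_genes >= 3:
        tgt = genes[2]
        add(mods[0], genes[0], tgt)
        add(mods[1], genes[1], tgt)
        remaining.remove(mods[0])
        remaining.remove(mods[1])

    # backbone pass keeps the graph connected: edge i links gene i -> i+1
    cursor = 0
    for mech in remaining:
        placed = False
        for _ in range(200):
            if cursor < spec.n_genes - 1:
                src, tgt = genes[cursor], genes[cursor + 1]
                cursor += 1
            else:
                src, tgt = (str(g) for g in rng.choice(genes, size=2, replace=False))
            if add(mech, src, tgt):
                placed = True
                break
        if not placed:  # pragma: no cover - astronomically unlikely
            raise ValueError(f"could not place a {mech} edge")

    return InteractionNetwork(
        nodes=[Biomolecule(g) for g in genes], edges=edges,
        provenance={"generator": "netkin.fixtures", "seed": spec.seed},
    )


def _measured_layers(sys_: ReactionSystem) -> dict[str, list[str]]:
    """Every gene with a protein element is measured on the protein layer;
    phospho where a phospho element exists; RNA where an mRNA element exists."""
    layers = {"protein": [], "phospho": [], "rna": []}
    for el in sys_.elements:
        if el.form is Form.PROTEIN and el.gene not in layers["protein"]:
            layers["protein"].append(el.gene)
        elif el.form is Form.PHOSPHO and el.gene not in layers["phospho"]:
            layers["phospho"].append(el.gene)
        elif el.form is Form.RNA and el.gene not in layers["rna"]:
            layers["rna"].append(el.gene)
    return {k: sorted(v) for k, v in layers.items()}


def _truth_initial_state(sys_: ReactionSystem, spec: FixtureSpec,
                         rng: np.random.Generator) -> np.ndarray:
    """Ground-truth X(0): per-gene baselines split 70/30, promoters free.

    The split matches the pipeline's own initial-state heuristic, so data
    generated here reconstruct the truth exactly at zero noise.
    """
    baselines = {}
    X0 = np.zeros(sys_.n_elements)
    for el in sys_.elements:
        if el.gene is not None and el.gene not in baselines:
            baselines[el.gene] = 10.0 ** rng.uniform(
                np.log10(spec.baseline_low), np.log10(spec.baseline_high))
    has_phospho = {el.gene for el in sys_.elements if el.form is Form.PHOSPHO}
    for el in sys_.elements:
        if el.form is Form.PROTEIN:
            frac = spec.phospho_fraction if el.gene in has_phospho else 0.0
            X0[el.index] = (1 - frac) * baselines[el.gene]
        elif el.form is Form.PHOSPHO:
            X0[el.index] = spec.phospho_fraction * baselines[el.gene]
        elif el.form is Form.RNA:
            X0[el.index] = 10.0 ** rng.uniform(-1.0, 1.0)
        elif el.form is Form.DNA_FREE:
            X0[el.index] = 2.0 / spec.cell_volume_ul
    return X0


def make_truth_and_data(
    net: InteractionNetwork,
    spec: FixtureSpec,
    max_retries: int = 10,
) -> tuple[np.ndarray, ExperimentalDataset, ReactionSystem, OdeSystem]:
    """Sample true kinetics, simulate every condition, emit noisy replicates.

    Returns (K_true, dataset, compiled system, ode system).  Replicate r of
    biomolecule i at time j is lognormal with mean equal to the simulated
    aggregate value and the layer's coefficient of variation; the phospho
    layer is additionally multiplied by a per-biomolecule random scale to
    make it a relative-intensity measurement.  RNA is emitted as per-cell
    counts (value × cell volume).  If a sampled parameter set fails to
    integrate, a fresh set is drawn up to ``max_retries`` times.
    """
    rng = np.random.default_rng(spec.seed)
    modes = infer_active_modes(net)
    sys_ = compile_network(net, modes, measured_rna=set(net.gene_ids))
    ode = build(sys_)
    measured = _measured_layers(sys_)
    agg = build_aggregation(sys_, measured)
    times = np.asarray(spec.times, dtype=float)
    X0 = _truth_initial_state(sys_, spec, rng)

    K_true = None
    trajs: dict[str, np.ndarray] = {}
    for attempt in range(max_retries):
        K_try = 10.0 ** rng.uniform(np.log10(spec.k_low), np.log10(spec.k_high),
                                    size=sys_.n_parameters)
        try:
            trajs = {}
            for cond in spec.conditions:
                K_eff = cond.apply(K_try, sys_)
                traj = ode.simulate(X0, times, K_eff)
                trajs[cond.name] = traj.states
            K_true = K_try
            break
        except SimulationError:
            continue
    if K_true is None:
        raise SimulationError(
            f"no integrable parameter set found in {max_retries} draws")

    phospho_scale = {g: 10.0 ** rng.uniform(1.0, 3.0) for g in measured["phospho"]}

    records = []
    for cond in spec.conditions:
        states = trajs[cond.name]
        for layer in ("protein", "phospho", "rna"):
            C, genes = agg.layer(layer)
            Y = np.asarray(C @ states.T)  # (n_genes, n_times)
            cv = spec.cv.get(layer, 0.0)
            for gi, gene in enumerate(genes):
                for ti, t in enumerate(times):
                    mean = Y[gi, ti]
                    if layer == "phospho":
                        mean = mean * phospho_scale[gene]
                    elif layer == "rna":
                        mean = mean * spec.cell_volume_ul  # per-cell counts
                    for r in range(1, spec.n_replicates + 1):
                        if cv > 0 and mean > 0:
                            sigma = np.sqrt(np.log1p(cv ** 2))
                            mu = np.log(mean) - sigma ** 2 / 2
                            value = rng.lognormal(mu, sigma)
                        else:
                            value = mean
                        records.append((gene, layer, cond.name, t, r, value))
    table = pd.DataFrame(
        records, columns=["gene", "layer", "condition", "time_h", "replicate", "value"])
    dataset = ExperimentalDataset(table, rna_units="counts",
                                  cell_volume_ul=spec.cell_volume_ul)
    return K_true, dataset, sys_, ode


def write_fixture(
    outdir: str | Path,
    net: InteractionNetwork,
    dataset: ExperimentalDataset,
    spec: FixtureSpec,
    K_true: np.ndarray | None = None,
) -> dict[str, Path]:
    """Emit the snapshot TSV, gene list, tidy expression CSV and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    snapshot = outdir / "snapshot.tsv"
    effect_word = {Effect.ACTIVATION: "up-regulates activity",
                   Effect.INHIBITION: "down-regulates activity"}
    with snapshot.open("w") as fh:
        fh.write("ENTITYA\tENTITYB\tEFFECT\tMECHANISM\tDIRECT\tPMID\n")
        for e in net.edges:
            fh.write(f"{e.source}\t{e.target}\t{effect_word.get(e.effect, '')}\t"
                     f"{e.mechanism.value.replace('_', ' ')}\tYES\t{e.evidence}\n")
    gene_list = outdir / "genes.txt"
    gene_list.write_text("\n".join(net.gene_ids) + "\n")
    expression = outdir / "expression.csv"
    dataset.to_csv(expression)
    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps({
        "seed": spec.seed,
        "n_genes": spec.n_genes,
        "mechanisms": spec.mechanisms,
        "times": list(spec.times),
        "n_replicates": spec.n_replicates,
        "cv": spec.cv,
        "conditions": [c.name for c in spec.conditions],
        "rna_units": "counts",
        "K_true": list(map(float, K_true)) if K_true is not None else None,
    }, indent=1))
    return {"snapshot": snapshot, "gene_list": gene_list,
            "expression": expression, "manifest": manifest}
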