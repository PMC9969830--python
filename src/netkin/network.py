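"""Signed, typed interaction networks harvested from a SIGNOR-style snapshot.

The entry point of the pipeline is a curated causal-interaction table (a
local tab-separated snapshot in the SIGNOR dialect).  Rows are filtered down
to the five mechanisms the downstream reaction dictionary understands
(phosphorylation, dephosphorylation, ubiquitination, binding, transcriptional
regulation), identifiers are normalised so isoforms and transcript variants
of one gene collapse onto a single node, and each protein's functionally
*active* post-translational form is inferred from the mechanism/effect
combinations of the edges that target it.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

logger = logging.getLogger(__name__)


class Mechanism(str, Enum):
    PHOSPHORYLATION = "phosphorylation"
    DEPHOSPHORYLATION = "dephosphorylation"
    UBIQUITINATION = "ubiquitination"
    BINDING = "binding"
    TRANSCRIPTIONAL_REGULATION = "transcriptional_regulation"


class Effect(str, Enum):
    ACTIVATION = "activation"
    INHIBITION = "inhibition"


class ActiveForm(str, Enum):
    UNMODIFIED = "unmodified"
    PHOSPHORYLATED = "phosphorylated"
    UBIQUITINATED = "ubiquitinated"
    UNRESOLVED = "unresolved"


#: mapping from raw snapshot MECHANISM strings to the supported enum.
MECHANISM_SYNONYMS = {
    "phosphorylation": Mechanism.PHOSPHORYLATION,
    "dephosphorylation": Mechanism.DEPHOSPHORYLATION,
    "ubiquitination": Mechanism.UBIQUITINATION,
    "binding": Mechanism.BINDING,
    "complex formation": Mechanism.BINDING,
    "transcriptional regulation": Mechanism.TRANSCRIPTIONAL_REGULATION,
    "transcriptional_regulation": Mechanism.TRANSCRIPTIONAL_REGULATION,
    "transcription": Mechanism.TRANSCRIPTIONAL_REGULATION,
}

#: default column names of the snapshot dialect; overridable via config.
DEFAULT_COLUMNS = {
    "source": "ENTITYA",
    "target": "ENTITYB",
    "effect": "EFFECT",
    "mechanism": "MECHANISM",
    "direct": "DIRECT",
    "evidence": "PMID",
}

_ISOFORM_SUFFIX = re.compile(r"-\d+$")


class SnapshotFormatError(ValueError):
    """The snapshot file does not match the declared tabular dialect."""


def normalize_gene_id(raw: str) -> str:
    """Canonicalise a gene symbol: uppercase, isoform suffix stripped.

    Isoforms ("AKT1-2") and transcript variants of one gene collapse to a
    single identifier so that every gene is one node.
    """
    return _ISOFORM_SUFFIX.sub("", raw.strip().upper())


@dataclass(frozen=True)
class Biomolecule:
    gene_id: str
    layers_present: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Interaction:
    source: str
    target: str
    mechanism: Mechanism
    effect: Effect | None
    evidence: str = ""

    def key(self) -> tuple:
        """Identity used for de-duplication; binding is undirected."""
        if self.mechanism is Mechanism.BINDING:
            ends: tuple = (frozenset((self.source, self.target)),)
        else:
            ends = (self.source, self.target)
        return (*ends, self.mechanism, self.effect)


@dataclass
class InteractionNetwork:
    nodes: list[Biomolecule]
    edges: list[Interaction]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [n.gene_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene_id among nodes")
        known = set(ids)
        for e in self.edges:
            if e.source not in known or e.target not in known:
                raise ValueError(f"edge {e.source}->{e.target} references unknown node")

    @property
    def gene_ids(self) -> list[str]:
        return [n.gene_id for n in self.nodes]

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiDiGraph()
        g.add_nodes_from(self.gene_ids)
        for e in self.edges:
            g.add_edge(e.source, e.target, mechanism=e.mechanism.value,
                       effect=e.effect.value if e.effect else None)
        return g


@dataclass
class ActiveModeTable:
    modes: dict[str, ActiveForm]
    conflicts: list[str] = field(default_factory=list)

    def __getitem__(self, gene_id: str) -> ActiveForm:
        return self.modes.get(gene_id, ActiveForm.UNMODIFIED)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.modes


def _parse_effect(raw: str) -> Effect | None:
    raw = raw.strip().lower()
    if "down-regulates" in raw or raw == "inhibition":
        return Effect.INHIBITION
    if "up-regulates" in raw or raw == "activation":
        return Effect.ACTIVATION
    return None


def load_snapshot(
    path: str | Path,
    biomolecules: list[str] | None = None,
    column_map: dict[str, str] | None = None,
) -> InteractionNetwork:
    """Read a SIGNOR-dialect TSV snapshot into an :class:`InteractionNetwork`.

    Only edges whose mechanism maps to the five supported types are kept;
    everything else is counted and logged.  If ``biomolecules`` is given,
    edges touching genes outside that list are dropped (and the node set is
    exactly the normalised input list); otherwise nodes are taken from the
    edges themselves.

    Raises
    ------
    SnapshotFormatError
        If a mandatory column is missing from the header.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for role in ("source", "target", "mechanism", "effect"):
            if cols[role] not in header:
                raise SnapshotFormatError(
                    f"snapshot {path} is missing mandatory column {cols[role]!r}"
                )
        rows = list(reader)

    allowed: set[str] | None = None
    if biomolecules is not None:
        allowed = {normalize_gene_id(g) for g in biomolecules}

    edges: list[Interaction] = []
    seen: set[tuple] = set()
    dropped_mechanism = Counter()
    dropped_node = 0
    duplicates = 0
    for row in rows:
        mech_raw = row[cols["mechanism"]].strip().lower()
        mech = MECHANISM_SYNONYMS.get(mech_raw)
        if mech is None:
            dropped_mechanism[mech_raw] += 1
            continue
        src = normalize_gene_id(row[cols["source"]])
        tgt = normalize_gene_id(row[cols["target"]])
        if allowed is not None and (src not in allowed or tgt not in allowed):
            dropped_node += 1
            logger.info("dropping edge %s->%s: endpoint not in biomolecule list", src, tgt)
            continue
        edge = Interaction(
            source=src,
            target=tgt,
            mechanism=mech,
            effect=_parse_effect(row[cols["effect"]]),
            evidence=row.get(cols["evidence"], "") or "",
        )
        if edge.key() in seen:
            duplicates += 1
            continue
        seen.add(edge.key())
        edges.append(edge)

    if dropped_mechanism:
        logger.info("dropped %d edges with unsupported mechanisms: %s",
                    sum(dropped_mechanism.values()), dict(dropped_mechanism))
    if allowed is not None:
        node_ids = sorted(allowed)
    else:
        node_ids = sorted({g for e in edges for g in (e.source, e.target)})
    if not edges:
        logger.warning("snapshot %s yielded an empty edge set after filtering", path)
    return InteractionNetwork(
        nodes=[Biomolecule(g) for g in node_ids],
        edges=edges,
        provenance={
            "snapshot": str(path),
            "n_rows": len(rows),
            "n_edges": len(edges),
            "n_dropped_mechanism": sum(dropped_mechanism.values()),
            "dropped_mechanisms": dict(dropped_mechanism),
            "n_dropped_unknown_node": dropped_node,
            "n_duplicates": duplicates,
        },
    )


def harvest_subnetwork(net: InteractionNetwork, inputs: list[str]) -> InteractionNetwork:
    """Restrict the network to edges with BOTH endpoints in ``inputs``.

    The returned node set is exactly the (normalised) input list, including
    isolated genes; an empty edge set is a valid result.
    """
    if not inputs:
        raise ValueError("input gene list must be nonempty")
    wanted = {normalize_gene_id(g) for g in inputs}
    edges = [e for e in net.edges if e.source in wanted and e.target in wanted]
    return InteractionNetwork(
        nodes=[Biomolecule(g) for g in sorted(wanted)],
        edges=edges,
        provenance={**net.provenance, "harvested_from": len(net.edges)},
    )


#: (mechanism, effect) -> active form implied for the TARGET protein.
_MODE_RULES = {
    (Mechanism.PHOSPHORYLATION, Effect.ACTIVATION): ActiveForm.PHOSPHORYLATED,
    (Mechanism.PHOSPHORYLATION, Effect.INHIBITION): ActiveForm.UNMODIFIED,
    (Mechanism.DEPHOSPHORYLATION, Effect.ACTIVATION): ActiveForm.UNMODIFIED,
    (Mechanism.DEPHOSPHORYLATION, Effect.INHIBITION): ActiveForm.PHOSPHORYLATED,
}


def infer_active_modes(net: InteractionNetwork) -> ActiveModeTable:
    """Infer each protein's active post-translational form from its in-edges.

    A phosphorylation edge that *activates* its target implies the
    phosphorylated form is the active one; a dephosphorylation edge that
    *inhibits* its target implies the same (removing the phosphate removes
    activity).  The two remaining combinations imply the unmodified form.
    Ubiquitination routes degradation and carries no vote; genes never
    targeted by a modification edge default to unmodified-active.

    Conflicting votes are resolved by majority; an exact tie resolves to
    phosphorylated-active with a logged warning (one active form per gene is
    a deliberate simplification).
    """
    votes: dict[str, Counter] = {}
    for e in net.edges:
        implied = _MODE_RULES.get((e.mechanism, e.effect))
        if implied is not None:
            votes.setdefault(e.target, Counter())[implied] += 1

    modes: dict[str, ActiveForm] = {}
    conflicts: list[str] = []
    for node in net.nodes:
        g = node.gene_id
        tally = votes.get(g)
        if not tally:
            modes[g] = ActiveForm.UNMODIFIED
            continue
        if len(tally) == 1:
            modes[g] = next(iter(tally))
            continue
        conflicts.append(g)
        n_phos = tally[ActiveForm.PHOSPHORYLATED]
        n_unmod = tally[ActiveForm.UNMODIFIED]
        if n_phos == n_unmod:
            logger.warning(
                "active-mode tie for %s (%d vs %d votes); resolving to phosphorylated",
                g, n_phos, n_unmod,
            )
            modes[g] = ActiveForm.PHOSPHORYLATED
        else:
            modes[g] = (ActiveForm.PHOSPHORYLATED if n_phos > n_unmod
                        else ActiveForm.UNMODIFIED)
    return ActiveModeTable(modes=modes, conflicts=conflicts)
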