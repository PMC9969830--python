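"""Compile an interaction network into an elementary reaction system.

Every network edge is expanded into elementary biochemical reactions through
a fixed "dictionary": binding becomes reversible complex formation,
(de)phosphorylation becomes a catalytic conversion carried out by the
enzyme's active form, ubiquitination tags the substrate for the universal
degradation, and transcriptional regulation is spelled out as TF–promoter
binding, transcription and translation.  Each distinct molecular species —
a protein form, a complex, an mRNA, free or TF-bound promoter DNA — is
registered once as an *element* with a unique integer id; reactions from
different edges are stitched together through these shared elements.

Housekeeping closes the system: basal protein synthesis for genes without
transcriptional regulation, and first-order degradation for every element
except DNA (total promoter DNA is conserved).

The compiled :class:`ReactionSystem` is the single source of truth for the
downstream ODE build, and the per-layer binary aggregation matrices map its
elements back onto the measured biomolecules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum

import scipy.sparse as sp

from .network import (
    ActiveForm,
    ActiveModeTable,
    Effect,
    Interaction,
    InteractionNetwork,
    Mechanism,
)

logger = logging.getLogger(__name__)


class Form(str, Enum):
    PROTEIN = "protein"
    PHOSPHO = "phospho_protein"
    UBIQ = "ubiq_protein"
    RNA = "rna"
    DNA_FREE = "dna_free"
    DNA_BOUND = "dna_bound"
    COMPLEX = "complex"


#: protein-mass forms (count toward total-protein measurements)
_PROTEIN_FORMS = {Form.PROTEIN, Form.PHOSPHO, Form.UBIQ}


@dataclass(frozen=True)
class Element:
    """One distinct molecular species.

    ``members`` carries (gene, form) pairs for composite species: the
    subunits of a complex, or the bound transcription factor of an occupied
    promoter.  ``gene`` is the owning gene for single-gene species and the
    regulated gene for promoters; complexes have ``gene=None``.
    """

    index: int
    form: Form
    gene: str | None
    members: tuple[tuple[str, str], ...] = ()

    @property
    def key(self) -> tuple:
        return (self.form.value, self.gene, self.members)

    @property
    def name(self) -> str:
        if self.form is Form.PROTEIN:
            return self.gene
        if self.form is Form.PHOSPHO:
            return f"{self.gene}_p"
        if self.form is Form.UBIQ:
            return f"{self.gene}_ub"
        if self.form is Form.RNA:
            return f"RNA_{self.gene}"
        if self.form is Form.DNA_FREE:
            return f"DNA_{self.gene}"
        if self.form is Form.DNA_BOUND:
            (tf_gene, tf_form), = self.members
            suffix = "_p" if tf_form == Form.PHOSPHO.value else ""
            return f"DNA_{self.gene}:TF_{tf_gene}{suffix}"
        parts = [g + ("_p" if f == Form.PHOSPHO.value else "") for g, f in self.members]
        return ":".join(parts)

    def contains_gene(self, gene: str) -> bool:
        if self.gene == gene and self.form is not Form.DNA_FREE:
            return True
        return any(g == gene for g, _ in self.members)

    def contains_phospho(self, gene: str) -> bool:
        if self.form is Form.PHOSPHO and self.gene == gene:
            return True
        return any(g == gene and f == Form.PHOSPHO.value for g, f in self.members)


@dataclass(frozen=True)
class Reaction:
    """An elementary reaction with mass-action kinetics by default.

    ``kf_index``/``kb_index`` are slots into the global parameter vector;
    ``kb_index is None`` marks an irreversible reaction.  ``origin`` records
    the edge or housekeeping rule that produced the reaction, ``mechanism``
    and ``enzyme_gene`` let interventions target catalytic steps.
    """

    reactants: tuple[int, ...]
    products: tuple[int, ...]
    kf_index: int
    kb_index: int | None
    origin: str
    rate_law: str = "mass_action"
    hill_coefficient: float = 2.0
    mechanism: str | None = None
    enzyme_gene: str | None = None

    @property
    def reversible(self) -> bool:
        return self.kb_index is not None

    def signature(self) -> tuple:
        return (tuple(sorted(self.reactants)), tuple(sorted(self.products)))


class CompileError(ValueError):
    pass


class ElementRegistry:
    """Interns elements: identical (form, gene, members) map to one id."""

    def __init__(self) -> None:
        self._by_key: dict[tuple, Element] = {}
        self.elements: list[Element] = []

    def get(self, form: Form, gene: str | None,
            members: tuple[tuple[str, str], ...] = ()) -> Element:
        key = (form.value, gene, members)
        el = self._by_key.get(key)
        if el is None:
            el = Element(index=len(self.elements), form=form, gene=gene, members=members)
            self._by_key[key] = el
            self.elements.append(el)
        return el

    def find(self, form: Form, gene: str | None,
             members: tuple[tuple[str, str], ...] = ()) -> Element | None:
        return self._by_key.get((form.value, gene, members))

    def __len__(self) -> int:
        return len(self.elements)


@dataclass
class ReactionSystem:
    elements: list[Element]
    reactions: list[Reaction]
    n_parameters: int
    parameter_names: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def element_named(self, name: str) -> Element:
        for el in self.elements:
            if el.name == name:
                return el
        raise KeyError(name)

    def find_element(self, form: Form, gene: str | None,
                     members: tuple[tuple[str, str], ...] = ()) -> Element | None:
        for el in self.elements:
            if el.form is form and el.gene == gene and el.members == members:
                return el
        return None

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "elements": [
                {"index": el.index, "form": el.form.value, "gene": el.gene,
                 "members": [list(m) for m in el.members], "name": el.name}
                for el in self.elements
            ],
            "reactions": [
                {"reactants": list(r.reactants), "products": list(r.products),
                 "kf_index": r.kf_index, "kb_index": r.kb_index,
                 "rate_law": r.rate_law, "hill_coefficient": r.hill_coefficient,
                 "origin": r.origin, "mechanism": r.mechanism,
                 "enzyme_gene": r.enzyme_gene}
                for r in self.reactions
            ],
            "n_parameters": self.n_parameters,
            "parameter_names": self.parameter_names,
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ReactionSystem":
        payload = json.loads(text)
        elements = [
            Element(index=d["index"], form=Form(d["form"]), gene=d["gene"],
                    members=tuple(tuple(m) for m in d["members"]))
            for d in payload["elements"]
        ]
        reactions = [
            Reaction(reactants=tuple(d["reactants"]), products=tuple(d["products"]),
                     kf_index=d["kf_index"], kb_index=d["kb_index"],
                     rate_law=d["rate_law"], hill_coefficient=d["hill_coefficient"],
                     origin=d["origin"], mechanism=d["mechanism"],
                     enzyme_gene=d["enzyme_gene"])
            for d in payload["reactions"]
        ]
        return cls(elements=elements, reactions=reactions,
                   n_parameters=payload["n_parameters"],
                   parameter_names=payload["parameter_names"],
                   provenance=payload.get("provenance", {}))

    def summary(self) -> dict:
        return {
            "n_elements": self.n_elements,
            "n_reactions": self.n_reactions,
            "n_parameters": self.n_parameters,
        }


@dataclass
class AggregationMatrix:
    """Binary element→biomolecule maps, one sparse matrix per measured layer.

    Row i of ``C_P`` sums every element carrying protein mass of biomolecule
    i (free, phosphorylated, ubiquitinated, in complexes, bound to DNA);
    ``C_Ph`` rows sum phospho-containing forms; ``C_RNA`` rows select mRNAs.
    """

    C_P: sp.csr_matrix
    C_Ph: sp.csr_matrix
    C_RNA: sp.csr_matrix
    genes_P: list[str]
    genes_Ph: list[str]
    genes_RNA: list[str]

    def layer(self, name: str) -> tuple[sp.csr_matrix, list[str]]:
        return {
            "protein": (self.C_P, self.genes_P),
            "phospho": (self.C_Ph, self.genes_Ph),
            "rna": (self.C_RNA, self.genes_RNA),
        }[name]


class _Builder:
    """Accumulates elements, reactions and parameter slots during compile."""

    def __init__(self, dialect: str = "lumped") -> None:
        if dialect not in ("lumped", "detailed"):
            raise CompileError(f"unknown dictionary dialect {dialect!r}")
        self.dialect = dialect
        self.registry = ElementRegistry()
        self.reactions: list[Reaction] = []
        self.parameter_names: list[str] = []
        self._signatures: set[tuple] = set()

    def new_slot(self, name: str) -> int:
        self.parameter_names.append(name)
        return len(self.parameter_names) - 1

    def add_reaction(self, reactants, products, origin, *, reversible=False,
                     mechanism=None, enzyme_gene=None) -> bool:
        """Register a reaction unless an identical one already exists.

        Returns True if the reaction was added.  Duplicate (reactants,
        products) pairs — e.g. the translation step contributed by two TFs
        regulating the same gene — are merged onto the first occurrence so
        every parameter slot is structurally identifiable.
        """
        sig = (tuple(sorted(e.index for e in reactants)),
               tuple(sorted(e.index for e in products)))
        if sig in self._signatures:
            return False
        self._signatures.add(sig)
        kf = self.new_slot(f"kF[{origin}]")
        kb = self.new_slot(f"kB[{origin}]") if reversible else None
        self.reactions.append(Reaction(
            reactants=tuple(e.index for e in reactants),
            products=tuple(e.index for e in products),
            kf_index=kf, kb_index=kb, origin=origin,
            mechanism=mechanism, enzyme_gene=enzyme_gene,
        ))
        return True

    # element shortcuts
    def protein(self, gene: str) -> Element:
        return self.registry.get(Form.PROTEIN, gene)

    def phospho(self, gene: str) -> Element:
        return self.registry.get(Form.PHOSPHO, gene)

    def active(self, gene: str, modes: ActiveModeTable) -> Element:
        mode = modes[gene]
        if mode is ActiveForm.UNRESOLVED:
            raise CompileError(f"active mode of {gene} is unresolved; cannot compile")
        if mode is ActiveForm.PHOSPHORYLATED:
            return self.phospho(gene)
        if mode is ActiveForm.UBIQUITINATED:
            return self.registry.get(Form.UBIQ, gene)
        return self.protein(gene)


def expand_edge(builder: _Builder, edge: Interaction, modes: ActiveModeTable) -> None:
    """Expand one interaction edge into its elementary reactions.

    The enzyme/TF always participates in its ACTIVE form; the substrate of a
    phosphorylation is the unphosphorylated form and dephosphorylation
    consumes the phospho form (chemical necessity).  In the default "lumped"
    dialect a catalytic edge is one irreversible reaction; in "detailed" it
    splits into reversible enzyme–substrate binding plus catalysis.
    """
    mech = edge.mechanism
    tag = f"{mech.value}:{edge.source}->{edge.target}"

    if mech in (Mechanism.PHOSPHORYLATION, Mechanism.DEPHOSPHORYLATION,
                Mechanism.UBIQUITINATION):
        enzyme = builder.active(edge.source, modes)
        if mech is Mechanism.PHOSPHORYLATION:
            substrate, product = builder.protein(edge.target), builder.phospho(edge.target)
        elif mech is Mechanism.DEPHOSPHORYLATION:
            substrate, product = builder.phospho(edge.target), builder.protein(edge.target)
        else:
            substrate = builder.protein(edge.target)
            product = builder.registry.get(Form.UBIQ, edge.target)
        if builder.dialect == "lumped":
            builder.add_reaction([enzyme, substrate], [enzyme, product], tag,
                                 mechanism=mech.value, enzyme_gene=edge.source)
        else:
            es_members = tuple(sorted(
                ((enzyme.gene, enzyme.form.value), (substrate.gene, substrate.form.value))
            ))
            es = builder.registry.get(Form.COMPLEX, None, es_members)
            builder.add_reaction([enzyme, substrate], [es], f"{tag}|bind",
                                 reversible=True, mechanism=mech.value,
                                 enzyme_gene=edge.source)
            builder.add_reaction([es], [enzyme, product], f"{tag}|cat",
                                 mechanism=mech.value, enzyme_gene=edge.source)
        return

    if mech is Mechanism.BINDING:
        a = builder.active(edge.source, modes)
        b = builder.active(edge.target, modes)
        members = tuple(sorted(((a.gene, a.form.value), (b.gene, b.form.value))))
        complex_el = builder.registry.get(Form.COMPLEX, None, members)
        builder.add_reaction([a, b], [complex_el], tag, reversible=True,
                             mechanism=mech.value)
        return

    if mech is Mechanism.TRANSCRIPTIONAL_REGULATION:
        tf = builder.active(edge.source, modes)
        gene = edge.target
        dna_free = builder.registry.get(Form.DNA_FREE, gene)
        dna_bound = builder.registry.get(
            Form.DNA_BOUND, gene, ((tf.gene, tf.form.value),))
        rna = builder.registry.get(Form.RNA, gene)
        protein = builder.protein(gene)
        builder.add_reaction([tf, dna_free], [dna_bound], f"{tag}|tf_binding",
                             reversible=True, mechanism=mech.value,
                             enzyme_gene=edge.source)
        if edge.effect is not Effect.INHIBITION:
            # transcription proceeds from the TF-occupied promoter
            builder.add_reaction([dna_bound], [dna_bound, rna],
                                 f"{tag}|transcription", mechanism=mech.value,
                                 enzyme_gene=edge.source)
        else:
            # the TF sequesters the promoter; transcription from free DNA only
            builder.add_reaction([dna_free], [rna, dna_free],
                                 f"transcription_basal:{gene}", mechanism=mech.value)
        builder.add_reaction([rna], [rna, protein], f"translation:{gene}")
        return

    raise CompileError(f"unsupported mechanism {mech}")  # pragma: no cover


def add_housekeeping(builder: _Builder, net: InteractionNetwork,
                     measured_rna: set[str] | None = None) -> None:
    """Close the system with basal synthesis and universal degradation.

    Genes without an incoming transcriptional-regulation edge get one basal
    protein-synthesis reaction (∅ → protein); if such a gene's mRNA is
    measured it additionally gets basal transcription (∅ → RNA) so its RNA
    trajectory is fittable.  Every element except promoter DNA degrades
    first-order (X → ∅): total DNA per gene stays constant.
    """
    regulated = {e.target for e in net.edges
                 if e.mechanism is Mechanism.TRANSCRIPTIONAL_REGULATION}
    measured_rna = measured_rna or set()
    for gene in sorted(net.gene_ids):
        if gene in regulated:
            continue
        protein = builder.protein(gene)
        builder.add_reaction([], [protein], f"basal_synthesis:{gene}")
        if gene in measured_rna:
            rna = builder.registry.get(Form.RNA, gene)
            builder.add_reaction([], [rna], f"basal_transcription:{gene}")
    # degradation of every non-DNA element; iterate over a fixed prefix since
    # no new elements are created here
    for el in list(builder.registry.elements):
        if el.form in (Form.DNA_FREE, Form.DNA_BOUND):
            continue
        builder.add_reaction([el], [], f"degradation:{el.name}")


def compile_network(
    net: InteractionNetwork,
    modes: ActiveModeTable | None = None,
    *,
    dialect: str = "lumped",
    measured_rna: set[str] | None = None,
    housekeeping: bool = True,
) -> ReactionSystem:
    """Compile the full network into a :class:`ReactionSystem`.

    Edge expansions are unioned with element de-duplication (species shared
    between edges merge onto one id), then housekeeping rules are applied.
    Compilation is deterministic: edges are processed in a canonical sorted
    order, so identical inputs serialize byte-identically regardless of the
    order edges appeared in the snapshot.
    """
    from .network import infer_active_modes

    if modes is None:
        modes = infer_active_modes(net)
    builder = _Builder(dialect=dialect)
    edges = sorted(
        net.edges,
        key=lambda e: (e.mechanism.value, e.source, e.target,
                       e.effect.value if e.effect else ""),
    )
    for edge in edges:
        try:
            expand_edge(builder, edge, modes)
        except CompileError as err:
            raise CompileError(
                f"while expanding {edge.mechanism.value} edge "
                f"{edge.source}->{edge.target}: {err}") from err
    if housekeeping:
        add_housekeeping(builder, net, measured_rna=measured_rna)
    return ReactionSystem(
        elements=builder.registry.elements,
        reactions=builder.reactions,
        n_parameters=len(builder.parameter_names),
        parameter_names=builder.parameter_names,
        provenance={"dialect": dialect, "n_edges": len(net.edges),
                    "n_genes": len(net.nodes)},
    )


def build_aggregation(
    sys_: ReactionSystem,
    measured: dict[str, list[str]],
) -> AggregationMatrix:
    """Build the binary per-layer aggregation matrices.

    ``measured`` maps layer name ("protein", "phospho", "rna") to the list
    of measured biomolecules in that layer.  A measured biomolecule with no
    matching element is a hard error (the model cannot produce a value to
    compare against).
    """
    n = sys_.n_elements

    def rows(layer: str, genes: list[str]):
        mat = sp.lil_matrix((len(genes), n), dtype=float)
        for i, gene in enumerate(genes):
            cols = []
            for el in sys_.elements:
                if layer == "protein":
                    if (el.form in _PROTEIN_FORMS and el.gene == gene) or \
                       (el.form in (Form.COMPLEX, Form.DNA_BOUND) and
                            any(g == gene for g, _ in el.members)):
                        cols.append(el.index)
                elif layer == "phospho":
                    if el.contains_phospho(gene):
                        cols.append(el.index)
                elif layer == "rna":
                    if el.form is Form.RNA and el.gene == gene:
                        cols.append(el.index)
            if not cols:
                raise CompileError(
                    f"measured {layer} biomolecule {gene!r} matches no element")
            mat[i, cols] = 1.0
        return mat.tocsr()

    genes_p = list(measured.get("protein", []))
    genes_ph = list(measured.get("phospho", []))
    genes_rna = list(measured.get("rna", []))
    return AggregationMatrix(
        C_P=rows("protein", genes_p),
        C_Ph=rows("phospho", genes_ph),
        C_RNA=rows("rna", genes_rna),
        genes_P=genes_p, genes_Ph=genes_ph, genes_RNA=genes_rna,
    )
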