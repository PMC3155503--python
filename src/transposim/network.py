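"""Reaction networks of the three transposon-control model variants.

The models describe a retrotransposon-like element with an intermediate
cytoplasmic stage (virus-like particles, VLPs) under two host defenses:
transcriptional gene silencing (TGS, nuclear, heterochromatin formation
guided by siRNAs) and post-transcriptional gene silencing (PTGS,
cytoplasmic, RISC-mediated mRNA degradation).  The three variants differ
only in how double-stranded RNA — the Dicer substrate — is produced:

``rdrp``
    Canonical pathway: RNA-dependent RNA polymerase converts
    single-stranded RNA into dsRNA, unprimed in nucleus and cytoplasm
    and additionally primed by cytoplasmic siRNAs (the amplification
    feedback).
``antisense``
    No RdRP.  Antisense transcripts from silenced elements anneal with
    mRNA in the nucleus, are also exported, and anneal in the cytoplasm.
``hairpin``
    No RdRP.  Nuclear sense-antisense annealing as above, but cytoplasmic
    dsRNA arises from hairpin folding of the mRNA itself; no antisense
    export.

Every reaction is engine-agnostic: the deterministic and stochastic
engines consume the same :class:`ReactionNetwork` and interpret each
rate law as a flux or a propensity respectively.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

from .params import ParameterSet, default_parameters

__all__ = [
    "ModelVariant",
    "RateLaw",
    "Reaction",
    "ReactionNetwork",
    "CompiledNetwork",
    "build_network",
    "validate_network",
    "export_network",
    "SPECIES_ALL",
]


class ModelVariant(str, enum.Enum):
    """The three dsRNA-formation strategies."""

    RDRP = "rdrp"
    ANTISENSE = "antisense"
    HAIRPIN = "hairpin"

    @classmethod
    def coerce(cls, value: "ModelVariant | str") -> "ModelVariant":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            valid = ", ".join(v.value for v in cls)
            raise ValueError(f"unknown model variant {value!r}; expected one of {valid}") from None


#: Canonical species order.  ``A_c`` (cytoplasmic antisense RNA) exists
#: only in the antisense variant and is dropped from the other networks.
SPECIES_ALL = (
    "T_act",  # active genomic TE copies
    "T_sil",  # heterochromatin-silenced TE copies
    "M_n",    # nuclear TE mRNA
    "A_n",    # nuclear antisense / short heterochromatic transcript
    "D_n",    # nuclear dsRNA
    "S_n",    # nuclear siRNA
    "M_c",    # cytoplasmic TE mRNA
    "A_c",    # cytoplasmic antisense RNA (antisense variant only)
    "D_c",    # cytoplasmic dsRNA
    "S_c",    # cytoplasmic siRNA
    "VLP",    # virus-like particles
)

# Rate-law kinds.  ``pair`` is second order in a single species: the
# deterministic flux is K*X**2 while the stochastic propensity uses the
# combinatorial count K*X*(X-1).
LAW_LINEAR = 0
LAW_BILINEAR = 1
LAW_PAIR = 2
LAW_SATURATING = 3

_LAW_NAMES = {
    "linear": LAW_LINEAR,
    "bilinear": LAW_BILINEAR,
    "pair": LAW_PAIR,
    "saturating": LAW_SATURATING,
}


@dataclass(frozen=True)
class RateLaw:
    """A flux formula over (state, parameters).

    ``kind`` selects the functional form, ``species`` the state variables
    it reads (which need not coincide with the consumed reactants — e.g.
    transcription reads the TE copy number without consuming it), and
    ``constant`` is a formula over parameter names evaluated once per
    parameter set (products and the complement ``1-f`` are the only forms
    used).
    """

    kind: str
    constant: str
    species: tuple[str, ...]
    saturation: str | None = None  # parameter naming the half-saturation constant

    def constant_value(self, params: ParameterSet) -> float:
        value = 1.0
        for factor in self.constant.split("*"):
            factor = factor.strip()
            if factor.startswith("1-"):
                value *= 1.0 - params[factor[2:]]
            else:
                value *= params[factor]
        return value

    def formula(self) -> str:
        terms = " * ".join(self.species)
        if self.kind == "linear":
            return f"{self.constant} * {terms}"
        if self.kind == "bilinear":
            return f"{self.constant} * {terms}"
        if self.kind == "pair":
            return f"{self.constant} * {self.species[0]}^2"
        if self.kind == "saturating":
            s, m = self.species
            return f"{self.constant} * {s} * {m} / ({self.saturation} + {m})"
        raise ValueError(f"unknown rate-law kind {self.kind!r}")


@dataclass(frozen=True)
class Reaction:
    """One pseudo-reaction: stoichiometry plus a rate law.

    Product counts are integers, or the string ``"n"`` for the siRNA
    burst size (resolved against the parameter set when the network is
    compiled).
    """

    id: str
    description: str
    section: str  # "life_cycle" | "tgs" | "ptgs"
    variants: frozenset[ModelVariant]
    reactants: Mapping[str, int]
    products: Mapping[str, int | str]
    law: RateLaw

    def resolved_products(self, params: ParameterSet) -> dict[str, int]:
        out: dict[str, int] = {}
        for species, count in self.products.items():
            if count == "n":
                out[species] = max(1, int(round(params.n)))
            else:
                out[species] = int(count)
        return out

    def net_te_change(self, params: ParameterSet | None = None) -> int:
        """Net change in genomic TE copies (T_act + T_sil) per firing."""
        params = params or default_parameters()
        prods = self.resolved_products(params)
        delta = 0
        for sp in ("T_act", "T_sil"):
            delta += prods.get(sp, 0) - self.reactants.get(sp, 0)
        return delta


def _r(
    rid: str,
    desc: str,
    section: str,
    variants: Iterable[str],
    reactants: Mapping[str, int],
    products: Mapping[str, int | str],
    kind: str,
    constant: str,
    species: tuple[str, ...],
    saturation: str | None = None,
) -> Reaction:
    return Reaction(
        id=rid,
        description=desc,
        section=section,
        variants=frozenset(ModelVariant(v) for v in variants),
        reactants=dict(reactants),
        products=dict(products),
        law=RateLaw(kind=kind, constant=constant, species=species, saturation=saturation),
    )


_ALL = ("rdrp", "antisense", "hairpin")

#: The full reaction inventory.  The ``variants`` tags reproduce the
#: availability grid of the three models; the saturating RNase sink is an
#: extra mRNA-degradation channel present in all variants (it carries the
#: v_s / k_s constants, which belong to no other reaction).
REACTIONS: tuple[Reaction, ...] = (
    # ---- transposon life cycle -------------------------------------
    _r("vlp_integration", "VLP integration in genome", "life_cycle", _ALL,
       {"VLP": 1}, {"T_act": 1}, "linear", "f*j", ("VLP",)),
    _r("vlp_integration_failed", "VLP integration failed", "life_cycle", _ALL,
       {"VLP": 1}, {}, "linear", "1-f*j", ("VLP",)),
    _r("transcription_active", "production of mRNA", "life_cycle", _ALL,
       {}, {"M_n": 1}, "linear", "v_ta", ("T_act",)),
    _r("transcription_silenced", "production of other/antisense RNA", "life_cycle", _ALL,
       {}, {"A_n": 1}, "linear", "v_ts", ("T_sil",)),
    _r("export_mrna", "transport of mRNA", "life_cycle", _ALL,
       {"M_n": 1}, {"M_c": 1}, "linear", "t_m", ("M_n",)),
    _r("decay_mrna_nuclear", "decay of mRNA", "life_cycle", _ALL,
       {"M_n": 1}, {}, "linear", "d_m", ("M_n",)),
    _r("vlp_production", "production of VLP", "life_cycle", _ALL,
       {"M_c": 1}, {"VLP": 1}, "pair", "q", ("M_c",)),
    _r("decay_vlp", "decay of VLP", "life_cycle", _ALL,
       {"VLP": 1}, {}, "linear", "d_v", ("VLP",)),
    # ---- transcriptional gene silencing ----------------------------
    _r("silencing_basal", "TE spontaneously silenced", "tgs", _ALL,
       {"T_act": 1}, {"T_sil": 1}, "linear", "h_b", ("T_act",)),
    _r("silencing_rits", "TE silenced by RITS", "tgs", _ALL,
       {"T_act": 1}, {"T_sil": 1}, "bilinear", "h_s", ("S_n", "T_act")),
    _r("activation", "TE activation", "tgs", _ALL,
       {"T_sil": 1}, {"T_act": 1}, "linear", "u", ("T_sil",)),
    _r("dsrna_rdrp_nuclear", "production of dsRNA by RdRP", "tgs", ("rdrp",),
       {"A_n": 1}, {"D_n": 1}, "linear", "p_n", ("A_n",)),
    _r("dsrna_pairing_nuclear", "dsRNA by sense-antisense base pairing", "tgs",
       ("antisense", "hairpin"),
       {"M_n": 1, "A_n": 1}, {"D_n": 1}, "bilinear", "p_nx", ("M_n", "A_n")),
    _r("export_asrna", "transport of antisense RNA", "tgs", ("antisense",),
       {"A_n": 1}, {"A_c": 1}, "linear", "t_an", ("A_n",)),
    _r("decay_asrna_nuclear", "decay of other/antisense RNA", "tgs", _ALL,
       {"A_n": 1}, {}, "linear", "d_r", ("A_n",)),
    _r("dicing_nuclear", "production of siRNA", "tgs", _ALL,
       {"D_n": 1}, {"S_n": "n"}, "linear", "g_s", ("D_n",)),
    # Nuclear siRNA turns over at the nuclear-RNA decay rate d_r; the
    # faster d_s applies to the cytoplasmic pool.
    _r("decay_sirna_nuclear", "decay of siRNA", "tgs", _ALL,
       {"S_n": 1}, {}, "linear", "d_r", ("S_n",)),
    # ---- post-transcriptional gene silencing -----------------------
    _r("dsrna_rdrp_cyto", "production of dsRNA by RdRP", "ptgs", ("rdrp",),
       {"M_c": 1}, {"D_c": 1}, "linear", "p_c", ("M_c",)),
    _r("dsrna_primed", "production of dsRNA from primed mRNA", "ptgs", ("rdrp",),
       {"M_c": 1, "S_c": 1}, {"D_c": 1}, "bilinear", "g", ("S_c", "M_c")),
    _r("dsrna_pairing_cyto", "dsRNA by sense-antisense base pairing", "ptgs",
       ("antisense",),
       {"M_c": 1, "A_c": 1}, {"D_c": 1}, "bilinear", "p_cx", ("M_c", "A_c")),
    _r("dsrna_hairpin", "dsRNA by hairpin formation", "ptgs", ("hairpin",),
       {"M_c": 1}, {"D_c": 1}, "linear", "p_cxx", ("M_c",)),
    _r("risc_degradation", "degradation by RISC", "ptgs", _ALL,
       {"M_c": 1}, {}, "bilinear", "b", ("S_c", "M_c")),
    _r("rnase_degradation", "degradation by RNase", "ptgs", _ALL,
       {"M_c": 1}, {}, "saturating", "v_s", ("S_c", "M_c"), "k_s"),
    _r("decay_mrna_cyto", "decay of mRNA", "ptgs", _ALL,
       {"M_c": 1}, {}, "linear", "d_m", ("M_c",)),
    _r("decay_asrna_cyto", "decay of antisense RNA", "ptgs", ("antisense",),
       {"A_c": 1}, {}, "linear", "d_m", ("A_c",)),
    _r("dicing_cyto", "production of siRNA", "ptgs", _ALL,
       {"D_c": 1}, {"S_c": "n"}, "linear", "g_s", ("D_c",)),
    _r("decay_sirna_cyto", "decay of siRNA", "ptgs", _ALL,
       {"S_c": 1}, {}, "linear", "d_s", ("S_c",)),
)


@dataclass(frozen=True)
class CompiledNetwork:
    """Array form of a network for one concrete parameter set.

    ``stoich`` is species-by-reaction; the law arrays encode, per
    reaction, the functional form (``law_type``), the numeric rate
    constant (``law_k``), the one or two state indices it reads
    (``law_s1``, ``law_s2``) and the saturation constant (``law_c``,
    only meaningful for saturating laws).
    """

    species: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    stoich: np.ndarray
    law_type: np.ndarray
    law_k: np.ndarray
    law_s1: np.ndarray
    law_s2: np.ndarray
    law_c: np.ndarray


@dataclass(frozen=True)
class ReactionNetwork:
    """Species list and reaction set of one model variant."""

    variant: ModelVariant
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.species)})

    def species_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"species {name!r} not present in the {self.variant.value} network") from None

    def reaction(self, rid: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rid:
                return rxn
        raise KeyError(f"no reaction {rid!r} in the {self.variant.value} network")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def compile(self, params: ParameterSet) -> CompiledNetwork:
        """Resolve rate constants and stoichiometry into flat arrays."""
        nr = len(self.reactions)
        ns = len(self.species)
        stoich = np.zeros((ns, nr), dtype=np.float64)
        law_type = np.zeros(nr, dtype=np.int64)
        law_k = np.zeros(nr, dtype=np.float64)
        law_s1 = np.zeros(nr, dtype=np.int64)
        law_s2 = np.full(nr, -1, dtype=np.int64)
        law_c = np.zeros(nr, dtype=np.float64)
        for r, rxn in enumerate(self.reactions):
            for sp, cnt in rxn.reactants.items():
                stoich[self.species_index(sp), r] -= cnt
            for sp, cnt in rxn.resolved_products(params).items():
                stoich[self.species_index(sp), r] += cnt
            law_type[r] = _LAW_NAMES[rxn.law.kind]
            law_k[r] = rxn.law.constant_value(params)
            law_s1[r] = self.species_index(rxn.law.species[0])
            if len(rxn.law.species) > 1:
                law_s2[r] = self.species_index(rxn.law.species[1])
            if rxn.law.saturation is not None:
                law_c[r] = params[rxn.law.saturation]
        return CompiledNetwork(
            species=self.species,
            reaction_ids=tuple(r.id for r in self.reactions),
            stoich=stoich,
            law_type=law_type,
            law_k=law_k,
            law_s1=law_s1,
            law_s2=law_s2,
            law_c=law_c,
        )


def build_network(
    variant: ModelVariant | str,
    risc_law: str = "mass_action",
    vlp_consumes_mrna: bool = True,
) -> ReactionNetwork:
    """Assemble the reaction network of one model variant.

    Parameters
    ----------
    variant :
        ``"rdrp"``, ``"antisense"`` or ``"hairpin"``.
    risc_law :
        Which cytoplasmic siRNA-guided mRNA sinks to include:
        ``"mass_action"`` (RISC slicing, flux ``b*S_c*M_c``; the
        default), ``"saturating"`` (RNase, flux
        ``v_s*S_c*M_c/(k_s+M_c)``) or ``"both"``.
    vlp_consumes_mrna :
        Whether packaging one VLP removes one cytoplasmic transcript
        (default) or leaves the mRNA pool untouched; the production flux
        ``q*M_c**2`` is the same either way.
    """
    variant = ModelVariant.coerce(variant)
    if risc_law not in ("mass_action", "saturating", "both"):
        raise ValueError(
            f"risc_law must be 'mass_action', 'saturating' or 'both', got {risc_law!r}"
        )
    dropped = set()
    if risc_law == "mass_action":
        dropped.add("rnase_degradation")
    elif risc_law == "saturating":
        dropped.add("risc_degradation")
    reactions = tuple(
        rxn for rxn in REACTIONS if variant in rxn.variants and rxn.id not in dropped
    )
    if not vlp_consumes_mrna:
        reactions = tuple(
            _r("vlp_production", rxn.description, rxn.section,
               [v.value for v in rxn.variants], {}, {"VLP": 1}, "pair", "q", ("M_c",))
            if rxn.id == "vlp_production" else rxn
            for rxn in reactions
        )
    species = tuple(
        s for s in SPECIES_ALL
        if s != "A_c" or variant is ModelVariant.ANTISENSE
    )
    return ReactionNetwork(variant=variant, species=species, reactions=reactions)


def validate_network(network: ReactionNetwork, params: ParameterSet | None = None) -> list[str]:
    """Check structural invariants; return human-readable violations.

    An empty list means the network is valid: all referenced species are
    declared, every declared species takes part in some reaction,
    stoichiometric counts are positive integers, and no reaction removes
    a genomic TE copy without replacing it (TE conservation — genomic
    copies only interconvert between active and silenced, or are added
    by integration; there is no TE decay).
    """
    params = params or default_parameters()
    violations: list[str] = []
    declared = set(network.species)
    used: set[str] = set()
    for rxn in network.reactions:
        touched = set(rxn.reactants) | set(rxn.products) | set(rxn.law.species)
        used |= touched
        for sp in sorted(touched - declared):
            violations.append(f"reaction {rxn.id!r} references unknown species {sp!r}")
        for sp, cnt in rxn.reactants.items():
            if not (isinstance(cnt, int) and cnt > 0):
                violations.append(
                    f"reaction {rxn.id!r}: non-positive-integer reactant count {cnt!r} for {sp!r}"
                )
        for sp, cnt in rxn.resolved_products(params).items():
            if not (isinstance(cnt, int) and cnt > 0):
                violations.append(
                    f"reaction {rxn.id!r}: non-positive-integer product count {cnt!r} for {sp!r}"
                )
        if rxn.net_te_change(params) < 0:
            violations.append(
                f"reaction {rxn.id!r} violates TE conservation: net genomic TE change "
                f"{rxn.net_te_change(params)} < 0"
            )
    for sp in sorted(declared - used):
        violations.append(f"species {sp!r} does not appear in any reaction")
    return violations


def export_network(network: ReactionNetwork) -> str:
    """Plain-text dump of the network, one reaction per line."""
    lines = [f"# {network.variant.value} model — {len(network.reactions)} reactions"]
    lines.append(f"# species: {', '.join(network.species)}")
    for rxn in network.reactions:
        lhs = " + ".join(f"{c} {s}" if c != 1 else s for s, c in rxn.reactants.items()) or "∅"
        rhs = " + ".join(
            f"{c} {s}" if c != 1 else s for s, c in rxn.products.items()
        ) or "∅"
        tags = "/".join(sorted(v.value for v in rxn.variants))
        lines.append(
            f"{rxn.id:24s} [{rxn.section}] ({tags}) {lhs} -> {rhs}  @ {rxn.law.formula()}"
        )
    return "\n".join(lines)
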