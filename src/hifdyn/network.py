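"""Reaction network: species, reactions, flux laws and the ODE right-hand side.

The model couples a "cytoplasmic" part (mRNA turnover, translation,
oxygen/PHD-dependent hydroxylation of the two HIF alpha proteins) with a
"nuclear" part (reversible dimerization with HIF1B, competitive binding of
the two heterodimers to two HRE site classes, and target-gene
transcription driven by the four HIF-HRE complexes).  All concentrations
are dimensionless relative units; HRE "concentrations" are motif counts.
Oxygen (``O2``) is a boundary input, never consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

# ---------------------------------------------------------------------------
# Species
# ---------------------------------------------------------------------------

#: The 15 dynamic species, in canonical state-vector order.
SPECIES: tuple[str, ...] = (
    "HIF1A_mrna",
    "HIF2A_mrna",
    "HIF1A_protein",
    "HIF2A_protein",
    "PHD_protein",
    "HIF1B",
    "HIF1AB",
    "HIF2AB",
    "HRE1",
    "HRE2",
    "HIF1AB_HRE1",
    "HIF2AB_HRE1",
    "HIF1AB_HRE2",
    "HIF2AB_HRE2",
    "Gene_mRNA",
)

#: Boundary species (held constant by the integrator, set by the protocol).
O2 = "O2"

#: Species of the cytoplasmic sub-model (first fitting step).
CYTOPLASMIC_SPECIES: tuple[str, ...] = (
    "HIF1A_mrna",
    "HIF2A_mrna",
    "HIF1A_protein",
    "HIF2A_protein",
    "PHD_protein",
)

REACTION_KINDS = (
    "constant_inflow",
    "first_order",
    "mm_hydroxylation",
    "reversible_binding",
    "catalytic_production",
)


class SpeciesState(dict):
    """Mapping species name -> non-negative concentration.

    A thin ``dict`` subclass so states serialize and compare trivially;
    :meth:`validate` enforces non-negativity and (optionally) that every
    key is a known species.
    """

    def validate(self, species: Sequence[str] | None = None) -> "SpeciesState":
        for name, value in self.items():
            if species is not None and name not in species:
                raise ValidationError(f"unknown species {name!r}")
            if not np.isfinite(value) or value < 0:
                raise ValidationError(
                    f"species {name!r} has invalid concentration {value!r}"
                )
        return self


@dataclass(frozen=True)
class ReactionSpec:
    """One reaction: kind, stoichiometry and the parameter keys it reads.

    ``reactants``/``products`` are ``(species, stoichiometry)`` pairs;
    ``modifiers`` are catalysts/templates that appear in the flux but are
    not consumed.  ``parameter_keys`` maps flux-law roles (``k``, ``kd``,
    ``kcat``, ``km_hif``, ``km_o2``) to :class:`ParameterSet` entries.
    """

    id: str
    kind: str
    reactants: tuple[tuple[str, float], ...] = ()
    products: tuple[tuple[str, float], ...] = ()
    modifiers: tuple[str, ...] = ()
    parameter_keys: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in REACTION_KINDS:
            raise ValidationError(f"unknown reaction kind {self.kind!r}")
        roles = set(self.parameter_keys)
        if self.kind == "mm_hydroxylation":
            if roles != {"kcat", "km_hif", "km_o2"}:
                raise ValidationError(
                    f"{self.id}: mm_hydroxylation needs kcat, km_hif, km_o2"
                )
        elif self.kind == "reversible_binding":
            if roles != {"k", "kd"}:
                raise ValidationError(
                    f"{self.id}: reversible_binding needs exactly k and kd"
                )
        elif roles != {"k"}:
            raise ValidationError(f"{self.id}: {self.kind} needs exactly one key k")

    def parameter_names(self) -> tuple[str, ...]:
        return tuple(self.parameter_keys.values())


class ParameterSet(dict):
    """Mapping parameter name -> non-negative real.

    Default initialization (:meth:`defaults_for`) sets every rate constant
    to 1 and every dissociation constant (``*.kd``) to 1e-4.
    """

    @classmethod
    def defaults_for(cls, model: "ModelDefinition") -> "ParameterSet":
        out = cls()
        for rxn in model.reactions:
            for name in rxn.parameter_keys.values():
                out[name] = 1e-4 if name.endswith(".kd") else 1.0
        return out

    def validate(self) -> "ParameterSet":
        for name, value in self.items():
            if not np.isfinite(value) or value < 0:
                raise ValidationError(f"parameter {name!r} has invalid value {value!r}")
        return self

    def require(self, name: str) -> float:
        try:
            return self[name]
        except KeyError:
            raise ConfigurationError(f"missing parameter {name!r}") from None


# ---------------------------------------------------------------------------
# Flux laws
# ---------------------------------------------------------------------------

def mm_hydroxylation_flux(
    hif_alpha: float,
    o2: float,
    phd: float,
    kcat: float,
    km_hif: float,
    km_o2: float,
) -> float:
    """Two-substrate Michaelis-Menten hydroxylation flux.

    ``kcat * [PHD] * hif/(km_hif+hif) * o2/(km_o2+o2)``.  The flux consumes
    the HIF alpha species only; PHD (enzyme) and O2 (boundary) are
    unchanged.
    """
    for label, value in (
        ("hif_alpha", hif_alpha),
        ("o2", o2),
        ("phd", phd),
        ("kcat", kcat),
    ):
        if value < 0:
            raise ValidationError(f"{label} must be >= 0, got {value}")
    if km_hif <= 0 or km_o2 <= 0:
        raise ValidationError("Michaelis constants must be > 0")
    return kcat * phd * (hif_alpha / (km_hif + hif_alpha)) * (o2 / (km_o2 + o2))


def mass_action_flux(
    reaction: ReactionSpec,
    state: Mapping[str, float],
    params: Mapping[str, float],
):
    """Flux of a non-MM reaction at ``state``.

    Returns a scalar for ``constant_inflow`` / ``first_order`` /
    ``catalytic_production`` and a ``(forward, reverse)`` pair for
    ``reversible_binding`` (reverse rate constant is ``k * kd`` so that
    equilibrium satisfies ``[A][B]/[AB] = kd``).
    """
    if reaction.kind == "mm_hydroxylation":
        raise ValidationError("use mm_hydroxylation_flux for mm_hydroxylation")

    def par(role: str) -> float:
        try:
            name = reaction.parameter_keys[role]
        except KeyError:
            raise ConfigurationError(
                f"reaction {reaction.id!r} has no {role!r} parameter key"
            ) from None
        try:
            return params[name]
        except KeyError:
            raise ConfigurationError(f"missing parameter {name!r}") from None

    if reaction.kind == "constant_inflow":
        return par("k")
    if reaction.kind == "first_order":
        (species, stoich), = reaction.reactants
        return par("k") * state[species]
    if reaction.kind == "catalytic_production":
        (modifier,) = reaction.modifiers
        return par("k") * state[modifier]
    # reversible_binding
    (a, _), (b, _) = reaction.reactants
    (ab, _), = reaction.products
    k = par("k")
    forward = k * state[a] * state[b]
    reverse = k * par("kd") * state[ab]
    return forward, reverse


# ---------------------------------------------------------------------------
# Model definition
# ---------------------------------------------------------------------------

@dataclass
class ModelDefinition:
    """Species list, reaction set and HRE totals of one model variant."""

    species: tuple[str, ...]
    reactions: tuple[ReactionSpec, ...]
    hre1_total: int = 0
    hre2_total: int = 0

    def __post_init__(self):
        self.species = tuple(self.species)
        self.reactions = tuple(self.reactions)
        self._index = {name: i for i, name in enumerate(self.species)}
        self.validate()

    # -- structure ---------------------------------------------------------

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ValidationError(f"unknown species {name!r}") from None

    def reaction(self, rid: str) -> ReactionSpec:
        for rxn in self.reactions:
            if rxn.id == rid:
                return rxn
        raise ValidationError(f"no reaction {rid!r}")

    def parameter_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for rxn in self.reactions:
            for name in rxn.parameter_keys.values():
                if name not in names:
                    names.append(name)
        return tuple(names)

    def default_parameters(self) -> ParameterSet:
        return ParameterSet.defaults_for(self)

    def stoichiometry(self, reaction: ReactionSpec) -> np.ndarray:
        """Net stoichiometry column of ``reaction`` (forward direction)."""
        col = np.zeros(len(self.species))
        for name, stoich in reaction.reactants:
            col[self.index(name)] -= stoich
        for name, stoich in reaction.products:
            col[self.index(name)] += stoich
        return col

    def validate(self) -> "ModelDefinition":
        if len(set(self.species)) != len(self.species):
            raise ValidationError("duplicate species names")
        if self.hre1_total < 0 or self.hre2_total < 0:
            raise ValidationError("HRE totals must be >= 0")
        for rxn in self.reactions:
            for name, _ in (*rxn.reactants, *rxn.products):
                if name not in self._index:
                    raise ValidationError(
                        f"reaction {rxn.id!r} references unknown species {name!r}"
                    )
            for name in rxn.modifiers:
                if name != O2 and name not in self._index:
                    raise ValidationError(
                        f"reaction {rxn.id!r} references unknown modifier {name!r}"
                    )
        # HRE sites only bind and unbind: conservation per class is structural.
        for hre in ("HRE1", "HRE2"):
            if hre not in self._index:
                continue
            for rxn in self.reactions:
                touched = {n for n, _ in (*rxn.reactants, *rxn.products)}
                if hre in touched and rxn.kind != "reversible_binding":
                    raise ValidationError(
                        f"{hre} may only participate in reversible_binding "
                        f"(violated by {rxn.id!r})"
                    )
        return self

    # -- evaluation --------------------------------------------------------

    def state_vector(self, state: Mapping[str, float]) -> np.ndarray:
        return np.array([state.get(name, 0.0) for name in self.species], float)

    def state_dict(self, vector: np.ndarray) -> SpeciesState:
        return SpeciesState(zip(self.species, map(float, vector)))

    def compile(self, params: Mapping[str, float]) -> "CompiledRHS":
        return CompiledRHS(self, params)

    def rhs(
        self,
        state: Mapping[str, float],
        params: Mapping[str, float],
        o2: float,
    ) -> SpeciesState:
        """Per-species time derivatives at ``state`` (dict in, dict out)."""
        SpeciesState(state).validate()
        y = self.state_vector(state)
        dy = self.compile(params)(0.0, y, o2)
        return self.state_dict(dy)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "species": list(self.species),
            "hre1_total": int(self.hre1_total),
            "hre2_total": int(self.hre2_total),
            "reactions": [
                {
                    "id": r.id,
                    "kind": r.kind,
                    "reactants": [[n, s] for n, s in r.reactants],
                    "products": [[n, s] for n, s in r.products],
                    "modifiers": list(r.modifiers),
                    "parameter_keys": dict(r.parameter_keys),
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelDefinition":
        reactions = tuple(
            ReactionSpec(
                id=r["id"],
                kind=r["kind"],
                reactants=tuple((n, float(s)) for n, s in r.get("reactants", [])),
                products=tuple((n, float(s)) for n, s in r.get("products", [])),
                modifiers=tuple(r.get("modifiers", [])),
                parameter_keys=dict(r.get("parameter_keys", {})),
            )
            for r in data["reactions"]
        )
        return cls(
            species=tuple(data["species"]),
            reactions=reactions,
            hre1_total=int(data.get("hre1_total", 0)),
            hre2_total=int(data.get("hre2_total", 0)),
        )


class CompiledRHS:
    """Vectorized right-hand side bound to one parameter set.

    Groups reactions by kind so a single evaluation is a handful of numpy
    operations; built once per (model, parameters) pair and reused across
    the thousands of evaluations an integration or fit performs.
    """

    def __init__(self, model: ModelDefinition, params: Mapping[str, float]):
        n = len(model.species)
        self.n = n
        get = lambda name: _require_param(params, name)

        const = np.zeros(n)
        lin_src: list[int] = []
        lin_k: list[float] = []
        lin_cols: list[np.ndarray] = []
        rev_a: list[int] = []
        rev_b: list[int] = []
        rev_ab: list[int] = []
        rev_kf: list[float] = []
        rev_kr: list[float] = []
        rev_cols: list[np.ndarray] = []
        self.mm: list[tuple[int, int, float, float, float, np.ndarray]] = []

        for rxn in model.reactions:
            col = model.stoichiometry(rxn)
            if rxn.kind == "constant_inflow":
                const += col * get(rxn.parameter_keys["k"])
            elif rxn.kind == "first_order":
                (name, _), = rxn.reactants
                lin_src.append(model.index(name))
                lin_k.append(get(rxn.parameter_keys["k"]))
                lin_cols.append(col)
            elif rxn.kind == "catalytic_production":
                (name,) = rxn.modifiers
                lin_src.append(model.index(name))
                lin_k.append(get(rxn.parameter_keys["k"]))
                lin_cols.append(col)
            elif rxn.kind == "reversible_binding":
                (a, _), (b, _) = rxn.reactants
                (ab, _), = rxn.products
                rev_a.append(model.index(a))
                rev_b.append(model.index(b))
                rev_ab.append(model.index(ab))
                kf = get(rxn.parameter_keys["k"])
                rev_kf.append(kf)
                rev_kr.append(kf * get(rxn.parameter_keys["kd"]))
                rev_cols.append(col)
            else:  # mm_hydroxylation
                (sub, _), = rxn.reactants
                phd = next(m for m in rxn.modifiers if m != O2)
                self.mm.append(
                    (
                        model.index(sub),
                        model.index(phd),
                        get(rxn.parameter_keys["kcat"]),
                        get(rxn.parameter_keys["km_hif"]),
                        get(rxn.parameter_keys["km_o2"]),
                        col,
                    )
                )

        self.const = const
        self.lin_src = np.array(lin_src, int)
        self.lin_k = np.array(lin_k)
        self.S_lin = np.column_stack(lin_cols) if lin_cols else np.zeros((n, 0))
        self.rev_a = np.array(rev_a, int)
        self.rev_b = np.array(rev_b, int)
        self.rev_ab = np.array(rev_ab, int)
        self.rev_kf = np.array(rev_kf)
        self.rev_kr = np.array(rev_kr)
        self.S_rev = np.column_stack(rev_cols) if rev_cols else np.zeros((n, 0))

    def __call__(self, t: float, y: np.ndarray, o2: float) -> np.ndarray:
        dy = self.const.copy()
        if self.lin_src.size:
            dy += self.S_lin @ (self.lin_k * y[self.lin_src])
        if self.rev_a.size:
            net = self.rev_kf * y[self.rev_a] * y[self.rev_b]
            net -= self.rev_kr * y[self.rev_ab]
            dy += self.S_rev @ net
        for i_sub, i_phd, kcat, km_hif, km_o2, col in self.mm:
            hif = y[i_sub]
            # guard 0/0 at km = substrate = 0 (no substrate -> no flux)
            sat_h = hif / (km_hif + hif) if km_hif + hif > 0 else 0.0
            sat_o = o2 / (km_o2 + o2) if km_o2 + o2 > 0 else 0.0
            dy += col * (kcat * y[i_phd] * sat_h * sat_o)
        return dy


def _require_param(params: Mapping[str, float], name: str) -> float:
    try:
        return params[name]
    except KeyError:
        raise ConfigurationError(f"missing parameter {name!r}") from None


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

#: Reactions fitted in the first (cytoplasmic) step.
CYTOPLASMIC_REACTIONS: tuple[str, ...] = (
    "hif1a_mrna_in",
    "hif1a_mrna_out",
    "hif2a_mrna_in",
    "hif2a_mrna_out",
    "hif1a_mrna_to_protein",
    "hif2a_mrna_to_protein",
    "hif1a_protein_out",
    "hif2a_protein_out",
    "phd_to_hif1a_protein",
    "phd_to_hif2a_protein",
    "phd_in",
    "phd_by_hif1a",
    "phd_by_hif2a",
    "phd_out",
)

#: Cytoplasmic reactions whose parameters are re-opened in the second step.
HIF2A_CYTOPLASMIC_REACTIONS: tuple[str, ...] = (
    "hif2a_mrna_to_protein",
    "hif2a_protein_out",
    "phd_to_hif2a_protein",
)

#: Nuclear-part reactions (dimerization, HRE binding, transcription, HIF1B
#: and target-gene turnover).
NUCLEAR_REACTIONS: tuple[str, ...] = (
    "hif1b_in",
    "hif1b_out",
    "hif1a_dimerization",
    "hif2a_dimerization",
    "hif1ab_hre1_binding",
    "hif2ab_hre1_binding",
    "hif1ab_hre2_binding",
    "hif2ab_hre2_binding",
    "transcription_hif1ab_hre1",
    "transcription_hif2ab_hre1",
    "transcription_hif1ab_hre2",
    "transcription_hif2ab_hre2",
    "gene_mrna_in",
    "gene_mrna_out",
)


def _inflow(rid: str, product: str) -> ReactionSpec:
    return ReactionSpec(
        id=rid,
        kind="constant_inflow",
        products=((product, 1.0),),
        parameter_keys={"k": f"{rid}.k"},
    )


def _decay(rid: str, reactant: str) -> ReactionSpec:
    return ReactionSpec(
        id=rid,
        kind="first_order",
        reactants=((reactant, 1.0),),
        parameter_keys={"k": f"{rid}.k"},
    )


def _catalytic(rid: str, modifier: str, product: str) -> ReactionSpec:
    return ReactionSpec(
        id=rid,
        kind="catalytic_production",
        products=((product, 1.0),),
        modifiers=(modifier,),
        parameter_keys={"k": f"{rid}.k"},
    )


def _binding(rid: str, a: str, b: str, ab: str) -> ReactionSpec:
    return ReactionSpec(
        id=rid,
        kind="reversible_binding",
        reactants=((a, 1.0), (b, 1.0)),
        products=((ab, 1.0),),
        parameter_keys={"k": f"{rid}.k", "kd": f"{rid}.kd"},
    )


def _hydroxylation(rid: str, substrate: str) -> ReactionSpec:
    return ReactionSpec(
        id=rid,
        kind="mm_hydroxylation",
        reactants=((substrate, 1.0),),
        modifiers=("PHD_protein", O2),
        parameter_keys={
            "kcat": f"{rid}.kcat",
            "km_hif": f"{rid}.km_hif",
            "km_o2": f"{rid}.km_o2",
        },
    )


def _cytoplasmic_reactions() -> tuple[ReactionSpec, ...]:
    return (
        _inflow("hif1a_mrna_in", "HIF1A_mrna"),
        _decay("hif1a_mrna_out", "HIF1A_mrna"),
        _inflow("hif2a_mrna_in", "HIF2A_mrna"),
        _decay("hif2a_mrna_out", "HIF2A_mrna"),
        _catalytic("hif1a_mrna_to_protein", "HIF1A_mrna", "HIF1A_protein"),
        _catalytic("hif2a_mrna_to_protein", "HIF2A_mrna", "HIF2A_protein"),
        _decay("hif1a_protein_out", "HIF1A_protein"),
        _decay("hif2a_protein_out", "HIF2A_protein"),
        _hydroxylation("phd_to_hif1a_protein", "HIF1A_protein"),
        _hydroxylation("phd_to_hif2a_protein", "HIF2A_protein"),
        _inflow("phd_in", "PHD_protein"),
        _catalytic("phd_by_hif1a", "HIF1A_protein", "PHD_protein"),
        _catalytic("phd_by_hif2a", "HIF2A_protein", "PHD_protein"),
        _decay("phd_out", "PHD_protein"),
    )


def _nuclear_reactions() -> tuple[ReactionSpec, ...]:
    return (
        _inflow("hif1b_in", "HIF1B"),
        _decay("hif1b_out", "HIF1B"),
        _binding("hif1a_dimerization", "HIF1A_protein", "HIF1B", "HIF1AB"),
        _binding("hif2a_dimerization", "HIF2A_protein", "HIF1B", "HIF2AB"),
        _binding("hif1ab_hre1_binding", "HIF1AB", "HRE1", "HIF1AB_HRE1"),
        _binding("hif2ab_hre1_binding", "HIF2AB", "HRE1", "HIF2AB_HRE1"),
        _binding("hif1ab_hre2_binding", "HIF1AB", "HRE2", "HIF1AB_HRE2"),
        _binding("hif2ab_hre2_binding", "HIF2AB", "HRE2", "HIF2AB_HRE2"),
        _catalytic("transcription_hif1ab_hre1", "HIF1AB_HRE1", "Gene_mRNA"),
        _catalytic("transcription_hif2ab_hre1", "HIF2AB_HRE1", "Gene_mRNA"),
        _catalytic("transcription_hif1ab_hre2", "HIF1AB_HRE2", "Gene_mRNA"),
        _catalytic("transcription_hif2ab_hre2", "HIF2AB_HRE2", "Gene_mRNA"),
        _inflow("gene_mrna_in", "Gene_mRNA"),
        _decay("gene_mrna_out", "Gene_mRNA"),
    )


def build_default_model(hre1_count: int, hre2_count: int) -> ModelDefinition:
    """Assemble the full 15-species network for a gene with the given
    HRE1/HRE2 motif counts (used as the binding-site totals)."""
    if hre1_count < 0 or hre2_count < 0:
        raise ValidationError("HRE counts must be >= 0")
    return ModelDefinition(
        species=SPECIES,
        reactions=_cytoplasmic_reactions() + _nuclear_reactions(),
        hre1_total=int(hre1_count),
        hre2_total=int(hre2_count),
    )


def build_cytoplasmic_model() -> ModelDefinition:
    """The 5-species cytoplasmic sub-model used in the first fitting step
    (no HIF1B, no heterodimers, no HRE sites, no target gene)."""
    return ModelDefinition(
        species=CYTOPLASMIC_SPECIES,
        reactions=_cytoplasmic_reactions(),
    )


# ---------------------------------------------------------------------------
# Algebraic rules
# ---------------------------------------------------------------------------

def total_alpha(state: Mapping[str, float]) -> tuple[float, float]:
    """Total HIF1A and HIF2A protein: free alpha subunit plus the alpha
    subunit contained in the heterodimer, free or HRE-bound.

    These derived totals are what western blots observe; they are never
    independently initialized.
    """
    get = lambda name: state.get(name, 0.0)
    hif1a = (
        get("HIF1A_protein") + get("HIF1AB")
        + get("HIF1AB_HRE1") + get("HIF1AB_HRE2")
    )
    hif2a = (
        get("HIF2A_protein") + get("HIF2AB")
        + get("HIF2AB_HRE1") + get("HIF2AB_HRE2")
    )
    return hif1a, hif2a


def parameter_names_for(model: ModelDefinition, reaction_ids: Iterable[str]) -> tuple[str, ...]:
    """All parameter names belonging to the given reaction ids."""
    names: list[str] = []
    for rid in reaction_ids:
        for name in model.reaction(rid).parameter_keys.values():
            if name not in names:
                names.append(name)
    return tuple(names)
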