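"""Genome-scale metabolic model stand-ins and their JSON serialization.

A :class:`MetabolicModel` is a minimal stoichiometric model of one species:
metabolites live either in the species' cytosol (compartment ``c:<species_id>``)
or in the shared extracellular ``lumen`` through which merged community members
exchange metabolites.  Exchange reactions are system-boundary reactions written
as ``metabolite -> nothing`` so that positive flux means outflow and the lower
bound encodes the maximal uptake (medium) capacity.

The JSON schema is deliberately small: top-level keys ``species_id``,
``metabolites`` (``[{id, name, compartment}]``), ``reactions``
(``[{id, stoichiometry, lower_bound, upper_bound, is_exchange, is_biomass}]``)
and ``biomass_reaction_id``; files are UTF-8 with sorted keys so that
serialization is byte-deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

LUMEN = "lumen"
CYTOSOL_PREFIX = "c:"


class ModelValidationError(ValueError):
    """Raised when a model violates its structural invariants.

    ``violations`` lists every failed check, not just the first one.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid metabolic model: " + "; ".join(self.violations))


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str
    compartment: str

    @property
    def in_lumen(self) -> bool:
        return self.compartment == LUMEN


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    is_exchange: bool = False
    is_biomass: bool = False


@dataclass
class MetabolicModel:
    species_id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str
    _met_index: dict[str, Metabolite] = field(
        default=None, repr=False, compare=False
    )

    def metabolite(self, met_id: str) -> Metabolite:
        if self._met_index is None or len(self._met_index) != len(self.metabolites):
            self._met_index = {m.id: m for m in self.metabolites}
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def violations(self) -> list[str]:
        """All structural invariant violations (empty list means valid)."""
        problems: list[str] = []
        met_ids = [m.id for m in self.metabolites]
        met_set = set(met_ids)
        if len(met_set) != len(met_ids):
            dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
            problems.append(f"duplicate metabolite ids: {dupes}")
        for m in self.metabolites:
            if m.compartment != LUMEN and not (
                m.compartment.startswith(CYTOSOL_PREFIX)
                and len(m.compartment) > len(CYTOSOL_PREFIX)
            ):
                problems.append(
                    f"metabolite {m.id!r}: malformed compartment {m.compartment!r}"
                )
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            problems.append(f"duplicate reaction ids: {dupes}")
        lumen_ids = {m.id for m in self.metabolites if m.in_lumen}
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                problems.append(
                    f"reaction {r.id!r}: lower_bound {r.lower_bound} > "
                    f"upper_bound {r.upper_bound}"
                )
            if not r.stoichiometry:
                problems.append(f"reaction {r.id!r}: empty stoichiometry")
            for met_id, coeff in r.stoichiometry.items():
                if met_id not in met_set:
                    problems.append(
                        f"reaction {r.id!r}: unknown metabolite {met_id!r}"
                    )
                if coeff == 0:
                    problems.append(
                        f"reaction {r.id!r}: zero coefficient for {met_id!r}"
                    )
            if r.is_exchange and not set(r.stoichiometry) <= lumen_ids:
                problems.append(
                    f"exchange reaction {r.id!r} touches non-lumen metabolites"
                )
        biomass = [r for r in self.reactions if r.is_biomass]
        if len(biomass) != 1:
            problems.append(f"expected exactly one biomass reaction, found {len(biomass)}")
        if self.biomass_reaction_id not in set(rxn_ids):
            problems.append(
                f"biomass_reaction_id {self.biomass_reaction_id!r} not among reactions"
            )
        elif biomass and biomass[0].id != self.biomass_reaction_id:
            problems.append(
                "biomass_reaction_id does not point at the reaction flagged is_biomass"
            )
        return problems

    def validate(self) -> "MetabolicModel":
        problems = self.violations()
        if problems:
            raise ModelValidationError(problems)
        return self


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "species_id": model.species_id,
        "biomass_reaction_id": model.biomass_reaction_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "is_exchange": r.is_exchange,
                "is_biomass": r.is_biomass,
            }
            for r in model.reactions
        ],
    }


def write_model_json(model: MetabolicModel, path: str | Path) -> None:
    """Serialize a validated model; output is byte-deterministic (sorted keys)."""
    model.validate()
    text = json.dumps(_model_to_dict(model), sort_keys=True, indent=1)
    Path(path).write_text(text + "\n", encoding="utf-8")


def read_model_json(path: str | Path) -> MetabolicModel:
    """Read and validate a model from the JSON schema.

    Raises ``ValueError`` naming the offending key on malformed input and
    :class:`ModelValidationError` listing all violations on invalid models.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed model JSON in {path}: {exc}") from exc
    for key in ("species_id", "metabolites", "reactions", "biomass_reaction_id"):
        if key not in raw:
            raise ValueError(f"model JSON {path} missing required key {key!r}")
    try:
        metabolites = [
            Metabolite(id=m["id"], name=m["name"], compartment=m["compartment"])
            for m in raw["metabolites"]
        ]
    except KeyError as exc:
        raise ValueError(f"metabolite entry missing key {exc.args[0]!r}") from exc
    try:
        reactions = [
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                is_exchange=bool(r.get("is_exchange", False)),
                is_biomass=bool(r.get("is_biomass", False)),
            )
            for r in raw["reactions"]
        ]
    except KeyError as exc:
        raise ValueError(f"reaction entry missing key {exc.args[0]!r}") from exc
    model = MetabolicModel(
        species_id=str(raw["species_id"]),
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=str(raw["biomass_reaction_id"]),
    )
    return model.validate()
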