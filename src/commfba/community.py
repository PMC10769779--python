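"""Abundance-filtered merging of species models into one community model.

Members passing the abundance filter (strictly greater than 0.1% by default)
are merged into a single stoichiometric model: species-internal metabolites
and all member reaction ids are namespaced with ``<species_id>|``, lumen
metabolites are shared, and one community-level exchange reaction per lumen
metabolite (``EX_<metabolite>``, written outflow-positive) forms the only
system boundary.  Member exchange reactions are absorbed into that boundary:
their bounds define the community exchange bounds (element-wise widest across
members), while the members' own transport reactions remain the species-to-
lumen transfers.

Community growth is a single rate ``mu`` to which every member's biomass flux
is hard-coupled in proportion to its abundance weight, v_biomass,i = w_i * mu.
This proportional coupling is the key modelling assumption: the community
grows as one unit with fixed composition, so the weakest member limits
everyone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .gem import MetabolicModel, Metabolite, Reaction
from .io import AbundanceTable

ABUNDANCE_THRESHOLD = 0.001  # strict ">" filter at 0.1% relative abundance
WEIGHT_SUM_TOL = 1e-9
SPECIES_SEP = "|"

# boundary bounds for lumen metabolites no member declares an exchange for:
# free outflow (secretion never blocked), no uptake (not part of the medium)
DEFAULT_COMMUNITY_EXPORT = (0.0, 1000.0)


class EmptyCommunityError(ValueError):
    pass


@dataclass
class CommunityModel:
    """Merged multispecies model with abundance-coupled growth."""

    sample_id: str
    members: list[tuple[str, float]]
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    #: (namespaced biomass reaction id, weight) per member, in members order
    coupling: list[tuple[str, float]]
    community_growth_id: str = "mu"
    lumen_exchange_ids: dict[str, str] = field(default_factory=dict)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)


def filter_members(
    sample_id: str,
    table: AbundanceTable,
    threshold: float = ABUNDANCE_THRESHOLD,
) -> list[tuple[str, float]]:
    """Apply the strict abundance filter and renormalize surviving weights.

    Returns (taxon_id, weight) sorted by descending weight, ties broken by id.
    """
    abundances = table.sample_abundances(sample_id)
    survivors = {t: a for t, a in abundances.items() if a > threshold}
    if not survivors:
        raise EmptyCommunityError(
            f"empty community: no taxon above {threshold:g} in sample {sample_id!r}"
        )
    total = sum(survivors.values())
    members = [(t, a / total) for t, a in survivors.items()]
    members.sort(key=lambda item: (-item[1], item[0]))
    return members


def build_community(
    members: list[tuple[MetabolicModel, float]],
    sample_id: str = "community",
) -> CommunityModel:
    """Merge weighted member models into one community model.

    Weights must sum to 1 (the caller renormalizes after filtering) and
    species ids must be distinct; every member needs a biomass reaction.
    """
    if not members:
        raise EmptyCommunityError("cannot build a community without members")
    total = sum(w for _, w in members)
    if abs(total - 1.0) > WEIGHT_SUM_TOL:
        raise ValueError(f"member weights sum to {total!r}, expected 1")
    species = [m.species_id for m, _ in members]
    if len(set(species)) != len(species):
        raise ValueError(f"duplicate species ids among members: {species}")

    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    coupling: list[tuple[str, float]] = []
    lumen_seen: dict[str, Metabolite] = {}
    # widest member exchange bounds per lumen metabolite
    exchange_bounds: dict[str, tuple[float, float]] = {}

    for model, weight in members:
        if weight <= 0 or weight > 1:
            raise ValueError(
                f"member {model.species_id!r} weight {weight!r} outside (0, 1]"
            )
        prefix = model.species_id + SPECIES_SEP
        has_biomass = False
        rename = {
            m.id: (m.id if m.in_lumen else prefix + m.id) for m in model.metabolites
        }
        for m in model.metabolites:
            if m.in_lumen:
                lumen_seen.setdefault(m.id, m)
            else:
                metabolites.append(
                    Metabolite(id=rename[m.id], name=m.name, compartment=m.compartment)
                )
        for r in model.reactions:
            if r.is_exchange:
                # absorbed into the community boundary: widen pool bounds
                (met_id,) = r.stoichiometry
                lo, hi = exchange_bounds.get(met_id, (0.0, 0.0))
                exchange_bounds[met_id] = (
                    min(lo, r.lower_bound),
                    max(hi, r.upper_bound),
                )
                continue
            new_rxn = Reaction(
                id=prefix + r.id,
                stoichiometry={rename[k]: v for k, v in r.stoichiometry.items()},
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                is_exchange=False,
                is_biomass=r.is_biomass,
            )
            reactions.append(new_rxn)
            if r.is_biomass:
                if r.id != model.biomass_reaction_id:
                    raise ValueError(
                        f"member {model.species_id!r}: biomass flag on {r.id!r} "
                        f"but biomass_reaction_id is {model.biomass_reaction_id!r}"
                    )
                coupling.append((new_rxn.id, weight))
                has_biomass = True
        if not has_biomass:
            raise ValueError(f"member {model.species_id!r} lacks a biomass reaction")

    lumen_exchange_ids: dict[str, str] = {}
    for met_id in lumen_seen:
        lo, hi = exchange_bounds.get(met_id, DEFAULT_COMMUNITY_EXPORT)
        ex_id = f"EX_{met_id}"
        lumen_exchange_ids[met_id] = ex_id
        reactions.append(
            Reaction(
                id=ex_id,
                stoichiometry={met_id: -1.0},
                lower_bound=lo,
                upper_bound=hi,
                is_exchange=True,
            )
        )

    return CommunityModel(
        sample_id=sample_id,
        members=[(m.species_id, w) for m, w in members],
        metabolites=metabolites + list(lumen_seen.values()),
        reactions=reactions,
        coupling=coupling,
        lumen_exchange_ids=lumen_exchange_ids,
    )


def validate_community(cm: CommunityModel) -> list[str]:
    """Machine-readable invariant report; an empty list means the model is sound."""
    failures: list[str] = []
    total = sum(w for _, w in cm.members)
    if abs(total - 1.0) > WEIGHT_SUM_TOL:
        failures.append(f"weights not normalized: sum {total!r}")
    for sp, w in cm.members:
        if not 0 < w <= 1:
            failures.append(f"member {sp!r} weight {w!r} outside (0, 1]")
    met_ids = [m.id for m in cm.metabolites]
    met_set = set(met_ids)
    if len(met_set) != len(met_ids):
        failures.append("duplicate metabolite ids after merge")
    lumen = {m.id for m in cm.metabolites if m.in_lumen}
    species = {sp for sp, _ in cm.members}
    for m in cm.metabolites:
        if not m.in_lumen:
            head = m.id.split(SPECIES_SEP, 1)[0]
            if head not in species:
                failures.append(f"internal metabolite {m.id!r} not species-prefixed")
    rxn_ids = set()
    for r in cm.reactions:
        if r.id in rxn_ids:
            failures.append(f"duplicate reaction id {r.id!r}")
        rxn_ids.add(r.id)
        for met_id in r.stoichiometry:
            if met_id not in met_set:
                failures.append(f"reaction {r.id!r}: dangling metabolite {met_id!r}")
        if r.is_exchange and not set(r.stoichiometry) <= lumen:
            failures.append(f"exchange {r.id!r} touches non-lumen metabolites")
        if r.lower_bound > r.upper_bound:
            failures.append(f"reaction {r.id!r}: inverted bounds")
    if len(cm.coupling) != len(cm.members):
        failures.append("coupling constraints do not cover every member")
    for rxn_id, w in cm.coupling:
        if rxn_id not in rxn_ids:
            failures.append(f"coupling references unknown reaction {rxn_id!r}")
    return failures


def write_community_json(cm: CommunityModel, path: str | Path) -> None:
    """Serialize a community model: the species-model JSON schema plus an
    ``extensions`` block carrying members, coupling and the growth variable."""
    payload = {
        "species_id": f"community:{cm.sample_id}",
        "biomass_reaction_id": cm.coupling[0][0] if cm.coupling else "",
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in cm.metabolites
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
            for r in cm.reactions
        ],
        "extensions": {
            "sample_id": cm.sample_id,
            "members": [[sp, w] for sp, w in cm.members],
            "coupling": [[rid, w] for rid, w in cm.coupling],
            "community_growth_id": cm.community_growth_id,
            "lumen_exchange_ids": cm.lumen_exchange_ids,
        },
    }
    Path(path).write_text(
        json.dumps(payload, sort_keys=True, indent=1) + "\n", encoding="utf-8"
    )


def read_community_json(path: str | Path) -> CommunityModel:
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        ext = raw["extensions"]
        cm = CommunityModel(
            sample_id=ext["sample_id"],
            members=[(sp, float(w)) for sp, w in ext["members"]],
            metabolites=[
                Metabolite(m["id"], m["name"], m["compartment"])
                for m in raw["metabolites"]
            ],
            reactions=[
                Reaction(
                    id=r["id"],
                    stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                    lower_bound=float(r["lower_bound"]),
                    upper_bound=float(r["upper_bound"]),
                    is_exchange=bool(r["is_exchange"]),
                    is_biomass=bool(r["is_biomass"]),
                )
                for r in raw["reactions"]
            ],
            coupling=[(rid, float(w)) for rid, w in ext["coupling"]],
            community_growth_id=ext["community_growth_id"],
            lumen_exchange_ids=dict(ext["lumen_exchange_ids"]),
        )
    except KeyError as exc:
        raise ValueError(
            f"community JSON {path} missing key {exc.args[0]!r}"
        ) from exc
    failures = validate_community(cm)
    if failures:
        raise ValueError(
            "invalid community model: " + "; ".join(failures)
        )
    return cm
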