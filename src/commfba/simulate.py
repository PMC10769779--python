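"""Synthetic species models, 16S sequences, and two-visit cohorts.

The generator produces everything the pipeline consumes so that the full
analysis runs with no external data:

* a registry of toy species models — butyrate producers obligately co-produce
  one unit of butyrate per unit of biomass (so community butyrate capacity is
  a deterministic, monotone readout of producer abundance), non-producers
  only grow; each species gets a random uptake capacity and a random
  reference 16S stand-in sequence;
* a cohort of responder/nonresponder patients sampled at baseline (V1) and
  week 4 (V2).  Each patient has a latent community profile drawn from a
  Dirichlet prior; both visits are independent Dirichlet draws concentrated
  around that profile, which makes the two visits exchangeable when no effect
  is planted (a clean null for the paired tests).  In responders a fixed
  fraction of total abundance mass is shifted onto the producer taxa at V2;
* OTU representative sequences mutated from the references at a small rate so
  the identity/coverage mapping recovers the true source species;
* Lichtiger scores constructed so the clinical response label matches the
  simulated group.

Defaults mirror the two-visit cohort the analysis targets: 69 responders and
24 nonresponders at V1, of whom 63 and 22 still provide a sample at V2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gem import LUMEN, MetabolicModel, Metabolite, Reaction
from .io import AbundanceTable, SampleMetadata

GLUCOSE = "glc"
BUTYRATE = "but"


@dataclass
class SimulationConfig:
    n_responders: int = 69
    n_nonresponders: int = 24
    v2_retained_responders: int = 63
    v2_retained_nonresponders: int = 22
    n_species: int = 20
    fraction_producers: float = 0.4
    #: absolute abundance mass shifted onto producers at V2 in responders
    producer_enrichment_delta: float = 0.15
    #: Dirichlet concentration of the patient latent profile
    abundance_concentration: float = 1.0
    #: concentration of per-visit draws around the latent profile
    within_patient_concentration: float = 50.0
    seq_length: int = 250
    mutation_rate_within: float = 0.01
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        problems = []
        if self.n_responders <= 0 or self.n_nonresponders <= 0:
            problems.append("group sizes must be positive")
        if not 0 <= self.v2_retained_responders <= self.n_responders:
            problems.append("v2_retained_responders outside 0..n_responders")
        if not 0 <= self.v2_retained_nonresponders <= self.n_nonresponders:
            problems.append("v2_retained_nonresponders outside 0..n_nonresponders")
        if self.n_species < 2:
            problems.append("need at least 2 species")
        if not 0.0 <= self.fraction_producers <= 1.0:
            problems.append("fraction_producers outside [0, 1]")
        if not 0.0 <= self.producer_enrichment_delta <= 0.9:
            problems.append("producer_enrichment_delta outside [0, 0.9]")
        if self.abundance_concentration <= 0 or self.within_patient_concentration <= 0:
            problems.append("Dirichlet concentrations must be positive")
        if self.seq_length < 50:
            problems.append("seq_length must be >= 50")
        if not 0.0 <= self.mutation_rate_within < 0.5:
            problems.append("mutation_rate_within outside [0, 0.5)")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))
        return self


@dataclass
class SpeciesRegistry:
    models: dict[str, MetabolicModel]
    producers: frozenset[str]
    references: list[tuple[str, str]]


def producer_model(
    species_id: str, uptake_cap: float, transport_cap: float | None = None
) -> MetabolicModel:
    """Toy butyrate producer: 1 glucose -> 1 biomass unit + 1 butyrate.

    ``transport_cap`` limits the species' own lumen->cytosol glucose
    transporter; the generator sets it to the uptake capacity so each member
    keeps its capacity inside a community, while the bare template leaves it
    wide open (the exchange bound is then the only limit).
    """
    c = f"c:{species_id}"
    t_cap = 1000.0 if transport_cap is None else transport_cap
    return MetabolicModel(
        species_id=species_id,
        metabolites=[
            Metabolite(GLUCOSE, "glucose", LUMEN),
            Metabolite(BUTYRATE, "butyrate", LUMEN),
            Metabolite("glc_c", "glucose (cytosol)", c),
            Metabolite("but_c", "butyrate (cytosol)", c),
        ],
        reactions=[
            Reaction("EX_glc", {GLUCOSE: -1.0}, -uptake_cap, 0.0, is_exchange=True),
            Reaction("T_glc", {GLUCOSE: -1.0, "glc_c": 1.0}, 0.0, t_cap),
            Reaction(
                "GROW", {"glc_c": -1.0, "but_c": 1.0}, 0.0, 1000.0, is_biomass=True
            ),
            Reaction("T_but", {"but_c": -1.0, BUTYRATE: 1.0}, 0.0, 1000.0),
            Reaction("EX_but", {BUTYRATE: -1.0}, 0.0, 1000.0, is_exchange=True),
        ],
        biomass_reaction_id="GROW",
    ).validate()


def fermenter_model(
    species_id: str, uptake_cap: float, transport_cap: float | None = None
) -> MetabolicModel:
    """Toy non-producer: glucose is consumed for growth only."""
    c = f"c:{species_id}"
    t_cap = 1000.0 if transport_cap is None else transport_cap
    return MetabolicModel(
        species_id=species_id,
        metabolites=[
            Metabolite(GLUCOSE, "glucose", LUMEN),
            Metabolite("glc_c", "glucose (cytosol)", c),
        ],
        reactions=[
            Reaction("EX_glc", {GLUCOSE: -1.0}, -uptake_cap, 0.0, is_exchange=True),
            Reaction("T_glc", {GLUCOSE: -1.0, "glc_c": 1.0}, 0.0, t_cap),
            Reaction("GROW", {"glc_c": -1.0}, 0.0, 1000.0, is_biomass=True),
        ],
        biomass_reaction_id="GROW",
    ).validate()


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base with probability ``rate`` (never to itself)."""
    bases = "ACGT"
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = bases.replace(out[i], "")
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def make_species_models(
    n_species: int,
    fraction_producers: float = 0.4,
    seed: int = 0,
    seq_length: int = 250,
    uptake_range: tuple[float, float] = (5.0, 15.0),
) -> SpeciesRegistry:
    """Build the model registry and matching reference 16S sequences."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 101)))
    n_producers = round(n_species * fraction_producers)
    producer_idx = set(rng.choice(n_species, size=n_producers, replace=False).tolist())
    models: dict[str, MetabolicModel] = {}
    producers = set()
    references = []
    for i in range(n_species):
        species_id = f"sp{i + 1:03d}"
        cap = float(rng.uniform(*uptake_range))
        if i in producer_idx:
            models[species_id] = producer_model(species_id, cap, transport_cap=cap)
            producers.add(species_id)
        else:
            models[species_id] = fermenter_model(species_id, cap, transport_cap=cap)
        references.append((species_id, _random_sequence(rng, seq_length)))
    return SpeciesRegistry(models, frozenset(producers), references)


@dataclass
class Cohort:
    abundances: AbundanceTable
    metadata: list[SampleMetadata]
    otus: list[tuple[str, str]]
    otu_to_species: dict[str, str]
    groups: dict[str, str]  # patient_id -> responder/nonresponder
    config: SimulationConfig = field(repr=False, default=None)


def _shift_producer_mass(
    profile: np.ndarray, producer_mask: np.ndarray, delta: float
) -> np.ndarray:
    """Move ``delta`` of total mass proportionally onto producers, renormalized."""
    m = float(profile[producer_mask].sum())
    if m <= 0.0 or m >= 1.0:
        return profile
    target = min(m + delta, 0.99)
    out = profile.copy()
    out[producer_mask] *= target / m
    out[~producer_mask] *= (1.0 - target) / (1.0 - m)
    return out / out.sum()


def make_cohort(config: SimulationConfig, registry: SpeciesRegistry) -> Cohort:
    """Generate abundances, metadata and OTU sequences for a two-visit cohort."""
    config.validate()
    if config.producer_enrichment_delta > 0 and not registry.producers:
        raise ValueError("planted effect requested but registry has no producers")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 202)))
    species = [sid for sid, _ in registry.references]
    n = len(species)
    producer_mask = np.array([sid in registry.producers for sid in species])

    otus = []
    otu_to_species = {}
    for i, (sid, ref_seq) in enumerate(registry.references):
        otu_id = f"OTU{i + 1:03d}"
        otus.append((otu_id, mutate_sequence(ref_seq, config.mutation_rate_within, rng)))
        otu_to_species[otu_id] = sid
    species_to_otu = {s: o for o, s in otu_to_species.items()}

    patients = [(f"R{i + 1:03d}", "responder") for i in range(config.n_responders)] + [
        (f"N{i + 1:03d}", "nonresponder") for i in range(config.n_nonresponders)
    ]
    groups = dict(patients)
    responder_ids = [p for p, g in patients if g == "responder"]
    nonresponder_ids = [p for p, g in patients if g == "nonresponder"]
    retained_v2 = set(
        rng.choice(
            responder_ids, size=config.v2_retained_responders, replace=False
        ).tolist()
    ) | set(
        rng.choice(
            nonresponder_ids, size=config.v2_retained_nonresponders, replace=False
        ).tolist()
    )

    entries: list[tuple[str, str, float]] = []
    metadata: list[SampleMetadata] = []
    alpha = np.full(n, config.abundance_concentration)
    kappa = config.within_patient_concentration
    for patient_id, group in patients:
        theta = rng.dirichlet(alpha)
        visit_alpha = np.maximum(kappa * theta, 1e-8)
        profiles = {"V1": rng.dirichlet(visit_alpha)}
        v2 = rng.dirichlet(visit_alpha)
        if group == "responder" and config.producer_enrichment_delta > 0:
            v2 = _shift_producer_mass(
                v2, producer_mask, config.producer_enrichment_delta
            )
        profiles["V2"] = v2

        l1 = int(rng.integers(8, 15))
        if group == "responder":
            u = rng.uniform(0.5, 0.9)
            l2 = math.floor(l1 * (1.0 - u))  # floor keeps the drop >= 50%
        else:
            u = rng.uniform(0.0, 0.4)
            l2 = math.ceil(l1 * (1.0 - u))  # ceil keeps the drop < 50%
        l2 = min(max(l2, 0), 21)

        visits = ["V1"] + (["V2"] if patient_id in retained_v2 else [])
        for visit in visits:
            sample_id = f"{patient_id}-{visit}"
            metadata.append(
                SampleMetadata(sample_id, patient_id, visit, l1 if visit == "V1" else l2)
            )
            profile = profiles[visit]
            for j, sid in enumerate(species):
                if profile[j] > 0:
                    entries.append((sample_id, species_to_otu[sid], float(profile[j])))

    table = AbundanceTable.from_entries(entries)
    return Cohort(table, metadata, otus, otu_to_species, groups, config)


def planted_effect_check(cohort: Cohort, registry: SpeciesRegistry) -> dict:
    """Mean V2-V1 producer-mass shift per group, against the planted truth."""
    producer_otus = {
        otu for otu, sid in cohort.otu_to_species.items() if sid in registry.producers
    }
    df = cohort.abundances.data
    producer_mass = (
        df[df["taxon_id"].isin(producer_otus)].groupby("sample_id")["rel_abundance"].sum()
    )
    shifts: dict[str, list[float]] = {"responder": [], "nonresponder": []}
    sampled = set(df["sample_id"])
    for patient_id, group in cohort.groups.items():
        s1, s2 = f"{patient_id}-V1", f"{patient_id}-V2"
        if s1 in sampled and s2 in sampled:
            shifts[group].append(
                float(producer_mass.get(s2, 0.0) - producer_mass.get(s1, 0.0))
            )
    return {
        "responder_mean_shift": float(np.mean(shifts["responder"]))
        if shifts["responder"]
        else float("nan"),
        "nonresponder_mean_shift": float(np.mean(shifts["nonresponder"]))
        if shifts["nonresponder"]
        else float("nan"),
        "n_responder_pairs": len(shifts["responder"]),
        "n_nonresponder_pairs": len(shifts["nonresponder"]),
        "planted_delta": cohort.config.producer_enrichment_delta
        if cohort.config
        else float("nan"),
    }
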