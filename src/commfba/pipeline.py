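"""End-to-end orchestration: simulate inputs, map, solve, test, report.

Every stage reads and writes plain-text artifacts (model JSON, FASTA, TSV)
so stages can be rerun in isolation; a manifest records the configuration,
its hash and the produced files, and reruns with the same seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    RANK_SUM_EXACT_CAP,
    SIGNED_RANK_EXACT_CAP,
    CohortResult,
    run_cohort_tests,
    tests_table,
)
from .community import ABUNDANCE_THRESHOLD
from .gem import MetabolicModel, read_model_json, write_model_json
from .io import (
    AbundanceTable,
    read_abundances,
    read_fasta,
    read_metadata,
    write_abundances,
    write_fasta,
    write_metadata,
)
from .mapping import (
    DEFAULT_MIN_COVERAGE,
    DEFAULT_MIN_IDENTITY,
    map_all,
    mapping_summary,
)
from .pfba import (
    PARSIMONY_COEF,
    CommunityLPCache,
    SampleResult,
    sample_butyrate_capacity,
)
from .simulate import SimulationConfig, make_cohort, make_species_models

logger = logging.getLogger(__name__)

LOG_FORMAT = "%(levelname)s %(name)s: %(message)s"  # no timestamps: reruns stay byte-identical


@dataclass
class PipelineConfig:
    models_dir: str = "models"
    reference_fasta: str = "references.fasta"
    otu_fasta: str = "otus.fasta"
    abundance_tsv: str = "abundances.tsv"
    metadata_tsv: str = "metadata.tsv"
    output_dir: str = "results"
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_coverage: float = DEFAULT_MIN_COVERAGE
    abundance_min: float = ABUNDANCE_THRESHOLD
    parsimony_coef: float = PARSIMONY_COEF
    rank_sum_exact_cap: int = RANK_SUM_EXACT_CAP
    signed_rank_exact_cap: int = SIGNED_RANK_EXACT_CAP
    dump_fluxes: bool = False
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        problems = []
        if not 0 <= self.min_identity <= 100:
            problems.append("min_identity outside [0, 100]")
        if not 0 <= self.min_coverage <= 100:
            problems.append("min_coverage outside [0, 100]")
        if not 0 <= self.abundance_min < 1:
            problems.append("abundance_min outside [0, 1)")
        if self.parsimony_coef < 0:
            problems.append("parsimony_coef must be >= 0")
        if problems:
            raise ValueError("invalid pipeline config: " + "; ".join(problems))
        return self


_PATH_FIELDS = {
    "models_dir",
    "reference_fasta",
    "otu_fasta",
    "abundance_tsv",
    "metadata_tsv",
    "output_dir",
}


def _manifest_config(config) -> dict:
    # paths reduced to basenames (and the output dir, which the manifest
    # sits in, omitted) so reruns into other directories stay byte-identical
    return {
        k: (Path(v).name if k in _PATH_FIELDS else v)
        for k, v in asdict(config).items()
        if k != "output_dir"
    }


def _config_hash(config) -> str:
    payload = json.dumps(_manifest_config(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _write_manifest(path: Path, config, outputs: list[str]) -> dict:
    manifest = {
        "tool": "commfba",
        "version": __version__,
        "config": _manifest_config(config),
        "config_sha256": _config_hash(config),
        "outputs": sorted(outputs),
    }
    path.write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return manifest


def simulate_inputs(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate all pipeline inputs into ``outdir`` and write a manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = make_species_models(
        config.n_species, config.fraction_producers, config.seed, config.seq_length
    )
    cohort = make_cohort(config, registry)
    models_dir = outdir / "models"
    models_dir.mkdir(exist_ok=True)
    for species_id in sorted(registry.models):
        write_model_json(registry.models[species_id], models_dir / f"{species_id}.json")
    write_fasta(registry.references, outdir / "references.fasta")
    write_fasta(cohort.otus, outdir / "otus.fasta")
    write_abundances(cohort.abundances, outdir / "abundances.tsv")
    write_metadata(cohort.metadata, outdir / "metadata.tsv")
    return _write_manifest(
        outdir / "manifest.json",
        config,
        ["models", "references.fasta", "otus.fasta", "abundances.tsv", "metadata.tsv"],
    )


def load_models(models_dir: str | Path) -> dict[str, MetabolicModel]:
    models_dir = Path(models_dir)
    if not models_dir.is_dir():
        raise FileNotFoundError(f"models directory not found: {models_dir}")
    registry = {}
    for path in sorted(models_dir.glob("*.json")):
        model = read_model_json(path)
        registry[model.species_id] = model
    if not registry:
        raise FileNotFoundError(f"no model JSON files in {models_dir}")
    return registry


def compute_sample_rates(
    table: AbundanceTable,
    registry: dict[str, MetabolicModel],
    taxon_map: dict[str, str | None] | None = None,
    abundance_min: float = ABUNDANCE_THRESHOLD,
    parsimony_coef: float = PARSIMONY_COEF,
    use_cache: bool = True,
    keep_fluxes: bool = False,
) -> list[SampleResult]:
    """Predict the butyrate production rate of every sample in the table."""
    cache = CommunityLPCache() if use_cache else None
    return [
        sample_butyrate_capacity(
            sample_id,
            table,
            registry,
            taxon_map=taxon_map,
            abundance_threshold=abundance_min,
            parsimony_coef=parsimony_coef,
            cache=cache,
            keep_fluxes=keep_fluxes,
        )
        for sample_id in table.samples()
    ]


def rates_table(results: list[SampleResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.sample_id,
                r.butyrate_rate if r.butyrate_rate is not None else float("nan"),
                r.mu,
                r.n_members,
                r.dropped_mass,
                r.status,
            )
            for r in results
        ],
        columns=["sample_id", "butyrate_rate", "mu", "n_members", "dropped_mass", "status"],
    )


def _require(path: str | Path, kind: str) -> Path:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing {kind}: {path}")
    return path


def run_pipeline(config: PipelineConfig) -> CohortResult:
    """Mapping -> per-sample pFBA -> cohort tests; writes all result tables."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter(LOG_FORMAT))
    root = logging.getLogger("commfba")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        otus = read_fasta(_require(config.otu_fasta, "OTU FASTA"))
        references = read_fasta(_require(config.reference_fasta, "reference FASTA"))
        table = read_abundances(_require(config.abundance_tsv, "abundance TSV"))
        metadata = read_metadata(_require(config.metadata_tsv, "metadata TSV"))
        registry = load_models(_require(config.models_dir, "models directory"))

        results_map = map_all(
            otus, references, config.min_identity, config.min_coverage
        )
        summary = mapping_summary(results_map)
        summary.to_csv(outdir / "mapping.tsv", sep="\t", index=False, float_format="%.6f")
        n_mapped = int((summary["status"] == "mapped").sum())
        logger.info(
            "mapping: %d/%d OTUs assigned (identity>=%.1f%%, coverage>=%.1f%%)",
            n_mapped,
            len(otus),
            config.min_identity,
            config.min_coverage,
        )
        taxon_map = {
            otu_id: res.assigned_reference for otu_id, res in results_map.items()
        }

        sample_results = compute_sample_rates(
            table,
            registry,
            taxon_map=taxon_map,
            abundance_min=config.abundance_min,
            parsimony_coef=config.parsimony_coef,
            keep_fluxes=config.dump_fluxes,
        )
        rates = rates_table(sample_results)
        rates.to_csv(outdir / "rates.tsv", sep="\t", index=False, float_format="%.12g")
        n_defined = int(rates["butyrate_rate"].notna().sum())
        logger.info(
            "rates: %d samples in = %d with rate + %d excluded; statuses: %s",
            len(sample_results),
            n_defined,
            len(sample_results) - n_defined,
            rates["status"].value_counts().to_dict(),
        )
        if config.dump_fluxes:
            flux_dir = outdir / "fluxes"
            flux_dir.mkdir(exist_ok=True)
            for r in sample_results:
                if r.fluxes is not None:
                    (flux_dir / f"{r.sample_id}.json").write_text(
                        json.dumps(r.fluxes, sort_keys=True, indent=1) + "\n"
                    )

        cohort_result = run_cohort_tests(
            sample_results,
            metadata,
            rank_sum_cap=config.rank_sum_exact_cap,
            signed_rank_cap=config.signed_rank_exact_cap,
        )
        tests_table(cohort_result).to_csv(
            outdir / "tests.tsv", sep="\t", index=False, float_format="%.12g"
        )
        cohort_result.per_sample.to_csv(
            outdir / "per_sample.tsv", sep="\t", index=False, float_format="%.12g"
        )
        for name, t in cohort_result.tests.items():
            logger.info(
                "test %s: statistic=%.6g p=%.6g n=%d (%s)",
                name,
                t.statistic,
                t.p_value,
                t.n,
                t.method,
            )
        outputs = ["mapping.tsv", "rates.tsv", "tests.tsv", "per_sample.tsv", "run.log"]
        if config.dump_fluxes:
            outputs.append("fluxes")
        _write_manifest(outdir / "manifest.json", config, outputs)
        return cohort_result
    finally:
        root.removeHandler(handler)
        handler.close()


def make_report(results_dir: str | Path) -> tuple[str, pd.DataFrame]:
    """Human-readable summary of the four tests plus a plot-ready long table."""
    results_dir = Path(results_dir)
    tests = pd.read_csv(_require(results_dir / "tests.tsv", "tests table"), sep="\t")
    per_sample = pd.read_csv(
        _require(results_dir / "per_sample.tsv", "per-sample table"), sep="\t"
    )
    lines = ["Predicted butyrate production capacity", "=" * 40]
    medians = (
        per_sample.groupby(["response_group", "visit"])["butyrate_rate"]
        .median()
        .sort_index()
    )
    for (group, visit), med in medians.items():
        n = len(
            per_sample[
                (per_sample["response_group"] == group) & (per_sample["visit"] == visit)
            ]
        )
        lines.append(f"median rate, {group:>13s} {visit}: {med:.4f} (n={n})")
    lines.append("-" * 40)
    label = {
        "rs_V1": "responders vs nonresponders at V1 (rank sum)",
        "rs_V2": "responders vs nonresponders at V2 (rank sum)",
        "sr_responders": "V1 vs V2 within responders (signed rank)",
        "sr_nonresponders": "V1 vs V2 within nonresponders (signed rank)",
    }
    for row in tests.itertuples():
        lines.append(
            f"{label.get(row.test_name, row.test_name)}: "
            f"P = {row.p_value:.4g} (n={row.n}, {row.method})"
        )
    text = "\n".join(lines) + "\n"
    (results_dir / "summary.txt").write_text(text)
    per_sample.to_csv(
        results_dir / "plot_data.tsv", sep="\t", index=False, float_format="%.12g"
    )
    return text, per_sample
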