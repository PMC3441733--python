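"""End-to-end pipeline: census -> scan -> classify -> enrich -> overlap.

The pipeline consumes a mature-miRNA catalog, optional transcript regions
and prediction lists, and one DE table per transfected miRNA, and writes
every stage's table plus a machine-readable run manifest (config echo,
input checksums, seed, package version).  Outputs are a pure function of
(inputs, config, seed): rerunning with identical inputs reproduces
identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalog import (
    SeedSpec,
    build_seed_catalog,
    census_summary,
    census_table,
    family_concordance,
)
from .enrichment import (
    PredictionSource,
    classify_de,
    enrich_experiment,
    target_set_overlap,
)
from .io import (
    assign_families,
    read_de_table,
    read_family_file,
    read_mature_fasta,
    read_predictions,
    read_regions_fasta,
    write_table,
)
from .scan import scan_transcriptome

logger = logging.getLogger("mirseed")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and modes for one pipeline run.

    ``de_tables`` maps the transfected miRNA id of each experiment to its
    DE-table path; ``prediction_files`` maps source names to pair-list
    paths.  Seed specs are (start, length) windows scanned in addition to
    any external sources.
    """

    mature_fasta: str
    de_tables: dict[str, str]
    outdir: str
    family_file: str | None = None
    utr3_fasta: str | None = None
    cds_fasta: str | None = None
    utr5_fasta: str | None = None
    prediction_files: dict[str, str] = field(default_factory=dict)
    seed_specs: list[tuple[int, int]] = field(default_factory=lambda: [(2, 6)])
    species_prefix: str | None = None
    a_min: float = 8.0
    m_cut: float = 0.5
    adjp_max: float = 0.05
    allow_wobble: bool = False
    max_wobbles: int = 1
    rng_seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat key-value config file; keyword overrides win."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.seed_specs = [tuple(s) for s in cfg.seed_specs]
        return cfg

    def validate(self) -> None:
        if not self.de_tables:
            raise ValueError("config error: at least one DE table is required")
        if not self.prediction_files and not (
            self.utr3_fasta or self.cds_fasta or self.utr5_fasta
        ):
            raise ValueError(
                "config error: need region FASTAs or a prediction file"
            )
        for p in self._input_paths():
            if not Path(p).exists():
                raise FileNotFoundError(f"config error: missing input {p}")

    def _input_paths(self) -> list[str]:
        paths = [self.mature_fasta]
        paths += [
            p for p in (self.family_file, self.utr3_fasta, self.cds_fasta,
                        self.utr5_fasta) if p
        ]
        paths += list(self.de_tables.values())
        paths += list(self.prediction_files.values())
        return paths


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the results bundle to ``outdir``.

    Returns a dict with the census summaries, enrichment tables and overlap
    tables, mirroring what is written to disk.
    """
    config.validate()
    logging.basicConfig(level=config.verbosity)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "census"
    try:
        mirnas = read_mature_fasta(config.mature_fasta, config.species_prefix)
        if not mirnas:
            logger.warning("no miRNAs after species filtering")
        if config.family_file:
            mirnas = assign_families(mirnas, read_family_file(config.family_file))
        logger.info("census: %d mature miRNAs", len(mirnas))
        results: dict = {"census": {}, "enrichment": {}, "overlap": {}}
        catalogs = {}
        for start, length in config.seed_specs:
            spec = SeedSpec(start, length)
            catalog = build_seed_catalog(mirnas, spec)
            catalogs[spec.name] = catalog
            summary = census_summary(catalog)
            results["census"][spec.name] = summary
            write_table(
                census_table(catalog), outdir / f"census_{spec.name}.tsv"
            )
            write_table(
                family_concordance(catalog),
                outdir / f"family_concordance_{spec.name}.tsv",
            )
            logger.info(
                "census %s: %d distinct, %d unique, %d shared seeds",
                spec.name, summary.n_distinct_seeds, summary.n_unique_seeds,
                summary.n_shared_seeds,
            )

        stage = "scan"
        sources: list[PredictionSource] = []
        if config.utr3_fasta or config.cds_fasta or config.utr5_fasta:
            transcripts = read_regions_fasta(
                utr3=config.utr3_fasta, cds=config.cds_fasta,
                utr5=config.utr5_fasta,
            )
            regions = tuple(
                r for r, p in (
                    ("5UTR", config.utr5_fasta), ("CDS", config.cds_fasta),
                    ("3UTR", config.utr3_fasta),
                ) if p
            )
            for start, length in config.seed_specs:
                spec = SeedSpec(start, length)
                sites, target_sets = scan_transcriptome(
                    transcripts, mirnas, spec=spec, regions=regions,
                    allow_wobble=config.allow_wobble,
                    max_wobbles=config.max_wobbles,
                )
                logger.info("scan %s: %d sites", spec.name, len(sites))
                write_table(sites, outdir / f"sites_{spec.name}.tsv")
                src = PredictionSource.from_target_sets(spec.name, target_sets)
                sources.append(src)
                write_table(
                    pd.DataFrame(
                        sorted(src.pairs),
                        columns=["mirna_id", "transcript_id"],
                    ),
                    outdir / f"predicted_pairs_{spec.name}.tsv",
                )
        for name, path in config.prediction_files.items():
            sources.append(read_predictions(path, name=name))

        stage = "enrich"
        down_sets_per_source: dict[str, dict[str, set[str]]] = {}
        for mirna_id, de_path in config.de_tables.items():
            records = read_de_table(de_path)
            declass = classify_de(
                records, a_min=config.a_min, m_cut=config.m_cut,
                adjp_max=config.adjp_max,
            )
            logger.info(
                "classify %s: universe=%d down=%d up=%d", mirna_id,
                len(declass.universe), len(declass.down), len(declass.up),
            )
            table = enrich_experiment(
                declass, sources, [m.id for m in mirnas]
            )
            results["enrichment"][mirna_id] = table
            write_table(table, outdir / f"enrichment_{mirna_id}.tsv")
            for src in sources:
                down_sets_per_source.setdefault(src.name, {})[mirna_id] = (
                    src.targets_of(mirna_id) & declass.down
                )

        stage = "overlap"
        for src_name, sets in down_sets_per_source.items():
            if len(sets) >= 2:
                table = target_set_overlap(sets)
                results["overlap"][src_name] = table
                write_table(table, outdir / f"overlap_{src_name}.tsv")

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "rng_seed": config.rng_seed,
            "config": asdict(config),
            "input_checksums": {
                p: _sha256(p) for p in sorted(config._input_paths())
            },
            "output_checksums": {
                f.name: _sha256(f)
                for f in sorted(outdir.glob("*.tsv"))
            },
        }
        (outdir / "manifest.yaml").write_text(
            yaml.safe_dump(manifest, sort_keys=True)
        )
        results["manifest"] = manifest
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
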