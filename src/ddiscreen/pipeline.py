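"""End-to-end orchestration: config, stage sequencing, reports, manifest.

``run_all`` wires the stages together in the order the method runs: expand
the query's domains into the partner set, build per-group virtual proteomes,
screen them for partner-domain carriers, partition the retained sets across
groups, tabulate and test per-domain occurrence, and run GO enrichment per
group.  Every report is a deterministic TSV (lexicographic sort), and a
machine-readable manifest records input hashes, the full configuration and
library versions; the timestamp is isolated to a single line so that reruns
are byte-identical everywhere else.

A stage failure aborts the run with a stage-named error and removes the
partial outputs written so far.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .domain_stats import (
    DF_MODES,
    build_occurrence_table,
    classify_domain_rows,
    estimate_background_rate,
    write_domain_table,
)
from .go_enrichment import enrich, parse_obo, write_enrichment_tsv
from .interaction_map import (
    ParseError,
    expand_partner_domains,
    load_s100b_interaction_map,
    load_s100b_query_hits,
    parse_hmmscan_domtblout,
    parse_interaction_table,
    query_domains_from_hits,
    write_partner_table,
)
from .virtual_proteome import (
    build_virtual_proteome,
    load_protein_table,
    load_taxa_profiles,
    partition_groups,
    partition_to_json,
    screen_interactors,
    write_partition_tsv,
    write_proteome_summary,
    write_screen_tsv,
)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    """All inputs and thresholds for one pipeline run.

    ``interactions`` and ``query_hits`` default to the packaged S100B
    fixtures when left unset; ``query_domains`` overrides the hits file with
    an explicit accession list.  ``background_mode`` selects the pooled
    estimate of the per-domain background rate or an external rate file
    (TSV: ``domain rate`` or ``domain observed size``).
    """

    proteins: str
    taxa: str
    obo: str | None = None
    interactions: str | None = None
    query_hits: str | None = None
    query_domains: tuple[str, ...] | None = None
    evalue_max: float = 0.01
    alpha_sig: float = 0.01
    ns_threshold: float = 0.5
    near_zero_min: int = 10
    df_mode: str = "k-1"
    background_mode: str = "pooled"
    background_file: str | None = None
    q_max: float = 0.01
    outdir: str = "ddiscreen_out"
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("evalue_max", "alpha_sig", "ns_threshold", "q_max"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.near_zero_min < 0:
            raise ConfigError("near_zero_min must be >= 0")
        if self.df_mode not in DF_MODES:
            raise ConfigError(f"df_mode must be one of {DF_MODES}")
        if self.background_mode not in ("pooled", "external"):
            raise ConfigError("background_mode must be 'pooled' or 'external'")
        if self.background_mode == "external" and not self.background_file:
            raise ConfigError("background_mode=external requires background_file")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "query_domains" in data and data["query_domains"] is not None:
            data = {**data, "query_domains": tuple(data["query_domains"])}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a key-value mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if d["query_domains"] is not None:
            d["query_domains"] = list(d["query_domains"])
        return d


def load_background_rates(path: str | Path) -> dict[str, float]:
    """Read an external background-rate file.

    TSV with header; either columns ``domain rate`` or
    ``domain observed size`` (rate then computed as observed/size).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    if {"domain", "rate"}.issubset(df.columns):
        return {str(r.domain): float(r.rate) for r in df.itertuples(index=False)}
    if {"domain", "observed", "size"}.issubset(df.columns):
        return {
            str(r.domain): estimate_background_rate(float(r.observed), float(r.size))
            for r in df.itertuples(index=False)
        }
    raise ParseError(
        f"background file {path}: need columns (domain, rate) or "
        "(domain, observed, size)"
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle; returns the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def _open(name: str):
        path = outdir / name
        written.append(path)
        return path.open("w", encoding="utf-8")

    try:
        # ---- stage: expand -------------------------------------------------
        stage = "expand"
        if config.interactions:
            with open(config.interactions, encoding="utf-8") as fh:
                dmap = parse_interaction_table(fh, source=config.interactions)
        else:
            dmap = load_s100b_interaction_map()
        if config.query_domains is not None:
            query_domains = set(config.query_domains)
        elif config.query_hits:
            with open(config.query_hits, encoding="utf-8") as fh:
                hits = parse_hmmscan_domtblout(fh, evalue_max=config.evalue_max)
            query_domains = query_domains_from_hits(hits)
        else:
            query_domains = query_domains_from_hits(
                load_s100b_query_hits(evalue_max=config.evalue_max)
            )
        partner_set = expand_partner_domains(query_domains, dmap)
        with _open("partner_domains.tsv") as fh:
            write_partner_table(query_domains, dmap, fh)

        # ---- stage: build-proteome ----------------------------------------
        stage = "build-proteome"
        records = load_protein_table(config.proteins)
        profiles = load_taxa_profiles(config.taxa)
        proteomes = [
            build_virtual_proteome(records, profile)
            for profile in profiles.values()
        ]

        # ---- stage: screen ---------------------------------------------
        stage = "screen"
        screens = {p.group: screen_interactors(p, partner_set) for p in proteomes}
        for group in sorted(screens):
            with _open(f"screen_{group}.tsv") as fh:
                write_screen_tsv(screens[group], fh)
        with _open("proteome_summary.tsv") as fh:
            write_proteome_summary(proteomes, screens, fh)

        # ---- stage: partition ----------------------------------------------
        stage = "partition"
        partition = partition_groups(list(screens.values()))
        with _open("partition.tsv") as fh:
            write_partition_tsv(partition, fh)
        with _open("partition.json") as fh:
            fh.write(partition_to_json(partition) + "\n")

        # ---- stage: domain-stats -------------------------------------------
        stage = "domain-stats"
        rates = None
        if config.background_mode == "external":
            rates = load_background_rates(config.background_file)
        table = build_occurrence_table(proteomes, partner_set, background_rates=rates)
        results = classify_domain_rows(
            table,
            alpha_sig=config.alpha_sig,
            ns_threshold=config.ns_threshold,
            near_zero_min=config.near_zero_min,
            df_mode=config.df_mode,
        )
        with _open("domain_tests.tsv") as fh:
            write_domain_table(results, table.groups, fh)

        # ---- stage: go-enrich ----------------------------------------------
        stage = "go-enrich"
        if config.obo:
            with open(config.obo, encoding="utf-8") as fh:
                dag = parse_obo(fh)
            for proteome in proteomes:
                rows = enrich(
                    screens[proteome.group], proteome, dag,
                    q_max=config.q_max, p_max=config.alpha_sig,
                )
                with _open(f"enrichment_{proteome.group}.tsv") as fh:
                    write_enrichment_tsv(rows, fh)

        # ---- stage: manifest -----------------------------------------------
        stage = "manifest"
        inputs = {}
        for name in ("proteins", "taxa", "obo", "interactions",
                     "query_hits", "background_file"):
            value = getattr(config, name)
            if value:
                inputs[name] = {"path": str(value), "sha256": _sha256(Path(value))}
        manifest = {
            "config": config.to_dict(),
            "inputs": inputs,
            "outputs": sorted({p.name for p in written} | {"manifest.json"}),
            "partner_set_size": len(partner_set),
            "groups": sorted(screens),
            "versions": {
                "ddiscreen": __version__,
                "python": sys.version.split()[0],
            },
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
        with _open("manifest.json") as fh:
            fh.write(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc
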