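"""End-to-end orchestration: counts -> candidates -> targets -> enrichment.

``run_all`` consumes a validated :class:`RunConfig`, executes every stage,
writes all intermediate tables to the output directory, and returns a JSON-
serializable run report whose central content is the funnel of set sizes at
each stage.  The report is deterministic: re-running with an identical
config and inputs produces byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment, io_formats, quant, seeds, selection

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "StageError", "run_all", "load_run_config"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """All inputs and parameters of one pipeline run."""

    counts_human1: Path
    counts_human2: Path
    counts_mouse: Path
    groups_human1: Path
    groups_human2: Path
    groups_mouse: Path
    mirna_fasta: Path
    ratios: Path
    targets: Path
    gene_sets: Path
    outdir: Path
    utr_fasta: Path | None = None
    thresholds: selection.SelectionThresholds = selection.SelectionThresholds()
    enrichment_cutoff: float = 0.8
    enrichment_top_n: int = 10

    def validate(self) -> None:
        for name in (
            "counts_human1", "counts_human2", "counts_mouse",
            "groups_human1", "groups_human2", "groups_mouse",
            "mirna_fasta", "ratios", "targets", "gene_sets",
        ):
            path = getattr(self, name)
            if not Path(path).is_file():
                raise ConfigError(f"{name}: no such file: {path}")
        if self.utr_fasta is not None and not Path(self.utr_fasta).is_file():
            raise ConfigError(f"utr_fasta: no such file: {self.utr_fasta}")
        if self.enrichment_cutoff <= 0:
            raise ConfigError("enrichment_cutoff must be positive")
        if self.enrichment_top_n < 1:
            raise ConfigError("enrichment_top_n must be >= 1")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a run configuration from YAML."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        inputs = raw["inputs"]
        config = RunConfig(
            counts_human1=Path(inputs["counts_human1"]),
            counts_human2=Path(inputs["counts_human2"]),
            counts_mouse=Path(inputs["counts_mouse"]),
            groups_human1=Path(inputs["groups_human1"]),
            groups_human2=Path(inputs["groups_human2"]),
            groups_mouse=Path(inputs["groups_mouse"]),
            mirna_fasta=Path(inputs["mirna_fasta"]),
            ratios=Path(inputs["ratios"]),
            targets=Path(inputs["targets"]),
            gene_sets=Path(inputs["gene_sets"]),
            utr_fasta=Path(inputs["utr_fasta"]) if inputs.get("utr_fasta") else None,
            outdir=Path(raw["outdir"]),
            thresholds=selection.SelectionThresholds(**raw.get("thresholds", {})),
            enrichment_cutoff=float(raw.get("enrichment", {}).get("cutoff", 0.8)),
            enrichment_top_n=int(raw.get("enrichment", {}).get("top_n", 10)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    config.validate()
    return config


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, str(exc)) from exc
        return wrapped
    return decorator


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write intermediates plus report.json."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "parameters": {
            "thresholds": dataclasses.asdict(config.thresholds),
            "enrichment_cutoff": config.enrichment_cutoff,
            "enrichment_top_n": config.enrichment_top_n,
        },
        "funnel": {},
    }

    # --- quantification ---------------------------------------------------
    @_stage("normalize")
    def _normalize() -> dict[str, tuple[pd.DataFrame, dict[str, str]]]:
        out = {}
        for name, counts_path, groups_path in (
            ("human1", config.counts_human1, config.groups_human1),
            ("human2", config.counts_human2, config.groups_human2),
            ("mouse", config.counts_mouse, config.groups_mouse),
        ):
            counts = io_formats.read_table(counts_path)
            rpm = quant.rpm_normalize(counts)
            io_formats.write_table(rpm, outdir / f"rpm_{name}.tsv")
            out[name] = (rpm, io_formats.read_groups(groups_path))
        return out

    rpm_tables = _normalize()

    # --- candidate cascade ------------------------------------------------
    @_stage("select_candidates")
    def _select() -> selection.CandidateReport:
        catalog = seeds.catalog_from_fasta(io_formats.read_fasta(config.mirna_fasta))
        result = selection.select_candidates(
            rpm_tables["human1"][0],
            rpm_tables["human2"][0],
            rpm_tables["mouse"][0],
            rpm_tables["human1"][1],
            rpm_tables["human2"][1],
            rpm_tables["mouse"][1],
            catalog,
            config.thresholds,
        )
        io_formats.write_table(result.flags, outdir / "selection_report.tsv")
        for name, table in result.fold_changes.items():
            io_formats.write_table(table, outdir / f"fold_changes_{name}.tsv")
        return result

    candidates = _select()
    report["funnel"].update(candidates.funnel)
    report["candidates"] = list(candidates.candidates)

    # --- per-candidate seed motifs and UTR scan ---------------------------
    @_stage("scan_utrs")
    def _scan() -> dict:
        catalog = {
            m.mirna_id: m
            for m in seeds.catalog_from_fasta(io_formats.read_fasta(config.mirna_fasta))
        }
        motifs = {
            mid: seeds.seed_match_motif(catalog[mid]) for mid in candidates.candidates
        }
        rows = []
        if config.utr_fasta is not None:
            utrs = io_formats.read_fasta(config.utr_fasta)
            for mid in candidates.candidates:
                for utr_id, seq in utrs.items():
                    rows.extend(
                        seeds.sites_to_rows(seeds.scan_utr(seq, catalog[mid], utr_id))
                    )
        frame = pd.DataFrame(rows, columns=["utr_id", "mirna_id", "start", "site_type"])
        frame.to_csv(outdir / "seed_sites.tsv", sep="\t", index=False, lineterminator="\n")
        return {"motifs": motifs, "n_sites": len(rows)}

    if candidates.candidates:
        scan_info = _scan()
        report["seed_motifs"] = scan_info["motifs"]
        report["funnel"]["n_seed_sites"] = scan_info["n_sites"]
    else:
        report["seed_motifs"] = {}
        report["skipped"] = ["scan_utrs: empty candidate set"]
        logger.info("empty candidate set: UTR scan skipped")

    # --- target analysis and enrichment -----------------------------------
    @_stage("target_enrichment")
    def _enrich() -> None:
        ratio_table = io_formats.read_table(config.ratios)
        ratio_series = ratio_table.iloc[:, 0]
        down = enrichment.filter_downregulated(ratio_series, config.enrichment_cutoff)
        with open(config.targets, encoding="utf-8") as fh:
            targets = [line.strip() for line in fh if line.strip()]
        overlap = enrichment.intersect_targets(down, targets)
        universe = set(ratio_series.index)

        with open(outdir / "downregulated.txt", "w", encoding="utf-8", newline="\n") as fh:
            fh.writelines(g + "\n" for g in sorted(down))
        with open(outdir / "intersected.txt", "w", encoding="utf-8", newline="\n") as fh:
            fh.writelines(g + "\n" for g in sorted(overlap))

        gene_sets = io_formats.read_gmt(config.gene_sets)
        results = enrichment.enrich(
            overlap, gene_sets, universe, top_n=config.enrichment_top_n
        )
        io_formats.write_table(
            enrichment.results_to_frame(results), outdir / "enrichment.tsv"
        )
        report["funnel"]["n_downregulated"] = len(down)
        report["funnel"]["n_predicted_targets"] = len(set(targets))
        report["funnel"]["n_intersected"] = len(overlap)
        report["top_terms"] = [r.term_id for r in results]

    _enrich()

    report_path = outdir / "report.json"
    with open(report_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run report written to %s", report_path)
    return report
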