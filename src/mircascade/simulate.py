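"""Seeded synthetic inputs for every pipeline stage.

Everything is a pure function of :class:`SyntheticConfig`: one global seed
fans out into independent per-generator substreams, so any piece of the
bundle can be regenerated on its own and two runs with the same config are
byte-identical.

Count tables use a Gamma-Poisson (negative binomial) model with log-normal
miRNA base abundances, per-sample library-size factors and planted
case-group fold changes.  ``nb_dispersion = 0`` is the noise-free limit:
counts are the rounded expected values, so case and control means are equal
for every non-planted miRNA.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io_formats
from .enrichment import GeneSet
from .seeds import MatureMiRNA, extract_seed, seed_match_motif

__all__ = [
    "PlantedMiRNA",
    "SyntheticConfig",
    "simulate_mature_mirnas",
    "simulate_counts",
    "simulate_utrs",
    "simulate_expression_ratios",
    "simulate_gene_sets",
    "simulate_qpcr",
    "write_bundle",
]

_STREAMS = {
    "mirnas": 0,
    "counts": 1,
    "utrs": 2,
    "ratios": 3,
    "gene_sets": 4,
    "qpcr": 5,
}

_RNA_LETTERS = np.array(list("ACGU"))


@dataclass(frozen=True)
class PlantedMiRNA:
    """A miRNA with planted log2 fold changes in the three count datasets."""

    mirna_id: str
    log2fc_human1: float
    log2fc_human2: float
    log2fc_mouse: float


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one simulated study."""

    seed: int = 0
    # count simulation
    n_mirnas: int = 300
    human1_sizes: tuple[int, int] = (6, 6)   # (cases, controls)
    human2_sizes: tuple[int, int] = (6, 7)
    mouse_sizes: tuple[int, int] = (3, 3)
    planted_mirnas: tuple[PlantedMiRNA, ...] = ()
    nb_dispersion: float = 0.1
    library_size_mean: float = 1_000_000.0
    library_size_sigma: float = 0.1          # lognormal sigma of size factors
    abundance_sigma: float = 1.0             # lognormal sigma of base abundances
    mirna_length: int = 22
    # UTR simulation
    n_utrs: int = 50
    utr_length: int = 500
    n_planted_utrs: int = 10
    # expression-ratio simulation
    n_genes: int = 2000
    n_planted_targets: int = 0
    background_ratio_sigma: float = 0.25
    planted_ratio_range: tuple[float, float] = (0.3, 0.7)
    # gene-set simulation
    n_gene_sets: int = 50
    set_size_range: tuple[int, int] = (20, 200)
    planted_term: str = "GO_PLANTED"
    planted_term_size: int = 100
    enrichment_strength: float = 0.8         # fraction of planted-term members from targets
    # qPCR simulation
    qpcr_group_sizes: tuple[int, int] = (6, 6)   # (treated, untreated)
    qpcr_mu_reference: float = 20.0
    qpcr_delta_ct_base: float = 5.0
    qpcr_sigma: float = 0.05
    qpcr_rq_fold: float = 1.0                # planted treated/untreated RQ ratio

    def __post_init__(self) -> None:
        if self.n_mirnas < len(self.planted_mirnas):
            raise ValueError("n_mirnas smaller than number of planted miRNAs")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for name in ("n_mirnas", "n_utrs", "utr_length", "n_genes", "n_gene_sets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.enrichment_strength <= 1:
            raise ValueError("enrichment_strength must be in [0, 1]")
        if self.n_planted_targets > self.n_genes:
            raise ValueError("more planted targets than genes")

    @property
    def mirna_ids(self) -> list[str]:
        planted = [p.mirna_id for p in self.planted_mirnas]
        n_background = self.n_mirnas - len(planted)
        return planted + [f"mir-{i:04d}" for i in range(n_background)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]

    @property
    def planted_target_ids(self) -> list[str]:
        return self.gene_ids[: self.n_planted_targets]


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _STREAMS[stream]])
    )


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_RNA_LETTERS, size=length))


def simulate_mature_mirnas(config: SyntheticConfig) -> list[MatureMiRNA]:
    """Random mature sequences, one per miRNA id.

    Planted miRNAs are guaranteed a seed unique in the whole catalog (they
    must survive the paralog stage); background seeds may collide with each
    other but never with a planted seed.
    """
    rng = _rng(config, "mirnas")
    planted_ids = {p.mirna_id for p in config.planted_mirnas}
    planted_seeds: set[str] = set()
    catalog: list[MatureMiRNA] = []
    background_seeds: set[str] = set()
    for mirna_id in config.mirna_ids:
        while True:
            seq = _random_rna(rng, config.mirna_length)
            seed = extract_seed(seq)
            if mirna_id in planted_ids:
                if seed not in planted_seeds and seed not in background_seeds:
                    planted_seeds.add(seed)
                    break
            elif seed not in planted_seeds:
                background_seeds.add(seed)
                break
        catalog.append(MatureMiRNA(mirna_id, seq))
    return catalog


def _planted_log2fc(config: SyntheticConfig, dataset: str) -> dict[str, float]:
    attr = {"human1": "log2fc_human1", "human2": "log2fc_human2", "mouse": "log2fc_mouse"}[dataset]
    return {p.mirna_id: getattr(p, attr) for p in config.planted_mirnas}


def simulate_counts(
    config: SyntheticConfig,
) -> dict[str, tuple[pd.DataFrame, dict[str, str]]]:
    """Three count tables with group labels: human1, human2 and mouse.

    Returns ``{dataset: (counts, {sample_id: "case"|"control"})}``.
    """
    rng = _rng(config, "counts")
    ids = config.mirna_ids
    abundance = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=config.n_mirnas)
    fractions = abundance / abundance.sum()

    datasets = {
        "human1": config.human1_sizes,
        "human2": config.human2_sizes,
        "mouse": config.mouse_sizes,
    }
    out: dict[str, tuple[pd.DataFrame, dict[str, str]]] = {}
    for name, (n_case, n_control) in datasets.items():
        log2fc = _planted_log2fc(config, name)
        effect = np.array([2.0 ** log2fc.get(mid, 0.0) for mid in ids])
        columns: dict[str, np.ndarray] = {}
        groups: dict[str, str] = {}
        for group, size in (("case", n_case), ("control", n_control)):
            for i in range(size):
                sample = f"{name}-{group}-{i + 1}"
                groups[sample] = group
                size_factor = rng.lognormal(mean=0.0, sigma=config.library_size_sigma)
                mu = fractions * config.library_size_mean * size_factor
                if group == "case":
                    mu = mu * effect
                if config.nb_dispersion == 0:
                    counts = np.rint(mu).astype(np.int64)
                else:
                    shape = 1.0 / config.nb_dispersion
                    p = shape / (shape + mu)
                    counts = rng.negative_binomial(shape, p)
                columns[sample] = counts
        table = pd.DataFrame(columns, index=pd.Index(ids, name="mirna_id"))
        out[name] = (table, groups)
    return out


def simulate_utrs(
    config: SyntheticConfig, mirna: MatureMiRNA
) -> tuple[dict[str, str], list[dict]]:
    """Random UTRs with the miRNA's seed-match heptamer planted in some.

    Returns the id->sequence mapping and a manifest of planted
    ``{"utr_id": ..., "position": ...}`` entries (position = 0-based start
    of the planted heptamer).
    """
    if config.n_planted_utrs > config.n_utrs:
        raise ValueError("more planted UTRs than UTRs")
    rng = _rng(config, "utrs")
    motif = seed_match_motif(mirna)
    if config.utr_length < len(motif):
        raise ValueError("UTR length shorter than the seed-match motif")
    utrs: dict[str, str] = {}
    manifest: list[dict] = []
    for i in range(config.n_utrs):
        utr_id = f"utr-{i:04d}"
        seq = _random_rna(rng, config.utr_length)
        if i < config.n_planted_utrs:
            pos = int(rng.integers(0, config.utr_length - len(motif) + 1))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
            manifest.append({"utr_id": utr_id, "position": pos})
        utrs[utr_id] = seq
    return utrs, manifest


def simulate_expression_ratios(config: SyntheticConfig) -> pd.Series:
    """Treated/untreated gene expression ratios with planted down-regulation.

    Background ratios are log-normal centered at 1; planted target genes get
    ratios drawn uniformly from ``planted_ratio_range`` (below the 0.8
    down-regulation cutoff by default).
    """
    rng = _rng(config, "ratios")
    ratios = rng.lognormal(mean=0.0, sigma=config.background_ratio_sigma, size=config.n_genes)
    lo, hi = config.planted_ratio_range
    if config.n_planted_targets:
        ratios[: config.n_planted_targets] = rng.uniform(lo, hi, size=config.n_planted_targets)
    series = pd.Series(ratios, index=pd.Index(config.gene_ids, name="gene_id"), name="ratio")
    return series


def simulate_gene_sets(config: SyntheticConfig) -> list[GeneSet]:
    """Random gene sets plus one planted term enriched for planted targets.

    A fraction ``enrichment_strength`` of the planted term's members is
    drawn from the planted target genes, the rest from the remaining
    universe; strength 0 makes the planted term an ordinary random set.
    """
    rng = _rng(config, "gene_sets")
    genes = np.array(config.gene_ids)
    lo, hi = config.set_size_range
    sets: list[GeneSet] = []
    for i in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        sets.append(GeneSet(f"GO_{i:04d}", f"random set {i}", tuple(sorted(members))))

    size = min(config.planted_term_size, config.n_genes)
    n_from_targets = min(
        int(round(config.enrichment_strength * size)), config.n_planted_targets
    )
    targets = np.array(config.planted_target_ids)
    rest = np.array(config.gene_ids[config.n_planted_targets:])
    members = []
    if n_from_targets:
        members.extend(rng.choice(targets, size=n_from_targets, replace=False))
    n_rest = size - n_from_targets
    if n_rest:
        pool = rest if len(rest) >= n_rest else genes
        members.extend(rng.choice(pool, size=n_rest, replace=False))
    sets.append(GeneSet(config.planted_term, "planted enriched term", tuple(sorted(set(members)))))
    return sets


def simulate_qpcr(config: SyntheticConfig) -> pd.DataFrame:
    """Ct table for a treated/untreated qPCR comparison.

    ct_reference ~ Normal(mu_reference, sigma); ct_target adds the group
    ΔCt (treated shifted by −log2 of the planted RQ fold change) plus
    independent noise.
    """
    rng = _rng(config, "qpcr")
    n_treated, n_untreated = config.qpcr_group_sizes
    shift = -np.log2(config.qpcr_rq_fold)
    rows = []
    for group, size, delta in (
        ("treated", n_treated, config.qpcr_delta_ct_base + shift),
        ("untreated", n_untreated, config.qpcr_delta_ct_base),
    ):
        for i in range(size):
            ct_ref = rng.normal(config.qpcr_mu_reference, config.qpcr_sigma)
            ct_tgt = ct_ref + delta + rng.normal(0.0, config.qpcr_sigma)
            rows.append(
                {
                    "sample_id": f"{group}-{i + 1}",
                    "group": group,
                    "ct_target": ct_tgt,
                    "ct_reference": ct_ref,
                }
            )
    return pd.DataFrame(rows)


def write_bundle(config: SyntheticConfig, outdir: str | Path) -> dict:
    """Generate the full bundle and write it as plain-text files.

    Emits count and group TSVs for the three datasets, a mature-miRNA FASTA,
    a UTR FASTA (planted against the first planted miRNA, or the first
    catalog entry), the expression-ratio TSV, a predicted-target gene list,
    a GMT file, a Ct TSV, and ``manifest.json`` recording every planted truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    catalog = simulate_mature_mirnas(config)
    io_formats.write_fasta({m.mirna_id: m.sequence for m in catalog}, outdir / "mirnas.fasta")

    counts = simulate_counts(config)
    for name, (table, groups) in counts.items():
        io_formats.write_table(table, outdir / f"counts_{name}.tsv")
        io_formats.write_groups(groups, outdir / f"groups_{name}.tsv")

    focus = catalog[0]
    utrs, utr_manifest = simulate_utrs(config, focus)
    io_formats.write_fasta(utrs, outdir / "utrs.fasta")

    ratios = simulate_expression_ratios(config)
    ratios.to_frame().to_csv(outdir / "ratios.tsv", sep="\t", lineterminator="\n")

    with open(outdir / "targets.txt", "w", encoding="utf-8", newline="\n") as fh:
        for gene in config.planted_target_ids:
            fh.write(gene + "\n")

    gene_sets = simulate_gene_sets(config)
    io_formats.write_gmt(gene_sets, outdir / "gene_sets.gmt")

    qpcr = simulate_qpcr(config)
    qpcr.to_csv(outdir / "qpcr.tsv", sep="\t", index=False, lineterminator="\n")

    manifest = {
        "config": asdict(config),
        "planted_mirnas": [asdict(p) for p in config.planted_mirnas],
        "utr_focus_mirna": focus.mirna_id,
        "planted_utr_sites": utr_manifest,
        "planted_targets": config.planted_target_ids,
        "planted_term": config.planted_term,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
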