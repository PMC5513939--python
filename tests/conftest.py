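from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mircascade.simulate import PlantedMiRNA, SyntheticConfig

RNA = "ACGU"


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RNA), size=length))


def make_rpm_table(values: dict[str, list[float]], samples: list[str]) -> pd.DataFrame:
    """Build an RPM table from {mirna_id: per-sample values}."""
    table = pd.DataFrame.from_dict(values, orient="index", columns=samples)
    table.index.name = "mirna_id"
    return table


def default_planted() -> tuple[PlantedMiRNA, ...]:
    """Four concordant planted miRNAs (two up, two down) with strong effects."""
    return (
        PlantedMiRNA("mir-planted-up1", 2.0, 2.0, 1.5),
        PlantedMiRNA("mir-planted-up2", 1.5, 2.0, 1.5),
        PlantedMiRNA("mir-planted-dn1", -2.0, -1.5, -1.5),
        PlantedMiRNA("mir-planted-dn2", -1.5, -2.0, -1.5),
    )


def random_cascade_instance(rng: np.random.Generator, n_mirnas: int, n_paralog_pairs: int = 1):
    """Random small RPM tables, group labels and catalog for oracle checks."""
    from mircascade.seeds import MatureMiRNA

    ids = [f"m{i}" for i in range(n_mirnas)]
    tables, groups = {}, {}
    for name, (n_case, n_control) in (
        ("ds1", (4, 4)),
        ("ds2", (3, 4)),
        ("mouse", (3, 3)),
    ):
        samples = [f"{name}-case-{i}" for i in range(n_case)] + [
            f"{name}-ctrl-{i}" for i in range(n_control)
        ]
        groups[name] = {s: ("case" if "case" in s else "control") for s in samples}
        values = rng.lognormal(mean=2.0, sigma=1.5, size=(n_mirnas, len(samples)))
        tables[name] = pd.DataFrame(values, index=ids, columns=samples)
    seqs = {mid: random_rna(rng, 22) for mid in ids}
    for i in range(min(n_paralog_pairs, n_mirnas // 2)):
        a, b = ids[2 * i], ids[2 * i + 1]
        seqs[b] = seqs[b][0] + seqs[a][1:8] + seqs[b][8:]
    catalog = [MatureMiRNA(mid, seqs[mid]) for mid in ids]
    return tables, groups, catalog


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def planted_config() -> SyntheticConfig:
    return SyntheticConfig(
        seed=42,
        n_mirnas=300,
        planted_mirnas=default_planted(),
        nb_dispersion=0.1,
    )


@pytest.fixture
def small_bundle_config() -> SyntheticConfig:
    """A compact bundle exercising every stage quickly."""
    return SyntheticConfig(
        seed=7,
        n_mirnas=60,
        planted_mirnas=default_planted(),
        nb_dispersion=0.05,
        n_utrs=20,
        utr_length=300,
        n_planted_utrs=5,
        n_genes=500,
        n_planted_targets=40,
        n_gene_sets=15,
        set_size_range=(10, 60),
        planted_term_size=30,
        enrichment_strength=0.8,
        qpcr_rq_fold=2.0,
    )


@pytest.fixture
def bundle_dir(tmp_path, small_bundle_config):
    from mircascade.simulate import write_bundle

    outdir = tmp_path / "bundle"
    write_bundle(small_bundle_config, outdir)
    return outdir
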