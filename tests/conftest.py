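"""Shared simulated cohorts and derived products for the test suite.

The ``study`` fixtures are the standard simulated conditions (four
20 Mb chromosomes, 10 Mb lesion-strand blocks, T-dominant damage, TCR
with saturation, translesion artefacts, NER-TRIM, a quarter of tumours
retaining both daughter lineages).  The ``twin`` cohort doubles the
symmetric arm for the shared-mutation VAF analyses, and the ``dense``
cohort is a small high-density genome used for permutation-null
calibration where pair-count statistics need large expected counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lesionseg import SimConfig, phase_cohort, simulate_cohort
from lesionseg import transcription as tx


@pytest.fixture(scope="session")
def study_cfg() -> SimConfig:
    return SimConfig(seed=7, symmetric_fraction=0.25)


@pytest.fixture(scope="session")
def cohort(study_cfg):
    return simulate_cohort(study_cfg)


@pytest.fixture(scope="session")
def phased(cohort):
    return phase_cohort(cohort.mutations, cohort.annotation.genome)


@pytest.fixture(scope="session")
def asym_phased(cohort, phased):
    return {tid: ph for tid, ph in phased.items() if not ph.symmetric}


@pytest.fixture(scope="session")
def expression(cohort, asym_phased):
    """Deduplicated genes with estimated nascent TPM plus strata."""
    ann = cohort.annotation
    intron_len = pd.Series({
        g.gene_id: sum(iv.length for iv in g.introns) for g in ann.genes
    })
    tpm = tx.nascent_tpm(ann.intron_counts, intron_len)
    genes = ann.genes
    for g in genes:
        v = tpm.get(g.gene_id, np.nan)
        if v == v:
            g.nascent_tpm = float(v)
    genes = tx.dedupe_overlapping_genes(genes)
    allm = pd.concat([ph.mutations for ph in asym_phased.values()])
    rates = {}
    for g in genes:
        n = int(((allm.chrom == g.interval.chrom) &
                 (allm.pos >= g.interval.start) &
                 (allm.pos < g.interval.end) &
                 (allm.kind == "sub")).sum())
        rates[g.gene_id] = n / (g.interval.length * len(asym_phased))
    strata = tx.strata_assign(
        pd.Series({g.gene_id: g.nascent_tpm for g in genes}),
        pd.Series(rates),
    )
    return genes, strata


@pytest.fixture(scope="session")
def twin_cfg() -> SimConfig:
    return SimConfig(seed=17, symmetric_fraction=0.5)


@pytest.fixture(scope="session")
def twin_cohort(twin_cfg):
    return simulate_cohort(twin_cfg)


@pytest.fixture(scope="session")
def twin_phased(twin_cohort):
    return phase_cohort(twin_cohort.mutations,
                        twin_cohort.annotation.genome)


@pytest.fixture(scope="session")
def twin_null_cohort(twin_cfg):
    """Twin-tumour conditions with the TRIM mechanism ablated."""
    cfg = SimConfig(**{**twin_cfg.to_dict(), "trim_rate": 0.0})
    cohort = simulate_cohort(cfg)
    return cohort, phase_cohort(cohort.mutations,
                                cohort.annotation.genome)


def dense_config(**overrides) -> SimConfig:
    """High-density small genome for permutation-null calibration."""
    base = dict(
        seed=5, n_chrom=2, chrom_length=2_000_000, block_size=500_000,
        n_tumours=8, n_genes=40, gene_min_length=5_000,
        gene_max_length=40_000, n_motifs=40,
        lesion_rate={"T": 1.2e-2, "C": 1.2e-3, "G": 3.6e-4, "A": 6e-5},
        p_cluster=0.0, p_skip_del=0.0, p_insertion=0.0, trim_rate=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def dense_null_cohort():
    return simulate_cohort(dense_config())


@pytest.fixture(scope="session")
def toy_cohort():
    cfg = SimConfig(
        seed=3, n_chrom=2, chrom_length=2_000_000, block_size=500_000,
        n_tumours=4, n_genes=40, gene_min_length=5_000,
        gene_max_length=40_000, n_motifs=40,
    )
    return simulate_cohort(cfg)
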