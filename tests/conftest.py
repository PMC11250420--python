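"""Shared builders for the test suite.

Everything is generated programmatically; no fixture files.
"""

from __future__ import annotations

import numpy as np
import pytest

from cismr import SnpAssociation, SummaryDataset
from cismr.harmonize import HarmonizedPair, harmonize_set
from cismr.instruments import InstrumentSet
from cismr.simulate import SimulationConfig, simulate_two_sample


def make_snp(
    rsid="rs1",
    chrom="16",
    pos=31_000_000,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.02,
    se=0.003,
    pvalue=1e-10,
    n=344_182,
) -> SnpAssociation:
    snp = SnpAssociation(
        rsid=rsid, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pvalue=pvalue, n=n,
    )
    snp.validate()
    return snp


def make_dataset(snps, trait="trait", build="GRCh37") -> SummaryDataset:
    return SummaryDataset(
        trait=trait, genome_build=build, ancestry="EUR",
        records={s.rsid: s for s in snps},
    )


def make_pair(
    rsid="rs1", beta_exp=0.05, se_exp=0.003, beta_out=0.025, se_out=0.004
) -> HarmonizedPair:
    return HarmonizedPair(
        rsid=rsid, beta_exp=beta_exp, se_exp=se_exp,
        beta_out=beta_out, se_out=se_out,
        eaf_exp=0.3, eaf_out=0.3, palindromic=False, action="none",
    )


def random_pairs(j, seed, theta=0.5):
    """Quick harmonized pairs with a known causal slope plus noise."""
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(j):
        bx = rng.uniform(0.02, 0.1)
        sy = rng.uniform(0.002, 0.006)
        by = theta * bx + rng.normal(0, sy)
        pairs.append(
            make_pair(rsid=f"rs{i}", beta_exp=bx, se_exp=0.002, beta_out=by, se_out=sy)
        )
    return pairs


def simulated_pairs(config: SimulationConfig):
    """Run the generator end to end through harmonization, keeping truth."""
    exposure, outcome, truth = simulate_two_sample(config)
    snps = sorted(exposure.records.values(), key=lambda s: s.pos)
    inst = InstrumentSet(exposure="sim", snps=snps, per_snp_r2={}, per_snp_f={})
    pairs, _ = harmonize_set(inst, outcome)
    return pairs, truth


@pytest.fixture
def clean_pairs():
    """Six pairs exactly on the line beta_out = 0.5 * beta_exp."""
    return [
        make_pair(rsid=f"rs{i}", beta_exp=bx, beta_out=0.5 * bx, se_out=0.004)
        for i, bx in enumerate([0.02, 0.03, 0.05, 0.06, 0.08, 0.1])
    ]
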