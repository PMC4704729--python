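"""End-to-end synthetic fixtures: a panel VCF plus a test-genome pileup.

Sites are simulated from a known demography, so the true projection of the
test genome is predictable, then dressed up as the files the read-based
pipeline consumes: a diploid panel VCF (panel lineages paired two-by-two
into individuals, genotypes phased, ancestral allele in the AA INFO tag) and
a per-read pileup for the test genome with Poisson coverage, a configurable
fraction of low-mapping-quality reads, and a configurable mixture of
transition and transversion sites.  A truth table records the simulated
derived counts and test alleles for direct comparison.

Deliberately absent from the default fixture: sequencing error and
post-mortem damage (an optional uniform base-error rate is available to
probe robustness), fragment-length structure, and reference bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .coalescent import simulate_site_arrays
from .demography import DemographicModel

__all__ = ["FixtureConfig", "FixturePaths", "generate_fixture"]

_BASES = np.array(list("ACGT"))
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION_PARTNERS = {
    "A": ["C", "T"],
    "G": ["C", "T"],
    "C": ["A", "G"],
    "T": ["A", "G"],
}


@dataclass
class FixtureConfig:
    """Generator settings.

    ``transition_fraction`` is the proportion of sites whose allele pair is a
    transition (these are exactly the sites the transversion filter must
    remove); ``mapq_low_fraction`` the proportion of reads drawn with mapping
    quality below 30 (uniform on 0..29), the rest getting ``mapq_high``;
    ``base_error`` an optional per-read probability of substituting a
    uniformly chosen different base.
    """

    model: DemographicModel
    num_sites: int
    mean_coverage: float = 10.0
    mapq_low_fraction: float = 0.1
    mapq_high: int = 60
    transition_fraction: float = 0.3
    base_error: float = 0.0
    seed: int = 0
    chrom: str = "1"

    def __post_init__(self):
        for name in ("mapq_low_fraction", "transition_fraction", "base_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.num_sites <= 0:
            raise ValueError("num_sites must be positive")


class FixturePaths(NamedTuple):
    vcf: Path
    pileup: Path
    truth: Path


def generate_fixture(config: FixtureConfig, out_prefix) -> FixturePaths:
    """Write ``<prefix>.panel.vcf``, ``<prefix>.pileup.tsv`` and
    ``<prefix>.truth.tsv``; fully deterministic given ``config.seed``."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vcf_path = Path(str(prefix) + ".panel.vcf")
    pileup_path = Path(str(prefix) + ".pileup.tsv")
    truth_path = Path(str(prefix) + ".truth.tsv")
    rng = np.random.default_rng(config.seed)
    kernel_seed = int(rng.integers(2**31))

    model = config.model if config.model.is_bound else config.model.bind()
    n_panel = model.panel_size
    if n_panel % 2 != 0:
        raise ValueError("panel lineage count must be even to form diploid individuals")
    n_ind = n_panel // 2

    derived_count, test_derived = simulate_site_arrays(
        model, config.num_sites, kernel_seed
    )
    m = config.num_sites
    pos = np.arange(1, m + 1)

    # nucleotide assignment: ancestral uniform; derived allele is the
    # transition partner for designated transition sites, else a uniformly
    # chosen transversion partner
    anc = _BASES[rng.integers(4, size=m)]
    is_transition = rng.random(m) < config.transition_fraction
    der = np.empty(m, dtype="<U1")
    for b in "ACGT":
        sel = anc == b
        der[sel & is_transition] = _TRANSITION_PARTNER[b]
        tv = rng.integers(2, size=m)
        for j, partner in enumerate(_TRANSVERSION_PARTNERS[b]):
            der[sel & ~is_transition & (tv == j)] = partner

    _write_vcf(vcf_path, config.chrom, pos, anc, der, derived_count, n_ind, rng)
    _write_pileup(pileup_path, config, pos, anc, der, test_derived, rng)

    truth = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": pos,
            "derived_count": derived_count,
            "panel_size": n_panel,
            "test_allele": np.where(test_derived == 1, "derived", "ancestral"),
            "ancestral": anc,
            "derived": der,
            "is_transition": is_transition,
        }
    )
    truth.to_csv(truth_path, sep="\t", index=False)

    return FixturePaths(vcf_path, pileup_path, truth_path)


def _write_vcf(path, chrom, pos, anc, der, derived_count, n_ind, rng):
    """Minimal valid VCF 4.2: REF = ancestral, ALT = derived, AA INFO tag,
    phased GT for n_ind diploid individuals.

    Given the panel derived count i at a site, the derived alleles are
    scattered over a uniformly random subset of i of the 2*n_ind lineages
    (exchangeability makes this distributionally exact); lineages 2j and
    2j+1 form individual j.
    """
    m = len(pos)
    n_lin = 2 * n_ind
    gt_lookup = np.array(["0|0", "0|1", "1|0", "1|1"])
    samples = [f"ind{j + 1}" for j in range(n_ind)]

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        chunk = 20_000
        for lo in range(0, m, chunk):
            hi = min(lo + chunk, m)
            k = hi - lo
            # rank < derived_count marks derived lineages, ranks uniform
            u = rng.random((k, n_lin))
            ranks = u.argsort(axis=1).argsort(axis=1)
            alleles = ranks < derived_count[lo:hi, None]
            codes = 2 * alleles[:, 0::2] + alleles[:, 1::2]
            gt = gt_lookup[codes]
            lines = []
            for r in range(k):
                i = lo + r
                lines.append(
                    f"{chrom}\t{pos[i]}\t.\t{anc[i]}\t{der[i]}\t.\t.\tAA={anc[i]}\tGT\t"
                    + "\t".join(gt[r])
                )
            fh.write("\n".join(lines) + "\n")


def _write_pileup(path, config, pos, anc, der, test_derived, rng):
    depth = rng.poisson(config.mean_coverage, size=len(pos))
    total = int(depth.sum())
    read_pos = np.repeat(pos, depth)
    true_base = np.where(test_derived == 1, der, anc)
    base = np.repeat(true_base, depth).astype("<U1")

    if config.base_error > 0:
        err = rng.random(total) < config.base_error
        if err.any():
            # substitute a uniformly chosen different base
            shift = rng.integers(1, 4, size=int(err.sum()))
            idx = np.searchsorted(_BASES, base[err])
            base[err] = _BASES[(idx + shift) % 4]

    low = rng.random(total) < config.mapq_low_fraction
    mapq = np.where(low, rng.integers(0, 30, size=total), config.mapq_high)

    pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": read_pos,
            "base": base,
            "mapping_quality": mapq,
        }
    ).to_csv(path, sep="\t", index=False)
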