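"""Site-level input for read-based projection analysis.

The real-data path of projection analysis needs two inputs: a reference
panel (a VCF with genotypes and an ancestral-allele INFO tag, from which the
per-site derived-allele frequency is computed) and the test genome as raw
reads (a per-site pileup table), because low-coverage ancient genomes cannot
be genotyped reliably.  The test genome is represented pseudo-haploidly: one
read is drawn uniformly at random per site and its allele taken at face
value.

Site filters applied here:

* biallelic SNPs only;
* transversions only (transitions are confounded by post-mortem cytosine
  deamination in ancient DNA);
* reads with mapping quality below 30 are discarded before the random draw
  (a per-site mean-MQ alternative is available via ``mapq_mode``);
* per-site coverage must fall inside the central 2.5%–97.5% interval of the
  sample's own coverage distribution;
* the ancestral allele must be known and match one of the two alleles.

Coordinates are 1-based throughout (VCF convention); inputs are assumed
reference-strand oriented and base qualities are not filtered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReadObservation",
    "PanelSite",
    "SiteObservation",
    "CoverageProfile",
    "read_panel",
    "read_pileup",
    "parse_mpileup",
    "is_transversion",
    "coverage_bounds",
    "call_test_genome",
    "build_observations",
    "observations_to_frame",
]

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")
_TRANSITIONS = ({"A", "G"}, {"C", "T"})

#: mapping-quality threshold: reads with MQ < 30 are discarded (MQ = 30 survives)
DEFAULT_MIN_MAPQ = 30


class ReadObservation(NamedTuple):
    """One sequencing read overlapping a site."""

    base: str
    mapping_quality: int


@dataclass(frozen=True)
class PanelSite:
    """One biallelic panel site with its derived-allele count.

    ``derived_count`` is the number of panel chromosomes carrying the
    non-ancestral allele; ``panel_size`` the number of called chromosomes.
    ``ancestral_allele`` is None when the annotation was absent, ambiguous,
    or matched neither allele (flagged ``no_ancestral`` downstream).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ancestral_allele: str | None
    derived_count: int
    panel_size: int

    def __post_init__(self):
        if not (0 <= self.derived_count <= self.panel_size):
            raise ValueError(
                f"{self.chrom}:{self.pos}: derived count {self.derived_count} "
                f"outside [0, {self.panel_size}]"
            )

    @property
    def derived_allele(self) -> str | None:
        if self.ancestral_allele is None:
            return None
        return self.alt_allele if self.ancestral_allele == self.ref_allele else self.ref_allele


@dataclass(frozen=True)
class SiteObservation:
    panel: PanelSite
    test_call: str  # "derived" | "ancestral" | "missing"
    coverage: int
    filter_reasons: frozenset = frozenset()

    @property
    def pass_filters(self) -> bool:
        return not self.filter_reasons


@dataclass(frozen=True)
class CoverageProfile:
    """Per-sample coverage histogram with its central-interval cutoffs."""

    histogram: dict
    min_cov: int
    max_cov: int

    @classmethod
    def from_depths(cls, depths: Iterable[int]) -> "CoverageProfile":
        hist: dict = {}
        for d in depths:
            hist[int(d)] = hist.get(int(d), 0) + 1
        lo, hi = coverage_bounds(hist)
        return cls(hist, lo, hi)


# ----------------------------------------------------------------------
# elementary operations
# ----------------------------------------------------------------------
def is_transversion(ancestral: str, derived: str) -> bool:
    """True unless the pair is a transition (A<->G or C<->T)."""
    a, d = ancestral.upper(), derived.upper()
    if a not in NUCLEOTIDES or d not in NUCLEOTIDES:
        raise ValueError(f"not nucleotides: {ancestral!r}, {derived!r}")
    if a == d:
        raise ValueError("ancestral and derived alleles are identical")
    return {a, d} not in _TRANSITIONS


def coverage_bounds(histogram: Mapping[int, int]) -> tuple[int, int]:
    """Central 2.5%–97.5% interval of a coverage histogram, rounded inward.

    Returns the largest ``min_cov`` with at most 2.5% of mass strictly below
    it and the smallest ``max_cov`` with at most 2.5% strictly above it; the
    interval is inclusive and always retains at least 95% of the mass.
    """
    total = sum(histogram.values())
    if total <= 0:
        raise ValueError("empty coverage histogram")
    values = sorted(histogram)
    below = 0
    min_cov = values[0]
    for v in values:
        if below / total <= 0.025:
            min_cov = v
        else:
            break
        below += histogram[v]
    above = 0
    max_cov = values[-1]
    for v in reversed(values):
        if above / total <= 0.025:
            max_cov = v
        else:
            break
        above += histogram[v]
    return min_cov, max_cov


def call_test_genome(
    reads: Sequence[ReadObservation],
    site: PanelSite,
    rng: np.random.Generator,
    min_cov: int | None = None,
    max_cov: int | None = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    mapq_mode: str = "per_read",
) -> SiteObservation:
    """Pseudo-haploid call: draw one read uniformly from the survivors.

    Reads failing the mapping-quality threshold or carrying a third allele
    are removed before the draw (``mapq_mode="per_read"``); with
    ``mapq_mode="site_mean"`` the site is instead filtered when the mean MQ
    over its reads falls below the threshold.  Degenerate inputs yield a
    missing/filtered observation, never an exception.
    """
    reasons = set()
    coverage = len(reads)
    if site.ancestral_allele is None:
        reasons.add("no_ancestral")
        # transversion status judged on the ref/alt pair regardless
    if not is_transversion(site.ref_allele, site.alt_allele):
        reasons.add("not_transversion")
    if min_cov is not None and max_cov is not None:
        if not (min_cov <= coverage <= max_cov):
            reasons.add("coverage_out_of_range")

    alleles = {site.ref_allele, site.alt_allele}
    if mapq_mode == "per_read":
        survivors = [
            r for r in reads if r.mapping_quality >= min_mapq and r.base in alleles
        ]
    elif mapq_mode == "site_mean":
        if reads and np.mean([r.mapping_quality for r in reads]) < min_mapq:
            reasons.add("low_mapq")
        survivors = [r for r in reads if r.base in alleles]
    else:
        raise ValueError(f"unknown mapq_mode {mapq_mode!r}")

    if not survivors:
        reasons.add("no_reads")
        return SiteObservation(site, "missing", coverage, frozenset(reasons))

    pick = survivors[int(rng.integers(len(survivors)))]
    derived = site.derived_allele
    if derived is None:
        # unknown ancestral allele: polarise against ALT as a placeholder;
        # the site carries no_ancestral and is never used downstream
        derived = site.alt_allele
    call = "derived" if pick.base == derived else "ancestral"
    return SiteObservation(site, call, coverage, frozenset(reasons))


# ----------------------------------------------------------------------
# file readers
# ----------------------------------------------------------------------
def read_panel(
    variant_file,
    aa_tag: str = "AA",
    allow_lowercase: bool = False,
) -> list:
    """Read a panel VCF into :class:`PanelSite` records.

    Only biallelic SNP rows are used; multi-allelic and non-SNP rows are
    skipped with a logged count.  The ancestral allele is taken from the
    ``aa_tag`` INFO field (first ``|``-separated token, 1000 Genomes style);
    lowercase (low-confidence) calls are rejected unless ``allow_lowercase``.
    The derived count is the number of non-ancestral alleles over all called
    genotypes, and the panel size the number of called chromosomes.
    """
    from cyvcf2 import VCF

    sites = []
    skipped = 0
    vcf = VCF(str(variant_file), gts012=True)
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            skipped += 1
            continue
        ref, alt = v.REF.upper(), v.ALT[0].upper()
        raw = v.INFO.get(aa_tag)
        anc = None
        if raw is not None:
            token = str(raw).split("|")[0].strip()
            if len(token) == 1 and (token.isupper() or allow_lowercase):
                token = token.upper()
                if token in (ref, alt):
                    anc = token
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = v.gt_types
        unknown = int(np.sum(gt == 3))
        called = 2 * (len(gt) - unknown)
        alt_count = int(np.sum(gt == 1) + 2 * np.sum(gt == 2))
        if anc is None:
            derived_count = alt_count  # placeholder; site will be flagged
        elif anc == ref:
            derived_count = alt_count
        else:
            derived_count = called - alt_count
        sites.append(
            PanelSite(v.CHROM, v.POS, ref, alt, anc, derived_count, called)
        )
    if skipped:
        logger.info("read_panel: skipped %d non-biallelic/non-SNP rows", skipped)
    return sites


def read_pileup(path) -> dict:
    """Read the tab-separated per-read table (chrom, pos, base,
    mapping_quality; one row per read) into a dict keyed by (chrom, pos)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "pos": int, "base": str, "mapping_quality": int},
    )
    missing = {"chrom", "pos", "base", "mapping_quality"} - set(df.columns)
    if missing:
        raise ValueError(f"pileup table lacks columns: {sorted(missing)}")
    out: dict = {}
    for chrom, pos, base, mq in zip(
        df["chrom"], df["pos"], df["base"], df["mapping_quality"]
    ):
        out.setdefault((chrom, int(pos)), []).append(
            ReadObservation(base.upper(), int(mq))
        )
    return out


def parse_mpileup(path, default_mapq: int = DEFAULT_MIN_MAPQ) -> dict:
    """Parse a samtools-mpileup text stream (documented subset).

    Supported columns: chrom, pos, ref, depth, read bases, base qualities and
    optionally a seventh per-read mapping-quality column (``samtools mpileup
    -s``, ASCII offset 33).  Handled base-string features: ``.``/``,`` (ref
    match), explicit bases, ``^X`` read starts, ``$`` read ends, ``*``/``#``
    deletions and ``+N``/``-N`` indel insertions (skipped).  Without the MQ
    column every read is assigned ``default_mapq``.
    """
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise ValueError(f"mpileup parse error at line {lineno}: too few columns")
            chrom, pos, ref = parts[0], int(parts[1]), parts[2].upper()
            bases = parts[4]
            mqs = parts[6] if len(parts) >= 7 else None
            reads = []
            i = 0
            while i < len(bases):
                c = bases[i]
                if c == "^":
                    i += 2
                    continue
                if c == "$":
                    i += 1
                    continue
                if c in "+-":
                    i += 1
                    num = ""
                    while i < len(bases) and bases[i].isdigit():
                        num += bases[i]
                        i += 1
                    i += int(num)
                    continue
                if c in ".,":
                    reads.append(ref)
                elif c.upper() in NUCLEOTIDES:
                    reads.append(c.upper())
                # '*', '#', '<', '>' and anything else: no usable base
                i += 1
            if mqs is not None and len(mqs) != len(reads):
                raise ValueError(
                    f"mpileup parse error at line {lineno}: mapping-quality string "
                    f"length {len(mqs)} != {len(reads)} reads"
                )
            obs = [
                ReadObservation(
                    b, ord(mqs[j]) - 33 if mqs is not None else default_mapq
                )
                for j, b in enumerate(reads)
            ]
            out.setdefault((chrom, pos), []).extend(obs)
    return out


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------
def build_observations(
    panel_sites: Sequence[PanelSite],
    reads_by_site: Mapping,
    rng: np.random.Generator,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    mapq_mode: str = "per_read",
) -> list:
    """Call every panel site against the pileup and apply all filters.

    Coverage cutoffs are the empirical 2.5%/97.5% quantiles of the raw depth
    distribution over all pileup sites with at least one read, computed
    before any other filter.
    """
    profile = CoverageProfile.from_depths(
        len(reads) for reads in reads_by_site.values() if reads
    )
    out = []
    for site in panel_sites:
        reads = reads_by_site.get((site.chrom, site.pos), [])
        out.append(
            call_test_genome(
                reads,
                site,
                rng,
                min_cov=profile.min_cov,
                max_cov=profile.max_cov,
                min_mapq=min_mapq,
                mapq_mode=mapq_mode,
            )
        )
    return out


def observations_to_frame(observations: Sequence[SiteObservation]) -> pd.DataFrame:
    """Tidy per-site table (chrom, pos, derived_count, panel_size, test_call,
    pass_filters, filter_reasons)."""
    return pd.DataFrame(
        {
            "chrom": [o.panel.chrom for o in observations],
            "pos": [o.panel.pos for o in observations],
            "derived_count": [o.panel.derived_count for o in observations],
            "panel_size": [o.panel.panel_size for o in observations],
            "test_call": [o.test_call for o in observations],
            "pass_filters": [o.pass_filters for o in observations],
            "filter_reasons": [
                ",".join(sorted(o.filter_reasons)) for o in observations
            ],
        }
    )
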