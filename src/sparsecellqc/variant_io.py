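"""Reading, writing and filtering of single-sample variant tables.

The package works on a narrow VCF dialect: single-sample VCF v4.2 records
with FORMAT fields GT, AD (ref,alt depths), DP and PL (phred-scaled
genotype likelihoods).  This module converts between that dialect and the
in-memory :class:`AssayReplicate` container, applies the standard
filters of the downstream analyses (PASS status, coding regions, read
depth), and derives the per-site quantities everything else consumes:
the variant allele frequency (VAF) and the genotype-likelihood
probability ``P = 10^(-PL/10)``.

Conventions: VCF positions are 1-based; BED intervals are 0-based
half-open.  The conversion between the two happens only inside
:meth:`RegionSet.contains`.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field, replace

import numpy as np
from cyvcf2 import VCF

from .errors import UndefinedStatisticError

logger = logging.getLogger(__name__)

GENOTYPE_CLASSES = ("hom_ref", "het", "hom_alt")

_CHROM_TOKEN = re.compile(r"(\d+)")


def chrom_sort_key(label: str):
    """Natural sort key for chromosome labels (chr2 < chr10 < chrX)."""
    parts = _CHROM_TOKEN.split(label)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True)
class VariantCall:
    """One non-reference VCF record from a single amplified sample."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype_class: str
    ref_depth: int
    alt_depth: int
    total_depth: int
    pl: tuple[int, int, int]
    filter_status: str = "PASS"

    def __post_init__(self):
        if self.genotype_class not in GENOTYPE_CLASSES:
            raise ValueError(f"unknown genotype class {self.genotype_class!r}")
        if self.ref_depth < 0 or self.alt_depth < 0 or self.total_depth < 0:
            raise ValueError("depths must be non-negative")
        if self.ref_depth + self.alt_depth > self.total_depth:
            raise ValueError(
                f"AD sum {self.ref_depth + self.alt_depth} exceeds DP "
                f"{self.total_depth} at {self.chrom}:{self.pos}"
            )
        if len(self.pl) != 3 or min(self.pl) != 0 or any(p < 0 for p in self.pl):
            raise ValueError(f"PL must be three non-negative values with min 0, got {self.pl}")

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_pass(self) -> bool:
        return self.filter_status == "PASS"


def vaf(call: VariantCall) -> float:
    """Variant allele frequency: alt depth over total allelic depth.

    Raises :class:`UndefinedStatisticError` when both allelic depths are
    zero — the VAF is undefined there, not 0.
    """
    denom = call.ref_depth + call.alt_depth
    if denom == 0:
        raise UndefinedStatisticError(
            f"VAF undefined at {call.chrom}:{call.pos}: zero allelic depth"
        )
    return call.alt_depth / denom


def pl_to_prob(pl_component: float) -> float:
    """Convert one phred-scaled genotype likelihood to a probability.

    ``P = 10^(-PL/10)``; PL 0 maps to probability 1.
    """
    if pl_component < 0:
        raise ValueError(f"PL must be non-negative, got {pl_component}")
    return 10.0 ** (-pl_component / 10.0)


@dataclass
class AssayReplicate:
    """All calls from one amplified sample.

    ``calls`` is kept sorted by (chromosome, position) with unique
    (chrom, pos, ref, alt) keys.  ``cell_count`` may be None for VCFs of
    unknown provenance.
    """

    sample_id: str
    cell_count: int | None
    replicate_index: int
    calls: list[VariantCall] = field(default_factory=list)

    def __post_init__(self):
        self.calls = sorted(self.calls, key=lambda c: (chrom_sort_key(c.chrom), c.pos))
        keys = [c.key for c in self.calls]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate variant keys in replicate {self.sample_id}")
        self._by_site = {c.site: c for c in self.calls}

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    @property
    def sites(self) -> set[tuple[str, int]]:
        return set(self._by_site)

    def at(self, chrom: str, pos: int) -> VariantCall | None:
        return self._by_site.get((chrom, pos))

    def subset(self, keep) -> "AssayReplicate":
        """New replicate retaining calls for which ``keep(call)`` is true."""
        return replace(self, calls=[c for c in self.calls if keep(c)])

    def chromosomes(self) -> list[str]:
        seen = dict.fromkeys(c.chrom for c in self.calls)
        return list(seen)


@dataclass
class RegionSet:
    """Half-open genomic intervals in BED convention (0-based start)."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        self.intervals = {c: _merge(ivs) for c, ivs in self.intervals.items()}
        self._starts = {c: [s for s, _ in ivs] for c, ivs in self.intervals.items()}

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        ivs: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                ivs.setdefault(chrom, []).append((int(start), int(end)))
        return cls(ivs)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals, key=chrom_sort_key):
                for s, e in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    def contains(self, chrom: str, pos: int) -> bool:
        """True if the 1-based VCF position falls in a region."""
        ivs = self.intervals.get(chrom)
        if not ivs:
            return False
        p0 = pos - 1  # 1-based VCF -> 0-based BED
        i = bisect_right(self._starts[chrom], p0) - 1
        return i >= 0 and p0 < ivs[i][1]


def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# filters


def filter_pass(rep: AssayReplicate) -> AssayReplicate:
    """Retain only FILTER=PASS calls, preserving order."""
    out = rep.subset(lambda c: c.is_pass)
    logger.info("filter_pass %s: %d -> %d records", rep.sample_id, len(rep), len(out))
    return out


def filter_depth(rep: AssayReplicate, min_depth: int = 30) -> AssayReplicate:
    """Retain calls with total read depth (DP) >= ``min_depth`` (inclusive)."""
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    out = rep.subset(lambda c: c.total_depth >= min_depth)
    logger.info("filter_depth>=%d %s: %d -> %d records", min_depth, rep.sample_id, len(rep), len(out))
    return out


def restrict_to_regions(rep: AssayReplicate, regions: RegionSet) -> AssayReplicate:
    """Retain calls whose position falls inside the region set.

    Calls on chromosomes absent from ``regions`` are dropped.
    """
    out = rep.subset(lambda c: regions.contains(c.chrom, c.pos))
    logger.info("restrict_to_regions %s: %d -> %d records", rep.sample_id, len(rep), len(out))
    return out


# ---------------------------------------------------------------------------
# VCF I/O

_GT_BY_CLASS = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1"}
_CLASS_BY_NALT = {0: "hom_ref", 1: "het", 2: "hom_alt"}


def write_vcf(
    rep: AssayReplicate,
    path,
    contigs: list[str] | None = None,
) -> None:
    """Write a replicate as a minimal single-sample VCF v4.2 file.

    Cell count and replicate index are recorded in custom header lines so
    that :func:`read_vcf` round-trips them.
    """
    if contigs is None:
        contigs = rep.chromosomes()
    lines = [
        "##fileformat=VCFv4.2",
        "##source=sparsecellqc",
        f"##cell_count={rep.cell_count if rep.cell_count is not None else '.'}",
        f"##replicate_index={rep.replicate_index}",
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [
        '##FILTER=<ID=PASS,Description="All filters passed">',
        '##FILTER=<ID=LowQual,Description="Low quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{rep.sample_id}",
    ]
    for c in rep.calls:
        gt = _GT_BY_CLASS[c.genotype_class]
        sample = f"{gt}:{c.ref_depth},{c.alt_depth}:{c.total_depth}:{','.join(map(str, c.pl))}"
        lines.append(
            f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t{c.filter_status}\t.\tGT:AD:DP:PL\t{sample}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path, multiallelic: str = "skip") -> AssayReplicate:
    """Read a single-sample VCF into an :class:`AssayReplicate`.

    Records missing GT/AD/DP/PL are skipped with a warning.  Multi-allelic
    records are skipped by default (``multiallelic="skip"``); pass
    ``"error"`` to reject the file instead.
    """
    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise ValueError(f"{path}: expected exactly one sample, found {len(vcf.samples)}")
    sample_id = vcf.samples[0]

    cell_count: int | None = None
    replicate_index = 0
    for line in vcf.raw_header.splitlines():
        if line.startswith("##cell_count=") and not line.endswith("."):
            cell_count = int(line.split("=", 1)[1])
        elif line.startswith("##replicate_index="):
            replicate_index = int(line.split("=", 1)[1])

    calls: list[VariantCall] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            if multiallelic == "error":
                raise ValueError(f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS}")
            n_skipped += 1
            continue
        try:
            ad = rec.format("AD")
            dp = rec.format("DP")
            pl = rec.format("PL")
            if ad is None or dp is None or pl is None:
                raise KeyError("missing FORMAT field")
            n_alt = sum(1 for a in rec.genotypes[0][:-1] if a == 1)
            gt_class = _CLASS_BY_NALT[n_alt]
            call = VariantCall(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                genotype_class=gt_class,
                ref_depth=int(ad[0][0]),
                alt_depth=int(ad[0][1]),
                total_depth=int(dp[0][0]) if np.ndim(dp) > 1 else int(dp[0]),
                pl=tuple(int(p) for p in pl[0][:3]),
                filter_status=rec.FILTER or "PASS",
            )
        except (KeyError, ValueError, IndexError) as exc:
            logger.warning("%s: skipping record %s:%s (%s)", path, rec.CHROM, rec.POS, exc)
            n_skipped += 1
            continue
        calls.append(call)
    logger.info("read_vcf %s: %d records kept, %d skipped", path, len(calls), n_skipped)
    return AssayReplicate(
        sample_id=sample_id,
        cell_count=cell_count,
        replicate_index=replicate_index,
        calls=calls,
    )
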