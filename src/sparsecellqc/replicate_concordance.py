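"""Reproducibility of replicate WGA assays.

Replicates amplified from distinct aliquots of the same cell population
should call identical variants.  This module quantifies how far they do
not: per-site mismatch classification (loss of heterozygosity, allele
change, total dropout), the mismatch fraction as a function of cell
input with an exponential fit, rank correlation of genotype-likelihood
probabilities between assays, STR dropout scoring from peak heights, and
variant-set overlap against an external reference list.

The comparison universe for SNV mismatch is the union of non-reference
calls of the two replicates: a site called in only one replicate counts
as total dropout.  Homozygous-reference calls never enter the universe
(single-sample VCFs do not emit them).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.stats import spearmanr

from .errors import FitConvergenceError, UndefinedStatisticError
from .synthetic_data import STRObservation
from .variant_io import AssayReplicate, VariantCall, pl_to_prob


class SitePairClass(enum.Enum):
    CONCORDANT = "concordant"
    LOH = "loh"
    ALLELE_CHANGE = "allele_change"
    TOTAL_DROPOUT = "total_dropout"


MISMATCH_CLASSES = (SitePairClass.LOH, SitePairClass.ALLELE_CHANGE, SitePairClass.TOTAL_DROPOUT)


def classify_site_pair(
    call_a: VariantCall | None, call_b: VariantCall | None
) -> SitePairClass:
    """Classify one site of the comparison universe.

    Same genotype class and alternate allele -> concordant; het in one
    replicate, homozygous-alt in the other (same allele) -> LoH;
    different alternate alleles -> allele change; called in only one
    replicate -> total dropout.
    """
    if call_a is None and call_b is None:
        raise ValueError("site absent from both replicates is not in the universe")
    if call_a is None or call_b is None:
        return SitePairClass.TOTAL_DROPOUT
    if call_a.site != call_b.site:
        raise ValueError(f"site mismatch: {call_a.site} vs {call_b.site}")
    if call_a.alt != call_b.alt:
        return SitePairClass.ALLELE_CHANGE
    if call_a.genotype_class == call_b.genotype_class:
        return SitePairClass.CONCORDANT
    return SitePairClass.LOH


@dataclass
class MismatchSummary:
    """Per-pair replicate discordance, by class."""

    cell_count: int | None
    n_sites_considered: int
    counts: dict[SitePairClass, int]
    # one-sided dropout counts, for the directional view
    dropout_only_a: int = 0
    dropout_only_b: int = 0

    @property
    def mismatch_fraction(self) -> float:
        return sum(self.counts[c] for c in MISMATCH_CLASSES) / self.n_sites_considered

    def as_dict(self) -> dict:
        d = {
            "cell_count": self.cell_count,
            "n_sites": self.n_sites_considered,
            "mismatch_fraction": self.mismatch_fraction,
            "dropout_only_a": self.dropout_only_a,
            "dropout_only_b": self.dropout_only_b,
        }
        d.update({c.value: self.counts[c] for c in SitePairClass})
        return d


def mismatch_fraction(
    rep_a: AssayReplicate, rep_b: AssayReplicate, snv_only: bool = True
) -> MismatchSummary:
    """Classify every site in the union of the two replicates' calls.

    Indels pass through I/O but are excluded from the SNV mismatch
    statistic by default.
    """
    def eligible(rep):
        return {c.site: c for c in rep if (c.is_snv or not snv_only)}

    a, b = eligible(rep_a), eligible(rep_b)
    universe = set(a) | set(b)
    if not universe:
        raise UndefinedStatisticError("empty comparison universe: mismatch fraction undefined")
    counts = {c: 0 for c in SitePairClass}
    only_a = only_b = 0
    for site in universe:
        cls = classify_site_pair(a.get(site), b.get(site))
        counts[cls] += 1
        if cls is SitePairClass.TOTAL_DROPOUT:
            if site in a:
                only_a += 1
            else:
                only_b += 1
    cc = rep_a.cell_count if rep_a.cell_count == rep_b.cell_count else None
    return MismatchSummary(
        cell_count=cc,
        n_sites_considered=len(universe),
        counts=counts,
        dropout_only_a=only_a,
        dropout_only_b=only_b,
    )


def mismatch_curve(
    pairs: list[tuple[AssayReplicate, AssayReplicate]], snv_only: bool = True
) -> list[tuple[int, float]]:
    """Mean mismatch fraction per cell count, sorted by cell count.

    Multiple pairs at the same cell count are averaged.
    """
    by_count: dict[int, list[float]] = {}
    for rep_a, rep_b in pairs:
        if rep_a.cell_count != rep_b.cell_count:
            raise ValueError(
                f"pair with differing cell counts: {rep_a.cell_count} vs {rep_b.cell_count}"
            )
        s = mismatch_fraction(rep_a, rep_b, snv_only=snv_only)
        by_count.setdefault(rep_a.cell_count, []).append(s.mismatch_fraction)
    if len(by_count) < 2:
        raise ValueError("need >= 2 distinct cell counts for a curve")
    return [(cc, float(np.mean(v))) for cc, v in sorted(by_count.items())]


@dataclass
class ExponentialFit:
    """Least-squares fit of y = a*exp(-b*x) + c with a, b, c >= 0."""

    amplitude: float
    decay_rate: float
    floor: float
    rss: float
    r_squared: float
    points: list[tuple[float, float]] = field(default_factory=list)

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.amplitude * np.exp(-self.decay_rate * x) + self.floor


def fit_exponential(points: list[tuple[float, float]]) -> ExponentialFit:
    """Fit the decaying-exponential mismatch model to (cell_count, fraction).

    The non-negativity constraints keep the fitted curve non-increasing
    with a non-negative plateau.  Raises
    :class:`FitConvergenceError` with solver diagnostics on failure.
    """
    if len(points) < 3:
        raise ValueError("need >= 3 points to fit a 3-parameter model")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)

    c0 = max(float(y.min()), 1e-9)
    a0 = max(float(y.max() - y.min()), 1e-9)
    # crude initial decay from the two extreme x values
    span = y.max() - y.min()
    b0 = 1.0 / max(x.mean(), 1e-9) if span > 0 else 1e-3

    def model(x, a, b, c):
        return a * np.exp(-b * x) + c

    try:
        import warnings

        with warnings.catch_warnings():
            # an exact 3-point fit has a degenerate covariance; only the
            # parameter estimates are used here
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                model, x, y, p0=(a0, b0, c0),
                bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
    except (RuntimeError, ValueError) as exc:
        raise FitConvergenceError(
            f"exponential fit did not converge: {exc}",
            diagnostics={"x": x.tolist(), "y": y.tolist(), "p0": (a0, b0, c0)},
        ) from exc
    resid = y - model(x, *popt)
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-12 else 0.0)
    return ExponentialFit(
        amplitude=float(popt[0]), decay_rate=float(popt[1]), floor=float(popt[2]),
        rss=rss, r_squared=r2, points=list(zip(x.tolist(), y.tolist())),
    )


def genotype_likelihood_correlation(
    rep_a: AssayReplicate, rep_b: AssayReplicate
) -> tuple[float, int]:
    """Spearman correlation of het-genotype likelihood probabilities.

    For every variant key shared by the two replicates, the het PL
    component is converted to a probability (10^(-PL/10)) in each, and
    the rank correlation of the two probability vectors is returned with
    the number of shared sites.  Ties get average ranks.
    """
    a = {c.key: c for c in rep_a}
    b = {c.key: c for c in rep_b}
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise UndefinedStatisticError(
            f"only {len(shared)} shared sites; correlation undefined"
        )
    pa = [pl_to_prob(a[k].pl[1]) for k in shared]
    pb = [pl_to_prob(b[k].pl[1]) for k in shared]
    rho = spearmanr(pa, pb).statistic
    return float(rho), len(shared)


# ---------------------------------------------------------------------------
# STR dropout scoring


class STRStatus(enum.Enum):
    CONCORDANT = "concordant"
    FULL_DROPOUT = "full_dropout"
    COMPLETE_LOH = "complete_loh"
    PARTIAL_DROPOUT = "partial_dropout"


@dataclass
class STRComparison:
    locus: str
    status: STRStatus
    heights: tuple[float, float]


def compare_str(
    reference: list[STRObservation],
    observed: list[STRObservation],
    imbalance_ratio_threshold: float = 3.0,
) -> tuple[list[STRComparison], int]:
    """Score an observed STR panel against the bulk reference.

    Heterozygous loci (per the reference) are classified as full dropout
    (both peaks absent), complete LoH (exactly one of the two peaks
    absent), or partial dropout (both peaks present but their height
    ratio exceeds the threshold).  Homozygous loci can only drop out
    entirely — one allele cannot lose heterozygosity.  Returns the
    per-locus comparisons and the count of non-concordant loci.
    """
    ref_by_locus = {r.locus: r for r in reference}
    obs_by_locus = {o.locus: o for o in observed}
    if set(ref_by_locus) != set(obs_by_locus):
        raise ValueError(
            "locus panels differ: "
            f"{sorted(set(ref_by_locus) ^ set(obs_by_locus))}"
        )
    out = []
    affected = 0
    for locus in ref_by_locus:
        ref, obs = ref_by_locus[locus], obs_by_locus[locus]
        h1, h2 = obs.height1, obs.height2
        if ref.heterozygous:
            if h1 == 0 and h2 == 0:
                status = STRStatus.FULL_DROPOUT
            elif h1 == 0 or h2 == 0:
                status = STRStatus.COMPLETE_LOH
            elif max(h1, h2) / min(h1, h2) > imbalance_ratio_threshold:
                status = STRStatus.PARTIAL_DROPOUT
            else:
                status = STRStatus.CONCORDANT
        else:
            status = STRStatus.FULL_DROPOUT if (h1 + h2) == 0 else STRStatus.CONCORDANT
        if status is not STRStatus.CONCORDANT:
            affected += 1
        out.append(STRComparison(locus, status, (h1, h2)))
    return out, affected


# ---------------------------------------------------------------------------
# variant-set overlap


@dataclass
class OverlapResult:
    replicate_id: str
    reference_size: int
    intersection: int

    @property
    def overlap_fraction(self) -> float:
        return self.intersection / self.reference_size


def variant_set_overlap(
    rep: AssayReplicate, reference_variants
) -> OverlapResult:
    """Fraction of a reference variant list recovered by the replicate.

    ``reference_variants`` is an iterable of (chrom, pos, ref, alt) keys.
    """
    ref_keys = set(tuple(k) for k in reference_variants)
    if not ref_keys:
        raise UndefinedStatisticError("empty reference list: overlap undefined")
    rep_keys = {c.key for c in rep}
    return OverlapResult(
        replicate_id=rep.sample_id,
        reference_size=len(ref_keys),
        intersection=len(ref_keys & rep_keys),
    )


def read_reference_variants(path) -> list[tuple[str, int, str, str]]:
    """Read a reference variant list from 4-column TSV or VCF."""
    keys = []
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.startswith("##fileformat=VCF"):
            from .variant_io import read_vcf

            return [c.key for c in read_vcf(path)]
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            chrom, pos, ref, alt = line.split("\t")[:4]
            keys.append((chrom, int(pos), ref, alt))
    return keys
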