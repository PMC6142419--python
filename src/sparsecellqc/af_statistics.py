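"""Signal-to-noise of heterozygous allele frequencies.

A heterozygous SNV in a diploid region has a true allele frequency of
one-half; the dispersion of observed het VAFs around it measures the
noise added by amplification and sequencing.  On chromosomes free of
copy-number alteration the signal-to-noise ratio is defined as
SNR = mu/sigma of the het VAF sample — the reciprocal of the
coefficient of variation — and grows with cell input, approximately
log-linearly.  Normality of the het VAF distribution (Anderson–Darling)
indicates bulk-like data quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import anderson, linregress

from .errors import UndefinedStatisticError
from .variant_io import AssayReplicate, vaf

#: scipy's anderson() significance levels, in percent
_AD_LEVELS = (15.0, 10.0, 5.0, 2.5, 1.0)


@dataclass
class HetAFStats:
    chromosomes: tuple[str, ...]
    n: int
    mean: float
    std: float
    anderson_darling_statistic: float | None = None
    normality_pass: bool | None = None

    @property
    def snr(self) -> float:
        if self.std == 0:
            raise UndefinedStatisticError("sigma = 0: SNR undefined")
        return self.mean / self.std

    @property
    def cv(self) -> float:
        if self.mean == 0:
            raise UndefinedStatisticError("mu = 0: CV undefined")
        return self.std / self.mean

    def as_dict(self) -> dict:
        return {
            "chromosomes": ",".join(self.chromosomes),
            "n": self.n,
            "mean": self.mean,
            "std": self.std,
            "snr": self.snr,
            "cv": self.cv,
            "ad_statistic": self.anderson_darling_statistic,
            "normality_pass": self.normality_pass,
        }


def het_af_values(
    rep: AssayReplicate,
    chromosomes,
    min_depth: int = 30,
) -> np.ndarray:
    """Het-genotype VAFs on the named chromosomes, depth-filtered, in order."""
    chromset = set(chromosomes)
    vals = [
        vaf(c)
        for c in rep
        if c.chrom in chromset
        and c.genotype_class == "het"
        and c.total_depth >= min_depth
        and (c.ref_depth + c.alt_depth) > 0
    ]
    return np.array(vals, dtype=float)


def compute_snr(values, chromosomes=()) -> HetAFStats:
    """Mean, sample s.d. (n-1), SNR and CV of a het VAF sample."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise UndefinedStatisticError(f"need >= 2 values for sigma, got {values.size}")
    mean = float(values.mean())
    std = float(values.std(ddof=1))
    stats = HetAFStats(tuple(chromosomes), int(values.size), mean, std)
    if std == 0:
        # mean/std is undefined; the object still carries mu and sigma,
        # and .snr raises on access
        return stats
    return stats


def test_normality(values, alpha: float = 0.05) -> tuple[float, bool]:
    """Anderson–Darling test for normality with estimated parameters.

    Returns (statistic, pass) where pass means the statistic is below
    the critical value at the given significance level.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 8:
        raise UndefinedStatisticError(f"need >= 8 values for normality test, got {values.size}")
    if np.ptp(values) == 0:
        raise UndefinedStatisticError("constant sample: normality test degenerate")
    level = alpha * 100.0
    if level not in _AD_LEVELS:
        raise ValueError(f"alpha must be one of {[l / 100 for l in _AD_LEVELS]}")
    import warnings

    with warnings.catch_warnings():
        # scipy >= 1.17 pre-announces an API change for anderson(); the
        # critical-value interface used here is still the current one
        warnings.simplefilter("ignore", FutureWarning)
        res = anderson(values, dist="norm")
    crit = res.critical_values[_AD_LEVELS.index(level)]
    return float(res.statistic), bool(res.statistic < crit)


@dataclass
class SNRTrend:
    points: list[tuple[int, float]]
    slope: float
    intercept: float
    r_squared: float

    @property
    def snr_ratio_extremes(self) -> float:
        """SNR at the largest cell count over SNR at the smallest."""
        pts = sorted(self.points)
        lo = np.mean([s for c, s in pts if c == pts[0][0]])
        hi = np.mean([s for c, s in pts if c == pts[-1][0]])
        return float(hi / lo)

    def predict(self, cell_count):
        return self.slope * np.log(np.asarray(cell_count, dtype=float)) + self.intercept


def snr_trend(points: list[tuple[int, float]]) -> SNRTrend:
    """Ordinary least squares of SNR against ln(cell count).

    ``points`` are (cell_count, SNR) pairs; replicate SNRs at the same
    cell count may repeat.  Requires >= 3 distinct cell counts.
    """
    counts = sorted({c for c, _ in points})
    if len(counts) < 3:
        raise ValueError(f"need >= 3 distinct cell counts, got {len(counts)}")
    x = np.log([c for c, _ in points])
    y = np.array([s for _, s in points], dtype=float)
    res = linregress(x, y)
    return SNRTrend(
        points=sorted(points),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
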