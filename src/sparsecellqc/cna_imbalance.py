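"""Copy-number alteration detection from allelic imbalance.

Without a paired normal sample, read-depth ratios are unavailable and
copy-number events must be read from the B-allele frequency structure
alone.  A trisomy shifts heterozygous VAFs from 1/2 to 1/3 and 2/3
(a trimodal density once homozygous-alt calls at ~1 are included); a
single-copy loss or copy-neutral LoH removes heterozygous sites
entirely, depleting mid-range VAFs.  The detection pipeline is:

1. per-chromosome VAF series (depth >= 30, optionally averaged over two
   replicates at shared sites);
2. mirroring: VAFs below 0.5 are folded to 1 - VAF, pooling the
   symmetric imbalance signal;
3. running median over a neighborhood of +/-100 variants (windows
   truncated at chromosome ends, never crossing a chromosome);
4. Gaussian kernel density estimation with Silverman's-rule bandwidth
   h = (4 sigma^5 / 3n)^(1/5) and prominence-based mode counting;
5. windowed thresholding of the filtered tracks against the noise level
   measured on user-designated CNA-free chromosomes.

Allele frequencies cannot distinguish a one-copy loss from copy-neutral
LoH, so both are reported as a single ``loss_or_cnloh`` class.

Note the median-filter neighborhood is a *radius*: range 100 means a
201-variant window.  A consequence — documented rather than patched —
is that a deletion spanning fewer than ~100 variants cannot form a
majority of any window and is smoothed away: a known false negative of
the noise-reduction step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import UndefinedStatisticError
from .variant_io import AssayReplicate, vaf

#: s.d. of a sample median relative to sigma/sqrt(n), for normal data
_MEDIAN_EFFICIENCY = float(np.sqrt(np.pi / 2.0))


@dataclass
class VAFSeries:
    """Ordered per-chromosome VAF track."""

    chrom: str
    positions: np.ndarray
    values: np.ndarray
    replicate_mean: bool = False

    def __post_init__(self):
        self.positions = np.asarray(self.positions)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.size != self.values.size:
            raise ValueError("positions and values differ in length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"positions not strictly increasing on {self.chrom}")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("VAF values outside [0, 1]")

    def __len__(self):
        return int(self.values.size)


def chrom_vaf_series(
    replicates,
    chrom: str,
    min_depth: int = 30,
    use_replicate_mean: bool = False,
    het_only: bool = False,
) -> VAFSeries:
    """Depth-filtered VAFs on one chromosome, in positional order.

    ``replicates`` is one :class:`AssayReplicate` or a pair.  With
    ``use_replicate_mean``, sites shared by both replicates contribute
    the mean of their two VAFs; unshared sites contribute their single
    VAF.  ``het_only`` restricts to het-genotype calls (the gain track).
    """
    if isinstance(replicates, AssayReplicate):
        replicates = [replicates]
    if use_replicate_mean and len(replicates) < 2:
        raise ValueError("use_replicate_mean requires two replicates")

    def qualifying(rep):
        return {
            c.site: vaf(c)
            for c in rep
            if c.chrom == chrom
            and c.total_depth >= min_depth
            and (c.ref_depth + c.alt_depth) > 0
            and (c.genotype_class == "het" or not het_only)
        }

    maps = [qualifying(r) for r in replicates]
    if use_replicate_mean:
        sites = sorted(set(maps[0]) | set(maps[1]), key=lambda s: s[1])
        vals = [float(np.mean([m[s] for m in maps if s in m])) for s in sites]
    else:
        merged: dict = {}
        for m in maps:
            merged.update(m)
        sites = sorted(merged, key=lambda s: s[1])
        vals = [merged[s] for s in sites]
    if not sites:
        raise UndefinedStatisticError(f"no qualifying VAFs on {chrom}")
    return VAFSeries(
        chrom=chrom,
        positions=np.array([p for _, p in sites]),
        values=np.array(vals),
        replicate_mean=use_replicate_mean,
    )


def mirror_af(values) -> np.ndarray:
    """Fold VAFs below 0.5 to the equal distance above (1 - v)."""
    values = np.asarray(values, dtype=float)
    if values.size and (values.min() < 0 or values.max() > 1):
        raise ValueError("VAF values outside [0, 1] cannot be mirrored")
    return np.where(values < 0.5, 1.0 - values, values)


def median_filter(values, radius: int = 100) -> np.ndarray:
    """Running median over a neighborhood of ``radius`` variants each side.

    The window at position i is values[max(0, i-radius) : i+radius+1] —
    truncated (shrinking) at the series ends, so output length equals
    input length and chromosome boundaries are never crossed.  A series
    shorter than the window reduces to the whole-series median
    everywhere.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot median-filter an empty series")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    n = values.size
    if n <= radius + 1:
        return np.full(n, np.median(values))
    out = np.empty(n)
    # interior windows all have full width 2r+1: vectorise them
    width = 2 * radius + 1
    if n >= width:
        windows = np.lib.stride_tricks.sliding_window_view(values, width)
        out[radius : n - radius] = np.median(windows, axis=1)
        edge = radius
    else:
        edge = n  # every window is truncated
    for i in range(min(edge, n)):
        out[i] = np.median(values[max(0, i - radius) : i + radius + 1])
    for i in range(max(n - radius, 0), n):
        out[i] = np.median(values[max(0, i - radius) : i + radius + 1])
    return out


def silverman_bandwidth(values) -> float:
    """Silverman's-rule KDE bandwidth h = (4 sigma^5 / 3n)^(1/5).

    sigma is the sample (n-1) standard deviation.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 values for a bandwidth")
    sigma = float(values.std(ddof=1))
    if sigma == 0:
        raise ValueError("zero variance: Silverman bandwidth undefined")
    n = values.size
    return float((4.0 * sigma**5 / (3.0 * n)) ** 0.2)


@dataclass
class KDEProfile:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    peak_scaled: bool = False
    modes: np.ndarray | None = None

    @property
    def mode_count(self) -> int:
        return 0 if self.modes is None else int(self.modes.size)


def kde(
    values,
    bandwidth: float | None = None,
    grid: np.ndarray | None = None,
    peak_scaled: bool = False,
) -> KDEProfile:
    """Gaussian kernel density estimate on a fixed grid.

    density(x) = (1 / n h) * sum_i phi((x - v_i) / h) with phi the
    standard normal density.  ``peak_scaled`` divides by the maximum so
    the highest peak equals 1 (for relative display); the raw density is
    what integrates to 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot estimate a density from no values")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(values)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - values[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (values.size * bandwidth * np.sqrt(2 * np.pi))
    if peak_scaled:
        dens = dens / dens.max()
    return KDEProfile(grid=grid, density=dens, bandwidth=float(bandwidth), peak_scaled=peak_scaled)


def default_grid(n_points: int = 512, margin: float = 0.1) -> np.ndarray:
    """Evaluation grid over [-margin, 1+margin]."""
    return np.linspace(-margin, 1.0 + margin, n_points)


def detect_modes(profile: KDEProfile, prominence_fraction: float = 0.1) -> KDEProfile:
    """Locate density modes: local maxima with prominence above a
    fraction of the global maximum.  Returns the profile with ``modes``
    filled in (grid locations of the modes).
    """
    if profile.grid.size < 64:
        raise ValueError("mode detection needs a grid of >= 64 points")
    prom = prominence_fraction * float(profile.density.max())
    peaks, _ = find_peaks(profile.density, prominence=prom)
    profile.modes = profile.grid[peaks]
    return profile


# ---------------------------------------------------------------------------
# segment calling


@dataclass
class CNAConfig:
    """Tunables of the imbalance caller; all thresholds config-exposed."""

    min_depth: int = 30
    filter_radius: int = 100
    window: int = 100  # variants per calling window
    stride: int = 50
    gain_multiplier: float = 2.5  # multiples of the window-median s.d.
    loss_level: float = 0.9  # filtered mirrored level implying loss
    mid_band: tuple[float, float] = (0.2, 0.8)
    mid_floor: float = 0.1  # raw mid-band fraction below which hets are depleted
    prominence_fraction: float = 0.1
    min_het_series: int = 20  # fewer het calls -> gain analysis skipped


@dataclass
class CNACall:
    chrom: str
    start_pos: int
    end_pos: int
    call: str  # "gain" | "loss_or_cnloh"
    n_variants: int
    evidence: dict = field(default_factory=dict)


def neutral_noise(
    replicates, neutral_chromosomes, min_depth: int = 30,
    use_replicate_mean: bool = False,
) -> tuple[float, float]:
    """Folded het-VAF level and spread on CNA-free chromosomes.

    Returns (median, sigma) of the mirrored het VAFs pooled across the
    designated neutral chromosomes — the sample's own noise floor, to
    which gain thresholds are tied.  Must be computed with the same
    replicate-averaging as the tracks it calibrates.
    """
    vals = []
    for chrom in neutral_chromosomes:
        try:
            s = chrom_vaf_series(
                replicates, chrom, min_depth=min_depth, het_only=True,
                use_replicate_mean=use_replicate_mean,
            )
        except UndefinedStatisticError:
            continue
        vals.append(mirror_af(s.values))
    if not vals:
        raise UndefinedStatisticError("no het VAFs on the designated neutral chromosomes")
    pooled = np.concatenate(vals)
    if pooled.size < 2:
        raise UndefinedStatisticError("too few neutral het VAFs for a noise estimate")
    return float(np.median(pooled)), float(pooled.std(ddof=1))


def _windows(n: int, window: int, stride: int):
    if n <= window:
        yield 0, n
        return
    start = 0
    while start < n:
        end = min(start + window, n)
        yield start, end
        if end == n:
            break
        start += stride


def _merge_windows(flags: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(flags):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def call_segments(
    replicates,
    chromosomes,
    neutral_chromosomes,
    config: CNAConfig | None = None,
    use_replicate_mean: bool | None = None,
) -> list[CNACall]:
    """Call gain and loss/CN-LoH segments from allelic imbalance.

    Gains: the mirrored, median-filtered *het* VAF track, in sliding
    windows, exceeds the neutral folded level by ``gain_multiplier``
    times the sampling s.d. of a window median
    (sqrt(pi/2) * sigma_neutral / sqrt(2*radius+1)).  KDE mode structure
    of the chromosome is attached as corroborating evidence.

    Losses / CN-LoH: the mirrored, median-filtered *all-call* track is
    near 1 (>= ``loss_level``) AND raw mid-range VAFs ([0.2, 0.8]) are
    depleted below ``mid_floor`` in the same window — heterozygous sites
    have vanished rather than merely wandered.

    Windows failing both criteria are neutral (no call emitted).
    """
    cfg = config or CNAConfig()
    if use_replicate_mean is None:
        use_replicate_mean = not isinstance(replicates, AssayReplicate) and len(replicates) > 1
    m_neutral, sigma_neutral = neutral_noise(
        replicates, neutral_chromosomes, min_depth=cfg.min_depth,
        use_replicate_mean=use_replicate_mean,
    )
    width = 2 * cfg.filter_radius + 1
    gain_threshold = m_neutral + cfg.gain_multiplier * _MEDIAN_EFFICIENCY * sigma_neutral / np.sqrt(width)

    calls: list[CNACall] = []
    for chrom in chromosomes:
        try:
            all_series = chrom_vaf_series(
                replicates, chrom, min_depth=cfg.min_depth,
                use_replicate_mean=use_replicate_mean, het_only=False,
            )
        except UndefinedStatisticError:
            continue
        filtered_all = median_filter(mirror_af(all_series.values), radius=cfg.filter_radius)

        # ---- gain track (het calls only)
        gain_windows = []
        gain_evidence = {}
        try:
            het_series = chrom_vaf_series(
                replicates, chrom, min_depth=cfg.min_depth,
                use_replicate_mean=use_replicate_mean, het_only=True,
            )
        except UndefinedStatisticError:
            het_series = None
        if het_series is not None and len(het_series) >= cfg.min_het_series:
            filtered_het = median_filter(mirror_af(het_series.values), radius=cfg.filter_radius)
            profile = detect_modes(
                kde(all_series.values), prominence_fraction=cfg.prominence_fraction
            )
            gain_evidence = {
                "gain_threshold": float(gain_threshold),
                "neutral_level": m_neutral,
                "mode_count": profile.mode_count,
                "mode_locations": None if profile.modes is None else profile.modes.tolist(),
            }
            for s, e in _windows(len(het_series), cfg.window, cfg.stride):
                if float(filtered_het[s:e].mean()) >= gain_threshold:
                    gain_windows.append((s, e))
            for s, e in _merge_windows(gain_windows):
                calls.append(
                    CNACall(
                        chrom=chrom,
                        start_pos=int(het_series.positions[s]),
                        end_pos=int(het_series.positions[e - 1]),
                        call="gain",
                        n_variants=e - s,
                        evidence={
                            **gain_evidence,
                            "filtered_level": float(filtered_het[s:e].mean()),
                        },
                    )
                )

        # ---- loss / CN-LoH track (all calls)
        loss_windows = []
        raw = all_series.values
        lo, hi = cfg.mid_band
        for s, e in _windows(len(all_series), cfg.window, cfg.stride):
            mid_fraction = float(np.mean((raw[s:e] >= lo) & (raw[s:e] <= hi)))
            if float(filtered_all[s:e].mean()) >= cfg.loss_level and mid_fraction <= cfg.mid_floor:
                loss_windows.append((s, e))
        for s, e in _merge_windows(loss_windows):
            seg = slice(s, e)
            calls.append(
                CNACall(
                    chrom=chrom,
                    start_pos=int(all_series.positions[s]),
                    end_pos=int(all_series.positions[e - 1]),
                    call="loss_or_cnloh",
                    n_variants=e - s,
                    evidence={
                        "filtered_level": float(filtered_all[seg].mean()),
                        "mid_fraction": float(
                            np.mean((raw[seg] >= lo) & (raw[seg] <= hi))
                        ),
                        "loss_level": cfg.loss_level,
                    },
                )
            )
    return calls


def calls_on(calls: list[CNACall], chrom: str, call_type: str | None = None) -> list[CNACall]:
    """Convenience filter over a call list."""
    return [
        c for c in calls
        if c.chrom == chrom and (call_type is None or c.call == call_type)
    ]
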