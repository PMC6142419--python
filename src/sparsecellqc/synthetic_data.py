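"""Forward simulation of sparse-cell MDA + exome sequencing.

No raw data is deposited for the study design this package targets, so the
simulator is the fixture factory for every downstream analysis.  It emulates
the statistical structure of multiple-displacement-amplified (MDA) DNA from
1–50 cells of a leukemic cell line with a complex karyotype, sequenced to a
theoretical mean depth of ~90x:

* a diploid genome with a configurable set of heterozygous and
  homozygous-alt SNV sites per chromosome, driver mutations that are always
  heterozygous, and copy-number segments (gain 3 copies at 2:1 allele
  ratio, single-copy loss, and copy-neutral LoH);
* cell-count-dependent allele dropout: each input cell contributes one
  template molecule per haplotype copy, each template seeds amplification
  with probability ``template_survival``;
* heavy-tailed amplification bias: surviving templates draw independent
  Gamma-distributed yields, so few-cell assays show broad allelic
  imbalance while many-cell assays concentrate around the true allele
  ratio;
* negative-binomial total depth and binomial allele sampling with a small
  per-read miscall rate;
* genotype calls and phred-scaled genotype likelihoods (PL) computed from
  the binomial likelihoods of the three diploid genotypes, min-normalised
  to 0, matching the standard caller convention.

Sites whose templates all fail amplification are omitted from the output
(not emitted as missing genotypes), as are sites called homozygous
reference — single-sample variant files only carry non-reference calls.

A 21-locus STR panel (18 heterozygous) is simulated with the same
template-survival/gain mechanism, yielding electrophoresis-like peak
heights for dropout scoring.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import binom

from .errors import ConfigError
from .variant_io import AssayReplicate, RegionSet, VariantCall, write_vcf

COPY_STATES = ("neutral", "gain", "loss", "cn_loh")

# (alt haplotype copies, ref haplotype copies) per state for a het site,
# before random phase assignment for gains/losses.
_BASES = "ACGT"


@dataclass(frozen=True)
class CNASegmentTruth:
    """A copy-number segment in variant-index space (half-open)."""

    chrom: str
    start: int
    end: int
    state: str

    def __post_init__(self):
        if self.state not in COPY_STATES:
            raise ConfigError(f"unknown copy state {self.state!r}")
        if not (0 <= self.start < self.end):
            raise ConfigError(f"bad segment bounds [{self.start},{self.end}) on {self.chrom}")


@dataclass(frozen=True)
class STRLocus:
    locus: str
    allele1_len: int
    allele2_len: int

    @property
    def heterozygous(self) -> bool:
        return self.allele1_len != self.allele2_len


@dataclass(frozen=True)
class STRObservation:
    """One simulated fragment-analysis readout: two peak heights."""

    locus: str
    allele1_len: int
    allele2_len: int
    height1: float
    height2: float

    @property
    def heterozygous(self) -> bool:
        return self.allele1_len != self.allele2_len


@dataclass
class GroundTruthGenome:
    """Per-site truth for the simulated cell line.

    ``alt_copies``/``tot_copies`` give, for every variant site, how many of
    the local chromosome copies carry the alternate allele — this encodes
    both the cell line's het/hom-alt zygosity and the karyotype.  Sites
    with ``alt_copies == 0`` (het sites whose alt haplotype was lost) are
    invisible to sequencing and exist only as truth records.
    """

    chromosomes: list[tuple[str, int]]
    positions: dict[str, np.ndarray]
    refs: dict[str, np.ndarray]
    alts: dict[str, np.ndarray]
    alt_copies: dict[str, np.ndarray]
    tot_copies: dict[str, np.ndarray]
    hom_alt_fraction: float
    driver_sites: dict[str, tuple[str, int]]
    cna_segments: list[CNASegmentTruth]
    str_loci: list[STRLocus]

    def n_sites(self) -> int:
        return sum(n for _, n in self.chromosomes)

    def copy_state(self, chrom: str, index: int) -> str:
        for seg in self.cna_segments:
            if seg.chrom == chrom and seg.start <= index < seg.end:
                return seg.state
        return "neutral"

    def state_array(self, chrom: str) -> np.ndarray:
        n = dict(self.chromosomes)[chrom]
        states = np.array(["neutral"] * n, dtype=object)
        for seg in self.cna_segments:
            if seg.chrom == chrom:
                states[seg.start : seg.end] = seg.state
        return states

    def truth_genotype(self, chrom: str, index: int) -> str:
        a, t = self.alt_copies[chrom][index], self.tot_copies[chrom][index]
        if a == 0:
            return "hom_ref"
        if a == t:
            return "hom_alt"
        return "het"

    def coding_regions(self, pad: int = 50) -> RegionSet:
        """Target/coding regions: a small window around every truth site.

        Mirrors an exome capture design where true variants sit on
        target; simulated false positives are placed off target.
        """
        ivs = {
            chrom: [(max(0, int(p) - 1 - pad), int(p) + pad) for p in pos]
            for chrom, pos in self.positions.items()
        }
        return RegionSet(ivs)

    def neutral_chromosomes(self) -> list[str]:
        affected = {seg.chrom for seg in self.cna_segments if seg.state != "neutral"}
        return [c for c, _ in self.chromosomes if c not in affected]


@dataclass(frozen=True)
class AmplificationModel:
    """Noise model for MDA + sequencing.

    Parameters
    ----------
    template_survival:
        Probability in (0, 1] that one template molecule seeds
        amplification.  Drives cell-count-dependent allele dropout.
    gain_shape:
        Shape of the per-template Gamma yield (scale 1).  Small values
        give heavy-tailed yields and broad single-cell allelic imbalance.
    sequencing_error:
        Per-read miscall probability.
    mean_depth:
        Target mean total depth of coverage.
    depth_dispersion:
        Negative-binomial size parameter; smaller = more overdispersed.
    false_positive_rate:
        Expected number of spurious (amplification-artifact) variant
        calls per assay, as a fraction of the genome's true site count.
        Spurious calls are placed outside the coding/target regions.
    """

    template_survival: float = 0.85
    gain_shape: float = 0.35
    sequencing_error: float = 0.002
    mean_depth: float = 90.0
    depth_dispersion: float = 3.0
    false_positive_rate: float = 0.0

    def __post_init__(self):
        if not (0 < self.template_survival <= 1):
            raise ConfigError("template_survival must be in (0, 1]")
        if not (0 <= self.sequencing_error <= 1):
            raise ConfigError("sequencing_error must be in [0, 1]")
        if self.gain_shape <= 0 or self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ConfigError("gain_shape, mean_depth and depth_dispersion must be > 0")
        if self.false_positive_rate < 0:
            raise ConfigError("false_positive_rate must be >= 0")


def _default_chromosomes() -> list[tuple[str, int]]:
    return [
        ("chr1", 600),
        ("chr2", 500),
        ("chr3", 500),
        ("chr5", 400),
        ("chr8", 400),
        ("chr13", 300),
        ("chr17", 350),
        ("chr19", 400),
    ]


def _default_cna_segments() -> list[CNASegmentTruth]:
    """Karyotype emulating a hyperdiploid AML cell line.

    Large p-arm loss and q-arm gain on chr1, whole-chromosome gains of
    chr5 and chr8 (trisomies), a small (<100 sites) interstitial loss on
    chr13, a partial q gain on chr17 and a copy-neutral LoH of 19q.
    chr2 and chr3 stay fully neutral.
    """
    return [
        CNASegmentTruth("chr1", 0, 240, "loss"),
        CNASegmentTruth("chr1", 300, 600, "gain"),
        CNASegmentTruth("chr5", 0, 400, "gain"),
        CNASegmentTruth("chr8", 0, 400, "gain"),
        CNASegmentTruth("chr13", 120, 200, "loss"),
        CNASegmentTruth("chr17", 150, 350, "gain"),
        CNASegmentTruth("chr19", 150, 400, "cn_loh"),
    ]


def _default_drivers() -> dict[str, tuple[str, int]]:
    # chromosome, variant index; all on locally diploid ground
    return {
        "DNMT3A_R882C": ("chr2", 120),
        "NPM1_W288fs": ("chr5", 200),
        "NRAS_Q61L": ("chr1", 270),
    }


def _default_str_loci(rng: np.random.Generator) -> list[STRLocus]:
    loci = []
    for i in range(21):
        a = int(rng.integers(8, 20))
        if i < 18:  # heterozygous loci
            b = a + int(rng.integers(1, 5))
        else:
            b = a
        loci.append(STRLocus(f"STR{i + 1:02d}", a, b))
    return loci


@dataclass
class GenomeSpec:
    """Declarative input to :func:`build_genome`."""

    chromosomes: list[tuple[str, int]] = field(default_factory=_default_chromosomes)
    cna_segments: list[CNASegmentTruth] = field(default_factory=_default_cna_segments)
    hom_alt_fraction: float = 0.25
    driver_sites: dict[str, tuple[str, int]] = field(default_factory=_default_drivers)
    position_spacing: int = 3000


def build_genome(spec: GenomeSpec | None = None, seed: int = 0) -> GroundTruthGenome:
    """Materialise a ground-truth genome from a spec, deterministically.

    Zygosity, gain phases and the haplotype retained in loss/CN-LoH
    segments are drawn once here, so the same (spec, seed) always yields
    the identical genome.
    """
    if spec is None:
        spec = GenomeSpec()
    if any(n < 0 for _, n in spec.chromosomes):
        raise ConfigError("site counts must be >= 0")
    chrom_sizes = dict(spec.chromosomes)
    for seg in spec.cna_segments:
        if seg.chrom not in chrom_sizes:
            raise ConfigError(f"segment on unknown chromosome {seg.chrom}")
        if seg.end > chrom_sizes[seg.chrom]:
            raise ConfigError(f"segment {seg} exceeds chromosome site count")
    by_chrom: dict[str, list[CNASegmentTruth]] = {}
    for seg in spec.cna_segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ConfigError(f"overlapping CNA segments on {chrom}: {a} and {b}")

    rng = np.random.default_rng(seed)
    positions, refs, alts, alt_copies, tot_copies = {}, {}, {}, {}, {}
    driver_lookup = {
        (chrom, idx): name for name, (chrom, idx) in spec.driver_sites.items()
    }
    for chrom, n in spec.chromosomes:
        gaps = rng.integers(spec.position_spacing // 2, spec.position_spacing * 2, size=n)
        pos = np.cumsum(gaps) + 1
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        hom_alt = rng.random(n) < spec.hom_alt_fraction

        states = np.array(["neutral"] * n, dtype=object)
        for seg in by_chrom.get(chrom, []):
            states[seg.start : seg.end] = seg.state

        a = np.ones(n, dtype=int)  # alt haplotype copies
        t = np.full(n, 2, dtype=int)  # total copies
        phase = rng.random(n)  # which haplotype is duplicated / retained
        for i in range(n):
            if (chrom, i) in driver_lookup:
                hom_alt[i] = False
            s = states[i]
            if s == "gain":
                t[i] = 3
                a[i] = 3 if hom_alt[i] else (2 if phase[i] < 0.5 else 1)
            elif s == "loss":
                t[i] = 1
                a[i] = 1 if hom_alt[i] else (1 if phase[i] < 0.5 else 0)
            elif s == "cn_loh":
                t[i] = 2
                a[i] = 2 if hom_alt[i] else (2 if phase[i] < 0.5 else 0)
            else:
                a[i] = 2 if hom_alt[i] else 1
        positions[chrom] = pos
        refs[chrom] = np.array([_BASES[i] for i in ref_idx], dtype=object)
        alts[chrom] = np.array([_BASES[i] for i in alt_idx], dtype=object)
        alt_copies[chrom] = a
        tot_copies[chrom] = t

    for name, (chrom, idx) in spec.driver_sites.items():
        if chrom not in chrom_sizes or idx >= chrom_sizes[chrom]:
            raise ConfigError(f"driver {name} outside genome")
        gt = "het" if alt_copies[chrom][idx] not in (0, tot_copies[chrom][idx]) else "non-het"
        if gt != "het":
            raise ConfigError(
                f"driver {name} at {chrom}[{idx}] falls in a {chrom} segment where "
                "heterozygosity cannot be preserved; move it to diploid ground"
            )

    return GroundTruthGenome(
        chromosomes=list(spec.chromosomes),
        positions=positions,
        refs=refs,
        alts=alts,
        alt_copies=alt_copies,
        tot_copies=tot_copies,
        hom_alt_fraction=spec.hom_alt_fraction,
        driver_sites=dict(spec.driver_sites),
        cna_segments=list(spec.cna_segments),
        str_loci=_default_str_loci(np.random.default_rng(seed + 1)),
    )


# ---------------------------------------------------------------------------
# assay simulation


def _amplified_fraction(
    rng: np.random.Generator,
    n_alt_templates: np.ndarray,
    n_ref_templates: np.ndarray,
    model: AmplificationModel,
):
    """Pooled alternate-allele fraction after template survival and gain.

    The sum of m independent Gamma(k) yields is Gamma(m*k), so per-site
    totals are drawn in one shot.  Returns (f, amplified) where
    ``amplified`` marks sites with at least one surviving template.
    """
    surv_alt = rng.binomial(n_alt_templates, model.template_survival)
    surv_ref = rng.binomial(n_ref_templates, model.template_survival)
    gain_alt = rng.gamma(surv_alt * model.gain_shape)
    gain_ref = rng.gamma(surv_ref * model.gain_shape)
    total = gain_alt + gain_ref
    amplified = total > 0
    f = np.divide(gain_alt, total, out=np.zeros_like(total), where=amplified)
    return f, amplified


def _genotype_and_pl(alt_reads: np.ndarray, depth: np.ndarray, error: float):
    """Call genotypes and phred-scaled likelihoods from allele counts.

    Likelihoods are binomial with alt-read probability e, 1/2 and 1-e for
    hom-ref, het and hom-alt; PL = -10*log10(L/Lmax), min-normalised to 0
    and capped at 9999.
    """
    e = min(max(error, 1e-10), 0.5)  # degenerate e=0 would give -inf logpmf
    probs = np.array([e, 0.5, 1.0 - e])
    ll = np.stack([binom.logpmf(alt_reads, depth, p) for p in probs], axis=1)
    best = ll.max(axis=1, keepdims=True)
    pl = np.rint(-10.0 * (ll - best) / np.log(10.0))
    pl = np.minimum(pl, 9999).astype(int)
    gt_idx = ll.argmax(axis=1)
    return gt_idx, pl


def simulate_assay(
    genome: GroundTruthGenome,
    model: AmplificationModel,
    cell_count: int,
    seed: int,
    replicate_index: int = 0,
    sample_id: str | None = None,
) -> AssayReplicate:
    """Simulate one WGA + exome-sequencing assay from ``cell_count`` cells.

    Per truth site, each local chromosome copy contributes ``cell_count``
    template molecules; survival and Gamma yields set the pooled alt
    fraction, a negative-binomial depth and binomial read sampling add
    sequencing noise, and genotypes/PLs are called from the reads.  Sites
    with no surviving template, zero depth, or a hom-ref call are omitted.
    Deterministic given (genome, model, cell_count, seed).
    """
    if cell_count < 1:
        raise ConfigError(f"cell_count must be >= 1, got {cell_count}")
    rng = np.random.default_rng(seed)
    if sample_id is None:
        sample_id = f"sim_{cell_count}cells_rep{replicate_index}"
    gt_names = np.array(["hom_ref", "het", "hom_alt"], dtype=object)

    calls: list[VariantCall] = []
    p_nb = model.depth_dispersion / (model.depth_dispersion + model.mean_depth)
    for chrom, n in genome.chromosomes:
        a_cop = genome.alt_copies[chrom]
        t_cop = genome.tot_copies[chrom]
        n_alt_t = cell_count * a_cop
        n_ref_t = cell_count * (t_cop - a_cop)
        f, amplified = _amplified_fraction(rng, n_alt_t, n_ref_t, model)
        depth = rng.negative_binomial(model.depth_dispersion, p_nb, size=n)
        e = model.sequencing_error
        f_eff = f * (1 - e) + (1 - f) * e
        alt_reads = rng.binomial(depth, f_eff)
        observed = amplified & (depth > 0)
        if not observed.any():
            continue
        idx = np.nonzero(observed)[0]
        gt_idx, pl = _genotype_and_pl(alt_reads[idx], depth[idx], e)
        keep = gt_idx > 0  # hom-ref calls are not emitted
        for j, g, p3 in zip(idx[keep], gt_idx[keep], pl[keep]):
            calls.append(
                VariantCall(
                    chrom=chrom,
                    pos=int(genome.positions[chrom][j]),
                    ref=str(genome.refs[chrom][j]),
                    alt=str(genome.alts[chrom][j]),
                    genotype_class=str(gt_names[g]),
                    ref_depth=int(depth[j] - alt_reads[j]),
                    alt_depth=int(alt_reads[j]),
                    total_depth=int(depth[j]),
                    pl=tuple(int(x) for x in p3),
                    filter_status="PASS",
                )
            )
    calls.extend(_false_positive_calls(genome, model, rng))
    return AssayReplicate(
        sample_id=sample_id,
        cell_count=cell_count,
        replicate_index=replicate_index,
        calls=calls,
    )


def _false_positive_calls(
    genome: GroundTruthGenome, model: AmplificationModel, rng: np.random.Generator
) -> list[VariantCall]:
    """Spurious amplification-artifact calls, placed off-target.

    Positions are offset midway between true sites so that they fall
    outside :meth:`GroundTruthGenome.coding_regions`.
    """
    if model.false_positive_rate == 0:
        return []
    n_fp = rng.poisson(model.false_positive_rate * genome.n_sites())
    chrom_labels = [c for c, n in genome.chromosomes if n > 1]
    calls = []
    used: set[tuple[str, int]] = set()
    for _ in range(n_fp):
        chrom = chrom_labels[rng.integers(len(chrom_labels))]
        pos_arr = genome.positions[chrom]
        i = int(rng.integers(len(pos_arr) - 1))
        pos = int((pos_arr[i] + pos_arr[i + 1]) // 2)
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        depth = max(int(rng.negative_binomial(
            model.depth_dispersion,
            model.depth_dispersion / (model.depth_dispersion + model.mean_depth))), 1)
        alt_reads = rng.binomial(depth, rng.uniform(0.1, 0.9))
        gt_idx, pl = _genotype_and_pl(np.array([alt_reads]), np.array([depth]), model.sequencing_error)
        if gt_idx[0] == 0:
            continue
        calls.append(
            VariantCall(
                chrom=chrom, pos=pos, ref=str(ref), alt=str(alt),
                genotype_class=["hom_ref", "het", "hom_alt"][gt_idx[0]],
                ref_depth=depth - int(alt_reads), alt_depth=int(alt_reads),
                total_depth=depth, pl=tuple(int(x) for x in pl[0]),
                filter_status="PASS",
            )
        )
    return calls


def simulate_str_panel(
    genome: GroundTruthGenome,
    model: AmplificationModel,
    cell_count: int,
    seed: int,
) -> list[STRObservation]:
    """Simulate fragment-analysis peak heights for the STR panel.

    Each haplotype of a locus carries ``cell_count`` templates subject to
    the same survival/Gamma-gain mechanism as SNV sites; peak height is
    the pooled yield scaled to ~1000 units for a balanced assay.  A
    haplotype whose templates all fail gives height 0.  Homozygous loci
    pool both haplotypes into a single peak.
    """
    if not genome.str_loci:
        raise ConfigError("genome carries no STR loci")
    if cell_count < 1:
        raise ConfigError("cell_count must be >= 1")
    rng = np.random.default_rng(seed)
    expected_yield = cell_count * model.template_survival * model.gain_shape
    out = []
    for locus in genome.str_loci:
        if locus.heterozygous:
            surv = rng.binomial(cell_count, model.template_survival, size=2)
            h = rng.gamma(surv * model.gain_shape) * 1000.0 / expected_yield
            h1, h2 = float(h[0]), float(h[1])
        else:
            surv = rng.binomial(2 * cell_count, model.template_survival)
            h1 = float(rng.gamma(surv * model.gain_shape) * 1000.0 / (2 * expected_yield))
            h2 = 0.0
        out.append(
            STRObservation(locus.locus, locus.allele1_len, locus.allele2_len, h1, h2)
        )
    return out


def reference_str_panel(genome: GroundTruthGenome) -> list[STRObservation]:
    """Bulk-DNA reference panel: balanced peaks at every locus."""
    return [
        STRObservation(l.locus, l.allele1_len, l.allele2_len,
                       1000.0, 1000.0 if l.heterozygous else 0.0)
        for l in genome.str_loci
    ]


# ---------------------------------------------------------------------------
# configuration + fixture emission


@dataclass
class SimulationConfig:
    cell_counts: list[int] = field(default_factory=lambda: [1, 2, 5, 10, 25, 50])
    replicates_per_count: int = 2
    seed: int = 0
    genome_spec: GenomeSpec = field(default_factory=GenomeSpec)
    model: AmplificationModel = field(default_factory=AmplificationModel)

    def __post_init__(self):
        if any(c < 1 for c in self.cell_counts):
            raise ConfigError("cell counts must be positive")
        if self.replicates_per_count < 2:
            raise ConfigError("replicates_per_count must be >= 2 for concordance analyses")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = AmplificationModel(**d["model"])
        if "genome_spec" in d and isinstance(d["genome_spec"], dict):
            gs = dict(d["genome_spec"])
            if "chromosomes" in gs:
                gs["chromosomes"] = [tuple(x) for x in gs["chromosomes"]]
            if "cna_segments" in gs:
                gs["cna_segments"] = [
                    CNASegmentTruth(**s) if isinstance(s, dict) else s
                    for s in gs["cna_segments"]
                ]
            if "driver_sites" in gs:
                gs["driver_sites"] = {k: tuple(v) for k, v in gs["driver_sites"].items()}
            d["genome_spec"] = GenomeSpec(**gs)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def assay_seed(base_seed: int, cell_count: int, replicate_index: int) -> int:
    """Stable per-assay child seed below 2**31."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(cell_count, replicate_index))
    return int(ss.generate_state(1)[0] % (2**31))


def write_fixture_set(config: SimulationConfig, out_dir) -> dict:
    """Simulate and write the full fixture set for a configuration.

    Emits one VCF per (cell_count, replicate), STR tables, a bulk STR
    reference, a coding-region BED, and a tab-separated truth sidecar of
    per-site genotypes and copy states for parameter-recovery tests.
    Returns a manifest of the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = build_genome(config.genome_spec, seed=config.seed)
    contigs = [c for c, _ in genome.chromosomes]

    vcfs: dict[tuple[int, int], str] = {}
    strs: dict[tuple[int, int], str] = {}
    for cc in config.cell_counts:
        for r in range(config.replicates_per_count):
            s = assay_seed(config.seed, cc, r)
            rep = simulate_assay(genome, config.model, cc, seed=s, replicate_index=r)
            vcf_path = out_dir / f"sim_{cc:03d}cells_rep{r}.vcf"
            write_vcf(rep, vcf_path, contigs=contigs)
            vcfs[(cc, r)] = str(vcf_path)
            panel = simulate_str_panel(genome, config.model, cc, seed=s + 1)
            str_path = out_dir / f"str_{cc:03d}cells_rep{r}.tsv"
            _write_str_table(panel, str_path)
            strs[(cc, r)] = str(str_path)

    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("chrom\tpos\ttruth_genotype\tcopy_state\n")
        for chrom, n in genome.chromosomes:
            states = genome.state_array(chrom)
            for i in range(n):
                fh.write(
                    f"{chrom}\t{genome.positions[chrom][i]}\t"
                    f"{genome.truth_genotype(chrom, i)}\t{states[i]}\n"
                )
    bed_path = out_dir / "coding_regions.bed"
    genome.coding_regions().to_bed(bed_path)
    str_ref_path = out_dir / "str_reference.tsv"
    _write_str_table(reference_str_panel(genome), str_ref_path)

    return {
        "vcfs": vcfs,
        "str_tables": strs,
        "str_reference": str(str_ref_path),
        "truth": str(truth_path),
        "coding_bed": str(bed_path),
        "genome": genome,
    }


def _write_str_table(panel: list[STRObservation], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tallele1_len\tallele2_len\theight1\theight2\n")
        for obs in panel:
            fh.write(
                f"{obs.locus}\t{obs.allele1_len}\t{obs.allele2_len}\t"
                f"{obs.height1:.2f}\t{obs.height2:.2f}\n"
            )


def read_str_table(path) -> list[STRObservation]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("locus"):
            raise ValueError(f"{path}: not an STR table")
        for line in fh:
            locus, a1, a2, h1, h2 = line.rstrip("\n").split("\t")
            out.append(STRObservation(locus, int(a1), int(a2), float(h1), float(h2)))
    return out


def model_to_dict(model: AmplificationModel) -> dict:
    return dataclasses.asdict(model)
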