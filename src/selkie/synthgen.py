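"""Synthetic genomes, depth tracks, variants, synteny blocks and k-mer spectra.

Every downstream stage of the pipeline (sex/PAR inference, heterozygosity
scans, inversion calling, spectral genome-size estimation) is exercised
against data generated here with planted ground truth: a diploid genome whose
X carries a terminal pseudoautosomal region (PAR), per-base read depth that is
diploid on autosomes and on the PAR but haploid on the male non-PAR X,
heterozygous SNPs at a configurable per-region density, oriented synteny
blocks with planted inversions, and k-mer multiplicity histograms composed of
an error peak plus a coverage peak.

All coordinates are 0-based half-open internally; VCF positions are converted
to 1-based only at serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Chromosome",
    "GenomeModel",
    "SimulationConfig",
    "SimVariant",
    "make_genome",
    "simulate_coverage",
    "simulate_variants",
    "simulate_synteny",
    "simulate_kmer_histogram",
    "standardize_reads",
]


class ConfigurationError(ValueError):
    """Raised when a simulation request is internally inconsistent."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    is_x: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ConfigurationError(f"chromosome {self.name!r} has non-positive length")


@dataclass(frozen=True)
class GenomeModel:
    """A haploid chromosome layout plus sex and an optional terminal PAR on X.

    ``par_interval`` is a 0-based half-open interval on the X chromosome that
    must abut one X terminus (start == 0 or end == X length); ``None`` means
    no PAR is modelled.
    """

    chromosomes: tuple[Chromosome, ...]
    sex: str
    par_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ConfigurationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        xs = [c for c in self.chromosomes if c.is_x]
        if len(xs) > 1:
            raise ConfigurationError("at most one X chromosome allowed")
        if self.par_interval is not None:
            if not xs:
                raise ConfigurationError("par_interval given but no X chromosome")
            x = xs[0]
            s, e = self.par_interval
            if not (0 <= s < e <= x.length):
                raise ConfigurationError("par_interval outside X bounds")
            if s != 0 and e != x.length:
                raise ConfigurationError("PAR must abut an X terminus")
            if e - s >= x.length:
                raise ConfigurationError("PAR length must be smaller than X length")

    @property
    def x(self) -> Chromosome | None:
        for c in self.chromosomes:
            if c.is_x:
                return c
        return None

    @property
    def lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    def is_par(self, chrom: str, pos: int) -> bool:
        x = self.x
        if x is None or chrom != x.name or self.par_interval is None:
            return False
        s, e = self.par_interval
        return s <= pos < e

    def is_hemizygous(self, chrom: str, pos: int) -> bool:
        """True at male non-PAR X positions, where het genotypes cannot occur."""
        x = self.x
        return (
            self.sex == "male"
            and x is not None
            and chrom == x.name
            and not self.is_par(chrom, pos)
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs shared by the generators.

    mean_depth
        expected reads per base on diploid sequence.
    depth_dispersion
        variance inflation factor (1.0 = Poisson; >1 switches per-base depth
        to a negative binomial with variance ``dispersion * mean``).
    het_density_map
        region name -> heterozygous SNPs per kbp; the key ``"default"``
        applies to chromosomes not named explicitly.
    error_rate
        fraction of read k-mers that are sequencing errors, in [0, 1).
    k
        k-mer length for spectra.
    """

    mean_depth: float = 30.0
    depth_dispersion: float = 1.0
    het_density_map: Mapping[str, float] = field(default_factory=lambda: {"default": 0.6})
    error_rate: float = 0.0
    k: int = 23
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be positive")
        if self.depth_dispersion < 1.0:
            raise ConfigurationError("depth_dispersion must be >= 1")
        if any(d < 0 for d in self.het_density_map.values()):
            raise ConfigurationError("heterozygosity densities must be >= 0")
        if not (0.0 <= self.error_rate < 1.0):
            raise ConfigurationError("error_rate must be in [0, 1)")
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")

    def density_for(self, chrom: str) -> float:
        if chrom in self.het_density_map:
            return self.het_density_map[chrom]
        return self.het_density_map.get("default", 0.0)


def make_genome(
    n_autosomes: int,
    autosome_lengths: Sequence[int],
    x_length: int,
    par_length: int,
    sex: str = "male",
    seed: int = 0,
    x_name: str = "chrX",
) -> GenomeModel:
    """Build a deterministic genome model with the PAR at the X start.

    ``par_length == 0`` yields a model with no PAR. The seed is accepted for
    interface uniformity; construction is fully deterministic.
    """
    if len(autosome_lengths) != n_autosomes:
        raise ConfigurationError("autosome_lengths must have n_autosomes entries")
    if par_length < 0:
        raise ConfigurationError("par_length must be >= 0")
    if x_length > 0 and par_length >= x_length:
        raise ConfigurationError("par_length must be smaller than x_length")
    chroms = [Chromosome(f"chr{i + 1}", int(l)) for i, l in enumerate(autosome_lengths)]
    par: tuple[int, int] | None = None
    if x_length > 0:
        chroms.append(Chromosome(x_name, int(x_length), is_x=True))
        if par_length > 0:
            par = (0, int(par_length))
    return GenomeModel(tuple(chroms), sex=sex, par_interval=par)


def _depth_draw(rng: np.random.Generator, mean: float, dispersion: float, n: int) -> np.ndarray:
    """Per-base depth: Poisson, or negative binomial when over-dispersed."""
    if dispersion <= 1.0:
        return rng.poisson(mean, n).astype(np.int32)
    # NB parameterised so that variance = dispersion * mean.
    p = 1.0 / dispersion
    r = mean * p / (1.0 - p)
    return rng.negative_binomial(r, p, n).astype(np.int32)


def simulate_coverage(genome: GenomeModel, config: SimulationConfig) -> dict[str, np.ndarray]:
    """Per-base depth arrays keyed by chromosome name.

    Autosomes and the PAR are drawn around ``mean_depth``; the male non-PAR X
    around ``mean_depth / 2``; a female X is indistinguishable from an
    autosome. Serializable as bedGraph via :func:`selkie.io.write_bedgraph`.
    """
    rng = np.random.default_rng(config.seed)
    out: dict[str, np.ndarray] = {}
    for c in genome.chromosomes:
        if c.is_x and genome.sex == "male":
            depth = _depth_draw(rng, config.mean_depth / 2.0, config.depth_dispersion, c.length)
            if genome.par_interval is not None:
                s, e = genome.par_interval
                depth[s:e] = _depth_draw(rng, config.mean_depth, config.depth_dispersion, e - s)
        else:
            depth = _depth_draw(rng, config.mean_depth, config.depth_dispersion, c.length)
        out[c.name] = depth
    return out


@dataclass(frozen=True)
class SimVariant:
    """One simulated heterozygous SNP with the FORMAT fields the filter reads."""

    chrom: str
    pos: int  # 0-based
    qual: float
    dp: int
    gq: int
    sp: float
    ref: str = "A"
    alt: str = "G"
    genotype: str = "het"
    is_snp: bool = True

    @property
    def is_het(self) -> bool:
        return self.genotype == "het"


def simulate_variants(genome: GenomeModel, config: SimulationConfig) -> list[SimVariant]:
    """Heterozygous SNPs at the planted per-region density.

    Counts per region are Poisson with mean ``density * length / 1000``;
    positions are uniform. The male non-PAR X is hemizygous and emits no
    heterozygous records regardless of its configured density. QUAL, DP, GQ
    and SP are sampled from distributions whose bulk passes the default
    quality filter: QUAL ~ Gamma(sh 4, sc 50), DP ~ Poisson(mean_depth),
    GQ ~ min(99, Gamma(sh 4, sc 15)), SP half-normal with scale 15 (only the
    >60 tail matters downstream).
    """
    rng = np.random.default_rng(config.seed + 1)
    records: list[SimVariant] = []
    for c in genome.chromosomes:
        density = config.density_for(c.name)
        regions: list[tuple[int, int]] = [(0, c.length)]
        if c.is_x and genome.sex == "male":
            if genome.par_interval is None:
                continue  # whole X hemizygous
            regions = [genome.par_interval]
        for start, end in regions:
            span = end - start
            n = int(rng.poisson(density * span / 1000.0))
            if n == 0:
                continue
            pos = np.sort(rng.integers(start, end, n))
            qual = rng.gamma(4.0, 50.0, n)
            dp = rng.poisson(config.mean_depth, n)
            gq = np.minimum(99, rng.gamma(4.0, 15.0, n).astype(int))
            sp = np.abs(rng.normal(0.0, 15.0, n))
            for i in range(n):
                records.append(
                    SimVariant(
                        chrom=c.name,
                        pos=int(pos[i]),
                        qual=round(float(qual[i]), 2),
                        dp=int(dp[i]),
                        gq=int(gq[i]),
                        sp=round(float(sp[i]), 2),
                    )
                )
    records.sort(key=lambda r: ([c.name for c in genome.chromosomes].index(r.chrom), r.pos))
    return records


def simulate_synteny(
    ref: GenomeModel,
    planted_inversions: Sequence[tuple[str, tuple[int, int]]] = (),
    scaffold_permutation: Mapping[str, str] | None = None,
    mean_block_len: int = 200_000,
    seed: int = 0,
):
    """Tile each reference chromosome with oriented synteny blocks.

    Query scaffolds are renamed/permuted copies of the reference chromosomes.
    Blocks whose reference span lies inside a planted inversion interval carry
    '-' orientation; all others '+'. Block lengths are exponential around
    ``mean_block_len`` (minimum 1 bp), non-overlapping and covering each
    chromosome. Returns a :class:`selkie.syntkar.SyntenyBlockSet`.
    """
    from .syntkar import SyntenyBlock, SyntenyBlockSet

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, (s, e) in planted_inversions:
        if chrom not in ref.lengths:
            raise ConfigurationError(f"planted inversion on unknown chromosome {chrom!r}")
        if not (0 <= s < e <= ref.lengths[chrom]):
            raise ConfigurationError("planted inversion outside chromosome bounds")
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ConfigurationError(f"overlapping planted inversions on {chrom}")

    perm = scaffold_permutation or {}
    rng = np.random.default_rng(seed)
    blocks: list[SyntenyBlock] = []
    for c in ref.chromosomes:
        qname = perm.get(c.name, c.name)
        # breakpoints: inversion edges are forced so planted intervals tile cleanly
        cuts = {0, c.length}
        for s, e in by_chrom.get(c.name, []):
            cuts.update((s, e))
        pos = 0
        while pos < c.length:
            step = max(1, int(rng.exponential(mean_block_len)))
            pos = min(pos + step, c.length)
            cuts.add(pos)
        edges = sorted(cuts)
        for s, e in zip(edges, edges[1:]):
            orient = "+"
            for is_, ie in by_chrom.get(c.name, []):
                if is_ <= s and e <= ie:
                    orient = "-"
                    break
            blocks.append(SyntenyBlock(c.name, s, e, qname, s, e, orient))
    q_lengths = {perm.get(c.name, c.name): c.length for c in ref.chromosomes}
    return SyntenyBlockSet(blocks=blocks, ref_lengths=ref.lengths, query_lengths=q_lengths)


def simulate_kmer_histogram(genome_size: int, config: SimulationConfig) -> dict[int, int]:
    """K-mer multiplicity histogram: error peak at multiplicity 1-2 plus a
    coverage peak near ``mean_depth``.

    Each of the ``genome_size`` distinct genomic k-mers receives a Poisson
    multiplicity at the mean depth, so the non-error mass Σ i·c_i is about
    ``genome_size * mean_depth``. Erroneous k-mer observations amount to a
    fraction ``error_rate`` of the total read k-mer mass and are spread over
    distinct k-mers with geometric multiplicities (mostly 1).
    """
    if genome_size <= 0:
        raise ConfigurationError("genome_size must be positive")
    rng = np.random.default_rng(config.seed + 2)
    mult = rng.poisson(config.mean_depth, int(genome_size))
    counts = np.bincount(mult)
    if config.error_rate > 0:
        total_mass = genome_size * config.mean_depth / (1.0 - config.error_rate)
        err_mass = config.error_rate * total_mass
        # geometric(p=0.8): mean multiplicity 1.25, concentrated at 1-2
        n_err = int(err_mass / 1.25)
        err_mult = rng.geometric(0.8, n_err)
        err_counts = np.bincount(err_mult)
        if len(err_counts) > len(counts):
            counts = np.pad(counts, (0, len(err_counts) - len(counts)))
            counts += err_counts
        else:
            counts[: len(err_counts)] += err_counts
    return {int(i): int(c) for i, c in enumerate(counts) if i >= 1 and c > 0}


class CoverageShortfallError(ValueError):
    """Input reads cannot supply the requested coverage after cutting."""


def standardize_reads(
    reads: Iterable,
    genome_size: int,
    target_len: int = 100,
    target_cov: float = 20.0,
    seed: int = 0,
) -> Iterator:
    """Cut reads to a fixed length and downsample to a target fold-coverage.

    Reads shorter than ``target_len`` are dropped (reads are only ever cut
    down, never padded); longer reads keep their first ``target_len`` bases.
    The survivors are subsampled without replacement so that the emitted bases
    total about ``target_cov * genome_size``. Accepts and yields Biopython
    ``SeqRecord`` objects.

    Raises :class:`CoverageShortfallError` naming the achievable coverage when
    the input cannot supply the target.
    """
    if genome_size <= 0:
        raise ConfigurationError("genome_size must be positive")
    if target_len <= 0 or target_cov <= 0:
        raise ConfigurationError("target_len and target_cov must be positive")
    cut = []
    for rec in reads:
        if len(rec.seq) >= target_len:
            cut.append(rec[:target_len])
    needed = int(round(target_cov * genome_size / target_len))
    if len(cut) < needed:
        achievable = len(cut) * target_len / genome_size
        raise CoverageShortfallError(
            f"only {achievable:.2f}x coverage available after cutting to "
            f"{target_len} bp; {target_cov:.2f}x requested"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cut), size=needed, replace=False)
    for i in np.sort(idx):
        yield cut[i]
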