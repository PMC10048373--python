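"""Variant filtering, ploidy masking, and sliding-window heterozygosity.

The filter chain mirrors a bcftools-style expression: a record is removed iff

    QUAL < 20.0  OR  SP > 60.0  OR  DP < 5.0  OR  GQ < 20.0

(all comparisons strict, exactly as written), after which survivors must have
sample depth within 30-250% of the mean genome coverage (band inclusive).
Heterozygous SNPs are then counted in overlapping sliding windows of 1 Mbp
with a 100 kbp step and scaled to SNPs per kbp. On a male sample the non-PAR
X is hemizygous, so heterozygous calls there are artifacts and are masked to
missing before counting; this produces the characteristic secondary mode at
density 0 in male summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .covsex import ParCall

__all__ = [
    "FilterConfig",
    "VariantRecord",
    "FilterTally",
    "HetWindow",
    "HetTrack",
    "HetSummary",
    "filter_variants",
    "apply_ploidy_mask",
    "het_windows",
    "het_summary",
]


@dataclass(frozen=True)
class FilterConfig:
    """Quality thresholds plus the relative coverage band.

    Quality comparisons are strict (a record at exactly the threshold is
    kept); the coverage band is closed on both ends.
    """

    min_qual: float = 20.0
    max_sp: float = 60.0
    min_dp: float = 5.0
    min_gq: float = 20.0
    cov_band: tuple[float, float] = (0.30, 2.50)

    def __post_init__(self) -> None:
        lo, hi = self.cov_band
        if not (0 <= lo < hi):
            raise ValueError("cov_band must satisfy 0 <= low < high")
        if min(self.min_qual, self.max_sp, self.min_dp, self.min_gq) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class VariantRecord:
    """One variant call with the FORMAT fields the filter inspects.

    ``pos`` is 0-based internally (VCF 1-based positions are converted at the
    parsing boundary). ``genotype`` is one of hom_ref / het / hom_alt /
    missing. Fields absent in the source VCF are ``None``.
    """

    chrom: str
    pos: int
    qual: float | None
    dp: float | None
    gq: float | None
    sp: float | None
    genotype: str
    is_snp: bool = True

    @property
    def is_het(self) -> bool:
        return self.genotype == "het"


@dataclass
class FilterTally:
    """Removals per rule, attributed to the first failing rule in written
    order (qual, sp, dp, gq, coverage band)."""

    kept: int = 0
    removed_qual: int = 0
    removed_sp: int = 0
    removed_dp: int = 0
    removed_gq: int = 0
    removed_band: int = 0
    errors: int = 0

    @property
    def removed(self) -> int:
        return (self.removed_qual + self.removed_sp + self.removed_dp
                + self.removed_gq + self.removed_band)


def filter_variants(
    records: Iterable[VariantRecord],
    config: FilterConfig = FilterConfig(),
    mean_cov: float = 30.0,
) -> tuple[list[VariantRecord], FilterTally]:
    """Apply the quality expression, then the relative coverage band.

    Records missing a required field are counted as errors and skipped; the
    run continues. Returns the surviving records and the removal tally.
    """
    if mean_cov <= 0:
        raise ValueError("mean_cov must be positive")
    lo = config.cov_band[0] * mean_cov
    hi = config.cov_band[1] * mean_cov
    kept: list[VariantRecord] = []
    tally = FilterTally()
    for r in records:
        if r.qual is None or r.dp is None or r.gq is None or r.sp is None:
            tally.errors += 1
            continue
        if r.qual < config.min_qual:
            tally.removed_qual += 1
        elif r.sp > config.max_sp:
            tally.removed_sp += 1
        elif r.dp < config.min_dp:
            tally.removed_dp += 1
        elif r.gq < config.min_gq:
            tally.removed_gq += 1
        elif not (lo <= r.dp <= hi):
            tally.removed_band += 1
        else:
            kept.append(r)
            tally.kept += 1
    return kept, tally


def apply_ploidy_mask(
    records: Sequence[VariantRecord],
    sex: str,
    par: ParCall | None,
) -> list[VariantRecord]:
    """Set male heterozygous genotypes on the non-PAR X to missing.

    Females and PAR positions are untouched. A male with no PAR call gets the
    whole X masked, with a warning (conservative: no het call on a possibly
    hemizygous region is trusted).
    """
    if sex == "female":
        return list(records)
    if par is None:
        raise ValueError("male sample requires a ParCall (possibly with par=None)")
    x_name = par.x_name
    interval = par.par
    if interval is None:
        warnings.warn(
            "male sample with unresolved PAR: masking the whole X chromosome",
            stacklevel=2,
        )
    out: list[VariantRecord] = []
    for r in records:
        if r.chrom == x_name and r.is_het:
            in_par = interval is not None and interval[0] <= r.pos < interval[1]
            if not in_par:
                r = replace(r, genotype="missing")
        out.append(r)
    return out


@dataclass(frozen=True)
class HetWindow:
    chrom: str
    start: int
    end: int
    het_count: int
    density: float  # SNPs per kbp over the actual window span


@dataclass
class HetTrack:
    windows: dict[str, list[HetWindow]]
    window_size: int
    step: int
    x_name: str | None = None

    def densities(self, exclude: set[str] | None = None) -> np.ndarray:
        vals = [
            w.density
            for chrom, wins in self.windows.items()
            if not exclude or chrom not in exclude
            for w in wins
        ]
        return np.asarray(vals, dtype=float)


def het_windows(
    records: Sequence[VariantRecord],
    chrom_lengths: dict[str, int],
    window: int = 1_000_000,
    step: int = 100_000,
    x_name: str | None = None,
) -> HetTrack:
    """Heterozygous-SNP densities in overlapping sliding windows.

    Only records that are SNPs with a heterozygous genotype contribute.
    Windows start at 0, step, 2*step, ... and are truncated at chromosome
    ends; densities are scaled by the actual span (in kbp), so end windows
    are comparable rather than dropped. A chromosome shorter than the step
    gets a single window covering it.
    """
    if window <= 0 or step <= 0 or window % step != 0:
        raise ValueError("window must be a positive multiple of step")
    positions: dict[str, np.ndarray] = {}
    for chrom in chrom_lengths:
        pos = sorted(r.pos for r in records
                     if r.chrom == chrom and r.is_het and r.is_snp)
        positions[chrom] = np.asarray(pos, dtype=np.int64)
    out: dict[str, list[HetWindow]] = {}
    for chrom, length in chrom_lengths.items():
        pos = positions[chrom]
        wins: list[HetWindow] = []
        for start in range(0, length, step):
            end = min(start + window, length)
            count = int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
            span_kbp = (end - start) / 1000.0
            wins.append(HetWindow(chrom, start, end, count, count / span_kbp))
        out[chrom] = wins
    return HetTrack(windows=out, window_size=window, step=step, x_name=x_name)


@dataclass(frozen=True)
class HetSummary:
    min: float
    median: float
    mean: float
    mode: float
    max: float
    secondary_zero_mode: bool
    mode_bin: float
    x_excluded: bool


def het_summary(
    track: HetTrack,
    exclude_x: bool = False,
    mode_bin: float = 0.02,
) -> HetSummary:
    """Min / median / mean / mode / max over window densities.

    The mode is the center of the most populated histogram bin (bin width
    ``mode_bin`` SNPs/kbp). When the zero bin is a local maximum of the
    histogram but not the global mode — the signature of a hemizygous male X
    — a secondary zero mode is flagged.
    """
    exclude = {track.x_name} if exclude_x and track.x_name else None
    dens = track.densities(exclude)
    if dens.size == 0:
        raise ValueError("empty heterozygosity track")
    n_bins = int(np.floor(dens.max() / mode_bin)) + 1
    edges = np.arange(n_bins + 1) * mode_bin
    hist, _ = np.histogram(dens, bins=edges)
    mode_idx = int(np.argmax(hist))
    mode = float((mode_idx + 0.5) * mode_bin) if mode_idx > 0 else 0.0
    zero_is_local_max = hist[0] > 0 and (len(hist) == 1 or hist[0] > hist[1])
    return HetSummary(
        min=float(dens.min()),
        median=float(np.median(dens)),
        mean=float(dens.mean()),
        mode=mode,
        max=float(dens.max()),
        secondary_zero_mode=bool(zero_is_local_max and mode_idx > 0),
        mode_bin=mode_bin,
        x_excluded=exclude_x,
    )
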