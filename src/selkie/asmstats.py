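"""Assembly contiguity, chromosome-scaffold cutoff, BUSCO percentages, and
spectral genome-size estimation from k-mer histograms."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ScaffoldStats",
    "CScaffoldCutoff",
    "BuscoPercentages",
    "KmerEstimate",
    "scaffold_stats",
    "c_scaffold_cutoff",
    "busco_percent",
    "genome_size_from_kmers",
]


@dataclass(frozen=True)
class ScaffoldStats:
    n_scaffolds: int
    total_length: int
    n50: int
    l50: int
    lengths_desc: tuple[int, ...]


def scaffold_stats(lengths: Sequence[int]) -> ScaffoldStats:
    """N50/L50 by the cumulative-half convention: N50 is the length of the
    scaffold at which the cumulative sum of descending-sorted lengths first
    reaches half the total; L50 is its 1-based rank."""
    if len(lengths) == 0:
        raise ValueError("empty length list")
    if min(lengths) <= 0:
        raise ValueError("scaffold lengths must be positive")
    desc = sorted((int(l) for l in lengths), reverse=True)
    total = sum(desc)
    cum = 0
    for i, l in enumerate(desc, start=1):
        cum += l
        if 2 * cum >= total:
            return ScaffoldStats(len(desc), total, l, i, tuple(desc))
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class CScaffoldCutoff:
    """The rank separating chromosome-length scaffolds from the debris tail.

    ``k`` is the 1-based rank maximizing the consecutive length ratio
    L_k / L_{k+1} on descending-sorted lengths; ties break to the smallest k.
    """

    k: int
    fold_gap: float
    fold_gap_rounded: int
    is_chromosome_scale: bool
    length_k: int
    length_k1: int


def c_scaffold_cutoff(
    lengths: Sequence[int],
    search_top: int = 64,
    flag_threshold: float = 10.0,
) -> CScaffoldCutoff:
    """Find the largest consecutive fold-gap among the top-ranked scaffolds.

    A pronounced gap (fold >= ``flag_threshold``) marks the boundary between
    chromosome-scale scaffolds and unplaced fragments.
    """
    if len(lengths) < 2:
        raise ValueError("need at least 2 scaffolds")
    desc = sorted((int(l) for l in lengths), reverse=True)
    n_ranks = min(search_top, len(desc) - 1)
    ratios = [desc[i] / desc[i + 1] for i in range(n_ranks)]
    best = int(np.argmax(ratios))  # first maximum on ties
    fold = ratios[best]
    return CScaffoldCutoff(
        k=best + 1,
        fold_gap=fold,
        fold_gap_rounded=int(Decimal(fold).quantize(0, rounding=ROUND_HALF_UP)),
        is_chromosome_scale=fold >= flag_threshold,
        length_k=desc[best],
        length_k1=desc[best + 1],
    )


@dataclass(frozen=True)
class BuscoPercentages:
    single: float
    duplicated: float
    fragmented: float
    missing: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.single, self.duplicated, self.fragmented, self.missing)


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal."""
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )


def busco_percent(
    counts: tuple[int, int, int, int],
    total: int,
) -> BuscoPercentages:
    """Convert BUSCO category counts (complete single-copy, complete
    duplicated, fragmented, missing) to percentages of the ortholog set.

    The four counts must sum exactly to ``total``. Rounding is half-up to one
    decimal; computed values are reported as-is, so a published table rounded
    differently will disagree visibly rather than being silently matched.
    """
    if len(counts) != 4:
        raise ValueError("expected (single, duplicated, fragmented, missing)")
    if any(c < 0 for c in counts) or total <= 0:
        raise ValueError("counts must be >= 0 and total > 0")
    if sum(counts) != total:
        raise ValueError(f"counts sum to {sum(counts)}, expected {total}")
    return BuscoPercentages(*(_pct(c, total) for c in counts))


@dataclass(frozen=True)
class KmerEstimate:
    genome_size: float
    peak_multiplicity: int
    coverage: float  # mean multiplicity of the coverage component
    trough: int
    used_mass: int  # Σ i·c_i over multiplicities >= trough


def genome_size_from_kmers(
    hist: Mapping[int, int],
    min_mult: int | None = None,
    k: int = 23,
) -> KmerEstimate:
    """Spectral genome-size estimate from a k-mer multiplicity histogram.

    The error peak at multiplicity 1-2 is separated from the coverage peak at
    the trough t — the first strict local minimum after multiplicity 1, or
    ``min_mult`` when given. The genome size is the k-mer mass above the
    trough divided by the sequencing coverage λ of the coverage component:

        G = Σ_{i >= t} i·c_i / λ,   λ = Σ_{i >= t} i·c_i / Σ_{i >= t} c_i

    i.e. λ is the mean multiplicity above the trough. The histogram argmax
    over multiplicities >= t is reported as ``peak_multiplicity`` for
    diagnostics but is not used as the divisor: a discrete spectrum whose
    underlying mean is near an integer has a two-bin tie at the peak (for a
    Poisson component, pmf(λ-1) = pmf(λ) exactly), which would bias the
    estimate by up to 1/λ depending on how sampling noise resolves the tie.
    """
    if not hist:
        raise ValueError("empty histogram")
    max_mult = max(hist)
    counts = np.zeros(max_mult + 2, dtype=np.int64)
    for i, c in hist.items():
        if i < 1 or c < 0:
            raise ValueError("multiplicities must be >= 1 with counts >= 0")
        counts[i] = c
    if min_mult is not None:
        if min_mult < 1:
            raise ValueError("min_mult must be >= 1")
        t = min_mult
    else:
        t = 0
        for i in range(2, max_mult + 1):
            if counts[i] <= counts[i - 1] and counts[i] < counts[i + 1]:
                t = i
                break
        if t == 0:
            raise ValueError(
                "no local minimum separating error and coverage peaks; "
                "pass an explicit min_mult"
            )
    m = t + int(np.argmax(counts[t : max_mult + 1]))
    mult = np.arange(t, max_mult + 1, dtype=np.int64)
    mass = int(np.sum(mult * counts[t : max_mult + 1]))
    distinct = int(np.sum(counts[t : max_mult + 1]))
    if distinct == 0:
        raise ValueError("histogram has no mass at or above the trough")
    coverage = mass / distinct
    return KmerEstimate(
        genome_size=mass / coverage,
        peak_multiplicity=m,
        coverage=coverage,
        trough=t,
        used_mass=mass,
    )
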