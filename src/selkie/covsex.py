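"""Windowed coverage medians, coverage-based sex inference, and PAR detection.

The pseudoautosomal region (PAR) of the X recombines with the Y and is
diploid in both sexes, so in a male it stands out as the only X segment with
autosomal read depth: the rest of the X sits near half the genome level.
Detection proceeds in two passes over 10 kbp stacking-window medians:

1. windows whose median depth is at least a threshold fraction (default 0.70)
   of the whole-genome level are marked and adjacent marked windows merge
   into segments;
2. consecutive segments merge whenever the pooled per-base median over the
   intervening gap also clears the threshold, repeated to a fixed point.

The surviving segment abutting an X terminus (subject to a minimum length)
is called the PAR. Sex is inferred from the ratio of the median normalized
X window level to the autosomal level: ~0.5 for males, ~1.0 for females.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoverageWindow",
    "CoverageWindowTrack",
    "SexInference",
    "ParCall",
    "window_medians",
    "genome_level",
    "infer_sex",
    "detect_par",
]


@dataclass(frozen=True)
class CoverageWindow:
    chrom: str
    start: int
    end: int
    median_depth: float
    partial: bool = False  # truncated terminal window


@dataclass
class CoverageWindowTrack:
    """Stacking-window depth medians per chromosome, with normalized levels.

    Windows tile each chromosome without overlap; the last window of a
    chromosome may be partial and is flagged. ``normalized`` (median depth
    divided by a genome level) is populated by :func:`genome_level` callers.
    """

    windows: dict[str, list[CoverageWindow]]
    window_size: int
    x_name: str | None = None
    normalized: dict[str, np.ndarray] = field(default_factory=dict)

    def chrom_medians(self, chrom: str) -> np.ndarray:
        return np.array([w.median_depth for w in self.windows[chrom]], dtype=float)

    def normalize(self, level: float) -> None:
        if level <= 0:
            raise ValueError("genome level must be positive")
        self.normalized = {c: self.chrom_medians(c) / level for c in self.windows}

    @property
    def chromosomes(self) -> list[str]:
        return list(self.windows)


@dataclass(frozen=True)
class SexInference:
    x_ratio: float
    label: str
    decision_threshold: float


@dataclass(frozen=True)
class ParCall:
    """Diploid-coverage segments on X and the terminal one designated as PAR."""

    x_name: str
    segments: tuple[tuple[int, int], ...]
    par: tuple[int, int] | None
    par_length: int
    threshold_used: float
    flag: str | None = None  # e.g. "diploid X, PAR not resolvable"


def window_medians(
    depth: dict[str, np.ndarray],
    window: int = 10_000,
    x_name: str | None = None,
) -> CoverageWindowTrack:
    """Median per-base depth in stacking (non-overlapping) windows.

    Positions missing from the per-base track are impossible here because the
    input arrays are dense; callers loading sparse bedGraph should expand
    through :func:`selkie.io.read_bedgraph`, which fills absent positions
    with depth 0.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not depth or all(arr.size == 0 for arr in depth.values()):
        raise ValueError("empty depth track")
    out: dict[str, list[CoverageWindow]] = {}
    for chrom, arr in depth.items():
        wins: list[CoverageWindow] = []
        for start in range(0, len(arr), window):
            end = min(start + window, len(arr))
            wins.append(
                CoverageWindow(
                    chrom, start, end,
                    float(np.median(arr[start:end])),
                    partial=(end - start) < window,
                )
            )
        out[chrom] = wins
    return CoverageWindowTrack(windows=out, window_size=window, x_name=x_name)


def genome_level(track: CoverageWindowTrack, autosomes_only: bool = True) -> float:
    """Whole-genome depth level: the median of per-window medians.

    By default only autosomal windows contribute, so a male X (at half depth)
    cannot depress the normalization denominator. Requires ``track.x_name``
    when ``autosomes_only`` and an X is present.
    """
    meds: list[np.ndarray] = []
    for chrom in track.chromosomes:
        if autosomes_only and track.x_name is not None and chrom == track.x_name:
            continue
        meds.append(track.chrom_medians(chrom))
    if not meds or sum(m.size for m in meds) == 0:
        raise ValueError("no qualifying windows for genome level")
    return float(np.median(np.concatenate(meds)))


def infer_sex(
    track: CoverageWindowTrack,
    level: float,
    decision_threshold: float = 0.75,
    par: "ParCall | tuple[int, int] | None" = None,
) -> SexInference:
    """Label a sample male iff the non-PAR X:autosome depth ratio falls below
    the decision threshold (default 0.75, midway between the expected male
    0.5 and female 1.0 ratios).

    The PAR is diploid in both sexes, so when a PAR call (or interval) is
    supplied its windows are excluded from the X median; run
    :func:`detect_par` first for samples where the PAR may be a substantial
    fraction of the X.
    """
    if track.x_name is None or track.x_name not in track.windows:
        raise ValueError("no X chromosome identified in the track")
    if level <= 0:
        raise ValueError("genome level must be positive")
    interval = par.par if isinstance(par, ParCall) else par
    x_meds = [
        w.median_depth
        for w in track.windows[track.x_name]
        if interval is None or not (interval[0] < w.end and w.start < interval[1])
    ]
    if not x_meds:
        raise ValueError("no non-PAR X windows to infer sex from")
    x_ratio = float(np.median(x_meds) / level)
    label = "male" if x_ratio < decision_threshold else "female"
    return SexInference(x_ratio=x_ratio, label=label, decision_threshold=decision_threshold)


def _pass1_segments(
    wins: list[CoverageWindow], cutoff: float
) -> list[tuple[int, int]]:
    """Merge adjacent windows with median >= cutoff into segments."""
    segs: list[tuple[int, int]] = []
    for w in wins:
        if w.median_depth >= cutoff:
            if segs and segs[-1][1] == w.start:
                segs[-1] = (segs[-1][0], w.end)
            else:
                segs.append((w.start, w.end))
    return segs


def _pass2_merge(
    segs: list[tuple[int, int]], depth_x: np.ndarray, cutoff: float
) -> list[tuple[int, int]]:
    """Merge consecutive segments whose intervening gap has pooled per-base
    median >= cutoff; iterate to a fixed point."""
    segs = list(segs)
    changed = True
    while changed:
        changed = False
        merged: list[tuple[int, int]] = []
        for seg in segs:
            if merged:
                gap = depth_x[merged[-1][1] : seg[0]]
                if gap.size and float(np.median(gap)) >= cutoff:
                    merged[-1] = (merged[-1][0], seg[1])
                    changed = True
                    continue
            merged.append(seg)
        segs = merged
    return segs


def detect_par(
    track: CoverageWindowTrack,
    depth_x: np.ndarray,
    level: float,
    threshold: float = 0.70,
    min_par: int = 100_000,
) -> ParCall:
    """Two-pass PAR caller on the X chromosome.

    ``track`` must contain X windows computed at the same window size used
    for ``level``; ``depth_x`` is the per-base X depth used for the pass-2
    gap medians. The PAR is the segment abutting an X terminus with length
    >= ``min_par`` (the longer one if both termini qualify); when the entire
    X is one diploid segment (a female-like profile) the PAR is reported
    absent with an explanatory flag.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if track.x_name is None or track.x_name not in track.windows:
        raise ValueError("no X chromosome identified in the track")
    wins = track.windows[track.x_name]
    x_len = wins[-1].end
    cutoff = threshold * level

    segs = _pass1_segments(wins, cutoff)
    segs = _pass2_merge(segs, depth_x, cutoff)

    if len(segs) == 1 and segs[0] == (0, x_len):
        return ParCall(track.x_name, tuple(segs), None, 0, threshold,
                       flag="diploid X, PAR not resolvable")

    candidates = [
        (s, e) for s, e in segs
        if (s == 0 or e == x_len) and (e - s) >= min_par
    ]
    par = max(candidates, key=lambda se: se[1] - se[0]) if candidates else None
    return ParCall(
        x_name=track.x_name,
        segments=tuple(segs),
        par=par,
        par_length=(par[1] - par[0]) if par else 0,
        threshold_used=threshold,
    )
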