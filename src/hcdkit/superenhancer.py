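"""ROSE-style super-enhancer calling.

Pipeline: remove enhancer candidates fully inside a ±500 bp window around any
transcription start site, stitch the survivors within 12.5 kb into candidate
regions, score each region by input-subtracted per-million ChIP signal summed
over its constituent enhancers (not the stitched gaps), and place the
super-enhancer cutoff where a line of slope (max-min)/N, swept along the
ascending ranked-score curve, leaves the fewest points below it — the
geometric "tangent line" elbow.  Regions scoring above the cutoff are the
super-enhancers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DataError
from .intervals import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    check_chrom_compatibility,
    connected_union,
    merge_within,
)

logger = logging.getLogger(__name__)


class SignalTrack:
    """Piecewise-constant, non-negative coverage per chromosome.

    Steps are sorted, non-overlapping ``(start, end, value)`` triples; bases
    not covered by any step have value 0.  ``library_total`` (sum of
    value x width unless supplied) is the denominator of the per-million
    normalisation used for scoring.
    """

    def __init__(
        self,
        steps: dict[str, np.ndarray] | Sequence[tuple[str, int, int, float]],
        library_total: float | None = None,
    ) -> None:
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        if isinstance(steps, dict):
            items = [
                (chrom, int(s), int(e), float(v))
                for chrom, arr in steps.items()
                for s, e, v in arr
            ]
        else:
            items = [(c, int(s), int(e), float(v)) for c, s, e, v in steps]
        for chrom, s, e, v in items:
            if not np.isfinite(v):
                raise DataError(f"non-finite signal value at {chrom}:{s}-{e}")
            if v < 0:
                raise DataError(f"negative signal value {v} at {chrom}:{s}-{e}")
            if e <= s:
                raise DataError(f"empty signal step at {chrom}:{s}-{e}")
            by_chrom.setdefault(chrom, []).append((s, e, v))
        self.steps: dict[str, np.ndarray] = {}
        total = 0.0
        for chrom, triples in by_chrom.items():
            triples.sort()
            for (s1, e1, _), (s2, _, _) in zip(triples, triples[1:]):
                if s2 < e1:
                    raise DataError(f"overlapping signal steps on {chrom} at {s2} < {e1}")
            arr = np.array(triples, dtype=float)
            self.steps[chrom] = arr
            total += float(np.sum((arr[:, 1] - arr[:, 0]) * arr[:, 2]))
        self.library_total = float(library_total) if library_total is not None else total
        if self.library_total <= 0:
            logger.warning("signal track has zero total signal; scores will be 0")

    @classmethod
    def from_bedgraph(cls, path: str | Path, library_total: float | None = None) -> "SignalTrack":
        """Read a 4-column headerless bedGraph (overlapping steps are a data
        error)."""
        triples: list[tuple[str, int, int, float]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                s = line.strip()
                if not s or s.startswith(("#", "track", "browser")):
                    continue
                fields = s.split()
                if len(fields) < 4:
                    raise DataError(f"{path}:{lineno}: expected 4 bedGraph columns")
                try:
                    triples.append(
                        (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                    )
                except ValueError as exc:
                    raise DataError(f"{path}:{lineno}: malformed bedGraph line") from exc
        return cls(triples, library_total=library_total)

    @classmethod
    def from_read_intervals(
        cls, reads: IntervalSet, library_total: float | None = None
    ) -> "SignalTrack":
        """Convert read-spanning intervals (e.g. a BED of fragments) into a
        coverage track by counting overlap depth per base."""
        triples: list[tuple[str, int, int, float]] = []
        for chrom, ivs in reads.by_chrom().items():
            edges = sorted(
                [(iv.start, 1) for iv in ivs] + [(iv.end, -1) for iv in ivs]
            )
            depth = 0
            prev = None
            for pos, delta in edges:
                if prev is not None and pos > prev and depth > 0:
                    triples.append((chrom, prev, pos, float(depth)))
                depth += delta
                prev = pos
        if library_total is None:
            library_total = float(len(reads))
        return cls(triples, library_total=library_total)

    def raw_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of value x covered-base over [start, end)."""
        arr = self.steps.get(chrom)
        if arr is None or len(arr) == 0:
            return 0.0
        starts, ends, values = arr[:, 0], arr[:, 1], arr[:, 2]
        overlap = np.minimum(ends, end) - np.maximum(starts, start)
        mask = overlap > 0
        return float(np.sum(overlap[mask] * values[mask]))

    def normalized_sum(self, chrom: str, start: int, end: int) -> float:
        """Per-million-normalised signal over [start, end)."""
        if self.library_total <= 0:
            return 0.0
        return self.raw_sum(chrom, start, end) * 1e6 / self.library_total


@dataclass
class StitchedRegion:
    """A stitched enhancer region with its constituents and signal scores.

    ``score = max(score_treatment - score_control, 0)``; signal is summed
    over constituent enhancers only, never the stitched-over gaps.
    """

    span: GenomicInterval
    constituents: tuple[GenomicInterval, ...]
    score_treatment: float = 0.0
    score_control: float = 0.0
    score: float = 0.0
    rank: int | None = None


@dataclass
class SECallResult:
    """Result of a super-enhancer call: the ascending ranked curve, the elbow
    cutoff, and the regions above it."""

    ranked: list[StitchedRegion]
    cutoff_value: float
    cutoff_index: int  # 1-based position on the ascending curve
    superenhancers: list[StitchedRegion] = field(default_factory=list)


def exclude_tss_proximal(
    enhancers: IntervalSet,
    genes: Sequence[GeneModel],
    zone_bp: int = 500,
    any_overlap: bool = False,
) -> IntervalSet:
    """Drop enhancer candidates inside TSS exclusion zones.

    The zone around a TSS at position t is ``[t - zone_bp, t + zone_bp + 1)``
    (±zone_bp bases inclusive).  By default only candidates *fully contained*
    in a zone are removed; ``any_overlap=True`` removes candidates touching a
    zone at all.
    """
    if zone_bp < 0:
        raise ValueError(f"zone_bp must be >= 0, got {zone_bp}")
    if len(enhancers) and genes:
        check_chrom_compatibility(enhancers.chroms(), (g.chrom for g in genes))
    zones: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        zones.setdefault(g.chrom, []).append(
            (max(0, g.tss - zone_bp), g.tss + zone_bp + 1)
        )
    kept = []
    for iv in enhancers.sorted():
        removed = False
        for zs, ze in zones.get(iv.chrom, ()):
            if any_overlap:
                if iv.start < ze and zs < iv.end:
                    removed = True
                    break
            elif zs <= iv.start and iv.end <= ze:
                removed = True
                break
        if not removed:
            kept.append(iv)
    return IntervalSet(kept)


def stitch(enhancers: IntervalSet, distance_bp: int = 12500) -> list[StitchedRegion]:
    """Stitch enhancer candidates separated by <= ``distance_bp`` into
    regions; singletons become their own region.  Spans equal
    :func:`merge_within` of the input at the same distance."""
    if distance_bp < 0:
        raise ValueError(f"distance_bp must be >= 0, got {distance_bp}")
    regions: list[StitchedRegion] = []
    for chrom, ivs in enhancers.by_chrom().items():
        group: list[GenomicInterval] = [ivs[0]]
        group_end = ivs[0].end
        for iv in ivs[1:]:
            if iv.start - group_end <= distance_bp:
                group.append(iv)
                group_end = max(group_end, iv.end)
            else:
                regions.append(_make_region(chrom, group))
                group = [iv]
                group_end = iv.end
        regions.append(_make_region(chrom, group))
    return regions


def _make_region(chrom: str, group: list[GenomicInterval]) -> StitchedRegion:
    start = min(iv.start for iv in group)
    end = max(iv.end for iv in group)
    return StitchedRegion(
        span=GenomicInterval(chrom, start, end), constituents=tuple(group)
    )


def score_regions(
    regions: Sequence[StitchedRegion],
    treatment: SignalTrack,
    control: SignalTrack | None = None,
) -> list[StitchedRegion]:
    """Score stitched regions by per-million treatment signal summed over
    constituents, minus control where supplied, floored at 0."""
    scored = []
    for r in regions:
        t = sum(
            treatment.normalized_sum(c.chrom, c.start, c.end) for c in r.constituents
        )
        c = (
            sum(control.normalized_sum(cv.chrom, cv.start, cv.end) for cv in r.constituents)
            if control is not None
            else 0.0
        )
        scored.append(
            StitchedRegion(
                span=r.span,
                constituents=r.constituents,
                score_treatment=t,
                score_control=c,
                score=max(t - c, 0.0),
            )
        )
    return scored


def elbow_cutoff(scores: Sequence[float]) -> tuple[float, int]:
    """Tangent-line elbow on the ascending ranked-score curve.

    Negatives are clamped to 0 and the scores sorted ascending.  With slope
    m = (max - min)/N, the cutoff position x minimises the number of points
    lying strictly below the line through (x, scores[x]) with slope m (ties
    broken toward the smallest x).  Returns ``(cutoff_value, cutoff_index)``
    with a 1-based index.  Constant scores are the degenerate case: the
    cutoff is the constant itself, so nothing exceeds it.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1 or len(s) < 3:
        raise ValueError(f"need >= 3 scores, got {len(s)}")
    if not np.all(np.isfinite(s)):
        raise DataError("scores must be finite")
    s = np.sort(np.clip(s, 0.0, None))
    n = len(s)
    slope = (s[-1] - s[0]) / n
    if slope == 0.0:
        logger.info("constant score curve; degenerate cutoff, zero super-enhancers")
        return float(s[0]), 1
    idx = np.arange(n)
    # line through (x, s[x]): value at j is s[x] + slope * (j - x)
    line = s[:, None] + slope * (idx[None, :] - idx[:, None])
    below = np.sum(s[None, :] < line, axis=1)
    x = int(np.argmin(below))  # argmin takes the smallest index on ties
    return float(s[x]), x + 1


def call_superenhancers(
    enhancers: IntervalSet,
    genes: Sequence[GeneModel],
    treatment: SignalTrack,
    control: SignalTrack | None = None,
    stitch_bp: int = 12500,
    zone_bp: int = 500,
    any_overlap_tss: bool = False,
) -> SECallResult:
    """Full super-enhancer pipeline: TSS exclusion -> stitch -> score ->
    elbow cutoff.  Super-enhancers are the regions scoring strictly above the
    cutoff value."""
    kept = exclude_tss_proximal(enhancers, genes, zone_bp, any_overlap=any_overlap_tss)
    regions = stitch(kept, stitch_bp)
    if len(regions) < 3:
        raise ValueError(
            f"only {len(regions)} stitched regions; >= 3 needed for a cutoff"
        )
    scored = score_regions(regions, treatment, control)
    scored.sort(key=lambda r: (r.score, r.span.sort_key()))
    for rank, r in enumerate(scored, start=1):
        r.rank = rank
    cutoff_value, cutoff_index = elbow_cutoff([r.score for r in scored])
    ses = [r for r in scored if r.score > cutoff_value]
    logger.info(
        "SE call: %d stitched regions, cutoff %.4g at rank %d, %d super-enhancers",
        len(scored), cutoff_value, cutoff_index, len(ses),
    )
    return SECallResult(
        ranked=scored,
        cutoff_value=cutoff_value,
        cutoff_index=cutoff_index,
        superenhancers=ses,
    )


def combine_marks(
    se_a: Sequence[StitchedRegion], se_b: Sequence[StitchedRegion]
) -> IntervalSet:
    """Union spans of overlapping super-enhancers from two marks; spans
    supported by only one mark are dropped."""
    comps = connected_union(
        IntervalSet(r.span for r in se_a).sorted(),
        IntervalSet(r.span for r in se_b).sorted(),
    )
    return IntervalSet(c.span for c in comps)


def write_se_results(
    result: SECallResult,
    bed_path: str | Path,
    tsv_path: str | Path | None = None,
    curve_path: str | Path | None = None,
) -> None:
    """Write super-enhancers as BED6 plus optional per-region score TSV and a
    (rank, score) curve table for external plotting."""
    from .intervals import write_intervals

    ses = IntervalSet(
        GenomicInterval(
            r.span.chrom, r.span.start, r.span.end,
            name=f"SE_{r.span.chrom}_{r.span.start}", score=r.score,
        )
        for r in result.superenhancers
    ).sorted()
    write_intervals(ses, bed_path, "bed6")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write(
                "chrom\tstart\tend\tn_constituents\tscore_treatment\t"
                "score_control\tscore\trank\tis_superenhancer\tcutoff_value\n"
            )
            for r in result.ranked:
                fh.write(
                    f"{r.span.chrom}\t{r.span.start}\t{r.span.end}\t"
                    f"{len(r.constituents)}\t{r.score_treatment:.6g}\t"
                    f"{r.score_control:.6g}\t{r.score:.6g}\t{r.rank}\t"
                    f"{int(r.score > result.cutoff_value)}\t{result.cutoff_value:.6g}\n"
                )
    if curve_path is not None:
        with open(curve_path, "w") as fh:
            fh.write("rank\tscore\n")
            for r in result.ranked:
                fh.write(f"{r.rank}\t{r.score:.6g}\n")
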