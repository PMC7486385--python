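"""Domain calling by peak breadth.

The core procedure: per-mark replicate peak calls are collapsed to their
base-pair intersection (replicate consensus), consensus peaks are ranked by
breadth (broadest first) and cut at a top fraction (2% for the dual-mark
acetyl/methyl analysis, 5% for H3K4Me3-only domains, 1% where a smaller
comparator list is wanted), and a hyperacetylated chromatin domain (HCD) is
emitted wherever top-tier peaks of the two marks overlap, as the union span
of the overlapping peaks.  Breadth — not signal height — is the ranking axis:
read-deduplication caps peak height, while breadth keeps discriminating at
the top of the distribution.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from functools import reduce
from pathlib import Path
from typing import Sequence

from .intervals import (
    GenomicInterval,
    IntervalSet,
    connected_union,
    pairwise_intersection,
    write_intervals,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedPeak:
    """A peak with its breadth rank (1 = broadest)."""

    interval: GenomicInterval
    breadth: int
    rank: int

    def __post_init__(self) -> None:
        if self.breadth != self.interval.breadth:
            raise ValueError("breadth must equal interval breadth")


@dataclass(frozen=True)
class BreadthCutoff:
    """Metadata of a top-breadth filter: the fraction applied, input/kept
    counts, and the smallest breadth among kept peaks."""

    fraction: float
    n_input: int
    n_kept: int
    threshold_bp: int

    def to_dict(self) -> dict:
        return {
            "fraction": self.fraction,
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "threshold_bp": self.threshold_bp,
        }


@dataclass(frozen=True)
class Domain:
    """A called domain: the union span plus the member peaks per mark."""

    span: GenomicInterval
    marks: frozenset[str]
    members: dict[str, tuple[RankedPeak, ...]]
    domain_id: str

    def total_member_breadth(self) -> int:
        return sum(p.breadth for peaks in self.members.values() for p in peaks)


def replicate_consensus(
    replicates: Sequence[IntervalSet], allow_single: bool = False
) -> IntervalSet:
    """Base-pair intersection across replicate peak calls.

    The consensus keeps exactly the bases called in *every* replicate, as
    maximal sub-intervals.  Base-pair intersection is associative, so the
    left fold is order-independent.  A single replicate is only accepted
    behind ``allow_single=True`` (explicit opt-out of replication).
    """
    if len(replicates) < 2:
        if allow_single and len(replicates) == 1:
            return replicates[0].sorted()
        raise ValueError(
            f"need >= 2 replicates (got {len(replicates)}); "
            "pass allow_single=True for deliberate single-replicate passthrough"
        )
    return reduce(pairwise_intersection, replicates)


def top_breadth_filter(
    peaks: IntervalSet, fraction: float
) -> tuple[list[RankedPeak], BreadthCutoff]:
    """Keep the top ``fraction`` of peaks ranked by breadth.

    Peaks are sorted by breadth descending (ties broken by coordinate for a
    stable rank order); the nominal cut is ceil(fraction * N) peaks, and any
    peak tying the boundary breadth is also kept so the result is independent
    of tie order.  ``threshold_bp`` is the smallest kept breadth.
    """
    if len(peaks) == 0:
        raise ValueError("cannot rank an empty peak set")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    by_breadth = sorted(
        peaks, key=lambda iv: (-iv.breadth, iv.chrom, iv.start, iv.end)
    )
    n = len(by_breadth)
    n_nominal = math.ceil(fraction * n)
    threshold_bp = by_breadth[n_nominal - 1].breadth
    kept = [
        RankedPeak(iv, iv.breadth, rank)
        for rank, iv in enumerate(by_breadth, start=1)
        if iv.breadth >= threshold_bp
    ]
    cutoff = BreadthCutoff(fraction, n, len(kept), threshold_bp)
    if len(kept) > n_nominal:
        logger.info(
            "breadth filter: %d boundary ties at %d bp included beyond the "
            "nominal %d peaks",
            len(kept) - n_nominal,
            threshold_bp,
            n_nominal,
        )
    return kept, cutoff


def call_hcds(
    top_mark_a: Sequence[RankedPeak],
    top_mark_b: Sequence[RankedPeak],
    mark_a: str = "H3K27Ac",
    mark_b: str = "H3K4Me2",
) -> list[Domain]:
    """Call dual-mark domains from two top-breadth peak lists.

    A domain is emitted for every overlap-connected component that contains
    top peaks of *both* marks, as the union span of its members.  Top peaks
    of one mark with no overlapping partner yield nothing.
    """
    if not top_mark_a or not top_mark_b:
        logger.warning(
            "empty top-peak list (%s: %d, %s: %d); no domains called",
            mark_a, len(top_mark_a), mark_b, len(top_mark_b),
        )
        return []
    idx_a = {p.interval.sort_key(): p for p in top_mark_a}
    idx_b = {p.interval.sort_key(): p for p in top_mark_b}
    components = connected_union(
        IntervalSet(p.interval for p in top_mark_a).sorted(),
        IntervalSet(p.interval for p in top_mark_b).sorted(),
    )
    domains = []
    for comp in components:
        domains.append(
            Domain(
                span=comp.span,
                marks=frozenset({mark_a, mark_b}),
                members={
                    mark_a: tuple(idx_a[iv.sort_key()] for iv in comp.members_a),
                    mark_b: tuple(idx_b[iv.sort_key()] for iv in comp.members_b),
                },
                domain_id=f"HCD_{comp.span.chrom}_{comp.span.start}",
            )
        )
    return domains


def call_single_mark_domains(
    peaks: IntervalSet, fraction: float, mark: str = "H3K4Me3"
) -> tuple[list[Domain], BreadthCutoff]:
    """Single-mark breadth domains (e.g. broadest 5% of H3K4Me3 consensus).

    Each kept peak is promoted to a Domain on its own; no cross-peak merging.
    """
    kept, cutoff = top_breadth_filter(peaks, fraction)
    domains = [
        Domain(
            span=p.interval,
            marks=frozenset({mark}),
            members={mark: (p,)},
            domain_id=f"HCD_{p.interval.chrom}_{p.interval.start}",
        )
        for p in sorted(kept, key=lambda p: p.interval.sort_key())
    ]
    return domains, cutoff


def domains_to_interval_set(domains: Sequence[Domain]) -> IntervalSet:
    return IntervalSet(
        GenomicInterval(
            d.span.chrom,
            d.span.start,
            d.span.end,
            name=d.domain_id,
            score=float(d.total_member_breadth()),
        )
        for d in domains
    ).sorted()


def write_domains(
    domains: Sequence[Domain],
    bed_path: str | Path,
    tsv_path: str | Path | None = None,
    cutoffs: dict[str, BreadthCutoff] | None = None,
    json_path: str | Path | None = None,
) -> None:
    """Write domains as BED6 (name=domain id, score=total member breadth),
    an optional per-member TSV sidecar, and optional cutoff metadata JSON."""
    write_intervals(domains_to_interval_set(domains), bed_path, "bed6")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("domain_id\tchrom\tstart\tend\tmark\tpeak_start\tpeak_end\tbreadth\trank\n")
            for d in domains:
                for mark in sorted(d.members):
                    for p in d.members[mark]:
                        fh.write(
                            f"{d.domain_id}\t{d.span.chrom}\t{d.span.start}\t{d.span.end}"
                            f"\t{mark}\t{p.interval.start}\t{p.interval.end}"
                            f"\t{p.breadth}\t{p.rank}\n"
                        )
    if json_path is not None:
        payload = {mark: c.to_dict() for mark, c in (cutoffs or {}).items()}
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
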