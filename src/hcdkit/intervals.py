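"""Genomic interval data model and algebra.

All coordinates are BED-style: 0-based, half-open ``[start, end)``.  This is
the single convention used internally and in every file the package reads or
writes; 1-based inputs are never auto-detected, because silently guessing the
convention is the classic source of off-by-one corruption in genome
arithmetic.

Two distinct adjacency conventions coexist, both deliberate and both the
dominant convention in the field's interval tooling:

* :func:`merge_within` with ``max_gap=0`` merges *bookended* intervals
  (``[0,10)`` + ``[10,20)`` -> ``[0,20)``), because a zero-base gap is a gap
  of size 0.
* Overlap-based operations (:func:`pairwise_intersection`,
  :func:`connected_union`) require at least one shared base; bookended
  intervals do not overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import ConfigError, DataError, ParseError

logger = logging.getLogger(__name__)

#: columns required by each supported BED dialect
DIALECT_COLUMNS = {"bed3": 3, "bed6": 6, "broadpeak": 9, "narrowpeak": 10}

_SKIP_PREFIXES = ("#", "track", "browser")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``chrom:[start, end)``.

    ``breadth`` (= end - start) is the quantity domain calling ranks on, as
    opposed to peak height/signal.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def breadth(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share >= 1 base (bookended does not count)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    Operations that require sorted input call :meth:`sorted` internally, so
    callers may hand over intervals in any order; ``sorted_flag`` records
    whether the current order is (chrom, start, end)-sorted.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self.sorted_flag: bool = all(
            self.intervals[i].sort_key() <= self.intervals[i + 1].sort_key()
            for i in range(len(self.intervals) - 1)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    def sorted(self) -> "IntervalSet":
        """Return self if already sorted, else a sorted copy."""
        if self.sorted_flag:
            return self
        out = IntervalSet(sorted(self.intervals, key=GenomicInterval.sort_key))
        return out

    def sort_and_validate(self, assembly: "GenomeAssembly | None" = None) -> "IntervalSet":
        """Sort in place; optionally check bounds against an assembly."""
        self.intervals.sort(key=GenomicInterval.sort_key)
        self.sorted_flag = True
        if assembly is not None:
            for iv in self.intervals:
                assembly.validate(iv)
        return self

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def total_bases(self) -> int:
        """Number of distinct bases covered (overlaps counted once)."""
        return sum(iv.breadth for iv in merge_within(self, 0))

    def rename_chroms(self, mapping: Mapping[str, str]) -> "IntervalSet":
        """Apply an explicit chromosome renaming map (e.g. ``{"1": "chr1"}``)."""
        return IntervalSet(
            replace(iv, chrom=mapping.get(iv.chrom, iv.chrom)) for iv in self.intervals
        )

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.sorted():
            out.setdefault(iv.chrom, []).append(iv)
        return out


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand and the derived transcription start site.

    The TSS — ``start`` on the + strand, ``end - 1`` on the - strand — is the
    anchor for promoter-exclusion zones and for domain/gene containment calls.
    """

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.gene_id)


@dataclass
class GenomeAssembly:
    """Chromosome name -> length map used to validate interval bounds."""

    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {size}")

    def validate(self, interval: GenomicInterval) -> None:
        size = self.chrom_sizes.get(interval.chrom)
        if size is None:
            raise DataError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > size:
            raise DataError(f"interval {interval} exceeds {interval.chrom} length {size}")


@dataclass(frozen=True)
class NearestHit:
    """One (query, gene) nearest-neighbour pair.

    ``signed_distance`` is 0 for overlap/bookended contact, negative when the
    gene lies at lower coordinates than the query (upstream on the reference +
    strand), positive when higher.  ``contained`` is true iff the gene's TSS
    falls inside the query span.
    """

    query: GenomicInterval
    gene: GeneModel
    signed_distance: int
    contained: bool


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _is_data_line(line: str) -> bool:
    s = line.strip()
    return bool(s) and not any(s.startswith(p) for p in _SKIP_PREFIXES)


def read_intervals(path: str | Path, dialect: str = "bed3") -> IntervalSet:
    """Read a BED-family file into an :class:`IntervalSet`.

    Supported dialects: bed3, bed6, broadPeak, narrowPeak (case-insensitive).
    Coordinates are taken verbatim (0-based half-open).  ``track``/``browser``
    and ``#`` comment lines are skipped.  Columns beyond chrom/start/end are
    kept: column 4 as ``name``, column 5 as ``score``, the rest verbatim in
    ``extra`` so writes round-trip.
    """
    dialect = dialect.lower()
    if dialect not in DIALECT_COLUMNS:
        raise ConfigError(
            f"unknown dialect {dialect!r}; expected one of {sorted(DIALECT_COLUMNS)}"
        )
    ncol = DIALECT_COLUMNS[dialect]
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not _is_data_line(line):
                continue
            fields = line.split()
            if len(fields) < ncol:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {ncol} columns for {dialect}, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid coordinates [{start}, {end})"
                )
            name = fields[3] if ncol > 3 else None
            score: float | None = None
            if ncol > 4:
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            extra = tuple(fields[5:ncol])
            intervals.append(
                GenomicInterval(chrom, start, end, name=name, score=score, extra=extra)
            )
    return IntervalSet(intervals)


def _format_score(score: float | None) -> str:
    if score is None:
        return "0"
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_intervals(intervals: IntervalSet, path: str | Path, dialect: str = "bed3") -> None:
    """Write an IntervalSet as a tab-delimited BED-family file (no header)."""
    dialect = dialect.lower()
    if dialect not in DIALECT_COLUMNS:
        raise ConfigError(f"unknown dialect {dialect!r}")
    ncol = DIALECT_COLUMNS[dialect]
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals.sorted()):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if ncol > 3:
                fields.append(iv.name if iv.name is not None else f"feature_{i + 1}")
            if ncol > 4:
                fields.append(_format_score(iv.score))
            if ncol > 5:
                extra = list(iv.extra)
                # pad missing dialect columns with neutral defaults
                defaults = {
                    "bed6": ["."],
                    "broadpeak": [".", "0", "-1", "-1"],
                    "narrowpeak": [".", "0", "-1", "-1", "-1"],
                }[dialect]
                extra += defaults[len(extra):]
                fields.extend(extra[: ncol - 5])
            fh.write("\t".join(fields) + "\n")


def read_gene_models(path: str | Path, fmt: str = "tsv") -> list[GeneModel]:
    """Read gene models.

    ``fmt="tsv"``: 5+ columns (chrom, start, end, strand, gene_id), optional
    header line.  ``fmt="bed6"``: standard BED6 with name=gene_id in column 4
    and strand in column 6.  Gene ids must be unique.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not _is_data_line(line):
                continue
            fields = line.split()
            if fmt == "tsv":
                if len(fields) < 5:
                    raise ParseError(f"{path}:{lineno}: expected >= 5 columns")
                chrom, s, e, strand, gene_id = fields[:5]
            elif fmt == "bed6":
                if len(fields) < 6:
                    raise ParseError(f"{path}:{lineno}: expected >= 6 columns")
                chrom, s, e, gene_id, _, strand = fields[:6]
            else:
                raise ConfigError(f"unknown gene model format {fmt!r}")
            try:
                start, end = int(s), int(e)
            except ValueError:
                if lineno == 1:
                    continue  # header line
                raise ParseError(f"{path}:{lineno}: non-integer coordinate")
            genes.append(GeneModel(chrom, start, end, strand, gene_id))
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})[:5]
        raise DataError(f"{path}: duplicate gene ids, e.g. {dupes}")
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tgene_id\n")
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{g.gene_id}\n")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def check_chrom_compatibility(a_chroms: Iterable[str], b_chroms: Iterable[str]) -> None:
    """Raise when two non-empty inputs share no chromosome names.

    A completely disjoint namespace (``chr1`` vs ``1``) silently drops every
    feature in naive pipelines; here it is a hard error, fixable via
    :meth:`IntervalSet.rename_chroms`.
    """
    a, b = set(a_chroms), set(b_chroms)
    if a and b and not (a & b):
        raise DataError(
            f"no shared chromosome names between inputs "
            f"(e.g. {sorted(a)[:3]} vs {sorted(b)[:3]}); apply a renaming map"
        )


def merge_within(intervals: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Merge intervals separated by <= ``max_gap`` bases on the same chromosome.

    ``max_gap=0`` merges overlapping *and* bookended intervals (the coverage
    union).  Output intervals are pairwise separated by > ``max_gap``.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    merged: list[GenomicInterval] = []
    for chrom, ivs in intervals.by_chrom().items():
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return IntervalSet(merged)


def pairwise_intersection(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-pair intersection: maximal sub-intervals covered by both sets.

    The output's base set is exactly (bases of a) AND (bases of b); bookended
    contact contributes nothing.
    """
    if len(a) and len(b):
        check_chrom_compatibility(a.chroms(), b.chroms())
    ca, cb = merge_within(a, 0).by_chrom(), merge_within(b, 0).by_chrom()
    out: list[GenomicInterval] = []
    for chrom in sorted(set(ca) & set(cb)):
        xs, ys = ca[chrom], cb[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return IntervalSet(out)


@dataclass(frozen=True)
class UnionComponent:
    """A connected component of the two-set overlap graph containing members
    of both sets, emitted as its spanning union interval."""

    span: GenomicInterval
    members_a: tuple[GenomicInterval, ...]
    members_b: tuple[GenomicInterval, ...]


def connected_union(a: IntervalSet, b: IntervalSet) -> list[UnionComponent]:
    """Union spans of overlap-connected components containing both sets.

    Build the overlap graph on a ∪ b (edge = >= 1 shared base).  For interval
    graphs the connected components are exactly the strict-overlap chains in
    coordinate order, so a single sweep suffices.  Components with members
    from only one input are discarded.
    """
    if len(a) and len(b):
        check_chrom_compatibility(a.chroms(), b.chroms())
    tagged = [(iv, 0) for iv in a] + [(iv, 1) for iv in b]
    tagged.sort(key=lambda t: (t[0].sort_key(), t[1]))
    out: list[UnionComponent] = []
    comp: list[tuple[GenomicInterval, int]] = []
    comp_end = None
    comp_chrom = None

    def flush() -> None:
        mem_a = tuple(iv for iv, tag in comp if tag == 0)
        mem_b = tuple(iv for iv, tag in comp if tag == 1)
        if mem_a and mem_b:
            start = min(iv.start for iv, _ in comp)
            end = max(iv.end for iv, _ in comp)
            out.append(UnionComponent(GenomicInterval(comp_chrom, start, end), mem_a, mem_b))

    for iv, tag in tagged:
        if comp and iv.chrom == comp_chrom and iv.start < comp_end:
            comp.append((iv, tag))
            comp_end = max(comp_end, iv.end)
        else:
            if comp:
                flush()
            comp = [(iv, tag)]
            comp_chrom, comp_end = iv.chrom, iv.end
    if comp:
        flush()
    out.sort(key=lambda c: c.span.sort_key())
    return out


def _gap_distance(q: GenomicInterval, g: GeneModel) -> int:
    """Signed gap: 0 on overlap/bookend, negative when gene is 5' (lower
    coordinate) of the query, positive when 3'."""
    if g.end <= q.start:
        return -(q.start - g.end)
    if g.start >= q.end:
        return g.start - q.end
    return 0


def nearest_features(query: IntervalSet, subject: Sequence[GeneModel]) -> list[NearestHit]:
    """For each query interval report the gene(s) with minimal gap distance.

    All equidistant ties are reported, ordered by (chrom, start, gene_id) —
    the tie-reporting behaviour of the standard closest-feature tools.
    Queries on chromosomes with no genes yield no hit (logged).
    """
    if not subject:
        raise ValueError("subject gene list must be non-empty")
    if len(query):
        check_chrom_compatibility(query.chroms(), (g.chrom for g in subject))
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(subject, key=lambda g: (g.chrom, g.start, g.gene_id)):
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    hits: list[NearestHit] = []
    for q in query.sorted():
        genes = genes_by_chrom.get(q.chrom)
        if not genes:
            logger.warning("no genes on %s; query %s has no nearest feature", q.chrom, q)
            continue
        dists = [abs(_gap_distance(q, g)) for g in genes]
        dmin = min(dists)
        for g, d in zip(genes, dists):
            if d == dmin:
                signed = _gap_distance(q, g)
                contained = q.start <= g.tss < q.end
                hits.append(NearestHit(q, g, signed, contained))
    return hits
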