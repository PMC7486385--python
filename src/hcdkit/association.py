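"""Domain/SE-to-gene association and expression comparison.

Domains and super-enhancers are tied to genes by the nearest-neighbour rule
(closest gene by gap distance, 0 on overlap, all ties reported).  Gene sets
are then partitioned into domain-only / SE-only / both categories plus an
"enhancers within introns" control group, joined to an expression table, and
compared with a two-sample Student's t-test (pooled variance by default,
Welch available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .intervals import GeneModel, GenomicInterval, IntervalSet, nearest_features

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneAssociation:
    """One feature-gene link: signed gap distance and TSS containment."""

    feature_id: str
    gene_id: str
    signed_distance: int
    contained: bool
    feature_kind: str  # "hcd" or "se"


class ExpressionTable:
    """gene_id -> expression value, one row per gene after aggregation.

    Multiple probes per gene are aggregated by mean (or max); values must be
    finite.  The scale is whatever the platform provides — no automatic log
    transform (``log2_transform`` is available explicitly).
    """

    def __init__(self, values: pd.Series | dict[str, float]):
        s = pd.Series(values, dtype=float)
        s.index = s.index.astype(str)
        if not np.isfinite(s.to_numpy()).all():
            raise DataError("expression values must be finite")
        if s.index.has_duplicates:
            raise DataError("gene ids must be unique after aggregation")
        self.values = s

    @classmethod
    def from_tsv(
        cls, path: str | Path, aggregate: str = "mean"
    ) -> "ExpressionTable":
        """Read a 2+-column TSV with a header (gene, value); duplicate gene
        rows (multiple probes) are aggregated by ``aggregate``."""
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise DataError(f"{path}: expected >= 2 columns (gene, value)")
        gene_col, value_col = df.columns[0], df.columns[1]
        if aggregate not in ("mean", "max"):
            raise ValueError(f"aggregate must be 'mean' or 'max', got {aggregate!r}")
        grouped = df.groupby(gene_col)[value_col].agg(aggregate)
        return cls(grouped)

    def to_tsv(self, path: str | Path) -> None:
        df = self.values.rename("expression").rename_axis("gene_id").reset_index()
        df.to_csv(path, sep="\t", index=False)

    def log2_transform(self) -> "ExpressionTable":
        return ExpressionTable(np.log2(self.values + 1.0))

    def get(self, gene_ids: Iterable[str]) -> np.ndarray:
        """Expression values for the genes present in the table."""
        ids = [g for g in gene_ids if g in self.values.index]
        return self.values.loc[ids].to_numpy()

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CategoryAssignment:
    """Disjoint domain/SE gene categories plus the intronic-enhancer control."""

    hcd_only: set[str]
    se_only: set[str]
    both: set[str]
    intron_enhancer_control: set[str]

    def as_dict(self) -> dict[str, set[str]]:
        return {
            "hcd_only": self.hcd_only,
            "se_only": self.se_only,
            "both": self.both,
            "intron_enhancer_control": self.intron_enhancer_control,
        }


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample t-test summary."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    n_x: int
    n_y: int
    mean_x: float
    mean_y: float


def associate_nearest(
    features: IntervalSet,
    genes: Sequence[GeneModel],
    feature_kind: str = "hcd",
    expression: ExpressionTable | None = None,
    expressed_only: float | None = None,
) -> list[GeneAssociation]:
    """Nearest-gene association for domain or SE spans.

    ``expressed_only`` restricts the candidate gene universe to genes at or
    above the threshold *before* the nearest search (an operational reading
    of "nearest active gene"); it requires an expression table.  All
    equidistant ties are emitted.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    if expressed_only is not None:
        if expression is None:
            raise ValueError("expressed_only requires an expression table")
        active = set(
            expression.values.index[expression.values >= expressed_only]
        )
        genes = [g for g in genes if g.gene_id in active]
        if not genes:
            raise ValueError("no genes pass the expression threshold")
    hits = nearest_features(features, genes)
    return [
        GeneAssociation(
            feature_id=h.query.name or str(h.query),
            gene_id=h.gene.gene_id,
            signed_distance=h.signed_distance,
            contained=h.contained,
            feature_kind=feature_kind,
        )
        for h in hits
    ]


def containment_fraction(assocs: Sequence[GeneAssociation]) -> float:
    """Fraction of features whose selected nearest gene has its TSS inside
    the feature span; the first tie (coordinate order) represents each
    feature."""
    if not assocs:
        raise ValueError("no associations supplied")
    first_per_feature: dict[str, GeneAssociation] = {}
    for a in assocs:
        first_per_feature.setdefault(a.feature_id, a)
    vals = [a.contained for a in first_per_feature.values()]
    return sum(vals) / len(vals)


def categorize_genes(
    hcd_assocs: Sequence[GeneAssociation],
    se_assocs: Sequence[GeneAssociation],
    intron_control: set[str] | None = None,
) -> CategoryAssignment:
    """Partition associated genes into hcd_only / se_only / both."""
    hcd_genes = {a.gene_id for a in hcd_assocs}
    se_genes = {a.gene_id for a in se_assocs}
    return CategoryAssignment(
        hcd_only=hcd_genes - se_genes,
        se_only=se_genes - hcd_genes,
        both=hcd_genes & se_genes,
        intron_enhancer_control=set(intron_control or ()),
    )


def intronic_enhancer_control(
    genes: Sequence[GeneModel],
    enhancers: IntervalSet,
    zone_bp: int = 500,
) -> set[str]:
    """Genes hosting at least one enhancer fully inside the gene body and
    clear of every TSS exclusion zone.

    This approximates "putative enhancers located within introns" without
    exon structure: gene-body containment stands in for intronic placement,
    and the TSS zone (any overlap disqualifies) keeps promoter-proximal
    candidates out.
    """
    zones: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        zones.setdefault(g.chrom, []).append(
            (max(0, g.tss - zone_bp), g.tss + zone_bp + 1)
        )

    def clear_of_zones(iv: GenomicInterval) -> bool:
        return not any(
            iv.start < ze and zs < iv.end for zs, ze in zones.get(iv.chrom, ())
        )

    enh_by_chrom = enhancers.sorted().by_chrom()
    out: set[str] = set()
    for g in genes:
        for iv in enh_by_chrom.get(g.chrom, ()):
            if g.start <= iv.start and iv.end <= g.end and clear_of_zones(iv):
                out.add(g.gene_id)
                break
    return out


def two_sample_ttest(
    x: Sequence[float], y: Sequence[float], variant: str = "pooled"
) -> ComparisonResult:
    """Two-tailed two-sample Student's t-test.

    ``variant="pooled"`` is the classic equal-variance test with
    df = n_x + n_y - 2; ``variant="welch"`` uses the Welch-Satterthwaite
    correction.  Degenerate inputs: zero variance in both samples with equal
    means gives t = 0, p = 1; zero variance with unequal means is an error
    (the statistic is undefined).
    """
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(xa) < 2 or len(ya) < 2:
        raise ValueError(f"need >= 2 values per sample, got {len(xa)} and {len(ya)}")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise DataError("samples must be finite")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    nx, ny = len(xa), len(ya)
    vx, vy = xa.var(ddof=1), ya.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if xa.mean() == ya.mean():
            return ComparisonResult(0.0, float(nx + ny - 2), 1.0, nx, ny,
                                    float(xa.mean()), float(ya.mean()))
        raise DataError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(xa, ya, equal_var=(variant == "pooled"))
    df = float(nx + ny - 2) if variant == "pooled" else float(res.df)
    return ComparisonResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=df,
        p_value=float(res.pvalue),
        n_x=nx,
        n_y=ny,
        mean_x=float(xa.mean()),
        mean_y=float(ya.mean()),
    )


def compare_categories(
    categories: CategoryAssignment,
    expression: ExpressionTable,
    pairs: Sequence[tuple[str, str]] = (("hcd_only", "se_only"),),
    variant: str = "pooled",
) -> dict[str, ComparisonResult]:
    """t-tests between expression values of category pairs (no multiplicity
    correction: these are individually reported pairwise tests)."""
    cats = categories.as_dict()
    out: dict[str, ComparisonResult] = {}
    for a, b in pairs:
        out[f"{a}_vs_{b}"] = two_sample_ttest(
            expression.get(cats[a]), expression.get(cats[b]), variant=variant
        )
    return out


def export_gene_lists(categories: CategoryAssignment, out_dir: str | Path) -> list[Path]:
    """Write one plain-text gene list per category (one symbol per line,
    sorted), ready to paste into external enrichment tools."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, genes in categories.as_dict().items():
        p = out_dir / f"{name}.txt"
        if not genes:
            logger.warning("category %s is empty; writing empty file", name)
        p.write_text("".join(f"{g}\n" for g in sorted(genes)))
        paths.append(p)
    return paths


def write_associations(assocs: Sequence[GeneAssociation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tgene_id\tsigned_distance\tcontained\tfeature_kind\n")
        for a in assocs:
            fh.write(
                f"{a.feature_id}\t{a.gene_id}\t{a.signed_distance}"
                f"\t{int(a.contained)}\t{a.feature_kind}\n"
            )


def read_associations(path: str | Path) -> list[GeneAssociation]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneAssociation(
            str(r.feature_id), str(r.gene_id), int(r.signed_distance),
            bool(r.contained), str(r.feature_kind),
        )
        for r in df.itertuples()
    ]
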