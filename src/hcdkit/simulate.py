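"""Synthetic regulatory landscape generator with ground truth.

Emulates the data shape the callers consume: a gene annotation; two
replicates of broad-peak calls for three histone marks, where a minority of
"identity" genes carry peaks from the heavy upper tail of the breadth
distribution at both the acetyl and methyl marks; TF-style enhancer
candidates near every gene, with planted high-signal clusters at a few loci
so the stitched-score curve has a sharp elbow; and an expression table where
planted-domain genes are shifted upward.  Every quantity is drawn from a
deterministic per-stage random substream, so a fixed seed gives byte-stable
outputs and calling stages independently or together yields identical data.

The generator trades realism for determinism where the two conflict: breadth
draws are truncated so planted domains are always broader than every
background peak, making recovery a construction guarantee rather than a
probabilistic outcome (see docs/methods.md for what that does and does not
demonstrate about real data).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .association import ExpressionTable
from .errors import ConfigError
from .intervals import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    write_gene_models,
    write_intervals,
)
from .superenhancer import SignalTrack

logger = logging.getLogger(__name__)

MARKS = ("H3K27Ac", "H3K4Me2", "H3K4Me3")

# fixed per-stage substream identifiers (genes -> peaks -> signal -> expression)
_STAGE_GENES, _STAGE_PEAKS, _STAGE_SIGNAL, _STAGE_EXPR = 1, 2, 3, 4


@dataclass
class SimulationConfig:
    """Parameters of the synthetic landscape.

    Breadths are log-normal in bp; the planted-domain median (15 kb) is 15x
    the background median (1 kb), and the truncation bounds keep the two
    populations strictly separated so the top-fraction filter is exact by
    construction.  Signal densities are arbitrary coverage units (only
    ratios matter after per-million normalisation); expression is on a
    log2-microarray-like scale.
    """

    seed: int = 42
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 16_000_000, "chr2": 16_000_000}
    )
    n_genes: int = 300
    n_hcd_genes: int = 15
    n_se_loci: int = 10
    gene_length: tuple[int, int] = (2_000, 8_000)
    gene_gap: tuple[int, int] = (50_000, 90_000)
    # log-normal (median_bp, sigma_log) with hard truncation bounds
    background_breadth: tuple[float, float] = (1_000.0, 0.35)
    background_breadth_bounds: tuple[int, int] = (300, 5_000)
    domain_breadth: tuple[float, float] = (15_000.0, 0.25)
    domain_breadth_bounds: tuple[int, int] = (9_000, 40_000)
    replicate_jitter: int = 50
    enhancer_width: tuple[int, int] = (800, 1_200)
    enhancer_offset: tuple[int, int] = (2_000, 10_000)  # |offset| of TSS, bp
    se_cluster_size: tuple[int, int] = (2, 4)
    se_cluster_spacing: int = 3_000
    signal_high: float = 8.0
    signal_low: float = 1.0
    control_density: float = 0.2
    expression_baseline: float = 8.0
    expression_effect: float = 3.0
    expression_noise: float = 1.0

    def validate(self) -> None:
        if self.n_genes < 0 or self.n_hcd_genes < 0 or self.n_se_loci < 0:
            raise ConfigError("counts must be >= 0")
        if self.n_hcd_genes + self.n_se_loci > self.n_genes:
            raise ConfigError(
                f"planted loci ({self.n_hcd_genes} + {self.n_se_loci}) exceed "
                f"n_genes ({self.n_genes})"
            )
        if self.domain_breadth_bounds[0] <= self.background_breadth_bounds[1]:
            raise ConfigError(
                "domain breadth lower bound must exceed background upper bound"
            )
        if self.replicate_jitter < 0:
            raise ConfigError("replicate_jitter must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """What was planted: identity genes with their domain spans, and SE loci
    with their constituent enhancer clusters."""

    planted_hcd_genes: set[str]
    planted_hcd_spans: IntervalSet
    planted_se_genes: set[str]
    planted_se_spans: IntervalSet
    planted_se_constituents: dict[str, tuple[GenomicInterval, ...]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_hcd_genes": sorted(self.planted_hcd_genes),
            "planted_hcd_spans": [
                [iv.chrom, iv.start, iv.end, iv.name] for iv in self.planted_hcd_spans
            ],
            "planted_se_genes": sorted(self.planted_se_genes),
            "planted_se_spans": [
                [iv.chrom, iv.start, iv.end, iv.name] for iv in self.planted_se_spans
            ],
            "planted_se_constituents": {
                g: [[iv.chrom, iv.start, iv.end] for iv in ivs]
                for g, ivs in sorted(self.planted_se_constituents.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            planted_hcd_genes=set(d["planted_hcd_genes"]),
            planted_hcd_spans=IntervalSet(
                GenomicInterval(c, s, e, name=n) for c, s, e, n in d["planted_hcd_spans"]
            ).sorted(),
            planted_se_genes=set(d["planted_se_genes"]),
            planted_se_spans=IntervalSet(
                GenomicInterval(c, s, e, name=n) for c, s, e, n in d["planted_se_spans"]
            ).sorted(),
            planted_se_constituents={
                g: tuple(GenomicInterval(c, s, e) for c, s, e in ivs)
                for g, ivs in d["planted_se_constituents"].items()
            },
        )


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, config.seed])


def _trunc_lognormal(
    rng: np.random.Generator, median: float, sigma: float, bounds: tuple[int, int]
) -> int:
    draw = math.exp(rng.normal(math.log(median), sigma))
    return int(min(max(draw, bounds[0]), bounds[1]))


def simulate_landscape(
    config: SimulationConfig,
) -> tuple[list[GeneModel], GroundTruth]:
    """Place genes and decide which loci carry planted domains / SE clusters.

    Genes are laid down left to right per chromosome with inter-gene gaps
    drawn uniformly from ``gene_gap``; the minimum gap (50 kb) exceeds the
    maximum planted-domain reach, so planted loci can never collide with a
    neighbour.  Planted HCD genes and SE loci are chosen disjointly.
    """
    config.validate()
    rng = _stage_rng(config, _STAGE_GENES)
    chroms = sorted(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    if config.n_genes == 0:
        empty = IntervalSet()
        return [], GroundTruth(set(), empty, set(), IntervalSet(), {})
    quota = np.floor(sizes / sizes.sum() * config.n_genes).astype(int)
    for i in np.argsort(-(sizes / sizes.sum() * config.n_genes - quota)):
        if quota.sum() == config.n_genes:
            break
        quota[i] += 1

    genes: list[GeneModel] = []
    margin = 60_000  # clearance at chromosome ends for broad peaks/clusters
    gid = 0
    for chrom, n_here in zip(chroms, quota):
        cursor = margin
        for _ in range(int(n_here)):
            gap = int(rng.integers(config.gene_gap[0], config.gene_gap[1] + 1))
            length = int(rng.integers(config.gene_length[0], config.gene_length[1] + 1))
            start = cursor + gap
            end = start + length
            if end > config.chrom_sizes[chrom] - margin:
                raise ConfigError(
                    f"cannot place {n_here} genes on {chrom} "
                    f"(size {config.chrom_sizes[chrom]}); enlarge chrom_sizes or "
                    "shrink gene_gap"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            genes.append(GeneModel(chrom, start, end, strand, f"gene_{gid:04d}"))
            cursor = end

    n_planted = config.n_hcd_genes + config.n_se_loci
    planted_idx = rng.choice(len(genes), size=n_planted, replace=False)
    hcd_idx = sorted(int(i) for i in planted_idx[: config.n_hcd_genes])
    se_idx = sorted(int(i) for i in planted_idx[config.n_hcd_genes:])

    hcd_spans = []
    for i in hcd_idx:
        g = genes[i]
        breadth = _trunc_lognormal(
            rng, config.domain_breadth[0], config.domain_breadth[1],
            config.domain_breadth_bounds,
        )
        start = max(0, g.tss - breadth // 2)
        end = min(start + breadth, config.chrom_sizes[g.chrom])
        hcd_spans.append(GenomicInterval(g.chrom, start, end, name=g.gene_id))

    se_spans = []
    se_constituents: dict[str, tuple[GenomicInterval, ...]] = {}
    for i in se_idx:
        g = genes[i]
        k = int(rng.integers(config.se_cluster_size[0], config.se_cluster_size[1] + 1))
        anchor = g.tss + int(rng.integers(config.enhancer_offset[0],
                                          config.enhancer_offset[1] + 1))
        cluster = []
        for j in range(k):
            width = int(rng.integers(config.enhancer_width[0],
                                     config.enhancer_width[1] + 1))
            s = anchor + j * config.se_cluster_spacing
            cluster.append(GenomicInterval(g.chrom, s, s + width))
        se_constituents[g.gene_id] = tuple(cluster)
        se_spans.append(
            GenomicInterval(
                g.chrom, cluster[0].start, cluster[-1].end, name=g.gene_id
            )
        )

    truth = GroundTruth(
        planted_hcd_genes={genes[i].gene_id for i in hcd_idx},
        planted_hcd_spans=IntervalSet(hcd_spans).sorted(),
        planted_se_genes={genes[i].gene_id for i in se_idx},
        planted_se_spans=IntervalSet(se_spans).sorted(),
        planted_se_constituents=se_constituents,
    )
    return genes, truth


def simulate_peak_replicates(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
) -> dict[str, list[IntervalSet]]:
    """Two replicates of broad-peak calls per mark.

    Planted genes receive their ground-truth broad span at every mark (the
    methyl marks shifted by <= 500 bp so the marks overlap but are not
    identical); background genes receive one narrow peak near their TSS.
    Replicate 2 is replicate 1 with each edge jittered by at most
    ``replicate_jitter`` bp, emulating replicate-to-replicate boundary noise.
    """
    rng = _stage_rng(config, _STAGE_PEAKS)
    span_by_gene = {iv.name: iv for iv in truth.planted_hcd_spans}
    out: dict[str, list[IntervalSet]] = {}
    for mark in MARKS:
        rep1 = []
        for g in genes:
            size = config.chrom_sizes[g.chrom]
            if g.gene_id in truth.planted_hcd_genes:
                base = span_by_gene[g.gene_id]
                shift = 0 if mark == "H3K27Ac" else int(rng.integers(-500, 501))
                start = max(0, base.start + shift)
                end = min(base.end + shift, size)
            else:
                width = _trunc_lognormal(
                    rng, config.background_breadth[0], config.background_breadth[1],
                    config.background_breadth_bounds,
                )
                center = g.tss + int(rng.integers(-500, 501))
                start = max(0, center - width // 2)
                end = min(start + width, size)
            rep1.append(
                GenomicInterval(g.chrom, start, end, name=f"{mark}_{g.gene_id}")
            )
        rep2 = []
        j = config.replicate_jitter
        for iv in rep1:
            ds = int(rng.integers(-j, j + 1))
            de = int(rng.integers(-j, j + 1))
            rep2.append(
                GenomicInterval(
                    iv.chrom, max(0, iv.start + ds), iv.end + de, name=iv.name
                )
            )
        out[mark] = [IntervalSet(rep1).sorted(), IntervalSet(rep2).sorted()]
    return out


def simulate_signal_tracks(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
) -> tuple[IntervalSet, SignalTrack, SignalTrack]:
    """Enhancer candidates and treatment/control coverage tracks.

    Every background gene gets one candidate 2-10 kb from its TSS at
    ``signal_low`` density; planted SE loci use their ground-truth clusters
    at ``signal_high``.  The control is flat ``control_density`` genome-wide.
    All candidates clear the ±500 bp TSS zone by construction.
    """
    rng = _stage_rng(config, _STAGE_SIGNAL)
    enhancers: list[GenomicInterval] = []
    steps: list[tuple[str, int, int, float]] = []
    n = 0
    for g in genes:
        if g.gene_id in truth.planted_se_genes:
            for iv in truth.planted_se_constituents[g.gene_id]:
                n += 1
                enhancers.append(
                    GenomicInterval(iv.chrom, iv.start, iv.end, name=f"enh_{n:04d}")
                )
                steps.append((iv.chrom, iv.start, iv.end, config.signal_high))
        else:
            offset = int(rng.integers(config.enhancer_offset[0],
                                      config.enhancer_offset[1] + 1))
            if rng.random() < 0.5:
                offset = -offset
            width = int(rng.integers(config.enhancer_width[0],
                                     config.enhancer_width[1] + 1))
            start = max(0, g.tss + offset - width // 2)
            n += 1
            enhancers.append(
                GenomicInterval(g.chrom, start, start + width, name=f"enh_{n:04d}")
            )
            steps.append((g.chrom, start, start + width, config.signal_low))
    treatment = SignalTrack(steps)
    control = SignalTrack(
        [(c, 0, size, config.control_density) for c, size in sorted(config.chrom_sizes.items())]
    )
    return IntervalSet(enhancers).sorted(), treatment, control


def simulate_expression(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
) -> ExpressionTable:
    """baseline + N(0, noise) per gene, plus ``expression_effect`` at planted
    domain genes."""
    rng = _stage_rng(config, _STAGE_EXPR)
    values = {}
    for g in genes:
        v = config.expression_baseline + rng.normal(0.0, config.expression_noise)
        if g.gene_id in truth.planted_hcd_genes:
            v += config.expression_effect
        values[g.gene_id] = v
    return ExpressionTable(values)


@dataclass
class RecoveryResult:
    precision: float
    recall: float
    matches: list[tuple[int, int, float]]  # (called index, truth index, jaccard)


def _jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    union = (a.end - a.start) + (b.end - b.start) - inter
    return inter / union


def evaluate_recovery(
    called: IntervalSet, truth_spans: IntervalSet, min_jaccard: float = 0.5
) -> RecoveryResult:
    """Greedy one-to-one matching of called vs planted spans by descending
    Jaccard; a pair counts as matched at Jaccard >= ``min_jaccard``.
    Precision with zero calls is reported as 0 (with a warning) rather than
    undefined."""
    if not (0.0 < min_jaccard <= 1.0):
        raise ValueError(f"min_jaccard must be in (0, 1], got {min_jaccard}")
    called_l = list(called.sorted())
    truth_l = list(truth_spans.sorted())
    pairs = [
        (i, j, _jaccard(c, t))
        for i, c in enumerate(called_l)
        for j, t in enumerate(truth_l)
        if _jaccard(c, t) >= min_jaccard
    ]
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    used_c: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for i, j, jac in pairs:
        if i not in used_c and j not in used_t:
            matches.append((i, j, jac))
            used_c.add(i)
            used_t.add(j)
    if not called_l:
        logger.warning("no called spans; precision reported as 0")
        precision = 0.0
    else:
        precision = len(matches) / len(called_l)
    recall = len(matches) / len(truth_l) if truth_l else 0.0
    return RecoveryResult(precision, recall, matches)


@dataclass
class SimulatedLandscape:
    """A full simulated dataset, as produced by :func:`simulate_all`."""

    config: SimulationConfig
    genes: list[GeneModel]
    truth: GroundTruth
    peaks: dict[str, list[IntervalSet]]
    enhancers: IntervalSet
    treatment: SignalTrack
    control: SignalTrack
    expression: ExpressionTable


def simulate_all(config: SimulationConfig) -> SimulatedLandscape:
    """Run every stage in the canonical order."""
    genes, truth = simulate_landscape(config)
    peaks = simulate_peak_replicates(config, genes, truth)
    enhancers, treatment, control = simulate_signal_tracks(config, genes, truth)
    expression = simulate_expression(config, genes, truth)
    return SimulatedLandscape(
        config, genes, truth, peaks, enhancers, treatment, control, expression
    )


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.steps):
            for s, e, v in track.steps[chrom]:
                val = int(v) if float(v).is_integer() else v
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{val}\n")


def write_landscape(sim: SimulatedLandscape, out_dir: str | Path) -> dict[str, str]:
    """Write the simulated dataset in the formats the pipeline reads:
    gene TSV, per-mark/replicate broadPeak, enhancer BED, bedGraph tracks,
    expression TSV, ground-truth JSON and the resolved config."""
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_gene_models(sim.genes, out / "genes.tsv")
    paths["genes"] = "genes.tsv"
    for mark, reps in sim.peaks.items():
        for r, rep in enumerate(reps, start=1):
            name = f"{mark}_rep{r}.broadPeak"
            write_intervals(rep, out / name, "broadpeak")
            paths[f"{mark}_rep{r}"] = name
    write_intervals(sim.enhancers, out / "enhancers.bed", "bed6")
    paths["enhancers"] = "enhancers.bed"
    write_bedgraph(sim.treatment, out / "treatment.bedgraph")
    write_bedgraph(sim.control, out / "control.bedgraph")
    paths["treatment"] = "treatment.bedgraph"
    paths["control"] = "control.bedgraph"
    sim.expression.to_tsv(out / "expression.tsv")
    paths["expression"] = "expression.tsv"
    sim.truth.to_json(out / "truth.json")
    paths["truth"] = "truth.json"
    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(sim.config.to_dict(), fh, sort_keys=True)
    paths["config"] = "sim_config.yaml"
    return paths
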