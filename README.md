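# hcdkit

Calling **hyperacetylated chromatin domains (HCDs)** — broad regions of
activation-associated histone marks ranked by *peak breadth* — alongside the
signal-strength comparator, ROSE-style **super-enhancer** calling, from
broad-peak ChIP-seq outputs.

Stratifying enhancers by ChIP-seq signal strength (super-enhancers) is the
standard way to nominate cell-identity genes. hcdkit implements the
alternative stratification by peak *breadth*: for each histone mark
(H3K27Ac and H3K4Me2 by default), replicate peak calls are collapsed to
their base-pair intersection, the consensus peaks are ranked by breadth
(end − start), the top fraction (2% by default) is kept, and an HCD is
emitted wherever top-tier peaks of the two marks overlap, as the union span
of the overlapping peaks. Because mapping pipelines discard duplicate reads,
peak *height* saturates; breadth keeps discriminating at the top of the
distribution, and the genes under broad dual-mark domains tend to be highly
expressed, lineage-defining genes whose TSS lies *inside* the domain.

The package is aimed at epigenomics analysts who already have broad-peak
calls (e.g. MACS2 `--broad`), enhancer candidate peaks (TF ChIP or ATAC) and
signal tracks, and want both rankings plus the downstream gene-level
comparison.

## What it computes

| step | method |
|---|---|
| replicate consensus | base-pair intersection across replicate peak calls |
| breadth filter | keep the ⌈f·N⌉ broadest consensus peaks (boundary ties included); f = 0.02 dual-mark, 0.05 single-mark defaults |
| HCD call | union spans of overlap-connected components containing top peaks of both marks |
| super-enhancers | ±500 bp TSS exclusion → 12.5 kb stitching → input-subtracted per-million signal over constituents → tangent-line elbow cutoff on the ranked curve |
| gene association | nearest gene by gap distance (ties reported), TSS-containment diagnostic |
| expression comparison | two-tailed Student's t-test (pooled; Welch optional) between gene categories |

The tangent cutoff: sort region scores ascending, set slope m = (max −
min)/N, and choose the position x minimising the number of points below the
line of slope m through (x, score_x); regions scoring above score_x are
super-enhancers.

A seeded synthetic-landscape generator (`hcdkit.simulate`) produces the full
input bundle — genes, dual-mark peak replicates with a heavy-tailed breadth
distribution, enhancer clusters with an elbow in the score curve, expression
with a planted shift — plus ground truth and recovery scoring, so the whole
pipeline is testable without any external data.

## Worked example

Simulate a landscape and run the full pipeline on it:

```sh
hcdkit simulate --seed 42 -o demo/sim
# simulated landscape (300 genes) -> demo/sim
hcdkit all --input-dir demo/sim -o demo/run
# 15 HCDs, 10 SEs -> demo/run
```

`demo/run/manifest.json` then records, among the stage counts:

```json
"expression_ttest": {"t": 10.838, "df": 298.0, "p": 2.697e-23},
"hcd_containment_fraction": 1.0,
"recovery": {"hcd_precision": 1.0, "hcd_recall": 1.0,
             "se_precision": 1.0, "se_recall": 1.0}
```

Reading: the 15 called domains match the 15 planted broad loci exactly
(precision = recall = 1.0), every domain contains its nearest gene's TSS
(containment 1.0 — on real data this fraction is high but below 1), the 10
called super-enhancers are the 10 planted clusters, and domain-associated
genes are expressed significantly above background (t = 10.8, p ≈ 3e-23).
`demo/run/hcds.bed` holds the domain spans:

```
chr1	2582989	2601296	HCD_chr1_2582989	36047	.
chr1	4389575	4403854	HCD_chr1_4389575	28119	.
```

On real data the same stages run from files: `hcdkit call-hcd --mark
H3K27Ac rep1.broadPeak rep2.broadPeak --mark H3K4Me2 ... --fraction 0.02
--genes genes.tsv -o out/`, `hcdkit call-se --enhancers enh.bed --treatment
t.bedgraph --control c.bedgraph --genes genes.tsv`, then `hcdkit associate`
and `hcdkit compare-expression`. Library use mirrors the CLI one-to-one
(`hcdkit.replicate_consensus`, `top_breadth_filter`, `call_hcds`,
`call_superenhancers`, ...).

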