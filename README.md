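# motudiet

DNA-metabarcoding diet analysis for ecologists comparing the diets of
co-occurring predators from fecal samples — from raw tagged amplicon
reads all the way to a null-model test of dietary niche overlap.

Amplicon sequencing of prey DNA in predator feces (here: a short COI
barcode fragment amplified with generic arthropod primers carrying
5′ sample tags) yields pooled reads that must be demultiplexed,
error-filtered, collapsed into Molecular Operational Taxonomic Units
(MOTUs, a species proxy when the reference library is incomplete),
identified against a reference library, and finally summarized as a
predator × prey utilization matrix on which niche statistics are
computed. `motudiet` implements that whole chain, together with a
synthetic-data generator so every stage can be exercised against known
ground truth, and ships the prey-occurrence table of a two-predator
bat diet study as a worked-example dataset.

## The statistics at the core

For one predator whose diet occurrence counts over *n* resources give
proportions *pᵢ*:

* **Levins' niche breadth** `B = 1 / Σ pᵢ²`, standardized to
  `B_A = (B − 1) / (n − 1)` in [0, 1];
* **Shannon diversity** `H = −Σ pᵢ ln pᵢ`;
* **Pianka's niche overlap** between predators *j* and *k*:
  `O_jk = Σ P_ij P_ik / √(Σ P_ij² · Σ P_ik²)`, 0 for disjoint diets, 1
  for identical ones.

Whether an observed overlap exceeds chance is tested with a
resource-utilization null model: **Randomization Algorithm 3 (RA3)**
independently permutes each predator's count vector across all
resource states (conserving its niche breadth exactly), and the
one-tailed p-value is the add-one permutation estimator
`(1 + #{null ≥ observed}) / (iterations + 1)`.

Upstream, MOTUs are single-linkage clusters of dereplicated haplotypes
under a p-distance threshold (Needleman–Wunsch global alignment, free
end gaps); the working threshold is chosen at the inflection point of
the MOTU-count-vs-threshold sweep curve, and each MOTU's three most
abundant haplotypes are identified against the reference library with
a three-tier confidence scheme (>98.5% similarity for species/genus,
>98% for family, with a regional-checklist tiebreak).

## Worked example

```python
from motudiet import NicheOverlapModel, load_table1_fixture

matrix = load_table1_fixture()          # 79 prey taxa x 2 predator bats
model = NicheOverlapModel(matrix, "P. austriacus", "P. auritus")
results = model.fit(n_iterations=10_000, seed=1)
print(results.summary())
```

```
Niche overlap (Pianka) — RA3 permutation test
====================================================
predators:        P. austriacus  vs  P. auritus
resources:        79
observed overlap: 0.7135
null mean:        0.2547
null 95% quant.:  0.4060
iterations:       10000
p-value (1-tail): 0.0022
----------------------------------------------------
P. austriacus: Levins B = 18.98, B_A = 0.37, Shannon H = 3.44 (n = 50)
P. auritus: Levins B = 21.33, B_A = 0.45, Shannon H = 3.51 (n = 46)
```

The two bats' diets overlap far more (0.71) than random reshufflings
of the same diet breadths ever produce (null mean 0.25, 95% quantile
0.41), so the overlap is highly non-random: both species concentrate
on the same common prey (the noctuid moth *Noctua pronuba* tops both
diets at 19 and 13 consumers). Per-predator breadth and diversity
show both species spreading their remaining diet across many prey
taxa.

The same analysis runs from the shell:

```sh
motudiet fixture --out matrix.tsv
motudiet nulltest matrix.tsv --iterations 10000 --seed 1
```

and the sequence side of the pipeline (simulate → filter → cluster →
assign → run-all) is available as further subcommands; see
`motudiet --help` and `docs/methods.md`.

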