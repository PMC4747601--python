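# panrecruit

Pan-genome fragment recruitment and diversity analysis for whole-genome
shotgun metagenomes, with a ground-truthed synthetic community simulator.

## The problem

Host-associated microbiomes — here the archetype is a carnivorous plant's
trap fluid versus its surrounding water — are routinely characterized from
short paired-end shotgun reads. Getting from raw reads to "which species
live here, how abundant are they, and how do two environments differ"
requires a chain of steps, each with its own thresholds: merging overlapping
read pairs, discarding low-quality and host-derived reads, building a
non-redundant reference per candidate species (a *pan-genome*: the union of
gene sequences across that species' strains after identity clustering),
recruiting reads to each pan-genome, assigning ambiguous reads by lowest
common ancestor (LCA), and summarizing community structure with diversity
indices and resampling-based group comparisons.

`panrecruit` implements that chain as a tested, reusable library with a thin
CLI. Because the interesting failure modes (cross-recruitment between
relatives, identity/coverage bias, over-confident taxonomic calls, miscalibrated
FDR) are invisible on real data, the package ships a first-class simulator
that generates communities with known abundances, known strain divergences,
sequencing error, and host contamination — so every stage can be scored
against ground truth.

## The quantities at the core

For a species *s* with pan-genome length *L* and filtered read alignments
(each read keeps one best-score hit per species, and a hit must cover at
least 80% of the read):

- **coverage depth** `C_s = (total aligned read bases) / L` (in X units),
- **average identity** — alignment-length-weighted mean of per-hit
  identity (matching columns / alignment columns); for reads drawn from a
  strain at divergence *d* with per-base error *e*, it recovers
  `(1 − d)(1 − e)`,
- **consensus** — per-position majority vote of aligned read bases (ties →
  reference base, uncovered → N), i.e. a draft of the environmental
  population's sequence.

Community structure is summarized per sample by observed richness
`S_obs`, **Chao1** `S_obs + F1(F1−1) / (2(F2+1))` (singletons F1,
doubletons F2; bias-corrected form), **Shannon** `H = −Σ p ln p`, and
**Simpson** `λ = Σ p²` (reported together with Gini–Simpson `1 − λ`).
Group differences use a Welch *t* statistic on relative proportions with a
label-permutation null, `p = (1 + #{|t*| ≥ |t|}) / (B + 1)` (exact
enumeration when feasible), and a permutation-based FDR
`q(t) = mean_perm #{|t*| ≥ t} / max(1, #{|t_obs| ≥ t})`, minimized over
thresholds and monotonized.

## Worked example

```python
from panrecruit import (SimulationConfig, mutate_strain, build_pangenomes,
                        GeneSequence)
from panrecruit.simulate import (simulate_reference_genes,
                                 simulate_host_genome, simulate_reads,
                                 species_ids)
from panrecruit.qc import merge_pairs, host_subtract
from panrecruit.recruit import recruit_reads, profile

divs = (0.03, 0.08, 0.12)
cfg = SimulationConfig(n_species=3, genes_per_species=10,
                       strain_divergence=divs, n_read_pairs=8000, seed=9)
refs = simulate_reference_genes(cfg)
strains = {sp: mutate_strain(refs[sp], divs[i], seed=[9, 21, i])
           for i, sp in enumerate(species_ids(3))}
host = simulate_host_genome(cfg.host_genome_length, seed=[9, 2])
reads, truth = simulate_reads(cfg, strains, host)

merged, _ = merge_pairs(reads.r1, reads.r2, reads.quality, reads.ids)
kept, _ = host_subtract(merged, [("host", host)])
pgs = build_pangenomes([GeneSequence(g, sp, "ref", s)
                        for sp in refs for g, s in sorted(refs[sp].items())])
hits = recruit_reads(((r.id, r.sequence) for r in kept), list(pgs.values()))
for sp, pg in pgs.items():
    p = profile(hits[sp], pg)
    print(sp, round(p.coverage_depth, 2), round(p.average_identity, 4))
```

prints (seed 9):

```
s000 167.49 0.9689
s001 13.6 0.9207
s002 100.18 0.8833
```

Coverage depth tracks each species' true abundance, and the average
identity per species recovers `(1 − d)(1 − e)` — 0.9695, 0.9195 and 0.8796
for the three planted divergences — which is exactly what a fragment
recruitment plot is meant to reveal about how far an environmental
population sits from its reference.

The `examples/` directory has one short script per capability (simulation,
QC, pan-genome construction, recruitment, LCA profiling,
diversity/differential abundance, and the full pipeline). The same chain
runs end-to-end from a shell:

```bash
panrecruit run --config run.yaml --out results/run1
```

writing per-stage TSV/FASTA/newick outputs plus a manifest with parameter
hashes and output checksums; identical config + seed reproduce identical
bytes.

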