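# mitocomp

Comparative mitogenomics of annotated mitochondrial genomes — built for the
kind of study that takes a set of congeneric mitogenomes (e.g. plovers and
lapwings, family Charadriidae) and asks: how is the genome organized, how is
composition biased between strands, which codons are preferred, which
protein-coding genes evolve fastest, is selection purifying, and what do the
data say about contested placements such as the golden-plover genus
*Pluvialis*?

From GenBank flat files, `mitocomp` computes:

* **Genome audits** — gene order, strand assignment, intergenic spacers and
  overlaps, parse warnings for unnameable features.
* **Composition** — per-genome, per-region and per-gene base composition
  with strand asymmetry: AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C).
* **Codon usage** — start/stop codons (including incomplete `T--`/`TA-`
  stops) and relative synonymous codon usage, RSCU(c) = count(c)·k/X, under
  the vertebrate mitochondrial code (translation table 2).
* **Divergence and selection** — per-gene variable / parsimony-informative /
  singleton site percentages, pooled ts/tv, mean uncorrected pairwise
  distance (Aupd), and Ka/Ks by Nei–Gojobori (1986) pathway counting with
  Jukes–Cantor correction (dN/dS < 1 ⇒ purifying selection).
* **Phylogenetics plumbing** — concatenated supermatrices with partition
  tables, relaxed-PHYLIP / NEXUS+charset / RAxML partition exports,
  neighbor-joining trees with deterministic tie-breaks, Robinson–Foulds
  distances and outgroup-rooted monophyly verdicts.
* **Simulation** — an annotated-mitogenome simulator (37 genes + control
  region, minus-strand ND6 and eight tRNAs, AT-rich skewed composition,
  per-gene dN/dS, ts/tv bias, incomplete stops) that evolves genomes along a
  known tree, so the whole analysis surface is testable offline against
  ground truth.

## Worked example

```python
import mitocomp as m

# 12 simulated genomes on a known tree, with ground truth attached
bundle = m.fixture_set(seed=1)
records = [bundle.records[k] for k in sorted(bundle.records)]

table = m.composition_table(records)
print(table[["organism", "length_bp", "pct_AT", "at_skew", "gc_skew"]].tail(4))

alns = {g: m.divergence.build_alignment(records, g) for g in ("COI", "ATP8")}
print(m.gene_divergence_table(alns)[["gene", "length_bp", "pct_Vs", "ka_ks", "aupd"]])
```

```
organism length_bp  pct_AT  at_skew  gc_skew
sim_sp11     16813   55.20     0.13    -0.37
sim_sp12     16813   55.13     0.13    -0.37
    mean             55.41     0.13    -0.37
      sd              0.16     0.00     0.00
gene  length_bp  pct_Vs  ka_ks   aupd
 COI       1548  27.003  0.017  0.089
ATP8        165  32.121  0.112  0.091
```

Each simulated genome is ~16.8 kb, AT-rich (55.4%) with positive AT skew
(+0.13) and negative GC skew (−0.37) — the strand asymmetry typical of bird
mitogenomes. Per gene, ATP8 shows the highest fraction of variable sites
and a Ka/Ks ≈ 0.11 versus COI's 0.017: both genes are under purifying
selection (Ka/Ks ≪ 1), with ATP8 the least and COI the most constrained,
exactly the contrast programmed into the simulator (ω = 0.16 vs 0.02).

The same surface is available from the shell:

```bash
mitocomp simulate --seed 1 --out-dir sim/
mitocomp run-all --input-dir sim/ --out-dir results/
```

which writes the full bundle — composition, divergence, RSCU, start/stop
and spacer tables, dataset (a) Cyt b+12S+ND2 and dataset (b) 13 PCGs+rRNAs
supermatrices with partition files, an NJ tree and a checksum manifest.

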