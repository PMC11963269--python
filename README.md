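# prare

Discovery and structural annotation of **Potentially Recently Active Retand
Elements (PRAREs)** — recently inserted copies of the Retand lineage of plant
Ty3/gypsy LTR-retrotransposons — in genome assemblies.

Retand elements are unusual among gypsy lineages for their very long internal
region: most of the extra length lies between the end of the *pol* gene and
the 3'LTR (the POL-3'LTR region), which hosts antisense ORFs — many encoding
the TRP28 (Transposase 28, PF04195) domain — and arrays of short tandem
repeats.  Because retrotransposon copies decay after insertion, structure is
best read from *recent* copies: elements whose two LTRs are still identical,
whose 5-bp target-site duplications (TSDs) still match, and whose sizes have
not drifted from their family consensus.

This package implements that discovery procedure as a tested, reusable
library, plus a synthetic-genome generator with machine-readable ground truth
to validate every stage.

## The method

For a genome set, the pipeline:

1. **RT search** — six-frame translated local alignment (BLOSUM62, affine
   gaps, gap of length *k* costs 11 + *k*) against four Retand reverse
   transcriptase (RT) domain queries; only *complete, uninterrupted* domains
   are kept: 157–162 aligned residues, no stop codons, no frameshifts (a hit
   never spans reading frames).  The score threshold is calibrated on shuffled
   background (`calibrate_min_score`), replacing a BLAST E-value cutoff.
2. **Lineage assignment** — candidate RT proteins are aligned (native
   progressive aligner) with a 62-sequence model panel spanning the plant
   gypsy and copia lineages plus a Caulimoviridae outgroup; a neighbor-joining
   tree on p-distances is midpoint-rooted and a candidate is kept iff it falls
   in the Retand reference clade.
3. **Element reconstruction** — 10-kb flanks around each Retand RT hit are
   searched for a *maximal exact* direct repeat (one copy per side of the RT
   domain): the identical-LTR pair.  The element is accepted only if the 5-bp
   sequences immediately outside the pair are identical (the TSD).
4. **Clustering and the PRARE filter** — LTRs are clustered greedily at ≥ 90%
   global identity (CD-HIT-style, longest first).  Cluster consensus sizes are
   member medians; an element is a PRARE iff both its LTR and its internal
   size are within 2% of the consensus.
5. **Annotation** — maximal ATG-to-stop ORFs (≥ 600 bp; shorter ones kept only
   when they encode TRP28), PSSM domain scans (GAG, AP, RT, RH, INT, TRP28 and
   auxiliary domains), the POL-3'LTR span (from the stop of the 3'-most
   pol-domain ORF to the 3'LTR), tandem arrays (≥ 3 copies, period ≤ 100), and
   autonomy (`complete` iff GAG+AP+RT+RH+INT are all encoded in sense).
6. **Reporting** — per-cluster summaries, consensus sequences, Weblogo-style
   conservation profiles (bins > 45% / > 35% / > 25%), a bootstrap NJ tree of
   cluster consensus RT domains, and TSV/GFF3/FASTA/Newick/JSON report files.

Real Pfam/CDD models and the original query accessions are not shipped: the
packaged RT panels and domain profiles are deterministic *synthetic stand-ins*
(see `src/prare/data/*.synthetic.*` and `docs/methods.md`).

## Worked example

`examples/07_full_pipeline.py` generates a 1.5-Mb genome set with three
planted element families (12 intact copies) and 10 decoys (diverged-LTR,
solo-LTR, truncated, wrong-lineage RT), then runs the full pipeline:

```
stage counts: {'genomes': 3, 'rt_hits': 19, 'retand_hits': 17, 'elements': 12,
               'rejections': 5, 'clusters': 3, 'prares': 12}
recovery: precision 1.00, recall 1.00
per-cluster summaries (copy number, LTR, internal, POL-3'LTR):
  cluster_1: n=3, LTR 1000, internal 12000, POL-3'LTR 5500, TRP28 YES
  cluster_2: n=5, LTR 600, internal 10000, POL-3'LTR 4600, TRP28 YES
  cluster_3: n=4, LTR 450, internal 9000, POL-3'LTR 3900, TRP28 YES
```

Reading: 19 RT hits include the two wrong-lineage decoys (dropped at the
lineage stage) and the diverged/truncated decoys (rejected during element
reconstruction with reason codes); the 12 recovered PRAREs match the planted
truth records exactly, one cluster per family, with the planted LTR /
internal / POL-3'LTR geometry reported per cluster.

The other examples each exercise one capability: element planting (01), RT
search (02), lineage assignment (03), element reconstruction (04), clustering
and the 2% filter (05), structural annotation (06), and the packaged
reference table of 63 published Retand cluster characteristics (08), whose
summary statistics — LTR 315–1,194 bp (mean 635), internal 7,380–12,869 bp
(mean 10,364), POL-3'LTR minimum 2,933 bp — the reporting module reproduces
exactly.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the full-size (5 Mb) synthetic scenario from the given seed, runs
the complete pipeline, prints the reference-table summary statistics and the
planted-element recovery achieved, and writes the acceptance JSON to `--out`.
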