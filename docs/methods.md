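# Methods

This note documents the models, parameters and numerical choices behind the
package, what the synthetic data does and does not emulate, and the known
limitations.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The discovery model

A PRARE (potentially recently active Retand element) is defined operationally:

* a complete, uninterrupted RT domain (157–162 aa, no stops, one reading
  frame) similar to Retand reference RT domains;
* the RT clusters with the Retand lineage in a reference phylogeny;
* two *identical* LTRs flank the internal region, and the 5-bp sequences
  immediately outside them are identical (the target-site duplication);
* LTR and internal sizes deviate ≤ 2% from the element's cluster consensus.

Each clause maps to one pipeline stage (rt_search → lineage → element builder
→ clustering/filter).  The identity criteria are implemented as *exact string
equality*, which makes them unambiguous and testable; the published procedure
used pairwise BLAST comparisons, where "identical" is a reading of the output
rather than a string predicate.

## 2. Stage parameters

| Parameter | Default | Why |
|---|---|---|
| RT completeness window | 157–162 aa | length range of the reference RT domains |
| Alignment scoring | BLOSUM62, gap 11 + k | defaults of the replaced translated-BLAST stage |
| `min_score` | 70 matrix units | calibrated: max null score on ≥ 1 Mb uniform background (~53–55) + margin; `calibrate_min_score` recomputes it for any background model |
| Flank window | 10,000 bp per side | the published mining window |
| `min_ltr` / `max_ltr` | 100 / 3,000 bp | generous margins around the observed 315–1,194 bp range, so the detector does not bake in the expected answer |
| TSD length | 5 bp (optional 4–6 tolerance) | "usually 5 bp" is not absolute |
| LTR clustering identity | 0.90, global alignment, matches / alignment length | the published CD-HIT cutoff; exact alignment instead of k-mer estimates at desk scale |
| Consensus size | member *median*, lower middle on ties | robust to single outliers; the source does not specify mean/median/mode (flagged for sensitivity) |
| PRARE tolerance | 0.02 on **both** LTR and internal size | literal reading of the removal rule ("LTR *or* internal … differed" ⇒ either deviation removes) |
| `min_orf` | 600 bp | the published ORF reporting threshold; shorter ORFs are kept only when they carry a TRP28 hit, flagged `short` |
| Tandem arrays | ≥ 3 copies, period ≤ 100, copy-to-consensus identity ≥ 0.8 | copy floor is the published rule; the identity floor and the (copies × period) overlap resolution are package choices (the replaced tool's alignment-weight model is not reproduced) |
| Reported array periods | ≥ 8 bp | ≥ 3-copy runs of period 1–7 occur constantly by chance in random DNA; the observed unit range is 8–100 bp.  Detection still starts at period 1 (the spec'd operation default); the cutoff applies only to cluster summaries |
| Bootstrap replicates | 100 (mining), 1,000 (cluster tree) | the two replicate counts given for the two stages |

## 3. Phylogenetics

Distances are p-distances over shared ungapped columns of a progressive
multiple alignment (guide tree: UPGMA on global-alignment identity distances;
profile–profile merge with frequency-weighted BLOSUM62 column scores and
affine gaps).  Neighbor-joining is authored here because reproducibility
requires a fixed tie-break: among Q-minimising pairs, the lexicographically
smallest sorted label pair is joined; negative branch estimates are clamped to
zero.  NJ recovers additive topologies exactly (verified against an
exhaustive least-squares topology search for ≤ 7 taxa).

Lineage assignment midpoint-roots the candidate+panel NJ tree and, for each
panel lineage, takes the smallest clade containing all of that lineage's
members; the clade is *valid* only if it contains no other panel member.  A
candidate receives the label of the smallest valid clade containing it,
otherwise "unassigned".  The source describes only "clustered with the Retand
sequences"; the smallest-clean-clade rule is this package's precise rendering.
The published figure tree is described as maximum likelihood, but the stated
methods are NJ with bootstrap; this package implements NJ for both stages and
exposes the replicate count.

## 4. Synthetic data: the stated world

`generate_scenario` plants, by default, **three families** (12 intact copies:
5/4/3) and **10 decoys** (3 diverged-LTR, 3 solo-LTR, 2 truncated, 2
wrong-lineage RT) into 5 Mb of i.i.d. uniform A/C/G/T across 5 contigs.
Family geometry sits inside the published ranges: LTRs 450/600/1,000 bp,
internal regions 9/10/12 kb, POL-3'LTR regions 3.9/4.6/5.5 kb, 5-bp TSDs,
one- and two-ORF gag-pol layouts, TRP28-bearing antisense ORFs, tandem arrays
of period 8–100 with ≥ 3 copies.  Intact copies of a family are byte-identical
copies of one master element (recency = no divergence yet), so LTR clustering
must group them; copies are planted on both strands.

Construction guarantees unambiguous truth:

* coding regions are codon-wise ATG…stop with an in-frame stop guard
  immediately 5' of each start, so every planted ORF is maximal and its span
  exact;
* the bases flanking the LTR pair are resampled so the pair is a *maximal*
  exact repeat — detectors recover exact LTR boundaries rather than
  boundaries ± 1 chance-matching base;
* tandem-array units are never themselves periodic and the bases flanking an
  array break its period, so leftmost-maximal detection recovers the planted
  (start, period, copies);
* diverged-LTR decoys receive substitutions at stratified positions, so the
  identical-LTR *sequence* test (not a length test) is what rejects them.

What the generator does **not** emulate: real base composition and repeat
landscapes, nested insertions, host genes, solo-LTR/TSD decay gradients,
within-family sequence divergence, transduction.  A green end-to-end test
therefore establishes that the pipeline's logic is correct on its stated
world, not that its thresholds are tuned for real genomes.

## 5. Reference panels and domain profiles (synthetic stand-ins)

The four Retand RT queries (named for the characterised elements Tat4-1,
Gret1, Cinful-1, Grande1-4; 159/159/159/160 aa) and the 62-sequence model
panel are **deterministic synthetic stand-ins**, generated by
`prare.panels.build_panels`: a random 160-aa ancestral RT diverged 35% into
each lineage ancestor (55% for the Caulimoviridae outgroup) and 8% into each
member.  The first and last 8 residues are kept invariant, mimicking the
conserved motifs that delimit real RT domains; without this, cross-lineage
local alignments trim below the 157-aa completeness floor and wrong-lineage
decoys would never reach the lineage filter that is supposed to reject them.

Domain profiles are toy PSSMs: column *i* is the BLOSUM62 row of a fixed
consensus residue, so the consensus maximises the score; thresholds are set to
the maximum best-window score over 200 shuffled 500-aa proteins + 1
(`calibrate_profile_threshold`).  Real Pfam/CDD models can be substituted via
the same JSON format.  The external DNA-binding prediction service used for
TRP28 interpretation has no offline replacement and is simply reported as
unavailable.

## 6. Numerical and tie-break conventions

* All coordinates 0-based half-open on the forward strand; GFF3 output
  converts to 1-based inclusive.
* Annotation works on the element oriented so the RT domain reads forward;
  "sense" always means the gag-pol direction.
* LTR pair selection: longest exact repeat, ties to the outermost (widest
  element) placement, then leftmost — nested or multiple repeat pairs resolve
  deterministically.
* Hit merging: overlapping RT hits keep the best score (ties: query id, then
  position).  Within one frame, reported hits are separated by at least one
  query length; planted domains are far sparser than that.
* Tandem-array overlap resolution: copies × period descending, then smaller
  period (so a homopolymer is period 1, not a multiple), then higher mean
  copy identity (so an exact array beats its own 1-bp-shifted shadow), then
  leftmost.
* Consensus sequences: per-column majority over non-gap residues, ties to a
  fixed residue ordering; columns ≥ 50% gaps are dropped from consensus but
  kept (flagged) in conservation profiles.
* Summary means are rounded half-up to integer bp, matching the printed style
  of the reference table; min/max/mean use exact integer/rational arithmetic.
* Bootstrap: alignment columns resampled with replacement per replicate;
  support = number of replicate NJ trees containing the bipartition, on the
  replicate scale; bipartitions absent from the full-data tree have support 0.

## 7. Known limitations

* Exact-equality LTR/TSD criteria cannot recover older, degenerate elements —
  by design: the method targets recent insertions only.
* The greedy clustering is quadratic in cluster count times sequences and is
  not meant for > 10⁵ LTRs.
* The full-DP translated search is desk-scale (≈ 13 s/Mb/4 queries on one
  CPU); genomes beyond ~100 Mb would need a seeded heuristic that this package
  deliberately omits.
* Tandem detection below 100% identity uses greedy anchor-extension; it is
  exact (oracle-verified) at 100% copy identity, heuristic below.
* The packaged reference table reproduces its published text summaries for
  LTR/internal/POL-3'LTR sizes exactly; its domain-presence flags are
  internally inconsistent with the prose counts in the source material and
  are shipped as printed (see the per-pattern counts the summary reports).
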