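# Methods

## Intron marks and the anchoring rule

A coding gene structure is an ordered list of CDS exons (1-based
inclusive genomic coordinates, transcription order). Each internal exon
junction defines an intron with CDS offset `o` = number of coding
nucleotides upstream. The intron's *phase* is `o mod 3` (0: between
codons; 1/2: after the first/second nucleotide of a codon) and its
*anchor residue* is `floor(o/3) + 1`. One rule is used for all phases:
phase-0 introns anchor to the residue following the splice, phase-1/2
introns to the residue whose codon they split. Any single consistent
rule works for homology comparison because introns are only ever
compared jointly as (position, phase) pairs; the uniform rule was
chosen over per-phase conventions because it makes the anchor a pure
function of the CDS offset and keeps round-trips exact. Drawing
conventions of gene-structure visualisation tools may differ by one
residue for split codons; this package's rule is its own definition,
applied identically on both sides of every comparison, so no comparison
is affected.

GFF3 `phase` columns are cross-checked against the computed phase;
disagreement warns and the computed value wins, since annotation phase
fields are frequently wrong in public data. CDS lengths may include or
exclude the stop codon; both conventions are accepted and recorded.

## Homology mapping and clustering

Marks are projected onto a protein alignment by taking the alignment
column of the anchor residue. The homology key is `(column, phase)`:
phase-discordant introns are never clustered, because they cannot be
homologous without intron sliding. The default window is 0 (exact
column equality); a window > 0 enables exploratory fuzzy matching via a
greedy left-to-right pass per phase over column-sorted introns, with at
most one intron per sequence per cluster (nearest to the
representative wins; ties break toward the lower column for
determinism). At window 0 the greedy pass provably equals transitive
closure; the test suite checks this against a brute-force union-find
oracle on random datasets.

A cluster is *clade-conserved* when ≥ `min_fraction` (default 0.9) of
the clade's sequences and ≥ `min_members` (default 2) sequences in
absolute terms carry it. The 0.9/2 defaults encode "near-universal but
exception-tolerant" conservation — real clades often contain one
derived member that lost an intron. Carriers from other clades are
listed but never counted toward a clade's fraction, and per-sequence
carriage is reported so individual exceptions can be inspected.

Cross-clade overlap requires equal phase and column distance ≤ window;
the full nearest-distance table is reported regardless, so near-misses
(adjacent columns, or same column with different phase) stay visible.
Cross-alignment robustness never compares column numbers between
alignments — columns are meaningless across alignments — but matches
conserved clusters by Jaccard similarity (default threshold 0.5) of
their alignment-invariant member identities `(seq_id, cds_offset,
phase)`. A position is robust iff every alignment contains a matching
conserved cluster.

## Bovine-numbering screen

Candidate residues are assigned reference positions through a global
pairwise alignment against bovine rod opsin (UniProt P08100; 348
residues; packaged as a FASTA fixture and treated as ordinary input).
Alignment parameters are the classic defaults — BLOSUM62, affine gaps,
open 10, extend 1 — because for genuine opsins, which align readily to
bovine rhodopsin over the transmembrane core, the resulting numbering
is insensitive to these choices; the parameters are exposed for edge
cases. A map whose score falls below 10 % of the reference
self-alignment score is flagged low-confidence (shuffled sequences of
opsin composition score well below this floor, genuine opsins far
above).

Checks read the candidate residue aligned to each diagnostic position:
Lys296; NPxxY at 302–306; the tripeptide at 310–312 classified NKQ →
c-type, HPK → r-type, anything else (including partial reads) → other;
and the C-terminal VxPx motif, which must end within `tail_window`
(default 2) residues of the C-terminus. A reference position falling in
a candidate gap yields "unaligned" — never a spurious present/absent
call. The positional NPxxY reading matches homologous-position
semantics; `--npxxy-scan` adds a free regex scan for poorly alignable
candidates. Retention requires the ≥ 160-residue length filter and
Lys296; the 7tm_1 domain criterion is delegated to an optional external
call table (profile-HMM search is tool- and version-dependent), and is
recorded as "not evaluated" when absent.

## Leaf stability

For a taxon `t` and each 3-taxon subset containing it, every tree in
the set votes for one of the three rooted triplet topologies (trees are
read as rooted at their Newick root; a polytomy casts no vote rather
than fractional votes). With topology frequencies `f1 ≥ f2 ≥ f3` over
the resolved trees, the score of `t` is the mean over its triplets of
`f1` (max variant) or `f1 − f2` (difference variant); triplets resolved
in no tree are excluded from the mean. Taxa scoring below the threshold
(default 0.55, strict inequality) are pruned.

The **difference variant is the default**. The reason is quantitative:
a taxon attached uniformly at random still produces a *plurality*
topology in most of its triplets, so its expected max-variant score
levels off near 0.6 on moderate-size trees (measured ≈ 0.59 on a
10-taxon backbone) and never crosses the conventional 0.55 cutoff,
while its difference-variant score is ≈ 0.2 and stable taxa remain
≥ 0.85. The max variant therefore cannot express "rogue" at the 0.55
threshold on realistic tree sizes, whereas the difference variant can.
Both variants are implemented, exposed (`--variant`) and recorded in
every output, and the per-taxon invariant `difference ≤ max` is tested.

Triplet resolution is computed from per-tree rooted-clade bitmasks
(resolution of `{a,b,c}` is a subset query on the smallest clade
containing each pair), making exhaustive enumeration cheap up to a few
dozen taxa. Beyond `max_triplets_per_taxon` (default 20 000) triplets
are subsampled uniformly without replacement with a seeded generator;
the subsampled estimator agrees with exhaustive enumeration within 0.05
on 20-taxon/200-tree sets in the test suite. Trees with mismatched leaf
sets are rejected rather than silently intersected: bootstrap
replicates share taxa, and intersection would hide input errors.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with truth known by construction:

- **Column architecture.** An ancestral core of `protein_length`
  uniform-random residues defines the true homology columns. Per clade,
  seeded deletion events (core columns, probability `indel_rate/2`
  each) and insertion events (clade-private columns, probability
  `indel_rate/2` per junction, run length 1–3) define the clade's row
  mask in the true alignment. Substitutions at `substitution_rate`
  (default 0.05 per site, a moderately diverged family) are applied
  once ancestor → clade consensus and once consensus → member.
  Member-level indels are deliberately absent: all members of a clade
  share the clade's column mask, so a planted anchor residue is
  homologous across the clade *exactly*, which is what makes recovery
  tests sharp. Real families also vary in length within clades; the
  alignment-projection code does not rely on the simplification, only
  the truth bookkeeping does.
- **Introns.** Each planted `(anchor, phase)` is realised per member
  with probability `1 − intron_loss_prob`, jittered by a uniform
  integer in `[-jitter, +jitter]` and clamped at sequence ends (clamping
  rather than rejection keeps carrier counts exact; clamps are recorded
  in the truth). The CDS is back-translated with uniform synonymous
  codons (codon identity is irrelevant — only offsets matter) plus a
  TAA stop, and GT..AG introns with lengths from `intron_length_range`
  (default 60–300 nt, short spliceosomal introns) are inserted at the
  realising nucleotide offsets. Genes alternate between plus and minus
  strand placement on per-gene contigs with 30 nt flanks, so strand
  handling is always exercised.
- **Trees.** The backbone is a ladder of clade ladders over the
  non-rogue taxa; each of `n_trees` replicates re-attaches every rogue
  taxon to an independently, uniformly chosen edge. This emulates the
  bootstrap signature of a rogue (uniform wandering) while all other
  relationships stay fixed — stable taxa therefore score higher than in
  real bootstrap sets, where everything fluctuates somewhat.

All randomness flows from one seeded generator; a fixed seed gives
byte-identical FASTA/GFF3/Newick/JSON outputs.

What passing tests on this generator show: exactness of the coordinate
arithmetic, the clustering/conservation/overlap logic, the
cross-alignment identity matching and the rogue-detection behaviour
under the planted noise model. What they do not show: robustness to
alignment *errors* (true alignments are known here), to incomplete gene
models, or to real substitution processes.

## Pipeline

Stages run in scientific order: screen → leaf-stability prune → intron
mapping → clade conservation → overlap → robustness. Excluded sequences
are removed from all downstream tables but always listed with reasons
(`excluded.tsv`); input = retained + excluded at every stage.
Conservation fractions are computed over the *retained* members of each
clade — a pruned rogue no longer counts against its clade's
denominator, matching the semantics of removing it from the dataset.
`apply_screen=False` records the diagnostic screen without letting it
gate retention; this is how the pipeline runs on synthetic families,
which are not opsins and would otherwise be emptied by the Lys296
criterion. The manifest records parameters, seeds, package version and
SHA-256 checksums of every input; reruns from the same inputs are
byte-identical.

## Problem sizes

Default validation runs use families of 12–16 sequences of length
120–250, tree sets of 100–200 trees over 10–20 taxa, and 100 seeded
replicates for the rogue-detection rate; these sizes give exact or
tightly bounded expectations while keeping the whole suite and the
acceptance script in the tens of seconds on a single CPU.

## Known limitations

- Alignment and tree inference are out of scope by design; the package
  consumes their outputs.
- The triplet reading of tree shape treats each tree as rooted at its
  Newick root; for bootstrap sets written with arbitrary basal
  orientation the scores depend on that orientation in the same way for
  all taxa, which preserves the ranking the pruning step uses.
- The intron-sharing argument is qualitative (counts and overlaps), as
  in standard practice; no significance model for independent intron
  gain at homologous positions is provided.
- The 7tm_1 domain criterion requires an external call table; without
  it, retention rests on length and Lys296 alone.
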