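# Methods

This note documents the models, parameter choices and numerical conventions
behind each pipeline stage, what the simulator does and does not emulate, and
the design decisions taken where more than one reasonable choice existed.

## Coordinates and formats

Genome coordinates are 1-based inclusive at the file boundary (GFF3
convention) and converted to 0-based half-open exactly once, inside the
helpers that slice sequence. Lowercase bases are uppercased on read; IUPAC
ambiguity codes other than `N` are normalized to `N` with a warning so that
downstream base counts are deterministic. GFF3 parsing is a strict
nine-column reader that reports the offending line number on error and
accepts either a `pseudo=true` or a `pseudogene=...` attribute as the
pseudogene mark, recording which one fired. Translation uses the bacterial
genetic code (table 11); alternative start codons are rendered as `M` only at
position 1; an internal stop or a length not divisible by three sets a
`partial` flag rather than raising.

## RdhA mining

RDase catalytic subunits are identified among annotated genes (product text
containing "dehalogenase alpha") and screened by, in fixed priority order:

1. length ≥ 200 aa (trailing stop excluded from the count);
2. at least one iron–sulphur binding motif `C-x(2)-C-x(3)-C`, counted over
   all 8-residue windows with overlaps allowed;
3. not a pseudogene;
4. not truncated (annotation partial flag, or a translation defect);
5. optionally, best identity ≥ 25 % against a user-supplied reference RdhA
   panel — a lightweight stand-in for a profile-domain search. No panel is
   bundled; the motif and length filters carry the discriminative load at
   desk scale, and a hook accepts any panel FASTA.

The first failing check becomes the single rejection reason, so rejection
tallies are reproducible.

## Pairwise identity and OG classification

Protein identity is defined over a global alignment with free end gaps
(BLOSUM62, gap open 11, extend 1): matches divided by aligned columns,
terminal-gap columns excluded. Free end gaps make the measure stable for
full-length RdhA comparisons and mean that appending residues to one sequence
does not dilute identity. This differs from BLAST local identity; sequences
engineered at an exact substitution count score exactly their planted
identity, which the threshold tests exploit.

OGs are the single-linkage connected components of the ≥90 % identity graph.
Components of two or more members are numbered `OG1, OG2, ...` in order of
(size descending, lexicographically smallest member); singletons receive
letters `A..Z, AA, ...` in lexicographic order of member id. Numbering is
internal — a label map can pin external database names when reproducing a
published classification.

### Gene trees

Trees are neighbour joining on distances corrected for multiple hits,
`d = -(19/20) ln(1 - (20/19) p)` with `p` the pairwise non-identity;
`p ≥ 0.95` makes the correction undefined and is capped at distance 10 with a
warning. Negative NJ branch lengths are clamped to zero. Bootstrap resamples
alignment columns; supports are counted per internal bipartition of the
point-estimate tree (canonicalized so complementation does not split
counts). The multiple alignment comes from mafft, except that equal-length
sequence sets — the substitution-only simulation regime — are already
positionally aligned and used as-is. An externally computed Newick can be
supplied wherever a tree is consumed, so a maximum-likelihood tree can be
swapped in to reproduce a published analysis exactly; the pipeline only
consumes topology and clades.

### Curation, umbrellas, concordance

Two labels merge during curation when neither forms a clean clade excluding
the other on the gene tree. Operationally, X and Y interleave when at least
one of them is non-monophyletic (unrooted bipartition sense) and either no
edge separates X from Y, or one label's members sit inside the smallest clade
containing the other (which absorbs a singleton nested within an OG's
clade). A singleton that is merely *sister* to an OG clade is not merged —
that relationship is umbrella territory. Each merge records the minimum
cross-label identity; identities are recorded, not enforced, because the
merge is a tree-topology judgement. The merged group keeps the label of its
largest constituent (ties to the lexicographically smaller label), and both
the pre- and post-merge partitions remain available.

Umbrella groups look exactly one node rootward of each label's clade (on a
midpoint-rooted copy): if every leaf pair under the parent node is >75 %
identical and the node covers at least two labels, those labels form an
umbrella; only maximal such nodes are emitted.

The HGT screen restricts the gene tree to one OG's members and tests, for
each genome clade contributing ≥2 members, whether those members are
monophyletic (unrooted bipartition definition). Zero violations → vertical;
any violation → `hgt_candidate`; OGs confined to one clade or with fewer
than three members are `not_applicable`. This clade-concordance screen is a
deliberately simple surrogate for full species-tree-aware reconciliation
with explicit duplication/transfer/loss costs, which is out of scope.

## ANI and species delineation

The query genome is chopped into consecutive 1020 bp fragments (trailing
fragments under 100 bp are skipped); each fragment is aligned to the
reference over both strands and retained at ≥30 % identity and ≥70 %
coverage; directional ANI is the mean identity of retained fragments and the
symmetric per-pair summary is the mean of the two directions (a
median-over-fragments option exists). The default aligner is edlib in infix
mode — the whole fragment aligns into the reference, so coverage is complete
by construction — accelerated by banded edit-distance passes whose band
starts small and escalates, then is capped by the best hit so far; a single
traceback on the winning target yields the identity. An exact local
dynamic-programming backend (Biopython) validates the fast path on small
inputs to within 0.1 ANI.

Species are single-linkage components at ≥95 % summary ANI, labelled by
their smallest member id. On calibration fixtures with planted site
identities of 99/97/95/92 %, recovered summary ANI is within 0.1 of the
planted value.

## Core pangenome and phylogenomics

Proteins cluster across genomes by single-linkage at ≥50 % global identity
with a length-ratio coverage bound of 80 % (connected components stand in
for Markov clustering; with the simulator's identity gaps the two coincide,
and MCL is a noted extension). Single-copy core clusters have copy number
exactly one in every genome. Two homogeneity indices score each cluster's
alignment:

- *geometric* — mean over columns of (1 − pairwise gap-state disagreement),
  1.0 for identical gap structure;
- *functional* — mean over non-fully-gapped columns of the modal residue
  frequency among non-gap members.

These formulas are this package's operationalization of indices other
pangenome suites define only informally; they are documented and unit-tested
here, not claimed identical to any external tool. Markers are ranked by
(geometric descending, functional ascending, cluster id) and the top n
(default 42, a conventional size for a concatenated bacterial marker set) are
concatenated per genome. The species tree is NJ on corrected p-distances of
the concatenation; bootstrap resamples whole genes, not columns, to respect
gene-level correlation.

## Synteny and genomic islands

RDase clusters are maximal runs of retained rdhA genes whose inter-gene gap —
measured boundary to boundary, end of one to start of the next, exclusive —
is at most 10 kb (the stricter reading of gene adjacency; the gap convention
is configurable). Isolated rdhA genes become size-1 clusters; truncation
flags mark clusters within 10 kb of a contig end, where an assembly break
may have cut the cluster.

Cross-cluster links come in two tiers: *solid* (same OG and >90 % identity)
and *umbrella* (labels share an umbrella, identity in [75, 90]). Each member
takes at most one counterpart per tier, best identity first, ties to the
smaller index. The adjacency-conservation score is the fraction of adjacent
linked pairs in one cluster whose counterparts are adjacent in the other,
scored under the better of the two global orientations so reverse-colinear
clusters score 1.0.

A genomic island around a query locus spans from the inner boundary of the
nearest upstream single-copy core gene to the inner boundary of the nearest
downstream one (a flag switches to gene-inclusive bounds); a missing flank
extends the island to the contig end and marks it open. Island-to-island
comparison maps 1 kb windows of one island into the other (both strands),
chains consecutive ≥90 %-identity windows into blocks, drops blocks under
1 kb, and reports per-block and length-weighted overall identity.
Mobile-element tallies are keyword matches on product text, in table order
with first match winning: transposase/insertion-sequence keywords (the bare
`IS` keyword matches only `IS<digits>` family names), then
conjugative/phage/recombinase keywords, then other recombinase-like terms.
The keyword table is versioned, and tallies are keyword-estimated — they
approximate, not reproduce, model-based mobile-element classifiers.

## The simulator

The generator is the package's experimental instrument: it produces
pangenomes whose every property the analysis stages must recover.

- **Species structure.** A Newick species tree with branch lengths in
  expected substitutions/site; the default is three clades of three genomes
  (within-clade path 0.01, across-clade ~0.09), which realizes within-clade
  nucleotide identity ≈99 % and across-clade ≈92 % — inside the bands the
  species-delineation stage is designed to separate at the 95 % cutoff.
- **Nucleotide evolution.** Core genes and intergenic spacers evolve per
  branch with the Jukes–Cantor transition probability
  `p = 3/4 (1 − e^(−4b/3))`, so realized divergence over a path matches the
  JC expectation (tested within three binomial standard deviations).
- **RdhA families.** Each orthologue family diverges from a virtual ancestor
  (the ancestor itself is never emitted, so planted families radiate as
  clean clades on a gene tree) at a pairwise amino-acid identity drawn from
  0.60–0.85, then evolves along the species tree under a slower protein
  clock (0.5 aa substitutions/site per unit nucleotide branch length) on a
  fixed codon backbone: within-family identity stays ≥92 % while
  between-family identity stays ≤85 %, bracketing the 90 % OG cutoff from
  both sides. Iron–sulphur motif positions, the start codon and the stop are
  protected from substitution.
- **Exact-identity mutants.** `mutate_to_identity` substitutes exactly
  `len − round(len·target)` uniformly chosen sites (no indels), so
  engineered pairs land exactly on threshold values — the basis of the 90 %
  and ANI calibration tests. Substitution-only is the default; this keeps
  identity arithmetic exact.
- **Clusters and island.** RDase cluster members are laid out with
  intergenic gaps well under 10 kb (cap 9 kb), so the adjacency rule holds
  by construction. The island (~20 kb of cargo: transposases, integrases,
  conjugal-transfer genes, hypotheticals) is inserted immediately 3′ of a
  designated hotspot core gene in the donor and each recipient; recipient
  copies are exact-count mutants of the donor's at the configured identity
  (default 98.5 %). The truth bounds are the full span between the inner
  edges of the flanking core genes — exactly what flanking-core-gene
  delimitation defines — so recovery can be checked for equality, not just
  overlap.
- **Events.** Losses and duplications apply to all leaves under a named
  lineage; horizontal transfers re-derive one leaf's family copy from
  another leaf's sequence at 99 % identity, producing a clade-discordant
  gene tree for that family and only that family.
- **Decoys.** Each genome carries three mining decoys (short-with-motif,
  motif-free, pseudogene-flagged) that evolve with protected motif sites so
  each keeps failing its intended filter in every genome.
- **Determinism.** One integer seed; per-branch, per-gene and per-island
  streams are derived by hashing names (CRC32), so output is byte-identical
  across runs and independent of iteration order.

**What the simulator does not emulate:** insertions/deletions (by default),
codon-usage and GC-content realism, recombination within genes, rearrangement
of gene order between genomes, assembly fragmentation and sequencing error.
Passing tests therefore demonstrate the correctness of thresholds, graph
algorithms, tree logic and coordinate arithmetic under controlled divergence
— not robustness to alignment ambiguity in indel-rich real data, where the
mafft path and the free-end-gap identity definition do the extra work.

## Problem sizes

Fixtures are desk-scale by design: genomes of 60–80 kb (40–50 core genes),
4–9 genomes per fixture, 40–72 RdhA proteins per classification run, 1000
random instances per oracle-equivalence check, and bootstrap counts of
30–100. These sizes exercise every code path while keeping the full test
suite and the acceptance script in the minutes range on one CPU.

## Known limitations

- Identity is alignment-defined; against BLAST-style local identity values
  near the 90 % cutoff can differ for sequences with long divergent tails.
- Connected components over-merge relative to MCL when between-cluster
  identity approaches the clustering threshold; the simulator's gap design
  avoids this regime, real data may not.
- The keyword MGE tally counts annotated products only; hypothetical
  proteins — the majority in real nested recombinase islands — are
  invisible to it.
- The clade-concordance screen detects transfers that cross clade
  boundaries; within-clade transfers and transfers from outside the sampled
  pangenome are not detectable by construction.
- NJ with distance correction is a topology workhorse, not a substitution
  model fit; supports near 50 % should not be over-read, and the external
  tree hook is the recommended route when an ML tree is available.
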