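# Methods

## The classification problem

Hsp70 chaperones share a collinear architecture — nucleotide-binding domain
(NBD), interdomain linker, β-sandwich substrate-binding domain (SBDβ),
α-helical lid (SBDα) and C-terminal domain (CTD) — and each cellular form
ends in a diagnostic C-terminal signature: `GPKIEEVD` for cytosolic Hsp70
(minimal core `EEVD`, strictly terminal), `HDEL` for the ER form (Bip, a
retention signal, strictly terminal), `EAEYEEVKK` for mitochondrial Hsp70
(core `EEVKK`) and `DVIDADFTDSK` for the chloroplast form (core `TDSK`).
Proteins that belong to a form but lack its signature are *truncated*
Hsp70s.  Truncated cytosolic proteins fall into two lineages: T1, which
retains most of the conserved sequence blocks of full-length cytosolic
Hsp70 and subdivides by its SBDα/CTD loss pattern into Types I–IV, and T2,
a divergent lineage carrying none of the blocks, an S/T-rich N-terminal
region and a C-terminal extension.

The pipeline reproduces that decision procedure as a deterministic cascade:

1. **Mass filter.** Candidates outside 50–90 kDa (inclusive) are removed —
   this excludes mis-annotations and larger relatives (e.g. Hsp110) that
   share Hsp70-like motifs.  Masses are average residue masses (ExPASy
   table) plus one water (18.0153 Da).
2. **Isoform dedup.** Identical sequences sharing a gene locus are
   collapsed to the lexicographically smallest protein id.
3. **Form assignment.** Nearest-reference classification: the query is
   globally aligned (BLOSUM62, gap open 10 / extend 0.5, affine) to one
   reference per form; the best full-length percent similarity wins,
   provided it reaches 60 %.  "Similarity" counts columns whose pair scores
   positively in the matrix (BLASTP "positives"); terminal gap columns are
   excluded from denominators so truncations are not penalised twice.
4. **Length class.** Full-length iff the form's minimal motif occurs within
   the last 20 residues with 0 mismatches (no indels); `EEVD`/`HDEL` must
   end exactly at the final residue, `EEVKK`/`TDSK` may end within the last
   3 residues.
5. **Lineage.** Truncated cytosolic proteins are scanned against the
   14-block library (below).  T2 requires zero hits *and* a T2 hallmark
   (S/T-rich N-terminus, or a measurable C-terminal extension).  T1
   requires ≥ 6 block hits including ≥ 4 NBD hits — an evidence floor that
   keeps spurious matches out of T1.  Everything else is unclassified.
6. **T1 subtype.**  With `s` = SBDα hits (0–4), `c` = CTD hits (0–2) and
   `e` = residues downstream of the last SBDα hit:
   Type I: s=4, c=0, e<40 (CTD deletion only); Type II: 1≤s≤3, c=0, e<40
   (CTD deleted, atypical SBDα); Type III: s=0, c=0 (lidless); Type IV:
   1≤s≤3, e≥40 (atypical SBDα plus a conserved extension); otherwise
   unclassified.  The rules are mutually exclusive by construction
   (property-tested over the full integer grid).

## Block profiles

Each of the 14 conserved blocks (6 NBD, 1 linker, 1 SBDβ, 4 SBDα, 2 CTD) is
a position-specific log-odds profile built from an ungapped seed alignment:
`w[i][r] = log2((count + pc·bg_r)/(n + pc)/bg_r)` with pseudocount 1.0 and a
uniform background by default.  A protein hits a block when some window
scores at least `f = 0.70` of the block's maximum attainable score — a
deterministic, dataset-size-independent replacement for a search E-value.
Positions aligned to `X` score zero.  For classification the canonical
block order is enforced: threshold-passing windows that cannot be arranged
collinearly are demoted via a dynamic selection that maximises the number
of hits (ties by total score).  Raising `f` can only remove hits
(monotonicity, property-tested).

The block sequences themselves are not fixed by nature here: the shipped
library is generated alongside the synthetic genome and is swappable for a
user-curated library (a directory of aligned FASTA seeds plus a manifest).

## C-terminal consensus

The last 20 residues of same-form proteins are progressively aligned (guide
tree: neighbour joining on pairwise p-distances; profile–profile steps with
linear gaps — deliberately lightweight, for short near-collinear segments
only) and summarised as a consensus with per-column information content
`IC = log2 20 − H` (gap-weighted).  The reported motif is the consensus
over the maximal trailing run of columns with IC ≥ 1 bit.

## Clusters and microsynteny

A tandem cluster is a maximal run of ≥ 3 family genes on one chromosome
with ≤ 5 intervening non-family genes between consecutive members (gene
order = rank by start coordinate, strand ignored).  The intervening-gene
cap is a tunable: the source observations constrain cluster sizes (3–24)
but not the gap, and raising the cap only merges runs (monotone).

Two genomic positions are *syntenic* when the 10 genes on each side of
their anchors (anchor/cluster members excluded; fewer near chromosome ends)
contain ≥ 3 homologous gene pairs.  Homology is protein-level: global
percent similarity ≥ 50 and residue-to-residue columns covering ≥ 50 % of
the shorter protein.  Pairs are counted by maximum bipartite matching, so a
tandem array cannot satisfy the rule by multi-mapping onto one partner.
Note that adjacent subclusters of a supercluster genuinely share flanking
genes, so neighbouring subclusters typically *are* syntenic with each other
under this rule — this mirrors the observed conservation inside real
superclusters and is not an artefact.

"Ten genes upstream and downstream" is read as 10 per side (exposed as a
parameter); the alternative reading (10 total) halves the neighbourhood.

## Molecular evolution

*Ka/Ks* is the Nei–Gojobori (1986) estimator on a protein-guided codon
alignment (each aligned residue expands to its source codon, each gap to a
3-nt gap; CDS/protein consistency is verified and a trailing stop codon
trimmed).  Synonymous sites per codon are counted over all nine single-base
mutants, with mutations to stop codons counted as nonsynonymous so that
N + S = 3 per codon exactly.  Differences in multi-substitution codon pairs
are averaged over all minimal mutational pathways; pathways through stop
codons are excluded and the average renormalised (all pathways are used if
every one is blocked).  Proportions are Jukes–Cantor corrected
(`d = −3/4·ln(1 − 4p/3)`); `p ≥ 3/4` is reported saturated, and the ratio
is undefined when Ks = 0.

Trees are Saitou–Nei neighbour joining with deterministic tie-breaking
(lexicographically smallest pair) and negative branch estimates clamped to
zero; on additive matrices the topology and branch lengths are recovered
exactly (tested to 1e-9).  Bootstrap supports are classic Felsenstein
column resampling (support = fraction of replicates containing each
original internal bipartition) — a deliberate, documented simplification
relative to transfer-bootstrap methods.  The pipeline's overview tree is
built from pairwise alignment distances of class representatives;
bootstrap supports are available through the `tree` subcommand for any
supplied alignment.

## The synthetic genome

The generator is the test bed: it emulates the study conditions, not any
particular real genome.  Defaults: 100 instances of each of the nine
classes (four full-length forms, T1 Types I–IV, T2) at a 5 % per-site
substitution rate; a 12/7/5 tandem T1 supercluster on chromosome 1
(echoing the largest supercluster observed in *Litsea cubeba*); a copy of
the first subcluster *with* its flanking genes on chromosome 2
(microsynteny positive); a copy of the second subcluster with fresh random
flanks on chromosome 3 (negative control); remaining instances scattered
with enough background genes between T1 genes that no accidental tandem
runs form.  The genome carries ~400 T1 genes, comfortably past the
15-gene T1-rich threshold.

Archetype construction guarantees the planted structure: the full-length
cytosolic archetype (696 aa, ~83 kDa) contains the 14 block consensi in
canonical order joined by random spacers and ends `GPKIEEVD`; the other
forms are 18 %-diverged bodies with their own termini; Type I drops the
CTD, Type II additionally scrambles the two middle SBDα blocks (verified
at build time to leave exactly 2 SBDα hits), Type III truncates after
SBDβ, Type IV adds a 60-residue leucine-rich extension to Type II; T2
scrambles every block region at 45 % (rejection-checked to 0/14 hits)
while keeping ~73 % overall similarity to the cytosolic reference, and
adds an S/T-rich 20-residue head plus a 45-residue extension.  Minimal
C-terminal motifs of full-length classes are shielded from instance
mutation; all class lengths sit safely inside the 50–90 kDa window.

Block widths are sized from the exact score model: with 10 near-identical
seeds and pseudocount 1, one substitution in a window costs 7.65 bits
against a 4.19-bit column maximum, so a width-32 block at `f = 0.70`
tolerates 5 substitutions and is missed with probability ≈ 0.005 at the
5 % substitution rate.  The subtype-critical SBDα blocks use width 32
(Type I, which needs all four hits, then succeeds ≈ 98 % of the time);
NBD/SBDβ use 24, CTD 20 and the linker 12 — the narrower blocks are never
decisive for a subtype call.

Coding sequences descend from one archetype CDS per class: codons of
unmutated residues are inherited, redrawn synonymously with probability
0.06; mutated residues get a random codon of the new amino acid.  This
keeps synonymous divergence between same-class instances far from
saturation, so tandem-paralog Ka/Ks is measurable (typical mean ≈ 0.4
under these neutral-substitution defaults).

What the generator does *not* emulate: indels within classes (truncations
are the only length variation), splice isoforms beyond exact duplicates,
compositional bias, genome rearrangement or gene loss, and real
phylogenetic covariance between instances (all instances of a class are
independent draws around one archetype).  Passing tests therefore
demonstrate correctness of the decision procedure and its numerical
kernels under the stated noise model — not classifier performance on real
proteomes, where block libraries and thresholds must come from curated
data.

## Numerical and degenerate-input conventions

Alignment tie-breaking follows the aligner's deterministic traceback
(diagonal over vertical over horizontal).  A domain whose projected query
slice covers < 20 % of its reference columns is reported absent rather
than 0 %.  A protein shorter than a block is scored absent for that block;
a protein shorter than the C-terminal window is searched whole.  Ordinal
ties in gene coordinates break lexicographically by gene id.  All
randomness flows from explicit seeds; reruns are byte-identical.

## Problem sizes used in the checks

The bundled verification runs use the default study-condition genome
(900 planted Hsp70 genes plus ≈ 2 900 background genes) for classifier
recovery, a compact genome (10 instances/class, 43 Type II) for cluster
and synteny recovery, 1 000 random codon pairs for the Ka/Ks oracle, 50
random 8-taxon additive matrices for neighbour joining, and exhaustive
alignment enumeration for sequences up to length 6 over a reduced
alphabet.
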