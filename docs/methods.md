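# Methods

This note documents the models, numerical choices, and limitations
behind `oligomod`: what each stage computes, which parameters matter,
and what the synthetic test fixtures do and do not demonstrate.

## Sequence profiles

A profile is an L×20 pair of matrices over the alphabet
`ACDEFGHIKLMNPQRSTVWY`: estimated residue frequencies (rows summing
to 1) and log-odds scores against BLOSUM62 marginal background
frequencies, in half-bit units (`2·log2(f/p)`), matching the PSI-BLAST
ASCII convention so that profiles built from alignments and profiles
read from `-out_ascii_pssm` files are interchangeable.

`build_pssm` drops alignment columns gapped in the query, deduplicates
identical rows exactly, weights the survivors with Henikoff
position-based weights, and blends observed frequencies with a
pseudocount target:

    f = (α·observed + β·mixture) / (α + β)

where `mixture = observed · P`, `P(k|a) ∝ p_k·2^{S(a,k)/2}` is the
conditional substitution distribution implied by the half-bit BLOSUM62
scores, `α = Neff − 1` with `Neff` the mean number of distinct residue
types per column, and `β` is the pseudocount weight (default 10).
Exact deduplication is what makes the profile invariant under
duplicating any alignment row; raw Henikoff weights alone do not have
that property, because each sequence's weight is accumulated over all
columns.  For a single sequence, `α = 0` and the profile's log-odds
reduce to the query's BLOSUM62 rows up to a per-row normalization
constant of a few hundredths of a half-bit — this is the fallback
profile used when no alignment or PSI-BLAST profile is supplied.
Unknown residues (`X`) are scored as background (zero log-odds);
`B/Z/U/O` are rejected so the dynamic-programming alphabet stays fixed
at 20.  A frequency floor of 1e-6 inside the logarithm keeps log-odds
finite for degenerate pseudocount-free profiles.

Writing a profile quantizes frequencies to integer percentages with
largest-remainder rounding (each row sums to exactly 100), so one
write/read cycle is quantizing and every further cycle is the identity.

## Domain scanning

Family models are plan7-style profile HMMs without flanking or I0
states: M match states with 20-way emission rows, insert states, and
per-node core transitions (M→M/I/D, I→M/I, D→M/D).  Models come from
three sources: HMMER3 ASCII files (via pyhmmer, renormalized to double
precision), or family alignments converted by maximum-likelihood counts
with Laplace smoothing — add-1 on emissions, add-0.1 on transitions.
The lighter transition pseudocount matters: an add-1 prior over the
3-way match split would drag M→M toward 1/2 for small families and
flatten the model's backbone; 0.1 keeps a 6-member family's M→M near
its observed value while still guarding zero counts.  Columns with
≥ 50% gaps become insert columns.

Scanning is local Viterbi in log2 space: entry into any match state at
any sequence position costs `log2(1/M)`, exit after any match state is
free, and emissions are scored as log-odds against the background.
Multiple domains are found by masking the sequence positions of the
best hit (masked positions cannot be emitted) and rescanning until the
score falls below the bit-score cutoff (default 10 bits) or 5 hits are
found.  Each hit carries its `match_map` — the (sequence position,
match state) pairs of its Viterbi path — which is the anchor for
transitive alignment.  The implementation is checked against exhaustive
enumeration of all legal state paths for M ≤ 4, L ≤ 6.

Overlapping hits are resolved greedily by descending score (ties:
longer hit, then lexicographic family name); the survivors, sorted by
start, form the domain architecture.  Architecture similarity is the
multiset Jaccard index of family names: 1 exactly for identical name
multisets, 0 for disjoint ones, and a template containing both of a
target's domains always outranks one containing a subset.  An
order-sensitive term (e.g. a longest-common-subsequence tiebreak) was
considered and dropped: template ranking breaks ties by resolution and
PDB id, and a hidden order term would make the similarity's documented
boundary values misleading.  Repeated domains count with multiplicity.

## Profile–profile alignment

The column score is the symmetric cross-product

    s(i,j) = ½ Σ_k [ lo_a(i,k)·f_b(j,k) + lo_b(j,k)·f_a(i,k) ]

in half-bits.  Gaps are affine: a run of length g costs
`open + g·extend`, default 7.0/0.7 half-bits.  Two modes share one DP:

- `global-free-ends` (default; templates are domain-sized): semiglobal
  alignment in which every gap run is charged except that, at each end,
  the terminal run of one sequence is free — the alignment may skip a
  prefix of one sequence and a suffix of one sequence at no cost, and
  those flanks appear as explicit gap columns so both sequences are
  fully covered.
- `local`: Smith–Waterman; the best block alone, empty if nothing
  scores above zero.

Adjacent gap-in-a/gap-in-b columns are allowed and charged as two runs.
Traceback ties prefer match over consuming `a` over consuming `b`,
making output bit-reproducible.  Both modes are verified against
exhaustive enumeration of all monotone match sets for lengths ≤ 5.

Identity is `100 × identical pairs / gap-free columns` — not alignment
length and not shorter-sequence length; with terminal flanks
represented as gap columns, the free-ends and block views of the same
alignment therefore agree on identity but differ on gap percentage,
which is `100 × columns containing a gap / total columns`.  An
alignment with no gap-free columns reports identity 0 with a warning.

## Transitive alignment and family analyses

Two sequences scanned against the same HMM are transitively aligned by
pairing residues mapped to the same match state; columns are ordered by
match state and contain no gaps.  This reproduces direct column-wise
identity exactly on gap-free families whose members all span all match
states, but in general covers only the intersection of the two local
hits — transitive identities are therefore not comparable to
full-length structure-alignment identities, which align more columns.

The per-family minimum of pairwise transitive identities summarizes how
deep a family's detectable homology reaches.  Densities over such
minima use a Gaussian KDE evaluated directly (mean of normal pdfs), with
the bandwidth given in identity-percent units or chosen by Silverman's
rule `h = 0.9·min(sd, IQR/1.34)·n^{-1/5}`; scipy's `gaussian_kde`
parameterizes bandwidth as a factor on the sample standard deviation
and cannot express a fixed-width kernel, so it serves as a cross-check
rather than the implementation.  Over a grid extending several
bandwidths beyond the data the trapezoidal integral is 1 within 1e-3.

Interface-cluster records (cluster id, one or two families, member
entries, crystal-form count, minimum identity) are filtered with the
recurrence criterion: at least 5 crystal forms and minimum identity
strictly below 90%.  Overlap between two clusters is classified on PDB
entry sets; the public cluster rows carry entries only, so crystal-form
overlap is assessed at entry granularity — a documented coarsening.

## Assemblies

Coordinates and entities are parsed with gemmi; only polymer amino-acid
residues are kept, waters and other heteroatoms are dropped, and
altlocs resolve to the highest-occupancy conformer (ties: first).
Entity sequences are derived from the observed residues of each
entity's first chain, so "sequence position k" always means the k-th
residue in chain order — alignments, threading, and assembly chains
stay index-consistent even when author numbering is irregular.  For
legacy PDB input, chains are grouped into entities by identical derived
sequence.

The assembly recipe is parsed by this package from the mmCIF
`pdbx_struct_oper_list` / `pdbx_struct_assembly_gen` categories or from
REMARK 350.  Operator expressions support comma lists, numeric ranges
and parenthesized products; `(P)(Q)` composes as "apply Q, then P"
(R = R_P·R_Q, t = R_P·t_Q + t_P), the wwPDB convention, verified by
applying compositions to random points.  Every operator must be a
proper rotation (determinant 1 and orthogonal within 1e-6).  Generated
chains are ordered source-chain-fastest within each composed operator;
new chain ids run A–Z, a–z, then two-character pairs (capped at 9999).
Identity-operator copies reuse the source coordinates bit-exactly,
which is what makes self-threading exactly lossless downstream.  When a
file defines several assemblies the first is the default, selectable by
id.  PDB output is fixed-column with TER records and is limited to 62
single-character chains.

## Threading and side-chain grafting

For every gap-free alignment column the template residue's N, CA, C, O
— and CB unless the target residue is glycine — are copied bit-exactly
and renumbered to the target position.  Target residues aligned to gaps
become *unmodeled insertions*: numbering gaps with no atoms, listed in
a REMARK block (no loop modeling).  Template residues unaligned to the
target are skipped.  Residue numbers are target positions throughout,
so a target with unaligned N-terminal residues simply starts at the
first aligned position.

Side chains follow the preservation rule: residues identical between
target and template keep every template side-chain heavy atom verbatim,
preserving the experimental rotamers exactly.  Mutated residues are
rebuilt atom by atom with the NeRF construction; bond lengths, angles
and non-rotatable torsions are measured at import time from the ideal
chemical-component coordinates bundled with biotite (so the geometry
table is the CCD's), and only the chi torsions about rotatable bonds
are free.  Branch atoms sharing a chi axis keep their ideal offset from
the primary chi atom, which reproduces e.g. carboxylate OD2 at
chi2+180 without per-residue special cases.  Rebuilt side chains
reproduce the CCD templates to < 1e-6 Å when all torsions are ideal.

Chi values come from a compact backbone-independent rotamer table
(~110 entries; gauche−/trans/gauche+ chi1 states with standard chi2+
combinations, priors normalized per residue type).  Candidates are
tried in descending prior; the first with zero heavy-atom contacts
closer than the clash cutoff (default 2.5 Å) to already-placed atoms —
own-residue atoms excluded — is taken, else the minimum-clash-count
rotamer with ties to the higher prior.  This greedy scheme is a
deliberate simplification of full combinatorial side-chain optimization
(no dead-end elimination, no backbone-dependent φ/ψ binning); the
selection rule itself is verified against an exhaustive clash count
over the whole library.  Chains are built in assembly order, each
seeing all previously built chains as environment.

Entity assignment aligns every target × entity pair sharing a domain
family and then assigns greedily by descending identity (ties: target
input order, then entity order), each target and entity used at most
once; all assembly copies of an entity are threaded with its one
assigned target.  Chains of unassigned entities are excluded with a
logged notice.

## Synthetic fixtures

The fixture generator emulates every external input from one RNG seed,
byte-identically per seed: five domain families (gap-free alignments of
4–8 members at 20–45% per-site mutation rates, including a two-clade
receptor family so the two receptor entities are homologous but
distinct), a heterohexamer template (three entities × two chains with
identity operators, the composition of a TGF-β-family ligand/receptor
assembly such as PDB entry 2H64), a monomer whose dimer is generated by
a C2 rotation — written once as mmCIF and once as REMARK 350 PDB so the
two dialect readers check each other — a template catalogue, target
FASTAs (mutants of the entities, drawn so each receptor target is
strictly closer to its intended entity), a PSSM and an `.ss2` file, an
interface-cluster table with boundary cases on both filter thresholds,
and the rotamer table.  Chain coordinates are ideal α-helices with
top-prior side chains placed on a circle; they are geometrically valid
but not energy-minimized, and fixture "crystal structures" have none of
the missing residues, altloc disorder, or non-ideal geometry of real
depositions.  Realized quantities (pairwise transitive identities per
family, target–entity identities, expected filter outcomes) are
recorded in a JSON manifest so analyses can be tested against the
generator's own bookkeeping.

Passing on these fixtures shows the machinery is self-consistent and
exact where exactness is claimed; it does not measure modeling accuracy
on real structures, which depends on profile quality and template
coverage that the fixtures idealize.  Family-identity densities
computed on the fixtures describe the synthetic families only and are
not comparable to PDB-wide statistics, which require full database
snapshots.

## Problem sizes and determinism

Oracle suites run hundreds of random instances at enumeration-feasible
sizes (alignment lengths ≤ 5, HMMs with M ≤ 4 on sequences of L ≤ 6,
≤ 5 domain hits, the full rotamer library per selection); fixture
structures are 20–36 residues per chain.  These sizes make exhaustive
enumeration exact rather than sampled.  All randomness flows through
seeded NumPy generators; the pipeline itself is deterministic — two
runs on the same inputs produce byte-identical model files.

## Known limitations

- Single-sequence fallback profiles are BLOSUM62-soft; below roughly
  40% identity their alignments lose signal faster than real
  PSI-BLAST profiles would.  Supplying real PSSMs is recommended for
  remote homology.
- No Pfam-clan awareness: targets and templates in different families
  of the same clan are not matched.
- Entity assignment is greedy, not globally optimal; with near-tied
  identities the assignment follows input order.
- Rebuilt rings (His, Phe, Tyr, Trp) close to ideal geometry only as
  well as the Z-matrix walk allows; closure-bond error is within the
  stated 0.05 Å tolerance but not zero.
- Crystal-form overlap between interface clusters is approximated by
  entry overlap.
- No loop modeling, refinement, or assembly-correctness assessment;
  models inherit whatever the deposited biological assembly asserts.
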