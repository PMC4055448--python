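# oligomod

Template-based homology modeling of protein homo- and heterooligomeric
complexes from the biological assemblies deposited in the PDB.

Most proteins act as oligomers, and when a homologous complex has been
crystallized, copying its quaternary arrangement is far more reliable
than docking monomers ab initio.  `oligomod` is a headless library and
CLI for that workflow, aimed at structural bioinformaticians who want
each stage scriptable and testable:

1. **Targets** — up to six distinct amino-acid sequences are read from
   FASTA and turned into PSSMs (position-specific scoring matrices,
   half-bit log-odds; PSI-BLAST ASCII profiles and PSIPRED `.ss2`
   secondary structure can be substituted).
2. **Domains** — each target is scanned against Pfam-style profile HMMs
   with a local plan7 Viterbi algorithm; surviving non-overlapping hits
   form the target's *domain architecture*.
3. **Template search** — assemblies in a template catalogue are ranked
   by the multiset Jaccard similarity between their entities' domain
   architectures and the targets'.
4. **Alignment** — targets are aligned to template entities by
   affine-gap profile–profile dynamic programming with the symmetric
   cross-product column score
   `s(i,j) = ½ Σ_k [ lo_a(i,k)·f_b(j,k) + lo_b(j,k)·f_a(i,k) ]`,
   and each target is assigned to the entity with the highest alignment
   identity.
5. **Assembly** — the template's biological assembly is expanded from
   its rigid-body operators (`x' = Rx + t`), parsed from either mmCIF
   (`pdbx_struct_assembly_gen` / `pdbx_struct_oper_list`, including
   product expressions such as `(1-60)(61-88)`) or legacy PDB
   REMARK 350 records.
6. **Model** — target sequences are threaded onto every assembly chain
   of their entity: backbone atoms of aligned residues are copied
   bit-exactly, insertions are left unmodeled as numbering gaps, side
   chains identical between target and template keep the template's
   rotamers verbatim, and mutated side chains are rebuilt from ideal
   internal coordinates using a compact backbone-independent rotamer
   table with greedy clash avoidance.  No loop modeling, no refinement.

The package also implements two family-level analyses: *transitive
alignment* (pairing residues of two sequences mapped to the same HMM
match state, giving within-family identity statistics without any
pairwise search) and a ProtCID-style interface-cluster filter (clusters
recurring in ≥ 5 crystal forms with minimum sequence identity < 90%,
plus entry-overlap classification).

## Worked example

Everything needed for a modeling session can be generated synthetically
— family alignments, a template catalogue, coordinates with assembly
operators, and target sequences:

```bash
oligomod fixtures --seed 17 -o fixtures
oligomod model fixtures/targets/hetero_targets.fasta \
    --catalogue fixtures/catalogue.tsv \
    --structures fixtures/structures \
    --hmm-dir fixtures/pfams \
    -o model.pdb --report report.txt
```

prints

```
model with 6 chain(s) written to model.pdb
  chain A: t_lig -> entity 1 (75.0% identity)
  chain B: t_lig -> entity 1 (75.0% identity)
  chain C: t_r1 -> entity 2 (84.8% identity)
  chain D: t_r1 -> entity 2 (84.8% identity)
  chain E: t_r2 -> entity 3 (87.9% identity)
  chain F: t_r2 -> entity 3 (87.9% identity)
```

The scenario mirrors a classic ligand/receptor session: template `9hex`
is a heterohexamer (a ligand-family dimer bound by two copies of each
of two homologous receptor ectodomain entities, the arrangement of PDB
entry 2H64).  The three targets share domain families with the three
entities; the two receptor targets both carry the same family, and each
is assigned to the entity it aligns to with higher identity (84.8% vs
42.4% for `t_r1`), so the model threads each target onto both copies of
its entity — six chains in all.  The hit-table report lists, per
template assembly and target: resolution, assembly architecture,
alignment identity, gap percentage, alignment length and start/end
positions.  The model PDB carries the same provenance in REMARK records:

```
REMARK   3 TEMPLATE 9hex ASSEMBLY 1
REMARK   3 CHAIN A TARGET t_lig ENTITY 1 IDENTITY 75.0% GAPS 0.0% UNMODELED 0
```

Other subcommands: `scan` (domain hits), `rank` (template ranking),
`align` (pairwise profile alignment serialized as editable gapped
FASTA; hand-edited copies are picked up by
`model --alignment-dir DIR`, replacing the GUI-style interactive
alignment editing with a file round trip), `assemble` (expand a
biological assembly to PDB), `analyze-identities`
(minimum transitive identity per family plus a kernel density
estimate), `analyze-clusters` (interface-cluster filtering and overlap
classification), and `config --show`.

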