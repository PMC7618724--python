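# structcheck

Verify that a protein structure file really contains the protein — and the
numbering — that its UniProt accession promises, and repair the numbering
when it does not.

## The problem

UniProt entries are revised several times a year; structure resources,
especially model databases, update on a different cadence.  A model built
from an older sequence version can lack residues, carry extra ones, differ
in individual amino acids, or simply number its residues differently from
the current UniProt entry.  The author residue identifier in a PDB file
(columns 23–26 of each `ATOM` line, plus the insertion code in column 27)
is only a label: nothing guarantees it equals the UniProt position that
sequence annotations (variants, domains, binding sites, PTMs) refer to.
Mapping annotations onto such a file by residue number silently hits the
wrong atoms.  Residue-level mappings exist for experimental structures
(SIFTS), but not for arbitrary model files.

`structcheck` takes a reference sequence (a local FASTA or a UniProt
accession) and a structure file, and answers two questions per chain:

1. **Sequence**: does the chain's amino-acid sequence, read off its `ATOM`
   records, match the reference end to end?
2. **Identifiers**: does each present residue's author number equal its
   UniProt position, so that annotation mapping is safe?

## Method

Let $r_1\dots r_L$ be the reference sequence (residue $i$ has UniProt
identifier $i$) and $q_1\dots q_M$ the chain sequence extracted from the
`ATOM` records (one residue per distinct residue-number/insertion-code
pair, in file order).  The two are aligned globally with the
Needleman–Wunsch algorithm under a linear scoring scheme
(default: match $+1$, mismatch $0$, gap $0$).  Because that scheme admits
many co-optimal alignments, traceback ties are broken deterministically at
every cell — diagonal over gap-in-query over gap-in-reference — so the
reported alignment is unique and reproducible.

Every alignment column becomes one row of a residue table:

| label | meaning |
|---|---|
| `ID match` | aligned residue whose author number equals its UniProt position (no insertion code) |
| `ID mismatch` | aligned residue whose identifier disagrees |
| `missing` | reference residue absent from the structure (deletion) |
| `insertion` | structure residue absent from the reference |

A *variation* is an aligned column whose amino acids differ.  Summary
statistics (alignment length, % identity, gap runs/columns, variations,
per-label counts) feed two verdicts: the sequence is *safe to use* only
for a gap-free 100 % identity, and the identifiers are *safe to map
features* only with zero `ID mismatch` and zero `insertion` rows (missing
residues are allowed).  A renumbering plan assigns every aligned residue
its UniProt position; insertions are dropped (with a warning) to keep the
mapping one-to-one, and the renumbered PDB is written by replacing only
columns 23–27 of the retained lines.

## Worked example

`examples/check_synthetic_model.py` builds a 150-residue reference and a
structure derived from it with a 12-residue internal deletion and all
residue numbers shifted by +96, then checks it:

```
Reference:              SYN00042 (150 aa)
Structure chain:        A (138 residues)
Alignment length:       150
Sequence identity:      92.00% of columns (100.00% of aligned pairs)
Gaps:                   1 run(s), 12 column(s)
Variations:             0
Residue IDs matching:   0
Residue IDs mismatched: 138
Missing from structure: 12
Insertions in structure: 0

Differences between the UniProt sequence and structure - use structure carefully
Differences between the UniProt residue identifiers and structure residue identifiers - map UniProt annotations carefully
```

Every aligned pair is identical (100 % of aligned pairs) yet 12 reference
residues are missing, so the sequence verdict is cautious; and because
every author number is 96 too high, all 138 present residues are
`ID mismatch` — annotation mapping by residue number would be wrong
everywhere.  `examples/renumber_structure.py` shows the repair: after
writing the renumbered file, a re-check reports 0 mismatches and the
safe-to-map verdict.

The other examples cover the residue mapping table
(`residue_mapping_table.py`) and reference retrieval with caching and
offline fallback (`fetch_reference.py`).

## Command line

```bash
structcheck --uniprot P69905 --structure model.pdb --chain A --out results/
structcheck --ref-fasta ref.fasta --structure model.pdb --offline
```

writes `mapping.tsv`, `mapping.json`, `alignment.fasta` and
`renumbered.pdb` into the output directory and prints the summary to
stderr.  The exit status encodes the verdict: 0 both match, 3 sequence
differs, 4 only identifiers differ, 5 network failure, 1 unusable input.
Custom files beyond 5 MB are rejected before any computation.

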