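# Methods

## Scope and model

`structcheck` checks one structure chain against one reference sequence.
The reference defines the coordinate system: residue *i* of the sequence
has identifier *i*.  The chain sequence is read off the `ATOM` records of
a PDB file — one residue per distinct (chain, residue number, insertion
code) triple, in file order — because the `ATOM` section is what defines
which residues a structure actually contains.  `HETATM` records, waters
and non-amino-acid residue names in `ATOM` records are excluded; unknown
residue names become `X`.  Multi-model (NMR-style) files contribute only
their first model: the sequence is identical across models, and a single
deterministic choice keeps outputs reproducible.  Alternate locations are
collapsed onto the first atom record of each residue, which cannot change
chain length because residue identity is keyed on the identifier triple,
not on atoms.  Non-contiguous re-use of an identifier within a chain is
kept as the first occurrence and reported as a warning.

## Alignment

The reference and chain sequences are aligned end-to-end by
Needleman–Wunsch dynamic programming with linear gap scoring.  Default
parameters: match +1, mismatch 0, gap 0 per gapped column — the score of
an alignment is then simply its number of identical pairs.  All three
values are configurable (`--scoring match,mismatch,gap`).

With free mismatches and gaps, co-optimal alignments are plentiful (a
mismatch column costs exactly as much as a pair of gap columns, and gaps
can slide along repeated residues).  The implementation therefore fixes
the traceback: at every cell, diagonal (pair the residues) is preferred
over up (gap in the query — a reference residue missing from the
structure) over left (gap in the reference — a structure-only insertion),
applied from the end of the alignment.  This selects a unique optimum:
repeated runs on identical inputs give byte-identical outputs.  The DP is
vectorised row-wise with NumPy; the in-row dependency of linear-gap
scoring is removed with a prefix-maximum identity, so a 2,700×2,700
problem (the largest a database-sourced entry can be) stays well under a
second.

Degenerate inputs: empty sequences are rejected; scores are compared with
an absolute tolerance of 1e-9 during traceback to keep float arithmetic
from flipping a preference.

## Classification and summaries

Each alignment column becomes one row of the residue table.  Aligned
residues are `ID match` when the author number equals the UniProt position
and the insertion code is blank, otherwise `ID mismatch`.  Reference-only
columns are `missing`, structure-only columns `insertion`.  A *variation*
flags an aligned column whose amino acids differ; `X` (unknown residue
name) never counts as an identity, so an `X`–`X` column is conservatively
a variation too.

Summary counts satisfy three conservation identities (checked by the test
suite on random fixtures):

* `ID match` + `ID mismatch` + `insertion` = structure residues,
* `ID match` + `ID mismatch` + `missing` = reference length,
* alignment length = structure residues + missing = reference length + insertions.

Percent identity uses the full alignment length as denominator, so it
penalises gaps as well as variations; the identical-over-aligned-pairs
ratio is exposed alongside (`identity_aligned_pct`) because a perfect
fragment is usefully described by "100 % of aligned pairs, partial
coverage".  The gap count is reported both as maximal gap runs (indel
events) and as gapped columns.

The sequence verdict is a *match* only for a gap-free 100 % identity; the
identifier verdict is a *match* only with zero `ID mismatch` and zero
`insertion` rows — missing residues do not block it, since annotations
can still be mapped onto every residue that is present.

## Renumbering

The renumbering plan maps each aligned residue's (number, insertion code)
key to its UniProt position.  Inserted residues have no UniProt
counterpart and are removed from the renumbered file to preserve a
one-to-one mapping; the plan carries a warning naming how many residues
that removes.  Writing is byte-level line surgery on the original file:
only columns 23–26 (new number, right-justified) and 27 (insertion code
blanked) of retained `ATOM` lines change; records of other chains are
omitted; a `REMARK` line names the tool and the reference accession.
New numbers outside −999…9999 cannot be represented in the fixed columns
and raise an error.

## Input limits

Custom structure files above 5 MB are rejected before any computation,
and database-sourced entries longer than 2,700 residues are rejected
because such entries are split across multiple files upstream and cannot
be fetched whole.  Both limits produce blocking warnings naming the
limit; the byte limit is configurable on the command line.

## Reference retrieval

All core computation consumes an in-memory reference value, so the
UniProt REST fetch is an isolated adapter (stdlib `urllib`; no third-party
HTTP dependency).  Accessions are validated against the UniProtKB grammar
before any network call; isoform suffixes pass through verbatim.
Retrieved sequences are cached as JSON keyed by accession with the
retrieval date, making repeated runs reproducible and enabling a strict
offline mode that never touches the network.  A fetch either returns a
non-empty sequence or raises a distinct network error — never a silent
empty result.

## Synthetic data generator

The generator emulates the discrepancy classes seen between model files
and current UniProt entries: terminal truncations, internal deletions,
insertions, point substitutions, global numbering offsets and insertion
codes.  Starting from a uniform random 20-letter reference sequence of
chosen length and seed, an edit plan is applied in coordinate order and
emitted as a minimal CA-only PDB with correct fixed-column formatting.
Because the perturbation is known, the exact residue table the checker
must produce is known by construction — the generator is the oracle for
the whole pipeline, and all of its outputs are pure functions of
(length, seed, plan).

For the construction to be an *exact* oracle, its optimal alignment must
be unique under the default scoring, and the spacing rule alone (edit
intervals separated by ≥ 2 unedited positions) does not guarantee that:

* a gap can slide whenever a deleted block contains its left-flank
  residue (the traceback would pair the flank inside the block);
* an insertion can slide whenever its text contains the residue at its
  anchor position;
* a substituted or inserted letter recurring anywhere between its own
  position and the end of a downstream deletion block lets the aligner
  trade the free mismatch for a match at equal score, relocating the
  whole stretch in between.

`validate_plan` rejects plans violating any of these, and the random-plan
sampler simply redraws until a valid plan appears.  The test suite
verifies exact ground-truth recovery on 100 random plans.

What the generator does *not* emulate: realistic coordinates or geometry,
B-factors/confidence values, multiple conformers, chain breaks without
sequence loss, and modified residues.  Passing tests therefore
demonstrate correctness of sequence extraction, alignment,
classification, renumbering and serialisation — not robustness to
malformed real-world coordinate blocks beyond the fixed-column rules the
parser enforces.

## The worked-example twin

The checker's headline scenario is an outdated model: a current
478-residue entry whose model lacks 96 consecutive residues ending before
position 107, differs in two residues near its start, and is numbered
consecutively from 1.  `worked_example_twin` builds exactly this: the
deletion spans positions 7–102, substitutions sit at positions 1 and 4
(letters drawn from those absent up to the deletion end, as the
uniqueness rules require), and the chain is renumbered 1…382 the way
model files are.  The reference draw is retried deterministically from
the seed until the deletion satisfies the uniqueness rules.  The reported
quantities — 382 structure residues, one 96-column missing run, 2
variations, UniProt 107 carrying structure number 11 (107 − 96), and zero
mismatches after renumbering — are forced by the construction and hence
identical for every seed; `scripts/acceptance.py` recomputes them through
the full pipeline at run time.

## Problem sizes and defaults

Default test and acceptance problem sizes are desk-scale by design:
references of 60–480 residues, 100-plan oracle sweeps, and a 1,000-pair
exhaustive-enumeration check at sequence length ≤ 8 (enumeration is
exponential; 8 is where it stays comfortable).  The full suite runs in
seconds on one CPU with no downloads.  A live test reproducing the
worked example from UniProt and a model database runs only when the
network is reachable, records its retrieval date, and reports upstream
revisions as a diagnostic rather than a bare assertion failure.

## Known limitations

* PDB format only; mmCIF/BinaryCIF input is out of scope.
* One chain per run; no joint multi-chain renumbering.
* No geometry validation — agreement of sequence and numbering says
  nothing about coordinate quality.
* The identity formula (alignment-length denominator) and the insertion
  label for structure-only residues are this package's definitions;
  other tools may report identity over aligned pairs only.
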