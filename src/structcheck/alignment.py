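"""Global alignment of reference vs structure sequence and its interpretation.

The reference (UniProt) sequence and the query sequence read off the
structure's ATOM records are aligned end-to-end with the Needleman-Wunsch
algorithm.  The default scoring (match 1, mismatch 0, gap 0) admits many
co-optimal alignments, so traceback ties are broken deterministically at
every cell: diagonal (pair the residues) over up (gap in the query,
i.e. a reference residue missing from the structure) over left (gap in
the reference, i.e. a structure-only insertion).  The result is a single
reproducible alignment.

Every alignment column is then classified against the author residue
identifiers of the structure:

* ``ID match``    — aligned residue whose author number equals its
  UniProt position (and no insertion code);
* ``ID mismatch`` — aligned residue whose identifier disagrees;
* ``missing``     — reference position with no structure residue
  (a deletion with respect to UniProt);
* ``insertion``   — structure residue absent from the reference,
  excluded from any renumbered output.

A *variation* is an aligned column whose amino acids differ.  ``'X'``
(unknown residue name) never counts as an identity, so an X-X column is
treated as a variation as well.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .reference_io import ReferenceSequence
from .structure_io import ChainSequence

__all__ = [
    "ScoringScheme",
    "DEFAULT_SCORING",
    "AlignmentColumn",
    "Label",
    "MappingRow",
    "SummaryStats",
    "Assessment",
    "SEQ_MATCH_MESSAGE",
    "SEQ_DIFFER_MESSAGE",
    "ID_MATCH_MESSAGE",
    "ID_DIFFER_MESSAGE",
    "align_strings",
    "global_align",
    "classify",
    "summarize",
    "assess_sequence",
    "assess_identifiers",
]

SEQ_MATCH_MESSAGE = "Your structure matches the UniProt sequence, safe to use!"
SEQ_DIFFER_MESSAGE = (
    "Differences between the UniProt sequence and structure - "
    "use structure carefully"
)
ID_MATCH_MESSAGE = (
    "Your structure matches the UniProt sequence identifiers, safe to map features!"
)
ID_DIFFER_MESSAGE = (
    "Differences between the UniProt residue identifiers and structure residue "
    "identifiers - map UniProt annotations carefully"
)


@dataclass(frozen=True)
class ScoringScheme:
    """Linear-gap Needleman-Wunsch parameters.

    The defaults (match 1, mismatch 0, gap 0) score an alignment by its
    number of identical pairs, with mismatches and gaps free — the
    classic general-purpose pairwise-aligner default.  All three values
    are configurable for stricter schemes.
    """

    match_score: float = 1.0
    mismatch_score: float = 0.0
    gap_score: float = 0.0


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class AlignmentColumn:
    """One column of the global alignment.

    ``ref_pos`` is the 1-based reference position (None for a gap in the
    reference); ``query_index`` the 0-based order index of the structure
    residue (None for a gap in the query).  Never both None.
    """

    ref_pos: int | None
    query_index: int | None
    ref_aa: str  # '-' when gapped
    query_aa: str


class Label(str, enum.Enum):
    ID_MATCH = "ID match"
    ID_MISMATCH = "ID mismatch"
    MISSING = "missing"
    INSERTION = "insertion"


@dataclass(frozen=True)
class MappingRow:
    """One row of the detailed residue table."""

    alignment_id: int  # 1-based column index
    uniprot_aa: str | None
    uniprot_id: int | None
    structure_aa: str | None
    structure_id: str | None  # res_seq + icode, e.g. "100A"
    label: Label
    variation: bool


class Assessment(enum.Enum):
    SEQ_MATCH = "SEQ_MATCH"
    SEQ_DIFFER = "SEQ_DIFFER"
    ID_MATCH = "ID_MATCH"
    ID_DIFFER = "ID_DIFFER"


@dataclass(frozen=True)
class SummaryStats:
    """Alignment-level and identifier-level counts with both assessments."""

    aln_length: int
    identity_pct: float  # identical pairs / alignment columns * 100
    identity_aligned_pct: float  # identical pairs / aligned pairs * 100
    n_identical: int
    n_gap_runs: int  # maximal runs of consecutive gapped columns
    n_gap_columns: int
    n_variations: int
    n_struct_residues: int
    n_id_match: int
    n_id_mismatch: int
    n_missing: int
    n_insertions: int
    sequence_assessment: Assessment
    id_assessment: Assessment


def _score_grid(a: str, b: str, scoring: ScoringScheme):
    """Dynamic-programming score matrix H, shape (len(a)+1, len(b)+1)."""
    n, m = len(a), len(b)
    g = float(scoring.gap_score)
    av = np.frombuffer(a.encode("latin-1"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("latin-1"), dtype=np.uint8)
    S = np.where(
        av[:, None] == bv[None, :],
        float(scoring.match_score),
        float(scoring.mismatch_score),
    )
    H = np.empty((n + 1, m + 1), dtype=np.float64)
    jg = g * np.arange(m + 1)
    H[0, :] = jg
    H[:, 0] = g * np.arange(n + 1)
    # Row recurrence.  The in-row dependence H[i,j-1] is removed with
    # the identity  H[i,j] = g*j + max_{k<=j} (cand_k - g*k)  where
    # cand_0 = H[i,0] and cand_k = max(diag, up) for k>=1, so each row
    # is a prefix-maximum (vectorised).
    for i in range(1, n + 1):
        cand = np.maximum(H[i - 1, :-1] + S[i - 1], H[i - 1, 1:] + g)
        shifted = np.concatenate(([H[i, 0]], cand - jg[1:]))
        H[i, 1:] = np.maximum.accumulate(shifted)[1:] + jg[1:]
    return H, S


_TOL = 1e-9


def align_strings(
    a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING
) -> tuple[float, str]:
    """Align two plain strings; return (score, ops).

    ``ops`` is the traceback path start-to-end: ``'D'`` pairs one
    character of each sequence, ``'U'`` consumes a character of ``a``
    only (gap in ``b``), ``'L'`` a character of ``b`` only.  Ties are
    broken diagonal > up > left at every traceback cell (applied from
    the alignment end), which selects a unique optimal alignment.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    H, S = _score_grid(a, b, scoring)
    g = float(scoring.gap_score)
    i, j = len(a), len(b)
    ops: list[str] = []
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0 and abs(h - (H[i - 1, j - 1] + S[i - 1, j - 1])) <= _TOL:
            ops.append("D")
            i -= 1
            j -= 1
        elif i > 0 and abs(h - (H[i - 1, j] + g)) <= _TOL:
            ops.append("U")
            i -= 1
        else:
            ops.append("L")
            j -= 1
    ops.reverse()
    return float(H[len(a), len(b)]), "".join(ops)


def _columns_from_ops(a: str, b: str, ops: str) -> list[AlignmentColumn]:
    cols = []
    i = j = 0
    for op in ops:
        if op == "D":
            cols.append(AlignmentColumn(i + 1, j, a[i], b[j]))
            i += 1
            j += 1
        elif op == "U":
            cols.append(AlignmentColumn(i + 1, None, a[i], "-"))
            i += 1
        else:
            cols.append(AlignmentColumn(None, j, "-", b[j]))
            j += 1
    return cols


def global_align(
    ref: ReferenceSequence,
    query: ChainSequence,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> list[AlignmentColumn]:
    """Needleman-Wunsch alignment of the reference against the chain.

    Deterministic: a unique optimal alignment is returned for fixed
    inputs (see module docstring for the tie-break).
    """
    if len(ref) == 0:
        raise ValueError("reference sequence is empty")
    if len(query) == 0:
        raise ValueError("structure chain has no residues")
    _, ops = align_strings(ref.sequence, query.sequence, scoring)
    return _columns_from_ops(ref.sequence, query.sequence, ops)


def classify(columns: list[AlignmentColumn], query: ChainSequence) -> list[MappingRow]:
    """Turn alignment columns into the detailed residue table."""
    rows: list[MappingRow] = []
    for aln_id, col in enumerate(columns, start=1):
        if col.query_index is None:
            rows.append(
                MappingRow(aln_id, col.ref_aa, col.ref_pos, None, None,
                           Label.MISSING, False)
            )
            continue
        residue = query.residues[col.query_index]
        if col.ref_pos is None:
            rows.append(
                MappingRow(aln_id, None, None, col.query_aa,
                           residue.structure_id, Label.INSERTION, False)
            )
            continue
        identical = col.ref_aa == col.query_aa and col.ref_aa != "X"
        id_ok = residue.icode == "" and residue.res_seq == col.ref_pos
        rows.append(
            MappingRow(
                aln_id,
                col.ref_aa,
                col.ref_pos,
                col.query_aa,
                residue.structure_id,
                Label.ID_MATCH if id_ok else Label.ID_MISMATCH,
                not identical,
            )
        )
    return rows


def summarize(rows: list[MappingRow]) -> SummaryStats:
    """Aggregate the residue table into summary counts and assessments."""
    if not rows:
        raise ValueError("cannot summarize an empty residue table")
    n_id_match = sum(r.label is Label.ID_MATCH for r in rows)
    n_id_mismatch = sum(r.label is Label.ID_MISMATCH for r in rows)
    n_missing = sum(r.label is Label.MISSING for r in rows)
    n_insertions = sum(r.label is Label.INSERTION for r in rows)
    n_variations = sum(r.variation for r in rows)
    aln_length = len(rows)
    n_aligned = n_id_match + n_id_mismatch
    n_identical = n_aligned - n_variations
    n_gap_columns = n_missing + n_insertions
    n_gap_runs = 0
    in_run = False
    for r in rows:
        gapped = r.label in (Label.MISSING, Label.INSERTION)
        if gapped and not in_run:
            n_gap_runs += 1
        in_run = gapped
    identity_pct = 100.0 * n_identical / aln_length
    identity_aligned_pct = 100.0 * n_identical / n_aligned if n_aligned else 0.0
    seq_ok = n_identical == aln_length  # 100% identity and gap-free
    id_ok = n_id_mismatch == 0 and n_insertions == 0
    return SummaryStats(
        aln_length=aln_length,
        identity_pct=identity_pct,
        identity_aligned_pct=identity_aligned_pct,
        n_identical=n_identical,
        n_gap_runs=n_gap_runs,
        n_gap_columns=n_gap_columns,
        n_variations=n_variations,
        n_struct_residues=n_aligned + n_insertions,
        n_id_match=n_id_match,
        n_id_mismatch=n_id_mismatch,
        n_missing=n_missing,
        n_insertions=n_insertions,
        sequence_assessment=Assessment.SEQ_MATCH if seq_ok else Assessment.SEQ_DIFFER,
        id_assessment=Assessment.ID_MATCH if id_ok else Assessment.ID_DIFFER,
    )


def assess_sequence(stats: SummaryStats) -> str:
    """Sequence-level verdict: safe only for a gap-free 100% identity."""
    if stats.sequence_assessment is Assessment.SEQ_MATCH:
        return SEQ_MATCH_MESSAGE
    return SEQ_DIFFER_MESSAGE


def assess_identifiers(stats: SummaryStats) -> str:
    """Identifier-level verdict: missing residues are allowed, mismatches and
    insertions are not."""
    if stats.id_assessment is Assessment.ID_MATCH:
        return ID_MATCH_MESSAGE
    return ID_DIFFER_MESSAGE
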