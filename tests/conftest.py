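"""Shared helpers: a brute-force alignment oracle and fixture builders."""

from __future__ import annotations

import random

import pytest

from structcheck.alignment import DEFAULT_SCORING, ScoringScheme
from structcheck.reference_io import ReferenceSequence
from structcheck.structure_io import ChainSequence, ResidueRecord, three_letter_code


def brute_force_align(a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING):
    """Exhaustively enumerate every global alignment of ``a`` and ``b``.

    Returns (best score, ops string).  Enumeration runs depth-first from
    the alignment end trying diagonal, then up, then left, so the first
    optimum encountered is the one the deterministic traceback
    preference selects; only strictly better scores replace it.
    Exponential — intended for sequences of length <= 8.
    """
    best = [None, None]
    ops: list[str] = []

    def rec(i: int, j: int, score: float) -> None:
        if i == 0 and j == 0:
            if best[0] is None or score > best[0]:
                best[0] = score
                best[1] = "".join(reversed(ops))
            return
        if i > 0 and j > 0:
            s = (
                scoring.match_score
                if a[i - 1] == b[j - 1]
                else scoring.mismatch_score
            )
            ops.append("D")
            rec(i - 1, j - 1, score + s)
            ops.pop()
        if i > 0:
            ops.append("U")
            rec(i - 1, j, score + scoring.gap_score)
            ops.pop()
        if j > 0:
            ops.append("L")
            rec(i, j - 1, score + scoring.gap_score)
            ops.pop()

    rec(len(a), len(b), 0.0)
    return best[0], best[1]


def chain_from_string(
    seq: str,
    start: int = 1,
    chain_id: str = "A",
    icodes: dict[int, str] | None = None,
) -> ChainSequence:
    """Build a chain numbered consecutively from ``start``.

    ``icodes`` maps 0-based indices to insertion-code letters.
    """
    icodes = icodes or {}
    chain = ChainSequence(chain_id)
    for k, aa in enumerate(seq):
        chain.residues.append(
            ResidueRecord(
                chain_id=chain_id,
                order_index=k,
                res_seq=start + k,
                icode=icodes.get(k, ""),
                res_name=three_letter_code(aa),
                one_letter=aa,
            )
        )
    return chain


def reference_from_string(seq: str, accession: str = "TESTREF") -> ReferenceSequence:
    return ReferenceSequence(accession=accession, sequence=seq)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260926)
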