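"""Synthetic reference/structure pairs with known ground truth.

Emulates the discrepancy classes seen between modelled structures and
their UniProt entries — terminal truncations, internal deletions,
insertions, point substitutions, numbering offsets and insertion codes —
starting from a random reference sequence.  Because the perturbation is
known, the exact residue table the checker should produce is known by
construction, which makes the generator an oracle for the whole
pipeline.

Ground-truth uniqueness.  Under the default scoring (match 1, mismatch
0, gap 0) co-optimal alignments are plentiful: a gap can realign
whenever a flanking residue recurs inside the deleted block, and a
substituted or inserted residue whose letter recurs before the end of a
downstream deletion can trade its mismatch for a match at equal score,
relocating the stretch in between.  :func:`validate_plan` therefore
rejects, besides overlapping or insufficiently separated edits: a
deletion/truncation containing its left-flank residue; an insertion
whose text contains the residue at its anchor position; and a
substitution or insertion whose letters recur between its own position
and the end of the furthest downstream deletion block.  Plans passing
these checks produce a construction the checker recovers exactly, which
is what makes the generator an oracle.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .alignment import Label, MappingRow
from .reference_io import ReferenceSequence
from .structure_io import ChainSequence, ResidueRecord, three_letter_code

__all__ = [
    "AA20",
    "EditPlan",
    "validate_plan",
    "make_reference",
    "apply_edits",
    "emit_pdb",
    "number_consecutively",
    "random_edit_plan",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class EditPlan:
    """Perturbation of a reference sequence into a structure chain.

    Positions are 1-based reference coordinates.  ``internal_deletions``
    holds (start, length) blocks; ``substitutions`` (position, new amino
    acid); ``insertions`` (after-position, inserted string) with
    1 <= after-position <= L-1; ``numbering_offset`` is added to every
    emitted residue number; ``icode_positions`` receive insertion code
    'A' (identifier change only).
    """

    n_term_trunc: int = 0
    c_term_trunc: int = 0
    internal_deletions: tuple[tuple[int, int], ...] = ()
    substitutions: tuple[tuple[int, str], ...] = ()
    insertions: tuple[tuple[int, str], ...] = ()
    numbering_offset: int = 0
    icode_positions: tuple[int, ...] = ()
    seed: int = 0


def _intervals(plan: EditPlan, length: int) -> list[tuple[int, int, str]]:
    """Edit intervals in reference coordinates as (start, end, kind)."""
    iv: list[tuple[int, int, str]] = []
    if plan.n_term_trunc:
        iv.append((1, plan.n_term_trunc, "n_term"))
    if plan.c_term_trunc:
        iv.append((length - plan.c_term_trunc + 1, length, "c_term"))
    for start, dlen in plan.internal_deletions:
        iv.append((start, start + dlen - 1, "deletion"))
    for pos, _ in plan.substitutions:
        iv.append((pos, pos, "substitution"))
    for pos, _ in plan.insertions:
        iv.append((pos, pos + 1, "insertion"))
    return sorted(iv)


def validate_plan(plan: EditPlan, ref: ReferenceSequence) -> None:
    """Raise ``ValueError`` if the plan is invalid or has ambiguous ground truth."""
    seq = ref.sequence
    L = len(seq)

    def r(i: int) -> str:  # 1-based accessor
        return seq[i - 1]

    if plan.n_term_trunc < 0 or plan.c_term_trunc < 0:
        raise ValueError("negative truncation length")
    for start, dlen in plan.internal_deletions:
        if dlen < 1 or start < 1 or start + dlen - 1 > L:
            raise ValueError(f"deletion ({start}, {dlen}) outside the sequence")
    for pos, aa in plan.substitutions:
        if not 1 <= pos <= L:
            raise ValueError(f"substitution position {pos} outside the sequence")
        if aa not in AA20:
            raise ValueError(f"substitution to non-standard amino acid {aa!r}")
        if aa == r(pos):
            raise ValueError(f"substitution at {pos} does not change the residue")
    for pos, txt in plan.insertions:
        if not 1 <= pos <= L - 1:
            raise ValueError(f"insertion after position {pos} must be internal")
        if not txt or any(ch not in AA20 for ch in txt):
            raise ValueError(f"invalid insertion text {txt!r}")
        if len(txt) > 26:
            raise ValueError("insertion longer than 26 residues")

    iv = _intervals(plan, L)
    for (s1, e1, k1), (s2, e2, k2) in zip(iv, iv[1:]):
        if s2 - e1 - 1 < 2:
            raise ValueError(
                f"edits {k1}@{s1}-{e1} and {k2}@{s2}-{e2} overlap or are "
                "separated by fewer than 2 unedited positions"
            )

    # anti-slide anchoring (see module docstring).  The canonical traceback
    # pairs a residue with the highest co-optimal reference position, so a
    # deleted block containing its left-flank residue, or inserted text
    # containing the residue at its anchor position, would realign.
    def check_deletion(s: int, e: int, kind: str) -> None:
        if s > 1 and r(s - 1) in seq[s - 1 : e]:
            raise ValueError(
                f"{kind} {s}-{e} contains its left-flank residue "
                f"{r(s - 1)!r} (ambiguous alignment)"
            )

    if plan.c_term_trunc:
        check_deletion(L - plan.c_term_trunc + 1, L, "c-terminal truncation")
    for start, dlen in plan.internal_deletions:
        check_deletion(start, start + dlen - 1, "deletion")
    for pos, txt in plan.insertions:
        if r(pos) in txt:
            raise ValueError(
                f"insertion after {pos} contains the anchor residue "
                f"{r(pos)!r} (ambiguous alignment)"
            )

    # a substituted or inserted residue recurring anywhere between its own
    # position and the end of a downstream deletion block lets the aligner
    # trade the mismatch/insertion for a match at equal score, relocating
    # the whole stretch in between into the block
    block_ends = [e for s, e, kind in iv if kind in ("deletion", "c_term")]

    def reach(pos: int) -> int:
        downstream = [e for e in block_ends if e > pos]
        return max(downstream) if downstream else pos

    for q, b in plan.substitutions:
        zone = seq[q : reach(q)]
        if b in zone:
            raise ValueError(
                f"substituted residue {b!r}@{q} recurs before the end of a "
                "downstream deletion (ambiguous alignment)"
            )
    for p, txt in plan.insertions:
        zone = seq[p : reach(p)]
        if set(txt) & set(zone):
            raise ValueError(
                f"insertion after {p} shares residues with the region up to "
                "a downstream deletion (ambiguous alignment)"
            )

    deleted = _deleted_positions(plan, L)
    insertion_anchors = {pos for pos, _ in plan.insertions}
    for pos in plan.icode_positions:
        if not 1 <= pos <= L:
            raise ValueError(f"icode position {pos} outside the sequence")
        if pos in deleted:
            raise ValueError(f"icode position {pos} is deleted")
        if pos in insertion_anchors:
            raise ValueError(
                f"icode position {pos} collides with an insertion anchor"
            )


def _deleted_positions(plan: EditPlan, length: int) -> set[int]:
    deleted = set(range(1, plan.n_term_trunc + 1))
    deleted |= set(range(length - plan.c_term_trunc + 1, length + 1))
    for start, dlen in plan.internal_deletions:
        deleted |= set(range(start, start + dlen))
    return deleted


def make_reference(length: int, seed: int) -> ReferenceSequence:
    """Uniform random amino-acid sequence; deterministic in (length, seed)."""
    if length < 1:
        raise ValueError(f"reference length must be >= 1, got {length}")
    rng = random.Random(seed)
    seq = "".join(rng.choice(AA20) for _ in range(length))
    return ReferenceSequence(accession=f"SYN{seed % 100000:05d}", sequence=seq)


def apply_edits(
    ref: ReferenceSequence, plan: EditPlan, chain_id: str = "A"
) -> tuple[ChainSequence, list[MappingRow]]:
    """Apply the plan and return the chain plus its ground-truth residue table.

    Residue numbers are ``position + numbering_offset``; inserted
    residues take the number of their anchor position with insertion
    codes A, B, ...; icode positions keep their number and gain code 'A'.
    """
    validate_plan(plan, ref)
    L = len(ref.sequence)
    deleted = _deleted_positions(plan, L)
    subs = dict(plan.substitutions)
    insertions = dict(plan.insertions)
    icodes = set(plan.icode_positions)
    offset = plan.numbering_offset

    chain = ChainSequence(chain_id)
    rows: list[MappingRow] = []

    def add_residue(aa: str, res_seq: int, icode: str) -> ResidueRecord:
        rec = ResidueRecord(
            chain_id=chain_id,
            order_index=len(chain.residues),
            res_seq=res_seq,
            icode=icode,
            res_name=three_letter_code(aa),
            one_letter=aa,
        )
        chain.residues.append(rec)
        return rec

    aln_id = 0
    for pos in range(1, L + 1):
        ref_aa = ref.sequence[pos - 1]
        if pos in deleted:
            aln_id += 1
            rows.append(
                MappingRow(aln_id, ref_aa, pos, None, None, Label.MISSING, False)
            )
        else:
            aa = subs.get(pos, ref_aa)
            icode = "A" if pos in icodes else ""
            rec = add_residue(aa, pos + offset, icode)
            id_ok = icode == "" and rec.res_seq == pos
            aln_id += 1
            rows.append(
                MappingRow(
                    aln_id, ref_aa, pos, aa, rec.structure_id,
                    Label.ID_MATCH if id_ok else Label.ID_MISMATCH,
                    aa != ref_aa,
                )
            )
        if pos in insertions and pos not in deleted:
            for k, ins_aa in enumerate(insertions[pos]):
                rec = add_residue(ins_aa, pos + offset, chr(ord("A") + k))
                aln_id += 1
                rows.append(
                    MappingRow(aln_id, None, None, ins_aa, rec.structure_id,
                               Label.INSERTION, False)
                )
    return chain, rows


def number_consecutively(chain: ChainSequence, start: int = 1) -> ChainSequence:
    """Re-key a chain with consecutive residue numbers and no insertion codes.

    This mimics model files (e.g. predicted structures) that are always
    numbered 1..N regardless of the reference coordinates.
    """
    renumbered = ChainSequence(chain.chain_id)
    for k, rec in enumerate(chain.residues):
        renumbered.residues.append(
            replace(rec, order_index=k, res_seq=start + k, icode="")
        )
    return renumbered


def emit_pdb(chain: ChainSequence, title: str | None = None) -> str:
    """Minimal valid CA-only PDB text for the chain.

    One CA ATOM line per residue with correct fixed-column formatting
    (residue number in columns 23-26, insertion code in 27) and
    placeholder coordinates; reading the output back recovers the chain
    exactly.
    """
    if not chain.residues:
        raise ValueError("cannot emit an empty chain")
    lines: list[str] = []
    if title:
        lines.append(f"TITLE     {title}")
    serial = 0
    for rec in chain.residues:
        if not -999 <= rec.res_seq <= 9999:
            raise ValueError(
                f"residue number {rec.res_seq} outside PDB range -999..9999"
            )
        serial += 1
        i = rec.order_index
        x = 3.8 * (i % 200)
        y = 5.0 * (i // 200)
        z = 0.0
        lines.append(
            f"ATOM  {serial:5d}  CA  {rec.res_name:>3} {chain.chain_id}"
            f"{rec.res_seq:4d}{rec.icode or ' '}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{'C':>2}"
        )
    last = chain.residues[-1]
    serial += 1
    lines.append(
        f"TER   {serial:5d}      {last.res_name:>3} {chain.chain_id}"
        f"{last.res_seq:4d}{last.icode or ' '}"
    )
    lines.append("END")
    return "\n".join(lines) + "\n"


def worked_example_twin(
    seed: int = 0,
) -> tuple[ReferenceSequence, EditPlan, ChainSequence]:
    """Synthetic twin of an outdated-model scenario.

    A 478-residue reference is perturbed by deleting 96 consecutive
    residues ending before position 107 and substituting two residues
    near the N-terminus; the resulting 382-residue chain is numbered
    consecutively from 1, the way model files are.  Reference position
    107 then carries structure number 11 (107 - 96), the alignment has
    one 96-column missing run and two variations.

    The reference draw is retried deterministically until the deletion
    satisfies the unambiguity constraints of :func:`validate_plan`.
    Returns (reference, plan, chain).
    """
    for attempt in range(100000):
        sub_seed = (seed * 100003 + attempt) % (2**31)
        ref = make_reference(478, sub_seed)
        rng = random.Random(sub_seed + 1)
        # substitution letters must not recur before the end of the deleted
        # block, otherwise the alignment is ambiguous (see validate_plan)
        subs = []
        for pos in (1, 4):
            zone = set(ref.sequence[pos:102])
            options = [a for a in AA20
                       if a not in zone and a != ref.sequence[pos - 1]]
            if options:
                subs.append((pos, rng.choice(options)))
        if len(subs) != 2:
            continue
        plan = EditPlan(
            internal_deletions=((7, 96),),
            substitutions=tuple(subs),
            seed=sub_seed,
        )
        try:
            validate_plan(plan, ref)
        except ValueError:
            continue
        chain, _ = apply_edits(ref, plan)
        return ref, plan, number_consecutively(chain, start=1)
    raise RuntimeError("could not build an unambiguous worked-example twin")


def random_edit_plan(
    ref: ReferenceSequence,
    seed: int,
    max_attempts: int = 1000,
) -> EditPlan:
    """Draw a random valid edit plan for ``ref``; deterministic in the seed.

    Proposals mixing truncations, deletions, substitutions, insertions,
    a numbering offset and insertion codes are rejection-sampled until
    :func:`validate_plan` accepts one.
    """
    rng = random.Random(seed)
    L = len(ref.sequence)
    for _ in range(max_attempts):
        plan = _propose_plan(rng, L)
        try:
            validate_plan(plan, ref)
        except ValueError:
            continue
        return plan
    raise RuntimeError(
        f"no valid edit plan found for seed {seed} in {max_attempts} attempts"
    )


def _propose_plan(rng: random.Random, L: int) -> EditPlan:
    n_term = rng.choice([0, 0, 0, rng.randint(1, max(1, L // 10))])
    c_term = rng.choice([0, 0, 0, rng.randint(1, max(1, L // 10))])
    deletions = []
    for _ in range(rng.randint(0, 2)):
        dlen = rng.randint(1, max(1, L // 8))
        start = rng.randint(2, max(2, L - dlen))
        deletions.append((start, dlen))
    substitutions = []
    for _ in range(rng.randint(0, 3)):
        pos = rng.randint(1, L)
        substitutions.append((pos, rng.choice(AA20)))
    insertions = []
    for _ in range(rng.randint(0, 2)):
        pos = rng.randint(1, max(1, L - 1))
        txt = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 4)))
        insertions.append((pos, txt))
    offset = rng.choice([0, 0, 1, -1, 10, 96, rng.randint(-50, 50)])
    icode_positions = tuple(
        rng.randint(1, L) for _ in range(rng.randint(0, 2))
    )
    return EditPlan(
        n_term_trunc=n_term,
        c_term_trunc=c_term,
        internal_deletions=tuple(sorted(deletions)),
        substitutions=tuple(sorted(substitutions)),
        insertions=tuple(sorted(insertions)),
        numbering_offset=offset,
        icode_positions=tuple(sorted(set(icode_positions))),
        seed=0,
    )
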