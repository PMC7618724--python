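"""Renumbering plans and serialisation of results (TSV, JSON, FASTA).

The renumbering plan assigns each aligned structure residue its UniProt
position.  Inserted residues have no UniProt counterpart and are dropped
from the renumbered structure so the mapping stays one-to-one; the plan
records a warning whenever that removes residues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .alignment import (
    Label,
    MappingRow,
    SummaryStats,
    AlignmentColumn,
    assess_identifiers,
    assess_sequence,
)

__all__ = [
    "RenumberPlan",
    "build_renumber_plan",
    "parse_structure_id",
    "rows_to_tsv",
    "tsv_to_rows",
    "rows_to_json",
    "alignment_to_fasta",
    "TSV_HEADER",
]

TSV_COLUMNS = (
    "Alignment ID",
    "UniProt residue AA",
    "UniProt residue ID",
    "Structure residue AA",
    "Structure residue ID",
    "label",
)
TSV_HEADER = "\t".join(TSV_COLUMNS)


@dataclass(frozen=True)
class RenumberPlan:
    """Mapping from author residue keys to UniProt numbers.

    ``assignments`` maps (res_seq, icode) to the new residue number;
    ``dropped`` lists the structure identifiers of inserted residues
    that will be removed.
    """

    assignments: dict[tuple[int, str], int]
    dropped: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    def as_renumber_map(self) -> dict[tuple[int, str], int | None]:
        """Combined map consumed by :func:`structure_io.write_renumbered_pdb`."""
        full: dict[tuple[int, str], int | None] = dict(self.assignments)
        for sid in self.dropped:
            full[parse_structure_id(sid)] = None
        return full


def parse_structure_id(structure_id: str) -> tuple[int, str]:
    """Invert the ``res_seq + icode`` rendering, e.g. ``"100A" -> (100, "A")``."""
    if structure_id and structure_id[-1].isalpha():
        return int(structure_id[:-1]), structure_id[-1]
    return int(structure_id), ""


def build_renumber_plan(rows: list[MappingRow]) -> RenumberPlan:
    """Derive the renumbering plan from the classified residue table."""
    assignments: dict[tuple[int, str], int] = {}
    dropped: list[str] = []
    seen: set[tuple[int, str]] = set()
    for row in rows:
        if row.label is Label.MISSING:
            continue
        key = parse_structure_id(row.structure_id)
        if key in seen:
            raise ValueError(
                f"structure residue {row.structure_id} appears in more than one "
                "row; inconsistent residue table"
            )
        seen.add(key)
        if row.label is Label.INSERTION:
            dropped.append(row.structure_id)
        else:
            assignments[key] = row.uniprot_id
    warnings: list[str] = []
    if dropped:
        warnings.append(
            f"renumbering removes {len(dropped)} inserted residue(s) with no "
            f"UniProt counterpart: {', '.join(dropped[:10])}"
            + (", ..." if len(dropped) > 10 else "")
        )
    return RenumberPlan(
        assignments=assignments, dropped=tuple(dropped), warnings=tuple(warnings)
    )


def _cell(value) -> str:
    return "" if value is None else str(value)


def rows_to_tsv(rows: list[MappingRow]) -> str:
    """Serialise the residue table; blank cells for absent sides."""
    lines = [TSV_HEADER]
    for r in rows:
        lines.append(
            "\t".join(
                (
                    str(r.alignment_id),
                    _cell(r.uniprot_aa),
                    _cell(r.uniprot_id),
                    _cell(r.structure_aa),
                    _cell(r.structure_id),
                    r.label.value,
                )
            )
        )
    return "\n".join(lines) + "\n"


def tsv_to_rows(text: str) -> list[MappingRow]:
    """Parse :func:`rows_to_tsv` output back into rows (round-trip safe)."""
    lines = text.splitlines()
    if not lines or lines[0] != TSV_HEADER:
        raise ValueError("unrecognised TSV header")
    rows: list[MappingRow] = []
    for line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != 6:
            raise ValueError(f"expected 6 TSV fields, got {len(fields)}: {line!r}")
        aln_id, u_aa, u_id, s_aa, s_id, label = fields
        label = Label(label)
        u_aa = u_aa or None
        s_aa = s_aa or None
        variation = (
            u_aa is not None
            and s_aa is not None
            and not (u_aa == s_aa and u_aa != "X")
        )
        rows.append(
            MappingRow(
                alignment_id=int(aln_id),
                uniprot_aa=u_aa,
                uniprot_id=int(u_id) if u_id else None,
                structure_aa=s_aa,
                structure_id=s_id or None,
                label=label,
                variation=variation,
            )
        )
    return rows


def rows_to_json(rows: list[MappingRow], stats: SummaryStats) -> str:
    """Single JSON document: summary object plus the residues array.

    Percentages carry 2 decimal places and counts are integers so the
    output is byte-stable across runs.
    """
    summary = {
        "aln_length": stats.aln_length,
        "identity_pct": round(stats.identity_pct, 2),
        "identity_aligned_pct": round(stats.identity_aligned_pct, 2),
        "n_identical": stats.n_identical,
        "n_gap_runs": stats.n_gap_runs,
        "n_gap_columns": stats.n_gap_columns,
        "n_variations": stats.n_variations,
        "n_struct_residues": stats.n_struct_residues,
        "n_id_match": stats.n_id_match,
        "n_id_mismatch": stats.n_id_mismatch,
        "n_missing": stats.n_missing,
        "n_insertions": stats.n_insertions,
        "sequence_assessment": stats.sequence_assessment.value,
        "sequence_message": assess_sequence(stats),
        "id_assessment": stats.id_assessment.value,
        "id_message": assess_identifiers(stats),
    }
    residues = [
        {
            "alignment_id": r.alignment_id,
            "uniprot_aa": r.uniprot_aa,
            "uniprot_id": r.uniprot_id,
            "structure_aa": r.structure_aa,
            "structure_id": r.structure_id,
            "label": r.label.value,
            "variation": r.variation,
        }
        for r in rows
    ]
    return json.dumps({"summary": summary, "residues": residues}, indent=2) + "\n"


def alignment_to_fasta(
    columns: list[AlignmentColumn],
    ref_id: str,
    query_id: str,
    width: int = 60,
) -> str:
    """Two-record FASTA of the alignment, reference first, '-' for gaps."""
    if not columns:
        raise ValueError("alignment has no columns")
    ref_aln = "".join(c.ref_aa for c in columns)
    query_aln = "".join(c.query_aa for c in columns)
    out: list[str] = []
    for header, seq in ((ref_id, ref_aln), (query_id, query_aln)):
        out.append(f">{header}")
        for i in range(0, len(seq), width):
            out.append(seq[i : i + width])
    return "\n".join(out) + "\n"
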