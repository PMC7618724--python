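"""End-to-end orchestration: align, classify, summarise, plan, write outputs."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .alignment import (
    DEFAULT_SCORING,
    AlignmentColumn,
    MappingRow,
    ScoringScheme,
    SummaryStats,
    assess_identifiers,
    assess_sequence,
    classify,
    global_align,
    summarize,
)
from .reference_io import ReferenceSequence
from .report import (
    RenumberPlan,
    alignment_to_fasta,
    build_renumber_plan,
    rows_to_json,
    rows_to_tsv,
)
from .structure_io import (
    ChainSequence,
    StructureModel,
    extract_chain_sequence,
    write_renumbered_pdb,
)

__all__ = ["CheckResult", "check", "write_outputs", "summary_table"]


@dataclass
class CheckResult:
    """Everything the check produces for one reference/chain pair."""

    reference: ReferenceSequence
    chain: ChainSequence
    columns: list[AlignmentColumn]
    rows: list[MappingRow]
    stats: SummaryStats
    plan: RenumberPlan

    @property
    def sequence_message(self) -> str:
        return assess_sequence(self.stats)

    @property
    def id_message(self) -> str:
        return assess_identifiers(self.stats)


def check(
    reference: ReferenceSequence,
    model: StructureModel,
    chain_id: str = "A",
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> CheckResult:
    """Run the full consistency check of one chain against the reference."""
    chain = extract_chain_sequence(model, chain_id)
    columns = global_align(reference, chain, scoring)
    rows = classify(columns, chain)
    stats = summarize(rows)
    plan = build_renumber_plan(rows)
    return CheckResult(
        reference=reference,
        chain=chain,
        columns=columns,
        rows=rows,
        stats=stats,
        plan=plan,
    )


def summary_table(result: CheckResult) -> str:
    """Human-readable summary printed by the CLI."""
    s = result.stats
    lines = [
        f"Reference:              {result.reference.accession} "
        f"({len(result.reference)} aa)",
        f"Structure chain:        {result.chain.chain_id} "
        f"({s.n_struct_residues} residues)",
        f"Alignment length:       {s.aln_length}",
        f"Sequence identity:      {s.identity_pct:.2f}% of columns "
        f"({s.identity_aligned_pct:.2f}% of aligned pairs)",
        f"Gaps:                   {s.n_gap_runs} run(s), {s.n_gap_columns} column(s)",
        f"Variations:             {s.n_variations}",
        f"Residue IDs matching:   {s.n_id_match}",
        f"Residue IDs mismatched: {s.n_id_mismatch}",
        f"Missing from structure: {s.n_missing}",
        f"Insertions in structure:{s.n_insertions:>2}",
        "",
        result.sequence_message,
        result.id_message,
    ]
    return "\n".join(lines)


def write_outputs(
    result: CheckResult,
    model: StructureModel,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write mapping.tsv, mapping.json, alignment.fasta and renumbered.pdb."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tsv": out / "mapping.tsv",
        "json": out / "mapping.json",
        "fasta": out / "alignment.fasta",
        "pdb": out / "renumbered.pdb",
    }
    paths["tsv"].write_text(rows_to_tsv(result.rows))
    paths["json"].write_text(rows_to_json(result.rows, result.stats))
    paths["fasta"].write_text(
        alignment_to_fasta(
            result.columns,
            ref_id=result.reference.accession,
            query_id=f"{model.source_label}|chain_{result.chain.chain_id}",
        )
    )
    paths["pdb"].write_text(
        write_renumbered_pdb(
            model,
            result.chain.chain_id,
            result.plan.as_renumber_map(),
            reference_label=result.reference.accession,
        )
    )
    return paths
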