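"""Read and write protein structures in fixed-column PDB format.

The sequence of a structure is defined by the residues appearing in its
``ATOM`` records: one residue per distinct (chain, residue number,
insertion code) triple, in file order.  The author residue number lives
in columns 23-26 of each ATOM line and the insertion code in column 27;
these columns carry no guaranteed relationship to UniProt numbering,
which is why they need checking.  Renumbering is performed as byte-level
line surgery so that everything outside those columns survives
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1

__all__ = [
    "ResidueRecord",
    "ChainSequence",
    "StructureModel",
    "StructureParseError",
    "ChainNotFoundError",
    "DROP",
    "read_pdb",
    "extract_chain_sequence",
    "write_renumbered_pdb",
]

#: Sentinel mapping value: residue is omitted from the renumbered output.
DROP = None

# standard 20 amino acids, three-letter (upper) -> one-letter
AA_3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}
AA_1TO3 = {k: v.upper() for k, v in protein_letters_1to3.items()}
STANDARD_AA = frozenset(AA_3TO1.values())

# common modified residues mapped to their parent standard amino acid;
# applied only when reading with include_modified=True
MODIFIED_AA = {
    "MSE": "M",  # selenomethionine
    "SEP": "S",  # phosphoserine
    "TPO": "T",  # phosphothreonine
    "PTR": "Y",  # phosphotyrosine
    "CSO": "C",  # S-hydroxycysteine
    "KCX": "K",  # N-epsilon-carboxylysine
    "MLY": "K",  # N-dimethyllysine
    "HYP": "P",  # hydroxyproline
}

# residue names that are never part of the polypeptide even when they
# appear in ATOM records (waters, nucleotides, frequent ions/ligands)
NON_AA_RESNAMES = frozenset(
    {
        "HOH", "WAT", "DOD",
        "DA", "DC", "DG", "DT", "DU", "A", "C", "G", "U", "I",
        "NA", "CL", "MG", "ZN", "CA2", "K", "MN", "FE", "CU",
        "SO4", "PO4", "GOL", "EDO", "ACT", "HEM", "NAG", "MAN",
    }
)


class StructureParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


class ChainNotFoundError(KeyError):
    """Raised when the requested chain is absent from the model."""

    def __init__(self, chain_id: str, available: list[str]):
        self.chain_id = chain_id
        self.available = available
        super().__init__(
            f"chain {chain_id!r} not found; available chains: {available}"
        )


@dataclass(frozen=True)
class ResidueRecord:
    """One residue observed in the ATOM records of a chain."""

    chain_id: str
    order_index: int  # 0-based position in file order within the chain
    res_seq: int  # author residue number, PDB columns 23-26
    icode: str  # insertion code, '' when blank
    res_name: str  # three-letter residue name
    one_letter: str  # standard one-letter code, 'X' for unknown names

    @property
    def structure_id(self) -> str:
        """Author identifier as rendered in reports, e.g. ``100`` or ``100A``."""
        return f"{self.res_seq}{self.icode}"


@dataclass
class ChainSequence:
    """Ordered residues of one chain with the derived amino-acid sequence."""

    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureModel:
    """A parsed structure: per-chain sequences plus the original lines."""

    source_label: str
    chains: dict[str, ChainSequence]
    raw_lines: list[str]
    model_number: int = 1
    warnings: list[str] = field(default_factory=list)


def one_letter_code(res_name: str, include_modified: bool = False) -> str:
    """Map a three-letter residue name to a one-letter code ('X' if unknown)."""
    name = res_name.strip().upper()
    if name in AA_3TO1:
        return AA_3TO1[name]
    if include_modified and name in MODIFIED_AA:
        return MODIFIED_AA[name]
    return "X"


def three_letter_code(one_letter: str) -> str:
    return AA_1TO3.get(one_letter.upper(), "UNK")


def _first_model_lines(lines: list[str]):
    """Yield (1-based line number, line) restricted to the first MODEL.

    Files without MODEL records are treated as a single model.
    """
    has_model = any(l.startswith("MODEL") for l in lines)
    in_model = not has_model
    seen_model = False
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("MODEL"):
            if seen_model:
                break
            seen_model = True
            in_model = True
            continue
        if line.startswith("ENDMDL"):
            if seen_model:
                break
            continue
        if in_model:
            yield lineno, line


def _parse_atom_line(lineno: int, line: str):
    """Split one ATOM line into (altloc, res_name, chain_id, res_seq, icode)."""
    # pad so that slicing short lines is safe
    padded = line.ljust(80)
    altloc = padded[16]
    res_name = padded[17:20].strip()
    chain_id = padded[21]
    res_seq_text = padded[22:26]
    try:
        res_seq = int(res_seq_text)
    except ValueError:
        raise StructureParseError(
            f"line {lineno}: malformed residue number in columns 23-26: "
            f"{res_seq_text!r}"
        ) from None
    icode = padded[26].strip()
    return altloc, res_name, chain_id, res_seq, icode


def read_pdb(
    text: str,
    source_label: str = "<string>",
    include_modified: bool = False,
) -> StructureModel:
    """Parse PDB text into per-chain sequences with author numbering.

    Only ``ATOM`` records of the first MODEL contribute; HETATM, waters
    and non-amino-acid residue names are excluded.  A residue is one
    distinct (chain, res_seq, icode) triple; additional atoms and
    alternate locations of the same triple are collapsed onto the first
    record seen.  Unknown residue names yield ``'X'``.
    """
    if not text.strip():
        raise StructureParseError("empty structure: no content")
    lines = text.splitlines()
    chains: dict[str, ChainSequence] = {}
    seen: dict[str, set[tuple[int, str]]] = {}
    last_key: dict[str, tuple[int, str]] = {}
    warnings: list[str] = []

    for lineno, line in _first_model_lines(lines):
        if not line.startswith("ATOM"):
            continue
        altloc, res_name, chain_id, res_seq, icode = _parse_atom_line(lineno, line)
        if res_name.upper() in NON_AA_RESNAMES:
            continue
        key = (res_seq, icode)
        chain = chains.setdefault(chain_id, ChainSequence(chain_id))
        keys = seen.setdefault(chain_id, set())
        if key in keys:
            # either more atoms / altlocs of the current residue, or a
            # true non-contiguous duplicate (keep first, warn)
            if last_key.get(chain_id) != key:
                warnings.append(
                    f"line {lineno}: duplicate residue {res_seq}{icode} in "
                    f"chain {chain_id}; keeping first occurrence"
                )
            continue
        keys.add(key)
        last_key[chain_id] = key
        chain.residues.append(
            ResidueRecord(
                chain_id=chain_id,
                order_index=len(chain.residues),
                res_seq=res_seq,
                icode=icode,
                res_name=res_name.upper(),
                one_letter=one_letter_code(res_name, include_modified),
            )
        )

    if not chains:
        raise StructureParseError(
            "empty structure: no ATOM records with amino-acid residues found"
        )
    return StructureModel(
        source_label=source_label,
        chains=chains,
        raw_lines=lines,
        model_number=1,
        warnings=warnings,
    )


def extract_chain_sequence(model: StructureModel, chain_id: str) -> ChainSequence:
    """Return the named chain, or raise listing the chains that exist."""
    try:
        return model.chains[chain_id]
    except KeyError:
        raise ChainNotFoundError(chain_id, sorted(model.chains)) from None


def write_renumbered_pdb(
    model: StructureModel,
    chain_id: str,
    renumber_map: dict[tuple[int, str], int | None],
    reference_label: str = "",
) -> str:
    """Rewrite the selected chain with new residue numbers.

    ``renumber_map`` maps each (res_seq, icode) of the chain to its new
    residue number, or to :data:`DROP` (``None``) to omit the residue.
    Retained ATOM lines are byte-identical to the input outside columns
    23-27: the number is replaced right-justified in 23-26 and the
    insertion code blanked.  Records of other chains are omitted.
    """
    chain = extract_chain_sequence(model, chain_id)
    missing = [r.structure_id for r in chain.residues
               if (r.res_seq, r.icode) not in renumber_map]
    if missing:
        raise ValueError(
            f"renumber map lacks entries for residues: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    for key, new in renumber_map.items():
        if new is not DROP and not (-999 <= new <= 9999):
            raise ValueError(
                f"new residue number {new} for {key} outside PDB range -999..9999"
            )

    out: list[str] = []
    label = f" {reference_label}" if reference_label else ""
    out.append(f"REMARK 999 RENUMBERED BY STRUCTCHECK TO UNIPROT NUMBERING{label}")
    allowed = {(r.res_seq, r.icode) for r in chain.residues}
    last_atom = None
    for lineno, line in _first_model_lines(model.raw_lines):
        if not line.startswith("ATOM"):
            continue
        padded = line.ljust(80).rstrip("\n")
        if padded[21] != chain_id:
            continue
        try:
            res_seq = int(padded[22:26])
        except ValueError:
            continue
        icode = padded[26].strip()
        key = (res_seq, icode)
        if key not in allowed:
            continue  # non-amino-acid ATOM line of this chain
        new = renumber_map[key]
        if new is DROP:
            continue
        base = line if len(line) >= 27 else line.ljust(27)
        newline = base[:22] + f"{new:4d}" + " " + base[27:]
        out.append(newline)
        last_atom = newline
    if last_atom is None:
        raise ValueError(f"no residues of chain {chain_id} retained after renumbering")
    out.append("TER")
    out.append("END")
    return "\n".join(out) + "\n"
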