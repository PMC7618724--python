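"""Reference sequences: local FASTA, the UniProt REST endpoint, input limits.

The reference sequence defines the coordinate system of the check: the
i-th residue of the UniProt entry has identifier i (1-based).  All core
computation consumes a :class:`ReferenceSequence` value, so the network
fetch is an isolated adapter and the rest of the package runs offline.
"""

from __future__ import annotations

import io
import json
import re
import time
import urllib.error
import urllib.request
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "ReferenceSequence",
    "ReferenceError",
    "NetworkError",
    "LimitWarning",
    "read_fasta",
    "write_fasta",
    "fetch_uniprot",
    "validate_limits",
    "MAX_CUSTOM_FILE_BYTES",
    "MAX_DATABASE_RESIDUES",
]

# Input limits enforced before any computation
MAX_CUSTOM_FILE_BYTES = 5 * 1024 * 1024  # custom PDB uploads: 5 MB
MAX_DATABASE_RESIDUES = 2700  # database-sourced entries beyond this are split

UNIPROT_FASTA_URL = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"

# UniProtKB accession grammar, with an optional isoform suffix
ACCESSION_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})"
    r"(?:-\d+)?$"
)

ALLOWED_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XUOBZJ")


class ReferenceError(ValueError):
    """Raised for unusable reference input (bad FASTA, bad accession)."""


class NetworkError(RuntimeError):
    """Raised when the UniProt endpoint cannot be reached or has no entry."""


@dataclass(frozen=True)
class ReferenceSequence:
    """A UniProt(-style) reference; residue i carries identifier i."""

    accession: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ReferenceError("reference sequence is empty")
        bad = set(self.sequence) - ALLOWED_ALPHABET
        if bad:
            raise ReferenceError(
                f"reference sequence contains invalid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LimitWarning:
    """A blocking input-limit violation."""

    message: str
    blocking: bool = True

    def __str__(self) -> str:
        return self.message


def _accession_from_header(header_id: str) -> str:
    # UniProt style "sp|P12345|NAME" or "tr|...|..."; otherwise bare token
    if "|" in header_id:
        parts = header_id.split("|")
        if len(parts) >= 2 and parts[1]:
            return parts[1]
    return header_id


def read_fasta(text: str, accession: str | None = None) -> ReferenceSequence:
    """Parse FASTA text into a reference sequence.

    With multiple records, ``accession`` selects the matching one; with a
    single record it is optional.  Sequences are uppercased and
    whitespace inside them ignored.
    """
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise ReferenceError("no FASTA records found")
    if accession is not None:
        chosen = [r for r in records if _accession_from_header(r.id) == accession]
        if not chosen:
            raise ReferenceError(
                f"no FASTA record with accession {accession!r}; headers: "
                f"{[r.id for r in records]}"
            )
        record = chosen[0]
        acc = accession
    elif len(records) == 1:
        record = records[0]
        acc = _accession_from_header(record.id)
    else:
        raise ReferenceError(
            f"{len(records)} FASTA records present; pass an accession to select one"
        )
    seq = "".join(str(record.seq).split()).upper()
    return ReferenceSequence(accession=acc, sequence=seq)


def write_fasta(ref: ReferenceSequence, width: int = 60) -> str:
    lines = [f">{ref.accession}"]
    for i in range(0, len(ref.sequence), width):
        lines.append(ref.sequence[i : i + width])
    return "\n".join(lines) + "\n"


def _cache_path(cache_dir: Path) -> Path:
    return Path(cache_dir) / "uniprot_cache.json"


def _load_cache(cache_dir: Path) -> dict:
    path = _cache_path(cache_dir)
    if path.is_file():
        return json.loads(path.read_text())
    return {}


def fetch_uniprot(
    accession: str,
    cache_dir: str | Path | None = None,
    offline: bool = False,
    timeout: float = 15.0,
) -> ReferenceSequence:
    """Fetch the current sequence for a UniProt accession.

    Retrieved sequences are cached as JSON under ``cache_dir`` so that
    repeated runs are reproducible; with ``offline=True`` only the cache
    is consulted and no network call is made.  Isoform accessions such
    as ``P12345-2`` are passed through verbatim.
    """
    if not ACCESSION_RE.match(accession):
        raise ReferenceError(f"not a valid UniProt accession: {accession!r}")

    cache: dict = {}
    if cache_dir is not None:
        cache = _load_cache(Path(cache_dir))
        if accession in cache:
            return ReferenceSequence(accession, cache[accession]["sequence"])
    if offline:
        raise NetworkError(
            f"offline mode and no cached sequence for {accession}"
        )

    url = UNIPROT_FASTA_URL.format(acc=accession)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode("utf-8")
    except urllib.error.HTTPError as exc:
        raise NetworkError(
            f"UniProt returned HTTP {exc.code} for {accession}: accession not "
            "found or obsolete"
        ) from exc
    except (urllib.error.URLError, OSError) as exc:
        raise NetworkError(f"could not reach UniProt for {accession}: {exc}") from exc
    if not text.strip():
        raise NetworkError(
            f"UniProt returned an empty document for {accession} (redundant or "
            "deleted entry?)"
        )
    ref = read_fasta(text, accession=accession)

    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        cache[accession] = {
            "sequence": ref.sequence,
            "retrieved": time.strftime("%Y-%m-%d"),
        }
        _cache_path(cache_dir).write_text(json.dumps(cache, indent=2, sort_keys=True))
    return ref


def validate_limits(
    structure_bytes: int,
    ref_length: int,
    source: str,
    max_bytes: int = MAX_CUSTOM_FILE_BYTES,
    max_database_residues: int = MAX_DATABASE_RESIDUES,
) -> list[LimitWarning]:
    """Check the input-size limits; returns blocking warnings (empty if OK).

    ``source`` is ``"custom"`` for uploaded files (byte limit applies) or
    ``"database"`` for database-sourced entries (residue limit applies —
    longer entries are split across files upstream and unsupported).
    """
    if source not in ("custom", "database"):
        raise ValueError(f"source must be 'custom' or 'database', got {source!r}")
    warnings: list[LimitWarning] = []
    if source == "custom" and structure_bytes > max_bytes:
        warnings.append(
            LimitWarning(
                "Custom PDB files are restricted to a maximum size of "
                f"{max_bytes / (1024 * 1024):g} MB; this file is "
                f"{structure_bytes / (1024 * 1024):.1f} MB."
            )
        )
    if source == "database" and ref_length > max_database_residues:
        warnings.append(
            LimitWarning(
                f"Database entries containing more than {max_database_residues:,} "
                f"amino acids are not supported; this entry has {ref_length} "
                "residues."
            )
        )
    return warnings
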