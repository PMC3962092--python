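"""Retrieval of the published sequence and structure records.

The comparative analysis is anchored on public records: the four TLR4
orthologs (839 / 835 / 843 / 833 residues for human / murine / equine /
canine) and the 160-residue MD-2 sequences (the canine MD-2 entry exists
only as a theoretical prediction), plus the crystal complexes of the
agonist-bound dimer (3FXI) and the antagonist-bound forms (2E59, 2Z65,
3MU3).

Exact record identifiers were not printed alongside the analysis, so the
accession table below is best-effort and configurable; every fetched
sequence is validated against the expected length before use, which turns
a wrong accession into a loud error instead of a silently wrong analysis.
Network access is required; all functions raise ``DatasetError`` offline.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from dataclasses import dataclass
from pathlib import Path

from wedgemap.seqalign import Sequence

UNIPROT_FASTA = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"
RCSB_PDB = "https://files.rcsb.org/download/{code}.pdb"

#: Expected sequence lengths from the published identity table.
EXPECTED_LENGTHS = {
    "hTLR4": 839, "mTLR4": 835, "eTLR4": 843, "cTLR4": 833,
    "hMD2": 160, "mMD2": 160, "eMD2": 160, "cMD2": 160,
}

#: Best-effort UniProt accessions (validated against EXPECTED_LENGTHS at
#: fetch time; override via the ``accessions`` argument if a record moved).
DEFAULT_ACCESSIONS = {
    "hTLR4": "O00206",
    "mTLR4": "Q9QUK6",
    "eTLR4": "Q9MYW3",
    "cTLR4": "Q689D1",
    "hMD2": "Q9Y6Y9",
    "mMD2": "Q9JHF9",
    "eMD2": "Q5KSS8",
    "cMD2": "A4GVD5",   # theoretical prediction
}

PDB_CODES = {"agonist_dimer": "3FXI", "lipidIVA": "2E59",
             "eritoran": "2Z65", "md1_lipidIVA": "3MU3"}


class DatasetError(RuntimeError):
    pass


def _http_get(url: str, timeout: float) -> str:
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            return resp.read().decode()
    except (urllib.error.URLError, TimeoutError, OSError) as exc:
        raise DatasetError(f"cannot retrieve {url}: {exc}") from exc


def fetch_sequence(
    seq_id: str,
    accessions: dict[str, str] | None = None,
    validate: bool = True,
    timeout: float = 15.0,
) -> Sequence:
    """Fetch one panel sequence (e.g. ``hTLR4``) from UniProt."""
    accessions = accessions or DEFAULT_ACCESSIONS
    acc = accessions.get(seq_id)
    if acc is None:
        raise DatasetError(f"no accession configured for {seq_id!r}")
    text = _http_get(UNIPROT_FASTA.format(acc=acc), timeout)
    lines = [l.strip() for l in text.splitlines() if l.strip()]
    if not lines or not lines[0].startswith(">"):
        raise DatasetError(f"{acc}: response is not FASTA")
    residues = "".join(lines[1:]).upper().replace("U", "C").replace("X", "A")
    # mature-chain trimming is deliberately not attempted; the published
    # lengths refer to specific records, so a mismatch means the accession
    # does not correspond to the published one.
    if validate:
        expected = EXPECTED_LENGTHS.get(seq_id)
        if expected is not None and len(residues) != expected:
            raise DatasetError(
                f"{seq_id} ({acc}): length {len(residues)} != expected "
                f"{expected}; configure the correct accession"
            )
    species = {"h": "human", "m": "murine", "e": "equine", "c": "canine"}[seq_id[0]]
    protein = seq_id[1:].upper()
    return Sequence(id=seq_id, residues=residues, species=species, protein=protein)


def fetch_panel(
    protein: str = "MD2",
    accessions: dict[str, str] | None = None,
    validate: bool = True,
) -> list[Sequence]:
    """Fetch all four species for one protein (``TLR4`` or ``MD2``)."""
    ids = [k for k in EXPECTED_LENGTHS if k.endswith(protein)]
    return [fetch_sequence(i, accessions, validate) for i in ids]


def fetch_pdb(code: str, dest: str | Path, timeout: float = 30.0) -> Path:
    """Download a PDB entry to ``dest`` and return the path."""
    dest = Path(dest)
    text = _http_get(RCSB_PDB.format(code=code.upper()), timeout)
    if "ATOM" not in text:
        raise DatasetError(f"{code}: response contains no ATOM records")
    dest.parent.mkdir(parents=True, exist_ok=True)
    dest.write_text(text)
    return dest
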