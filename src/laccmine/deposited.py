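"""Access to the ten deposited laccase CDSs (GenBank MF176136-MF176145).

These coding sequences are the published reference set for this family
(Lcc1-Lcc8 plus the isoforms Lcc3B and Lcc5B). They are not redistributed
with the package; ``scripts/fetch_deposited.py`` downloads them once from
NCBI into ``data/deposited_laccase_cds.fasta``, after which the
accession-based checks in the test suite run against the real records.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from .errors import InputError

#: laccase name -> GenBank nucleotide accession
ACCESSIONS = {
    "Lcc1": "MF176136",
    "Lcc2": "MF176137",
    "Lcc3": "MF176138",
    "Lcc3B": "MF176139",
    "Lcc4": "MF176140",
    "Lcc5": "MF176141",
    "Lcc5B": "MF176142",
    "Lcc6": "MF176143",
    "Lcc7": "MF176144",
    "Lcc8": "MF176145",
}

DEFAULT_PATH = Path(__file__).resolve().parents[2] / "data" / "deposited_laccase_cds.fasta"


def load_deposited_cds(path=None) -> dict[str, str]:
    """Load the deposited CDS set as {laccase name: nucleotide CDS}.

    Raises InputError when the FASTA has not been fetched; run
    ``python scripts/fetch_deposited.py`` (requires network) to create it.
    """
    p = Path(path) if path is not None else DEFAULT_PATH
    if not p.exists():
        raise InputError(
            f"deposited CDS file not found at {p}; run scripts/fetch_deposited.py "
            "once (network required) to download GenBank MF176136-MF176145"
        )
    by_acc = {acc: name for name, acc in ACCESSIONS.items()}
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(p), "fasta"):
        acc = rec.id.split()[0].split(".")[0]
        if acc in by_acc:
            out[by_acc[acc]] = str(rec.seq).upper()
        elif rec.id in ACCESSIONS:
            out[rec.id] = str(rec.seq).upper()
    missing = sorted(set(ACCESSIONS) - set(out))
    if missing:
        raise InputError(f"deposited CDS file {p} is missing records for {missing}")
    return out
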