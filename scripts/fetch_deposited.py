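#!/usr/bin/env python
"""One-time download of the ten deposited laccase CDSs from GenBank.

Fetches the coding sequences of accessions MF176136-MF176145 via NCBI
efetch and writes them to data/deposited_laccase_cds.fasta, enabling the
accession-based checks in the test suite. Requires network access; run
once from the repository root:

    python scripts/fetch_deposited.py
"""

from __future__ import annotations

import sys
import urllib.parse
import urllib.request
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from laccmine.deposited import ACCESSIONS, DEFAULT_PATH  # noqa: E402

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch(accessions: list[str]) -> str:
    params = urllib.parse.urlencode({
        "db": "nuccore",
        "id": ",".join(accessions),
        "rettype": "fasta_cds_na",
        "retmode": "text",
    })
    with urllib.request.urlopen(f"{EFETCH}?{params}", timeout=60) as resp:
        return resp.read().decode()


def main() -> int:
    accs = sorted(ACCESSIONS.values())
    try:
        text = fetch(accs)
    except OSError as exc:
        print(f"download failed ({exc}); network access to NCBI is required", file=sys.stderr)
        return 1
    # fasta_cds_na headers look like lcl|MF176136.1_cds_...; normalize to accession
    lines = []
    for line in text.splitlines():
        if line.startswith(">"):
            for acc in accs:
                if acc in line:
                    line = f">{acc}"
                    break
        lines.append(line)
    DEFAULT_PATH.parent.mkdir(parents=True, exist_ok=True)
    DEFAULT_PATH.write_text("\n".join(lines) + "\n")
    print(f"wrote {DEFAULT_PATH}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
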