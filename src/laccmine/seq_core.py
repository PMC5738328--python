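"""Transcript I/O and open-reading-frame discovery.

Front end of the laccase-mining pipeline: FASTA reading/writing with
Trinity-style ``compX_cY_seqZ`` identifier parsing, longest-isoform
(unigene) selection, six-frame ORF finding and standard-code translation.

Coordinates are 0-based half-open internally; report writers print
1-based inclusive positions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError, ValidationError

log = logging.getLogger(__name__)

#: IUPAC nucleotide codes accepted on input. Ambiguity codes other than N
#: are tolerated but translate as X (conservative).
IUPAC_NT = frozenset("ACGTNRYSWKMBDHV")

_TRINITY_RE = re.compile(r"^(comp\d+_c\d+)_(seq\d+)$")

_STANDARD_TABLE = unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
_CODON_TO_AA.update({c: "*" for c in _STANDARD_TABLE.stop_codons})
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)


@dataclass(frozen=True)
class Transcript:
    """An assembled contig, optionally carrying Trinity component/isoform identity."""

    id: str
    seq: str
    component: Optional[str] = None
    isoform: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValidationError(f"transcript {self.id!r}: empty sequence")
        if (self.component is None) != (self.isoform is None):
            raise ValidationError(
                f"transcript {self.id!r}: component and isoform must both be set or both absent"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class OrfRecord:
    """A candidate coding region on a transcript.

    ``start``/``end`` are 0-based half-open offsets on the forward strand of
    the transcript regardless of ``strand``; ``nt_seq`` is the coding-strand
    sequence (reverse-complemented for minus-strand ORFs) and includes the
    terminal stop codon when present; ``aa_seq`` excludes the stop.
    """

    transcript_id: str
    strand: str
    frame: int
    start: int
    end: int
    has_start_codon: bool
    has_stop_codon: bool
    nt_seq: str
    aa_seq: str

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValidationError("ORF span not divisible by 3")
        if "*" in self.aa_seq:
            raise ValidationError("aa_seq contains a stop symbol")
        if self.has_stop_codon and len(self.nt_seq) != 3 * (len(self.aa_seq) + 1):
            raise ValidationError("complete ORF violates nt = 3*(aa+1)")

    @property
    def aa_len(self) -> int:
        return len(self.aa_seq)

    @property
    def nt_len(self) -> int:
        return len(self.nt_seq)


def normalize_nt(seq: str, name: str = "?") -> str:
    """Uppercase, map U->T, and validate against IUPAC nucleotide codes."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - IUPAC_NT
    if bad:
        raise ValidationError(
            f"record {name!r}: non-nucleotide characters {sorted(bad)!r}"
        )
    return s


def make_transcript(header: str, seq: str) -> Transcript:
    """Build a Transcript from a FASTA header token and raw sequence."""
    ident = header.split()[0]
    m = _TRINITY_RE.match(ident)
    comp, iso = (m.group(1), m.group(2)) if m else (None, None)
    return Transcript(id=ident, seq=normalize_nt(seq, ident), component=comp, isoform=iso)


def read_fasta(path) -> list[Transcript]:
    """Read a FASTA file into an ordered list of Transcripts.

    Sequences are uppercased with U mapped to T; Trinity identifiers are
    parsed into component/isoform. An empty file yields an empty list with
    a logged warning.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"FASTA file not found: {p}")
    try:
        records = list(SeqIO.parse(str(p), "fasta"))
    except OSError as exc:  # pragma: no cover - OS-dependent
        raise InputError(f"cannot read {p}: {exc}") from exc
    if not records:
        log.warning("FASTA file %s contains no records", p)
        return []
    return [make_transcript(r.description, str(r.seq)) for r in records]


def write_fasta(records: Iterable[tuple[str, str]], path, wrap: int = 60) -> None:
    """Write (name, sequence) pairs as FASTA, wrapped at ``wrap`` columns."""
    seq_records = [SeqRecord(Seq(s), id=n, description="") for n, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seq_records)


def select_unigenes(transcripts: Sequence[Transcript]) -> list[Transcript]:
    """Keep the longest isoform per Trinity component (unigene selection).

    Ties go to the lexicographically smallest isoform id. Transcripts with
    no parsed component pass through unchanged. Idempotent.
    """
    best: dict[str, Transcript] = {}
    for t in transcripts:
        if t.component is None:
            continue
        cur = best.get(t.component)
        if (
            cur is None
            or len(t) > len(cur)
            or (len(t) == len(cur) and t.isoform < cur.isoform)
        ):
            best[t.component] = t
    kept = {id(t) for t in best.values()}
    return [t for t in transcripts if t.component is None or id(t) in kept]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(nt: str) -> str:
    """Standard-code translation; codons containing any non-ACGT base -> X."""
    if len(nt) % 3 != 0:
        raise ValidationError(f"length {len(nt)} not divisible by 3")
    out = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        out.append(_CODON_TO_AA[codon] if set(codon) <= set("ACGT") else "X")
    return "".join(out)


def find_orfs(
    t: Transcript, min_aa: int = 100, allow_partial_start: bool = False
) -> list[OrfRecord]:
    """All maximal ORFs of >= ``min_aa`` codons over six frames.

    An ORF runs from an ATG (the first one after the preceding in-frame
    stop) to the first in-frame stop (complete) or to the end of the
    transcript (3'-partial). With ``allow_partial_start`` a frame may also
    open at its first codon without an ATG (5'-partial ORFs).
    """
    if min_aa < 1:
        raise ValidationError("min_aa must be >= 1")
    n = len(t.seq)
    orfs: list[OrfRecord] = []
    for strand, s in (("+", t.seq), ("-", revcomp(t.seq))):
        for frame in range(3):
            start: Optional[int] = None
            has_atg = False
            if allow_partial_start and frame + 3 <= n:
                start, has_atg = frame, s[frame : frame + 3] == "ATG"
            i = frame
            while i + 3 <= n:
                codon = s[i : i + 3]
                if start is None:
                    if codon == "ATG":
                        start, has_atg = i, True
                elif codon in STOP_CODONS:
                    _emit(orfs, t, strand, frame, s, start, i + 3, has_atg, True, min_aa, n)
                    start = None
                i += 3
            if start is not None:
                end = frame + 3 * ((n - frame) // 3)
                if end > start:
                    _emit(orfs, t, strand, frame, s, start, end, has_atg, False, min_aa, n)
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def _emit(out, t, strand, frame, s, start, end, has_atg, has_stop, min_aa, n):
    nt_seq = s[start:end]
    coding = nt_seq[:-3] if has_stop else nt_seq
    aa = translate(coding)
    if "*" in aa or len(aa) < min_aa:
        return
    if strand == "+":
        fstart, fend = start, end
    else:
        fstart, fend = n - end, n - start
    out.append(
        OrfRecord(
            transcript_id=t.id,
            strand=strand,
            frame=frame,
            start=fstart,
            end=fend,
            has_start_codon=has_atg,
            has_stop_codon=has_stop,
            nt_seq=nt_seq,
            aa_seq=aa,
        )
    )


def longest_orf(
    t: Transcript, min_aa: int = 100, allow_partial_start: bool = False
) -> Optional[OrfRecord]:
    """The ORF maximizing peptide length.

    Ties break complete-before-partial, then smallest forward-strand start,
    then strand + before -.
    """
    orfs = find_orfs(t, min_aa=min_aa, allow_partial_start=allow_partial_start)
    if not orfs:
        return None
    return min(
        orfs,
        key=lambda o: (-o.aa_len, 0 if o.has_stop_codon else 1, o.start, 0 if o.strand == "+" else 1),
    )


def orfs_to_bed(orfs: Iterable[OrfRecord]) -> str:
    """ORF catalogue as transcript-relative BED (0-based half-open)."""
    lines = []
    for i, o in enumerate(orfs):
        name = f"{o.transcript_id}.orf{i + 1}"
        lines.append(
            "\t".join(
                [o.transcript_id, str(o.start), str(o.end), name, str(o.aa_len), o.strand]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
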