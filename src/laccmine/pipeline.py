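"""Pipeline orchestration: mine -> characterize -> compare -> tree.

``mine_transcripts`` turns an assembled transcriptome into a catalogue of
true laccases (with physicochemical characterization, glycosylation sites,
secretion heuristic and axial class) plus per-candidate status calls;
``compare_records`` builds the similarity matrix and the bootstrapped
neighbor-joining family tree. File-level wrappers emit plain TSV/CSV/
Newick/FASTA only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO

from . import __version__
from .comparative import (
    bootstrap_support,
    progressive_msa,
    similarity_matrix,
    write_newick,
)
from .errors import ConfigError, InputError, ValidationError
from .physchem import (
    GlycoSite,
    find_sequons,
    gc_content,
    isoelectric_point,
    molecular_weight,
    predict_signal_peptide,
)
from .seq_core import (
    Transcript,
    find_orfs,
    read_fasta,
    select_unigenes,
    write_fasta,
)
from .signature import (
    DEFAULT_SIGNATURES,
    CandidateStatus,
    SignatureSet,
    axial_class,
    classify_candidate,
    extract_ligand_map,
    scan_regions,
    signature_from_text,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LaccaseRecord:
    """One row of the laccase catalogue."""

    name: str
    transcript_id: str
    length_bp: int  # CDS including the stop codon
    length_aa: int
    mol_weight_kda: float
    gc_percent: float
    cleavage_site: Optional[tuple[int, int]]  # adjacent 1-based positions
    theoretical_pi: float
    axial_class: object  # 1 | 2 | 3 | "unclassified"
    axial_residue: str
    secreted: bool
    status: str
    aa_seq: str
    nt_seq: str
    glyco_sites: tuple[GlycoSite, ...] = ()

    def __post_init__(self):
        if self.length_bp != 3 * (self.length_aa + 1):
            raise ValidationError(
                f"{self.name}: CDS length {self.length_bp} != 3*({self.length_aa}+1)"
            )
        if not 0.0 <= self.gc_percent <= 100.0:
            raise ValidationError(f"{self.name}: GC% out of range")
        if not 2.0 < self.theoretical_pi < 13.0:
            raise ValidationError(f"{self.name}: pI out of range")
        if self.secreted != (self.cleavage_site is not None):
            raise ValidationError(f"{self.name}: secreted flag inconsistent with cleavage site")


@dataclass
class RunReport:
    """Per-stage counts and provenance of a pipeline run."""

    n_transcripts: int = 0
    n_after_unigenes: int = 0
    n_with_orfs: int = 0
    n_candidates: int = 0
    n_true_laccases: int = 0
    n_pseudogene_no_stop: int = 0
    n_pseudogene_premature_stop: int = 0
    n_partial_signature: int = 0
    version: str = __version__
    config_hash: str = ""
    wall_clock_s: dict = field(default_factory=dict)

    def validate(self) -> None:
        total = (self.n_true_laccases + self.n_pseudogene_no_stop
                 + self.n_pseudogene_premature_stop + self.n_partial_signature)
        if total > self.n_candidates:
            raise ValidationError("inconsistent stage counts in run report")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline; round-trips through plain text."""

    input: str = ""
    out_dir: str = "laccmine_out"
    min_aa: int = 100
    unigenes: bool = False
    signature_path: str = ""
    min_regions_pseudo: int = 3
    matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5
    distance_model: str = "p"
    bootstrap_reps: int = 1000
    seed: int = 1

    def __post_init__(self):
        if self.min_aa < 1:
            raise ConfigError("min_aa must be >= 1")
        if self.bootstrap_reps < 1:
            raise ConfigError("bootstrap_reps must be >= 1")
        if self.distance_model not in ("p", "poisson"):
            raise ConfigError(f"unknown distance model {self.distance_model!r}")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ConfigError("gap scores must be <= 0")

    def to_text(self) -> str:
        return "\n".join(f"{f.name} = {getattr(self, f.name)}" for f in fields(self)) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        kv = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"malformed config line: {line!r}")
            k, v = (s.strip() for s in line.split("=", 1))
            kv[k] = v
        kwargs = {}
        for f in fields(cls):
            if f.name not in kv:
                continue
            raw = kv.pop(f.name)
            if f.type == "int":
                kwargs[f.name] = int(raw)
            elif f.type == "float":
                kwargs[f.name] = float(raw)
            elif f.type == "bool":
                kwargs[f.name] = raw.lower() in ("1", "true", "yes")
            else:
                kwargs[f.name] = raw
        if kv:
            raise ConfigError(f"unknown config keys: {sorted(kv)}")
        return cls(**kwargs)

    def hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:12]

    def signature_set(self) -> SignatureSet:
        if not self.signature_path:
            return DEFAULT_SIGNATURES
        p = Path(self.signature_path)
        if not p.exists():
            raise ConfigError(f"signature config not found: {p}")
        return signature_from_text(p.read_text())


# ---------------------------------------------------------------------------
# mining

def characterize_orf(name: str, transcript_id: str, orf, sig: SignatureSet) -> LaccaseRecord:
    """Full Table-style characterization of one complete laccase ORF."""
    aa, nt = orf.aa_seq, orf.nt_seq
    hits = scan_regions(aa, sig)
    lig = extract_ligand_map(hits, aa, sig)
    sp = predict_signal_peptide(aa)
    cleavage = (sp.cleavage_after, sp.cleavage_after + 1) if sp.secreted else None
    return LaccaseRecord(
        name=name,
        transcript_id=transcript_id,
        length_bp=len(nt),
        length_aa=len(aa),
        mol_weight_kda=molecular_weight(aa),
        gc_percent=gc_content(nt),
        cleavage_site=cleavage,
        theoretical_pi=isoelectric_point(aa),
        axial_class=axial_class(lig),
        axial_residue=lig.axial_residue,
        secreted=sp.secreted,
        status="true_laccase",
        aa_seq=aa,
        nt_seq=nt,
        glyco_sites=tuple(find_sequons(aa)),
    )


def mine_transcripts(
    transcripts: Sequence[Transcript],
    sig: SignatureSet = DEFAULT_SIGNATURES,
    min_aa: int = 100,
    unigenes: bool = False,
    min_regions_pseudo: int = 3,
) -> tuple[list[LaccaseRecord], dict[str, CandidateStatus], RunReport]:
    """Mine a transcript collection for laccases.

    Returns the catalogue of true laccases (named Lcc1.. in input order),
    the per-candidate status map (every transcript with at least one
    signature region), and the run report.
    """
    t0 = time.perf_counter()
    report = RunReport(n_transcripts=len(transcripts))
    if unigenes:
        transcripts = select_unigenes(transcripts)
    report.n_after_unigenes = len(transcripts)

    records: list[LaccaseRecord] = []
    statuses: dict[str, CandidateStatus] = {}
    for t in transcripts:
        orfs = find_orfs(t, min_aa=min_aa)
        if not orfs:
            continue
        report.n_with_orfs += 1
        status = classify_candidate(orfs, sig, min_regions_pseudo=min_regions_pseudo)
        if not status.regions_found:
            continue
        report.n_candidates += 1
        statuses[t.id] = status
        if status.status == "true_laccase":
            carriers = [
                o for o in orfs
                if o.has_stop_codon and len(scan_regions(o.aa_seq, sig)) == 4
            ]
            best = max(carriers, key=lambda o: o.aa_len)
            records.append(
                characterize_orf(f"Lcc{len(records) + 1}", t.id, best, sig)
            )
            report.n_true_laccases += 1
        elif status.status == "pseudogene_no_stop":
            report.n_pseudogene_no_stop += 1
        elif status.status == "pseudogene_premature_stop":
            report.n_pseudogene_premature_stop += 1
        else:
            report.n_partial_signature += 1
    report.wall_clock_s["mine"] = round(time.perf_counter() - t0, 3)
    report.validate()
    log.info(
        "mine: %d transcripts -> %d with ORFs -> %d candidates -> %d true laccases, "
        "%d pseudogenes, %d partial",
        report.n_transcripts, report.n_with_orfs, report.n_candidates,
        report.n_true_laccases,
        report.n_pseudogene_no_stop + report.n_pseudogene_premature_stop,
        report.n_partial_signature,
    )
    return records, statuses, report


# ---------------------------------------------------------------------------
# table writers

def _fmt_cleavage(site: Optional[tuple[int, int]]) -> str:
    return "No" if site is None else f"{site[0]}-{site[1]}"


TABLE1_COLUMNS = [
    "Sequence", "Laccase", "Length (bp)", "Peptide chain (aa)", "Mol. weight (kDa)",
    "GC content (%)", "Cleavage site", "Theoretical pI", "Axial class", "Status",
]


def write_table1(records: Sequence[LaccaseRecord], path) -> None:
    """Catalogue TSV mirroring the characterization-table layout."""
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE1_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join([
                r.transcript_id, r.name, str(r.length_bp), str(r.length_aa),
                f"{r.mol_weight_kda:.1f}", f"{r.gc_percent:.1f}",
                _fmt_cleavage(r.cleavage_site), f"{r.theoretical_pi:.2f}",
                str(r.axial_class), r.status,
            ]) + "\n")


def write_table2(records: Sequence[LaccaseRecord], path) -> None:
    """Glycosylation-site TSV (1-based Asn positions per laccase)."""
    with open(path, "w") as fh:
        fh.write("Laccase\tN-glycosylation sites\n")
        for r in records:
            sites = " ".join(str(g.position) for g in r.glyco_sites) or "-"
            if not r.secreted:
                sites = "-"
            fh.write(f"{r.name}\t{sites}\n")


def write_status(statuses: dict[str, CandidateStatus], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tstatus\tregions_found\n")
        for tid in sorted(statuses):
            s = statuses[tid]
            fh.write(f"{tid}\t{s.status}\t{','.join(s.regions_found)}\n")


def read_peptides(path) -> list[tuple[str, str]]:
    """Read a protein FASTA as (name, sequence) pairs."""
    p = Path(path)
    if not p.exists():
        raise InputError(f"FASTA file not found: {p}")
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(p), "fasta")]


# ---------------------------------------------------------------------------
# comparison stage

def compare_records(
    named_peptides: Sequence[tuple[str, str]],
    reps: int = 1000,
    seed: int = 1,
    distance_model: str = "p",
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
):
    """Similarity matrix plus (for n >= 3) a bootstrapped NJ tree.

    Returns (similarity DataFrame, tree-or-None, msa-or-None); with fewer
    than three peptides the tree is refused with a logged message.
    """
    align_kw = dict(matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)
    sim = similarity_matrix(named_peptides, **align_kw)
    if len(named_peptides) < 3:
        log.warning("tree refused: need >= 3 sequences, got %d", len(named_peptides))
        return sim, None, None
    msa = progressive_msa(named_peptides, **align_kw)
    tree = bootstrap_support(msa, reps=reps, seed=seed, model=distance_model)
    return sim, tree, msa


def write_similarity(sim, square_path, triangle_path=None) -> None:
    """Square CSV, plus the upper-triangle layout used in print."""
    sim.to_csv(square_path, float_format="%.1f")
    if triangle_path is None:
        return
    names = list(sim.index)
    with open(triangle_path, "w") as fh:
        fh.write("," + ",".join(str(i + 1) for i in range(1, len(names))) + "\n")
        for i, name in enumerate(names[:-1]):
            cells = ["" for _ in range(i)]
            cells += [f"{sim.iloc[i, j]:.1f}" for j in range(i + 1, len(names))]
            fh.write(f"{i + 1}. {name}," + ",".join(cells) + "\n")


def write_msa_fasta(msa: Sequence[tuple[str, str]], path) -> None:
    write_fasta(msa, path)


# ---------------------------------------------------------------------------
# file-level drivers

def run_mine(config: PipelineConfig):
    """File-level mining stage: FASTA in, catalogue + status + report out."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    transcripts = read_fasta(config.input)
    sig = config.signature_set()
    records, statuses, report = mine_transcripts(
        transcripts, sig, min_aa=config.min_aa, unigenes=config.unigenes,
        min_regions_pseudo=config.min_regions_pseudo,
    )
    report.config_hash = config.hash()
    write_table1(records, out / "table1_catalogue.tsv")
    write_table2(records, out / "table2_glycosylation.tsv")
    write_status(statuses, out / "candidate_status.tsv")
    if records:
        write_fasta([(r.name, r.aa_seq) for r in records], out / "laccases_protein.fasta")
        write_fasta([(r.name, r.nt_seq) for r in records], out / "laccases_cds.fasta")
    (out / "run_report.json").write_text(report.to_json() + "\n")
    if not transcripts:
        log.warning("empty input: wrote empty catalogue")
    return records, statuses, report


def run_compare(records_or_peptides, config: PipelineConfig):
    """File-level comparison stage over catalogued peptides."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    named = [
        (r.name, r.aa_seq) if isinstance(r, LaccaseRecord) else tuple(r)
        for r in records_or_peptides
    ]
    t0 = time.perf_counter()
    sim, tree, msa = compare_records(
        named, reps=config.bootstrap_reps, seed=config.seed,
        distance_model=config.distance_model, matrix=config.matrix,
        gap_open=config.gap_open, gap_extend=config.gap_extend,
    )
    write_similarity(sim, out / "table3_similarity.csv", out / "table3_similarity_triangle.csv")
    if tree is not None:
        write_msa_fasta(msa, out / "laccases_msa.fasta")
        write_newick(tree, out / "laccase_family_tree.nwk")
    log.info("compare: %d peptides in %.1fs", len(named), time.perf_counter() - t0)
    return sim, tree


def run_all(config: PipelineConfig):
    """mine + compare + report into ``config.out_dir``."""
    records, statuses, report = run_mine(config)
    sim = tree = None
    if records:
        sim, tree = run_compare(records, config)
    return records, statuses, report, sim, tree
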