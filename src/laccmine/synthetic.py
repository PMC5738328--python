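"""Synthetic transcriptomes with planted laccase families and ground truth.

The generator emulates the structure of a fungal transcriptome assembly
that contains a laccase multigene family: true laccase CDSs carrying the
four conserved regions in order with correct copper-ligand residues and a
chosen T1 axial residue; isoform pairs differing by short in-frame
insertions; pseudogene variants (coding region running off the transcript
end, or split by a premature internal stop); decoy multicopper-oxidase-like
sequences with exactly one copper-ligand residue disrupted (the hardest
negative); and background transcripts from an order-3 Markov model at
~50% GC. Every emitted transcript is described by one manifest row, which
serves as the oracle for pipeline tests.

All randomness flows through explicit ``numpy.random.Generator`` objects
derived from integer seeds; no global state is touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, ValidationError
from .physchem import find_sequons, predict_signal_peptide
from .seq_core import Transcript, find_orfs, revcomp, translate, write_fasta
from .signature import (
    DEFAULT_SIGNATURES,
    REGION_ORDER,
    SignatureSet,
    classify_candidate,
    extract_ligand_map,
    scan_regions,
)

log = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
STOPS = ("TAA", "TAG", "TGA")

# Synonymous codons per amino acid (standard code).
_CODONS: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _c = _b1 + _b2 + _b3
            _aa = translate(_c)
            if _aa != "*":
                _CODONS.setdefault(_aa, []).append(_c)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class PlantedCds:
    """A generated coding sequence plus its ground truth."""

    aa_seq: str
    nt_seq: str  # includes the terminal stop codon
    region_starts: dict  # region -> 0-based aa start
    axial_residue: str
    axial_position: int  # 0-based aa index
    sequon_positions: tuple[int, ...]  # 1-based Asn positions
    signal_cleavage: Optional[int]  # 1-based, cleavage after this residue


@dataclass(frozen=True)
class ManifestRow:
    transcript_id: str
    truth_class: str  # laccase | decoy_mco | pseudogene_no_stop | pseudogene_premature_stop | background
    family: str
    mutation_distance: int
    strand: str
    cds_start: int  # forward-strand, 0-based half-open; -1 for background
    cds_end: int
    axial_residue: str
    sequons: tuple[int, ...]
    signal_cleavage: Optional[int]


@dataclass(frozen=True)
class SyntheticConfig:
    """Default study conditions for the mock transcriptome."""

    family_sizes: tuple[int, ...] = (4, 3, 1)
    n_decoys: int = 5
    n_background: int = 50
    pseudogene_modes: tuple[str, ...] = ("no_stop", "premature_stop")
    length_aa: int = 520
    gc_target: float = 55.5
    sub_prob: float = 0.03
    indel_prob: float = 1.0  # probability that the first derived member is insertion-only
    min_utr: int = 20
    max_utr: int = 120
    minus_strand_prob: float = 0.3

    def to_text(self) -> str:
        out = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            out.append(f"{f.name} = {v}")
        return "\n".join(out) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SyntheticConfig":
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
            if f.name == "pseudogene_modes":
                kwargs[f.name] = tuple(s for s in raw.split(",") if s)
            elif f.name == "family_sizes":
                kwargs[f.name] = tuple(int(s) for s in raw.split(",") if s)
            elif f.type in ("int",):
                kwargs[f.name] = int(raw)
            elif f.type in ("float",):
                kwargs[f.name] = float(raw)
            else:
                kwargs[f.name] = raw
        if kv:
            raise ConfigError(f"unknown config keys: {sorted(kv)}")
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# low-level builders

def _sample_from_class(rng, token: str) -> str:
    return token if len(token) == 1 else str(rng.choice(list(token)))


def _tokenize_pattern(pattern: str) -> list[str]:
    """Pattern -> per-position residue-class tokens ('.' = any, 'HW' = class)."""
    tokens, i = [], 0
    while i < len(pattern):
        c = pattern[i]
        if c == "[":
            j = pattern.index("]", i)
            tokens.append(pattern[i + 1 : j])
            i = j + 1
        elif c == ".":
            tokens.append(AA20)
            i += 1
        else:
            tokens.append(c)
            i += 1
    return tokens


def _instantiate_core(rng, region: str, sig: SignatureSet) -> str:
    spec = sig.regions[region]
    tokens = _tokenize_pattern(spec.pattern)
    core = [_sample_from_class(rng, t) for t in tokens]
    for off, cls in spec.ligands:
        core[off] = cls
    return "".join(core)


def backtranslate(rng, aa_seq: str, gc_target: float, explore: float = 0.1) -> str:
    """Back-translate with codon choice greedily steering GC toward ``gc_target``."""
    rng = _rng(rng)
    gc = total = 0
    out = []
    for aa in aa_seq:
        codons = _CODONS[aa]
        if rng.random() < explore:
            codon = codons[int(rng.integers(len(codons)))]
        else:
            target = gc_target / 100.0
            errs = [
                abs((gc + c.count("G") + c.count("C")) / (total + 3) - target)
                for c in codons
            ]
            lo = min(errs)
            best = [c for c, e in zip(codons, errs) if e <= lo + 1e-12]
            codon = best[int(rng.integers(len(best)))]
        out.append(codon)
        gc += codon.count("G") + codon.count("C")
        total += 3
    return "".join(out)


def _choose_stop(rng, nt: str, gc_target: float) -> str:
    target = gc_target / 100.0
    gc = nt.count("G") + nt.count("C")
    errs = [abs((gc + s.count("G")) / (len(nt) + 3) - target) for s in STOPS]
    return STOPS[int(np.argmin(errs))]


def _signal_prefix(rng) -> str:
    run = int(rng.integers(8, 13))
    return "MKK" + "L" * run + "ASA"


def _plant_sequons(rng, aa: list, blocked: set, n_sequons: int, start_from: int) -> list[int]:
    """Plant N-X-[S/T] triplets outside blocked positions; 1-based Asn positions."""
    candidates = [
        p
        for p in range(start_from, len(aa) - 3)
        if not ({p, p + 1, p + 2} & blocked)
    ]
    rng.shuffle(candidates)
    chosen: list[int] = []
    for p in candidates:
        if len(chosen) >= n_sequons:
            break
        if all(abs(p - q) >= 4 for q in chosen):
            chosen.append(p)
    for p in chosen:
        aa[p] = "N"
        x = AA20[int(rng.integers(len(AA20)))]
        while x == "P":
            x = AA20[int(rng.integers(len(AA20)))]
        aa[p + 1] = x
        aa[p + 2] = "ST"[int(rng.integers(2))]
    return sorted(p + 1 for p in chosen)


def _verify_planted(planted: "PlantedCds", sig: SignatureSet, want_signal: bool) -> bool:
    """The generated CDS must scan and predict exactly as planted."""
    hits = scan_regions(planted.aa_seq, sig)
    if len(hits) != 4:
        return False
    for h in hits:
        if h.start != planted.region_starts[h.region]:
            return False
    lig = extract_ligand_map(hits, planted.aa_seq, sig)
    if lig.axial_position != planted.axial_position:
        return False
    sp = predict_signal_peptide(planted.aa_seq)
    if want_signal:
        if sp.cleavage_after != planted.signal_cleavage:
            return False
    elif sp.secreted:
        return False
    return True


def generate_laccase_cds(
    rng_seed,
    length_aa: int = 520,
    axial: str = "L",
    sig: SignatureSet = DEFAULT_SIGNATURES,
    gc_target: float = 55.5,
    signal: bool = True,
    n_sequons: int = 4,
    max_tries: int = 60,
) -> PlantedCds:
    """A random laccase CDS with the four regions planted in order.

    The peptide starts with M (or a planted signal peptide), carries the
    L1-L4 cores at randomized spacings with correct ligand residues, the
    requested axial residue downstream of the L4 cysteine, and planted
    sequons; it is back-translated to hit ``gc_target`` GC% with a single
    terminal stop and no internal stops.
    """
    if axial not in "MLF":
        raise ConfigError(f"axial residue must be M, L or F, got {axial!r}")
    if length_aa < 300:
        raise ConfigError("length_aa must be >= 300")
    rng = _rng(rng_seed)
    core_lens = {r: len(_tokenize_pattern(sig.regions[r].pattern)) for r in REGION_ORDER}
    axial_rel = sig.cys_offset_in_l4() + sig.axial_offset  # from L4 start
    for _ in range(max_tries):
        prefix = _signal_prefix(rng) if signal else "M"
        cores = {r: _instantiate_core(rng, r, sig) for r in REGION_ORDER}
        tail_extra = axial_rel - core_lens["L4"] + 6
        gap_min = (10, 30, 40, 30)
        avail = length_aa - len(prefix) - sum(core_lens.values()) - tail_extra - sum(gap_min)
        if avail < 0:
            raise ConfigError(
                f"length_aa={length_aa} too short for motif spacing (need {-avail} more)"
            )
        extra = rng.multinomial(avail, [0.15, 0.2, 0.35, 0.3])
        gaps = [m + int(e) for m, e in zip(gap_min, extra)]

        aa: list[str] = list(prefix)
        region_starts: dict[str, int] = {}
        for r, g in zip(REGION_ORDER, gaps):
            aa.extend(AA20[i] for i in rng.integers(len(AA20), size=g))
            region_starts[r] = len(aa)
            aa.extend(cores[r])
        while len(aa) < length_aa:
            aa.append(AA20[int(rng.integers(len(AA20)))])
        axial_pos = region_starts["L4"] + axial_rel
        aa[axial_pos] = axial

        blocked = set(range(len(prefix) + 2))
        for r in REGION_ORDER:
            blocked.update(range(region_starts[r] - 2, region_starts[r] + core_lens[r] + 2))
        blocked.update(range(axial_pos - 2, axial_pos + 3))
        sequons = _plant_sequons(rng, aa, blocked, n_sequons, len(prefix) + 2)

        aa_seq = "".join(aa)
        planted = PlantedCds(
            aa_seq=aa_seq,
            nt_seq="",
            region_starts=region_starts,
            axial_residue=axial,
            axial_position=axial_pos,
            sequon_positions=tuple(sequons),
            signal_cleavage=len(prefix) if signal else None,
        )
        if not _verify_planted(planted, sig, signal):
            continue
        nt = backtranslate(rng, aa_seq, gc_target)
        nt += _choose_stop(rng, nt, gc_target)
        return replace(planted, nt_seq=nt)
    raise ConfigError("could not generate a clean laccase CDS; relax parameters")


def mutate_family(
    ancestor: PlantedCds,
    n_members: int,
    indel_prob: float,
    sub_prob: float,
    rng_seed,
    sig: SignatureSet = DEFAULT_SIGNATURES,
    gc_target: float = 55.5,
    insertion_codons: tuple[int, int] = (3, 15),
    max_tries: int = 40,
) -> list[tuple[PlantedCds, int]]:
    """Derive family members from an ancestor CDS.

    Each member optionally receives one in-frame insertion of 3-15 codons
    (probability ``indel_prob``) and point substitutions at unprotected
    positions (per-site probability ``sub_prob``). Signature cores, the
    axial residue, the initial methionine and the signal-peptide prefix
    are immutable. Returns (member, substitution count) pairs.
    """
    rng = _rng(rng_seed)
    core_lens = {r: len(_tokenize_pattern(sig.regions[r].pattern)) for r in REGION_ORDER}
    prefix_len = ancestor.signal_cleavage or 1
    members: list[tuple[PlantedCds, int]] = []
    for _ in range(n_members):
        for _try in range(max_tries):
            aa = list(ancestor.aa_seq)
            protected = set(range(prefix_len))
            for r in REGION_ORDER:
                protected.update(
                    range(ancestor.region_starts[r], ancestor.region_starts[r] + core_lens[r])
                )
            protected.add(ancestor.axial_position)
            shift_from = None
            if rng.random() < indel_prob:
                ins_len = int(rng.integers(insertion_codons[0], insertion_codons[1] + 1))
                spots = [
                    p
                    for p in range(prefix_len + 2, len(aa) - 2)
                    if p not in protected and (p - 1) not in protected
                ]
                pos = spots[int(rng.integers(len(spots)))]
                ins = [AA20[i] for i in rng.integers(len(AA20), size=ins_len)]
                aa[pos:pos] = ins
                shift_from = pos
            n_subs = 0
            shift = 0 if shift_from is None else len(ins)
            for p in range(len(aa)):
                orig_p = p if shift_from is None or p < shift_from else p - shift
                if shift_from is not None and shift_from <= p < shift_from + shift:
                    continue
                if orig_p in protected:
                    continue
                if rng.random() < sub_prob:
                    cur = aa[p]
                    alt = AA20[int(rng.integers(len(AA20)))]
                    while alt == cur:
                        alt = AA20[int(rng.integers(len(AA20)))]
                    aa[p] = alt
                    n_subs += 1
            aa_seq = "".join(aa)
            hits = scan_regions(aa_seq, sig)
            if len(hits) != 4:
                continue
            lig = extract_ligand_map(hits, aa_seq, sig)
            sp = predict_signal_peptide(aa_seq)
            if ancestor.signal_cleavage is not None:
                if sp.cleavage_after != ancestor.signal_cleavage:
                    continue
            elif sp.secreted:
                continue
            nt = backtranslate(rng, aa_seq, gc_target)
            nt += _choose_stop(rng, nt, gc_target)
            member = PlantedCds(
                aa_seq=aa_seq,
                nt_seq=nt,
                region_starts={h.region: h.start for h in hits},
                axial_residue=lig.axial_residue,
                axial_position=lig.axial_position,
                sequon_positions=tuple(g.position for g in find_sequons(aa_seq)),
                signal_cleavage=ancestor.signal_cleavage,
            )
            members.append((member, n_subs))
            break
        else:
            raise ConfigError("could not derive a clean family member")
    return members


def degrade_to_pseudogene(
    cds: PlantedCds, mode: str, rng_seed, sig: SignatureSet = DEFAULT_SIGNATURES
) -> PlantedCds:
    """Turn a laccase CDS into a pseudogene variant.

    ``no_stop``: drop the terminal stop codon (the transcript built from
    this CDS must end flush with it, so the reading frame runs off the 3'
    end). ``premature_stop``: replace a sense codon between L2 and L3 with
    a stop and make the following codon an ATG so the downstream fragment
    forms its own ORF.
    """
    rng = _rng(rng_seed)
    if mode == "no_stop":
        return replace(cds, nt_seq=cds.nt_seq[:-3])
    if mode == "premature_stop":
        l2_end = cds.region_starts["L2"] + len(_tokenize_pattern(sig.regions["L2"].pattern))
        l3_start = cds.region_starts["L3"]
        if l3_start - l2_end < 12:
            raise ConfigError("L2-L3 gap too small to place an internal stop")
        q = int(rng.integers(l2_end + 5, l3_start - 6))
        nt = list(cds.nt_seq)
        nt[3 * q : 3 * q + 3] = STOPS[int(rng.integers(3))]
        nt[3 * (q + 1) : 3 * (q + 1) + 3] = "ATG"
        aa = list(cds.aa_seq)
        aa[q] = "*"
        aa[q + 1] = "M"
        return replace(cds, nt_seq="".join(nt), aa_seq="".join(aa))
    raise ConfigError(f"unknown pseudogene mode {mode!r}")


# ---------------------------------------------------------------------------
# background model

class MarkovBackground:
    """Order-3 Markov nucleotide model with symmetric (GC ~ 50%) context weights."""

    def __init__(self, rng):
        rng = _rng(rng)
        self.contexts = {}
        bases = "ACGT"
        for i in range(64):
            ctx = bases[i % 4] + bases[(i // 4) % 4] + bases[(i // 16) % 4]
            self.contexts[ctx] = rng.dirichlet([5.0, 5.0, 5.0, 5.0])

    def generate(self, rng, length: int) -> str:
        rng = _rng(rng)
        bases = "ACGT"
        out = [bases[i] for i in rng.integers(4, size=3)]
        for _ in range(length - 3):
            probs = self.contexts["".join(out[-3:])]
            out.append(bases[int(rng.choice(4, p=probs))])
        return "".join(out[:length])


# ---------------------------------------------------------------------------
# full transcriptome

def _build_transcript(
    rng,
    bg: MarkovBackground,
    ident: str,
    cds_nt: str,
    cfg: SyntheticConfig,
    no_utr3: bool = False,
    allow_minus: bool = True,
) -> tuple[Transcript, str, int, int]:
    """Wrap a CDS in UTRs, optionally flipping to the minus strand.

    Returns (transcript, strand, cds_start, cds_end) with forward-strand
    coordinates.
    """
    utr5 = bg.generate(rng, int(rng.integers(cfg.min_utr, cfg.max_utr + 1)))
    utr3 = "" if no_utr3 else bg.generate(rng, int(rng.integers(cfg.min_utr, cfg.max_utr + 1)))
    seq = utr5 + cds_nt + utr3
    start, end = len(utr5), len(utr5) + len(cds_nt)
    strand = "+"
    if allow_minus and rng.random() < cfg.minus_strand_prob:
        seq = revcomp(seq)
        start, end = len(seq) - end, len(seq) - start
        strand = "-"
    return Transcript(id=ident, seq=seq, component=ident.rsplit("_", 1)[0],
                      isoform=ident.rsplit("_", 1)[1]), strand, start, end


def _make_decoy(rng, cfg: SyntheticConfig, sig: SignatureSet, max_tries: int = 40) -> PlantedCds:
    """A laccase-like CDS with exactly one copper-ligand residue disrupted."""
    for _ in range(max_tries):
        cds = generate_laccase_cds(rng, length_aa=cfg.length_aa, axial="L", sig=sig,
                                   gc_target=cfg.gc_target, signal=bool(rng.random() < 0.5))
        region = REGION_ORDER[int(rng.integers(4))]
        spec = sig.regions[region]
        off, _cls = spec.ligands[int(rng.integers(len(spec.ligands)))]
        aa = list(cds.aa_seq)
        aa[cds.region_starts[region] + off] = "Q"
        aa_seq = "".join(aa)
        if len(scan_regions(aa_seq, sig)) != 3:
            continue
        nt = backtranslate(rng, aa_seq, cfg.gc_target)
        nt += _choose_stop(rng, nt, cfg.gc_target)
        return replace(cds, aa_seq=aa_seq, nt_seq=nt)
    raise ConfigError("could not build a decoy")


def generate_transcriptome(
    config: Optional[SyntheticConfig] = None,
    rng_seed: int = 0,
    sig: SignatureSet = DEFAULT_SIGNATURES,
) -> tuple[list[Transcript], list[ManifestRow]]:
    """Mock transcriptome: planted families, pseudogenes, decoys, background.

    Fully reproducible from ``rng_seed``; families and pseudogenes share
    Trinity-style components the way real isoform groups do.
    """
    cfg = config or SyntheticConfig()
    rng = _rng(rng_seed)
    bg = MarkovBackground(rng)
    transcripts: list[Transcript] = []
    manifest: list[ManifestRow] = []

    family_ancestor: Optional[PlantedCds] = None
    comp_no = 1001
    for fi, size in enumerate(cfg.family_sizes):
        axial = "LF"[fi % 2]
        signal = fi != len(cfg.family_sizes) - 1  # last family: intracellular analog
        ancestor = generate_laccase_cds(
            rng, length_aa=cfg.length_aa, axial=axial, sig=sig,
            gc_target=cfg.gc_target, signal=signal,
        )
        if family_ancestor is None:
            family_ancestor = ancestor
        members: list[tuple[PlantedCds, int]] = [(ancestor, 0)]
        if size > 1:
            members += mutate_family(ancestor, 1, cfg.indel_prob, 0.0, rng, sig, cfg.gc_target)
        if size > 2:
            members += mutate_family(ancestor, size - 2, 0.0, cfg.sub_prob, rng, sig, cfg.gc_target)
        comp = f"comp{comp_no}_c0"
        comp_no += 1
        for mi, (m, dist) in enumerate(members):
            ident = f"{comp}_seq{mi + 1}"
            t, strand, s, e = _build_transcript(rng, bg, ident, m.nt_seq, cfg)
            transcripts.append(t)
            manifest.append(ManifestRow(
                transcript_id=ident, truth_class="laccase", family=f"fam{fi + 1}",
                mutation_distance=dist, strand=strand, cds_start=s, cds_end=e,
                axial_residue=m.axial_residue, sequons=m.sequon_positions,
                signal_cleavage=m.signal_cleavage,
            ))

    # pseudogenes as extra isoforms of the first family's component
    assert family_ancestor is not None
    pseudo_comp = f"comp1001_c0"
    next_iso = cfg.family_sizes[0] + 1
    for mode in cfg.pseudogene_modes:
        pg = degrade_to_pseudogene(family_ancestor, mode, rng, sig)
        ident = f"{pseudo_comp}_seq{next_iso}"
        next_iso += 1
        t, strand, s, e = _build_transcript(
            rng, bg, ident, pg.nt_seq, cfg, no_utr3=(mode == "no_stop")
        )
        transcripts.append(t)
        manifest.append(ManifestRow(
            transcript_id=ident, truth_class=f"pseudogene_{mode}", family="fam1",
            mutation_distance=0, strand=strand, cds_start=s, cds_end=e,
            axial_residue=pg.axial_residue, sequons=pg.sequon_positions,
            signal_cleavage=pg.signal_cleavage,
        ))

    for di in range(cfg.n_decoys):
        decoy = _make_decoy(rng, cfg, sig)
        ident = f"comp{comp_no}_c0_seq1"
        comp_no += 1
        t, strand, s, e = _build_transcript(rng, bg, ident, decoy.nt_seq, cfg)
        transcripts.append(t)
        manifest.append(ManifestRow(
            transcript_id=ident, truth_class="decoy_mco", family="",
            mutation_distance=0, strand=strand, cds_start=s, cds_end=e,
            axial_residue="", sequons=(), signal_cleavage=None,
        ))

    for bi in range(cfg.n_background):
        for _ in range(20):
            length = int(rng.integers(300, 2001))
            seq = bg.generate(rng, length)
            probe = Transcript(id="probe", seq=seq)
            status = classify_candidate(find_orfs(probe, min_aa=100), sig)
            if status.status != "true_laccase":
                break
            log.info("re-rolling background transcript %d: accidental laccase", bi)
        ident = f"comp{comp_no}_c0_seq1"
        comp_no += 1
        transcripts.append(Transcript(id=ident, seq=seq,
                                      component=f"comp{comp_no - 1}_c0", isoform="seq1"))
        manifest.append(ManifestRow(
            transcript_id=ident, truth_class="background", family="",
            mutation_distance=0, strand="+", cds_start=-1, cds_end=-1,
            axial_residue="", sequons=(), signal_cleavage=None,
        ))
    return transcripts, manifest


def write_manifest(manifest: Sequence[ManifestRow], path) -> None:
    cols = ["transcript_id", "truth_class", "family", "mutation_distance", "strand",
            "cds_start", "cds_end", "axial_residue", "sequons", "signal_cleavage"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in manifest:
            fh.write("\t".join([
                r.transcript_id, r.truth_class, r.family, str(r.mutation_distance),
                r.strand, str(r.cds_start), str(r.cds_end), r.axial_residue,
                ";".join(str(p) for p in r.sequons),
                "" if r.signal_cleavage is None else str(r.signal_cleavage),
            ]) + "\n")


def read_manifest(path) -> list[ManifestRow]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            d = dict(zip(header, line.rstrip("\n").split("\t")))
            rows.append(ManifestRow(
                transcript_id=d["transcript_id"], truth_class=d["truth_class"],
                family=d["family"], mutation_distance=int(d["mutation_distance"]),
                strand=d["strand"], cds_start=int(d["cds_start"]), cds_end=int(d["cds_end"]),
                axial_residue=d["axial_residue"],
                sequons=tuple(int(x) for x in d["sequons"].split(";") if x),
                signal_cleavage=int(d["signal_cleavage"]) if d["signal_cleavage"] else None,
            ))
    return rows


def write_transcriptome(transcripts: Sequence[Transcript], manifest: Sequence[ManifestRow],
                        fasta_path, manifest_path) -> None:
    write_fasta([(t.id, t.seq) for t in transcripts], fasta_path)
    write_manifest(manifest, manifest_path)


def planted_cds_from_transcript(t: Transcript, row: ManifestRow) -> str:
    """Extract the planted CDS from the emitted transcript (manifest oracle)."""
    if row.cds_start < 0:
        raise ValidationError(f"{t.id} has no planted CDS")
    seg = t.seq[row.cds_start : row.cds_end]
    return seg if row.strand == "+" else revcomp(seg)


def evaluate_against_manifest(
    statuses: dict, manifest: Sequence[ManifestRow]
) -> dict:
    """Per-class precision/recall of predicted statuses against ground truth.

    ``statuses`` maps transcript id -> predicted status string (transcripts
    with no prediction count as negatives).
    """
    mapping = {
        "laccase": "true_laccase",
        "pseudogene_no_stop": "pseudogene_no_stop",
        "pseudogene_premature_stop": "pseudogene_premature_stop",
    }
    out = {}
    for truth_class, predicted_label in mapping.items():
        truth_ids = {r.transcript_id for r in manifest if r.truth_class == truth_class}
        pred_ids = {tid for tid, s in statuses.items() if s == predicted_label}
        tp = len(truth_ids & pred_ids)
        out[predicted_label] = {
            "precision": tp / len(pred_ids) if pred_ids else 1.0,
            "recall": tp / len(truth_ids) if truth_ids else 1.0,
            "n_truth": len(truth_ids),
            "n_predicted": len(pred_ids),
        }
    return out
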