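"""Laccase signature scanning and candidate classification.

True fungal laccases are distinguished from other multicopper oxidases by
four conserved sequence regions, L1-L4, which together carry the copper
ligand architecture: 10 histidines and 1 cysteine (2 His in L1, 2 in L2,
3 in L3, 3 His + 1 Cys in L4) plus the variable axial ligand of the T1
copper, located a fixed offset downstream of the L4 cysteine. The axial
residue defines the classical laccase classes: Met -> class 1,
Leu -> class 2, Phe -> class 3.

The default patterns are conservative cores of the published fungal
laccase signatures, expressed as residue-class regular expressions; they
are configurable and serializable as plain text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import ConfigError, ExtractionError, ValidationError
from .seq_core import OrfRecord

REGION_ORDER = ("L1", "L2", "L3", "L4")


@dataclass(frozen=True)
class RegionSpec:
    """One conserved region: a residue-class pattern plus copper-ligand offsets."""

    pattern: str
    ligands: tuple[tuple[int, str], ...]  # (offset within match, residue class)

    def compiled(self) -> re.Pattern:
        try:
            return re.compile(self.pattern)
        except re.error as exc:
            raise ConfigError(f"malformed region pattern {self.pattern!r}: {exc}") from exc


@dataclass(frozen=True)
class SignatureSet:
    """The four-region laccase signature with the axial-ligand offset.

    ``axial_offset`` is measured from the L4 cysteine to the variable T1
    axial residue (+10 is the canonical spacing in basidiomycete laccases).
    """

    regions: dict = field(default_factory=dict)  # region name -> RegionSpec
    axial_offset: int = 10

    def __post_init__(self):
        missing = [r for r in REGION_ORDER if r not in self.regions]
        if missing:
            raise ConfigError(f"signature set missing regions: {missing}")

    def cys_offset_in_l4(self) -> int:
        for off, cls in self.regions["L4"].ligands:
            if cls == "C":
                return off
        raise ConfigError("L4 ligand spec contains no cysteine")


DEFAULT_SIGNATURES = SignatureSet(
    regions={
        "L1": RegionSpec("H[WF]H[GAS]", ((0, "H"), (2, "H"))),
        "L2": RegionSpec("G[TS].[WF][WYF]H[SCA]H", ((5, "H"), (7, "H"))),
        "L3": RegionSpec("HP.H[LIF]HG", ((0, "H"), (3, "H"), (5, "H"))),
        "L4": RegionSpec("HCH[IVLF]..H", ((0, "H"), (1, "C"), (2, "H"), (6, "H"))),
    },
    axial_offset=10,
)


@dataclass(frozen=True)
class SignatureHit:
    region: str
    start: int  # 0-based half-open aa coordinates on the peptide
    end: int
    matched_text: str
    ligand_positions: tuple[int, ...]  # absolute aa indices of copper ligands

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError("empty signature hit")
        if any(not self.start <= p < self.end for p in self.ligand_positions):
            raise ValidationError("ligand position outside hit span")


@dataclass(frozen=True)
class CopperLigandMap:
    """The 10 His + 1 Cys copper ligands plus the variable axial residue."""

    his_positions: tuple[int, ...]
    cys_position: int
    axial_residue: str
    axial_position: int


@dataclass(frozen=True)
class CandidateStatus:
    status: str  # true_laccase | partial_signature | pseudogene_no_stop | pseudogene_premature_stop
    regions_found: tuple[str, ...]


def _region_matches(aa_seq: str, name: str, spec: RegionSpec, limit: int = 16):
    """All pattern matches whose ligand offsets carry the expected residue class."""
    pat = spec.compiled()
    out = []
    for m in pat.finditer(aa_seq):
        ok = True
        for off, cls in spec.ligands:
            pos = m.start() + off
            if pos >= len(aa_seq) or aa_seq[pos] != cls:
                ok = False
                break
        if ok:
            out.append(m)
            if len(out) >= limit:
                break
    return out


def scan_regions(aa_seq: str, sig: SignatureSet = DEFAULT_SIGNATURES) -> list[SignatureHit]:
    """Locate the L1-L4 regions on a peptide, at most one hit per region.

    Region hits must appear in L1 < L2 < L3 < L4 order and may not overlap.
    Among all order-consistent assignments the one covering the most
    regions is chosen; ties go to the leftmost chain. A region is reported
    only when its pattern matches and every ligand offset carries the
    expected residue.
    """
    if not aa_seq:
        raise ValidationError("empty peptide")
    if "*" in aa_seq:
        raise ValidationError("peptide contains stop symbols")
    candidates = {r: _region_matches(aa_seq, r, sig.regions[r]) for r in REGION_ORDER}

    best_chain: list = []
    best_key: Optional[tuple] = None

    def extend(idx: int, floor: int, chain: list) -> None:
        nonlocal best_chain, best_key
        if idx == len(REGION_ORDER):
            # maximize count, then leftmost starts
            key = (-len([c for c in chain if c is not None]),
                   tuple(m.start() if m else 10 ** 9 for m in chain))
            if best_key is None or key < best_key:
                best_key, best_chain = key, list(chain)
            return
        region = REGION_ORDER[idx]
        for m in candidates[region]:
            if m.start() >= floor:
                chain.append(m)
                extend(idx + 1, m.end(), chain)
                chain.pop()
        chain.append(None)
        extend(idx + 1, floor, chain)
        chain.pop()

    extend(0, 0, [])
    hits = []
    for region, m in zip(REGION_ORDER, best_chain):
        if m is None:
            continue
        spec = sig.regions[region]
        hits.append(
            SignatureHit(
                region=region,
                start=m.start(),
                end=m.end(),
                matched_text=m.group(0),
                ligand_positions=tuple(m.start() + off for off, _ in spec.ligands),
            )
        )
    return hits


def regions_present(aa_seq: str, sig: SignatureSet = DEFAULT_SIGNATURES) -> set[str]:
    """Regions with at least one pattern+ligand match, ignoring L1..L4 order.

    Used when a coding region has been split into fragments (pseudogenes
    with internal stops): each fragment carries only part of the signature,
    so the whole-peptide ordering constraint of :func:`scan_regions` does
    not apply.
    """
    return {
        r for r in REGION_ORDER if _region_matches(aa_seq, r, sig.regions[r], limit=1)
    }


def extract_ligand_map(
    hits: Sequence[SignatureHit], aa_seq: str, sig: SignatureSet = DEFAULT_SIGNATURES
) -> CopperLigandMap:
    """Assemble the copper-ligand map from a full set of L1-L4 hits."""
    by_region = {h.region: h for h in hits}
    missing = [r for r in REGION_ORDER if r not in by_region]
    if missing:
        raise ValidationError(f"cannot build ligand map, regions missing: {missing}")
    his: list[int] = []
    cys: Optional[int] = None
    for region in REGION_ORDER:
        hit = by_region[region]
        for pos, (_, cls) in zip(hit.ligand_positions, sig.regions[region].ligands):
            if cls == "C":
                cys = pos
            else:
                his.append(pos)
    assert cys is not None
    axial_pos = cys + sig.axial_offset
    if axial_pos >= len(aa_seq):
        raise ExtractionError(
            f"axial position {axial_pos + 1} beyond peptide end ({len(aa_seq)} aa): truncated C-terminus?"
        )
    return CopperLigandMap(
        his_positions=tuple(his),
        cys_position=cys,
        axial_residue=aa_seq[axial_pos],
        axial_position=axial_pos,
    )


def axial_class(m: CopperLigandMap):
    """Laccase class from the T1 axial ligand: M->1, L->2, F->3."""
    return {"M": 1, "L": 2, "F": 3}.get(m.axial_residue, "unclassified")


def classify_candidate(
    orfs: Sequence[OrfRecord],
    sig: SignatureSet = DEFAULT_SIGNATURES,
    min_regions_pseudo: int = 3,
) -> CandidateStatus:
    """Classify one transcript's ORF set as laccase / pseudogene / partial.

    - true_laccase: a single complete ORF carries all four regions;
    - pseudogene_no_stop: a 3'-partial ORF carries >= ``min_regions_pseudo``
      regions (a coding region that runs off the transcript end);
    - pseudogene_premature_stop: no single ORF has all four regions but the
      union over >= 2 same-strand ORFs does (an internal stop split the
      signature across frames/segments);
    - partial_signature: anything else with at least one region.
    """
    if not orfs:
        return CandidateStatus(status="partial_signature", regions_found=())
    tids = {o.transcript_id for o in orfs}
    if len(tids) > 1:
        raise ValidationError(f"ORFs from multiple transcripts: {sorted(tids)}")

    per_orf = []
    for o in orfs:
        ordered = tuple(h.region for h in scan_regions(o.aa_seq, sig))
        present = regions_present(o.aa_seq, sig)
        per_orf.append((o, ordered, present))

    all_regions: set[str] = set()
    for _, _, present in per_orf:
        all_regions.update(present)
    found = tuple(r for r in REGION_ORDER if r in all_regions)

    for o, ordered, _ in per_orf:
        if o.has_stop_codon and len(ordered) == 4:
            return CandidateStatus(status="true_laccase", regions_found=found)
    for o, ordered, _ in per_orf:
        if not o.has_stop_codon and len(ordered) >= min_regions_pseudo:
            return CandidateStatus(status="pseudogene_no_stop", regions_found=found)
    for strand in "+-":
        strand_orfs = [(o, p) for o, _, p in per_orf if o.strand == strand and p]
        union: set[str] = set()
        for _, p in strand_orfs:
            union.update(p)
        if len(strand_orfs) >= 2 and len(union) == 4:
            return CandidateStatus(status="pseudogene_premature_stop", regions_found=found)
    return CandidateStatus(status="partial_signature", regions_found=found)


# ---------------------------------------------------------------------------
# plain-text serialization and report helpers

def signature_to_text(sig: SignatureSet) -> str:
    lines = [f"axial_offset = {sig.axial_offset}"]
    for region in REGION_ORDER:
        spec = sig.regions[region]
        lig = ",".join(f"{off}:{cls}" for off, cls in spec.ligands)
        lines.append(f"{region}.pattern = {spec.pattern}")
        lines.append(f"{region}.ligands = {lig}")
    return "\n".join(lines) + "\n"


def signature_from_text(text: str) -> SignatureSet:
    kv = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"malformed signature config line: {line!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        kv[key] = val
    try:
        axial = int(kv.pop("axial_offset", "10"))
    except ValueError as exc:
        raise ConfigError("axial_offset must be an integer") from exc
    regions = {}
    for region in REGION_ORDER:
        try:
            pattern = kv[f"{region}.pattern"]
            lig_txt = kv[f"{region}.ligands"]
        except KeyError as exc:
            raise ConfigError(f"signature config missing key for region {region}") from exc
        ligands = []
        for part in lig_txt.split(","):
            off, cls = part.strip().split(":")
            ligands.append((int(off), cls))
        spec = RegionSpec(pattern, tuple(ligands))
        spec.compiled()  # validate early
        regions[region] = spec
    return SignatureSet(regions=regions, axial_offset=axial)


def hits_to_gff3(name: str, hits: Iterable[SignatureHit]) -> str:
    """Signature hits as GFF3 on protein coordinates (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for h in hits:
        lines.append(
            "\t".join(
                [
                    name, "laccmine", "conserved_region",
                    str(h.start + 1), str(h.end), ".", ".", ".",
                    f"ID={name}.{h.region};Name={h.region};ligands="
                    + ",".join(str(p + 1) for p in h.ligand_positions),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def annotate_regions_text(name: str, aa_seq: str, hits: Sequence[SignatureHit],
                          width: int = 60) -> str:
    """A text report marking region spans (dots) and copper ligands (asterisks)."""
    marks = [" "] * len(aa_seq)
    for h in hits:
        for i in range(h.start, h.end):
            marks[i] = "."
        for p in h.ligand_positions:
            marks[p] = "*"
    out = [f"# {name}: regions " + ",".join(h.region for h in hits)]
    for s in range(0, len(aa_seq), width):
        out.append(f"{s + 1:>6} {aa_seq[s:s + width]}")
        out.append("       " + "".join(marks[s:s + width]).rstrip())
    return "\n".join(out) + "\n"
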