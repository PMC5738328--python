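"""L1-L4 scanning, copper-ligand mapping, axial classes, candidate calls."""

import pytest

from laccmine.errors import ConfigError, ExtractionError, ValidationError
from laccmine.seq_core import Transcript, find_orfs
from laccmine.signature import (
    DEFAULT_SIGNATURES,
    CopperLigandMap,
    axial_class,
    classify_candidate,
    extract_ligand_map,
    hits_to_gff3,
    scan_regions,
    signature_from_text,
    signature_to_text,
)
from laccmine.synthetic import degrade_to_pseudogene, generate_laccase_cds


class TestScanRegions:
    def test_planted_peptide_yields_four_ordered_hits(self, planted_cds):
        hits = scan_regions(planted_cds.aa_seq)
        assert [h.region for h in hits] == ["L1", "L2", "L3", "L4"]
        starts = [h.start for h in hits]
        assert starts == sorted(starts)
        assert {h.region: h.start for h in hits} == planted_cds.region_starts

    def test_mutated_l4_ligand_removes_region(self, planted_cds):
        aa = list(planted_cds.aa_seq)
        aa[planted_cds.region_starts["L4"]] = "Q"  # HCH... -> QCH...
        hits = scan_regions("".join(aa))
        assert [h.region for h in hits] == ["L1", "L2", "L3"]

    def test_hit_order_is_consistent_across_seeds(self):
        for seed in range(5):
            cds = generate_laccase_cds(seed, axial="F")
            starts = [h.start for h in scan_regions(cds.aa_seq)]
            assert len(starts) == 4 and starts == sorted(starts)

    def test_rejects_stops_and_empty(self):
        with pytest.raises(ValidationError):
            scan_regions("")
        with pytest.raises(ValidationError):
            scan_regions("MA*HWHG")


class TestLigandMap:
    def test_planted_ligand_architecture(self, planted_cds):
        hits = scan_regions(planted_cds.aa_seq)
        lig = extract_ligand_map(hits, planted_cds.aa_seq)
        assert len(lig.his_positions) == 10
        assert planted_cds.aa_seq[lig.cys_position] == "C"
        assert all(planted_cds.aa_seq[p] == "H" for p in lig.his_positions)
        assert lig.axial_position == planted_cds.axial_position
        assert lig.axial_residue == planted_cds.axial_residue

    def test_truncated_tail_raises_extraction_error(self, planted_cds):
        l4 = planted_cds.region_starts["L4"]
        short = planted_cds.aa_seq[: l4 + 8]  # core present, axial cut off
        hits = scan_regions(short)
        assert [h.region for h in hits] == ["L1", "L2", "L3", "L4"]
        with pytest.raises(ExtractionError):
            extract_ligand_map(hits, short)

    def test_missing_region_rejected(self, planted_cds):
        hits = scan_regions(planted_cds.aa_seq)[:3]
        with pytest.raises(ValidationError):
            extract_ligand_map(hits, planted_cds.aa_seq)


@pytest.mark.parametrize("residue,expected", [("M", 1), ("L", 2), ("F", 3), ("W", "unclassified")])
def test_axial_class_closed_world(residue, expected):
    m = CopperLigandMap(his_positions=tuple(range(10)), cys_position=11,
                        axial_residue=residue, axial_position=21)
    assert axial_class(m) == expected


class TestClassifyCandidate:
    def test_complete_orf_with_four_regions_is_true_laccase(self, planted_cds):
        t = Transcript(id="t", seq=planted_cds.nt_seq)
        status = classify_candidate(find_orfs(t))
        assert status.status == "true_laccase"
        assert status.regions_found == ("L1", "L2", "L3", "L4")

    def test_no_stop_variant_is_pseudogene(self, planted_cds):
        pg = degrade_to_pseudogene(planted_cds, "no_stop", 1)
        status = classify_candidate(find_orfs(Transcript(id="t", seq=pg.nt_seq)))
        assert status.status == "pseudogene_no_stop"

    def test_premature_stop_variant_is_pseudogene(self, planted_cds):
        pg = degrade_to_pseudogene(planted_cds, "premature_stop", 1)
        status = classify_candidate(find_orfs(Transcript(id="t", seq=pg.nt_seq)))
        assert status.status == "pseudogene_premature_stop"

    def test_three_region_decoy_is_partial(self, planted_cds):
        aa = list(planted_cds.aa_seq)
        aa[planted_cds.region_starts["L1"]] = "Q"
        from laccmine.synthetic import backtranslate
        nt = backtranslate(0, "".join(aa), 55.0) + "TAA"
        status = classify_candidate(find_orfs(Transcript(id="t", seq=nt)))
        assert status.status == "partial_signature"

    def test_mixed_transcripts_rejected(self, planted_cds):
        a = find_orfs(Transcript(id="a", seq=planted_cds.nt_seq))
        b = find_orfs(Transcript(id="b", seq=planted_cds.nt_seq))
        with pytest.raises(ValidationError):
            classify_candidate(a + b)


class TestSignatureConfig:
    def test_text_round_trip(self):
        text = signature_to_text(DEFAULT_SIGNATURES)
        back = signature_from_text(text)
        assert back == DEFAULT_SIGNATURES

    def test_malformed_pattern_is_config_error(self):
        text = signature_to_text(DEFAULT_SIGNATURES).replace("H[WF]H[GAS]", "H[WF")
        with pytest.raises(ConfigError):
            signature_from_text(text)

    def test_missing_region_is_config_error(self):
        text = "\n".join(
            l for l in signature_to_text(DEFAULT_SIGNATURES).splitlines()
            if not l.startswith("L2")
        )
        with pytest.raises(ConfigError):
            signature_from_text(text)


def test_gff3_export_uses_one_based_coordinates(planted_cds):
    hits = scan_regions(planted_cds.aa_seq)
    gff = hits_to_gff3("pep", hits)
    lines = [l for l in gff.splitlines() if not l.startswith("#")]
    assert len(lines) == 4
    first = lines[0].split("\t")
    assert int(first[3]) == hits[0].start + 1 and int(first[4]) == hits[0].end
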