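"""The synthetic-transcriptome generator and its ground-truth manifest."""

import numpy as np
import pytest

from laccmine.comparative import global_align, percent_similarity
from laccmine.errors import ConfigError
from laccmine.physchem import gc_content
from laccmine.seq_core import Transcript, find_orfs, translate
from laccmine.signature import classify_candidate, scan_regions
from laccmine.synthetic import (
    MarkovBackground,
    SyntheticConfig,
    evaluate_against_manifest,
    generate_laccase_cds,
    generate_transcriptome,
    mutate_family,
    planted_cds_from_transcript,
    write_transcriptome,
)


class TestGenerateLaccaseCds:
    def test_planted_structure_by_construction(self, planted_cds):
        hits = scan_regions(planted_cds.aa_seq)
        assert [h.region for h in hits] == ["L1", "L2", "L3", "L4"]
        assert planted_cds.nt_seq[:3] == "ATG"
        assert translate(planted_cds.nt_seq[:-3]) == planted_cds.aa_seq
        assert translate(planted_cds.nt_seq[-3:]) == "*"
        assert "*" not in planted_cds.aa_seq

    @pytest.mark.parametrize("axial,expected", [("M", "M"), ("L", "L"), ("F", "F")])
    def test_requested_axial_residue_planted(self, axial, expected):
        cds = generate_laccase_cds(13, axial=axial)
        assert cds.aa_seq[cds.axial_position] == expected

    def test_gc_within_one_percent_of_target(self):
        devs = [
            abs(gc_content(generate_laccase_cds(seed, gc_target=55.5).nt_seq) - 55.5)
            for seed in range(100)
        ]
        assert max(devs) < 1.0

    def test_planted_sequons_are_detectable(self, planted_cds):
        from laccmine.physchem import find_sequons

        found = {g.position for g in find_sequons(planted_cds.aa_seq)}
        assert set(planted_cds.sequon_positions) <= found

    def test_infeasible_length_is_parameter_error(self):
        with pytest.raises(ConfigError):
            generate_laccase_cds(0, length_aa=200)


class TestMutateFamily:
    def test_insertion_only_members_keep_full_similarity(self, planted_cds):
        (member, dist), = mutate_family(planted_cds, 1, indel_prob=1.0, sub_prob=0.0, rng_seed=5)
        assert dist == 0
        assert len(member.aa_seq) > len(planted_cds.aa_seq)
        pair = global_align(planted_cds.aa_seq, member.aa_seq)
        assert percent_similarity(pair) == 100.0

    def test_substitution_only_similarity_matches_binomial_expectation(self, planted_cds):
        sub_prob = 0.05
        members = mutate_family(planted_cds, 6, indel_prob=0.0, sub_prob=sub_prob, rng_seed=8)
        sims = [
            percent_similarity(global_align(planted_cds.aa_seq, m.aa_seq))
            for m, _ in members
        ]
        assert abs(float(np.mean(sims)) - (1 - sub_prob) * 100.0) < 2.0

    def test_members_remain_true_laccases(self, planted_cds):
        members = mutate_family(planted_cds, 3, indel_prob=0.5, sub_prob=0.03, rng_seed=9)
        for m, _ in members:
            status = classify_candidate(find_orfs(Transcript(id="m", seq=m.nt_seq)))
            assert status.status == "true_laccase"


class TestGenerateTranscriptome:
    def test_manifest_counts_echo_config(self, synthetic_bundle):
        transcripts, manifest = synthetic_bundle
        cfg = SyntheticConfig()
        by_class = {}
        for r in manifest:
            by_class[r.truth_class] = by_class.get(r.truth_class, 0) + 1
        assert by_class["laccase"] == sum(cfg.family_sizes)
        assert by_class["pseudogene_no_stop"] == 1
        assert by_class["pseudogene_premature_stop"] == 1
        assert by_class["decoy_mco"] == cfg.n_decoys
        assert by_class["background"] == cfg.n_background
        assert len(transcripts) == len(manifest)
        assert len({t.id for t in transcripts}) == len(transcripts)

    def test_manifest_coordinates_reproduce_planted_cds(self, synthetic_bundle):
        transcripts, manifest = synthetic_bundle
        by_id = {t.id: t for t in transcripts}
        checked = 0
        for row in manifest:
            if row.truth_class == "background":
                continue
            cds = planted_cds_from_transcript(by_id[row.transcript_id], row)
            assert cds[:3] == "ATG"
            assert len(cds) % 3 == 0
            if row.truth_class != "pseudogene_no_stop":
                assert translate(cds[-3:]) == "*"
            checked += 1
        assert checked == 10 + 5  # planted laccases + pseudogenes + decoys

    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(family_sizes=(2,), n_decoys=1, n_background=3)
        for run in ("a", "b"):
            ts, mf = generate_transcriptome(cfg, rng_seed=42)
            write_transcriptome(ts, mf, tmp_path / f"{run}.fasta", tmp_path / f"{run}.tsv")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_end_to_end_classification_is_perfect(self, synthetic_bundle, mined):
        _, manifest = synthetic_bundle
        _, statuses, _ = mined
        ev = evaluate_against_manifest(
            {tid: s.status for tid, s in statuses.items()}, manifest
        )
        for cls, metrics in ev.items():
            assert metrics["precision"] == 1.0, cls
            assert metrics["recall"] == 1.0, cls

    def test_config_text_round_trip(self):
        cfg = SyntheticConfig(family_sizes=(2, 2), n_background=7, gc_target=54.0)
        assert SyntheticConfig.from_text(cfg.to_text()) == cfg
        with pytest.raises(ConfigError):
            SyntheticConfig.from_text("nonsense_key = 3\n")


def test_markov_background_is_near_fifty_percent_gc():
    rng = np.random.default_rng(4)
    bg = MarkovBackground(rng)
    seqs = [bg.generate(rng, 1000) for _ in range(20)]
    mean_gc = np.mean([gc_content(s) for s in seqs])
    assert abs(mean_gc - 50.0) < 5.0
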