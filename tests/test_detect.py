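import numpy as np
import pytest

from inteinflow.detect import (DetectionConfig, build_pssm, detect_inteins,
                               extract_insertion, iterate_detection,
                               refine_termini, scan, size_filter,
                               verify_splicing_motifs)
from inteinflow.io import AMINO_ACIDS
from inteinflow.simulate import SimulationConfig, run_simulation


def _random_protein(rng, n):
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n))


class TestBuildPssm:
    def test_uniform_column_scores_zero(self):
        rows = [AMINO_ACIDS, AMINO_ACIDS[::-1]]  # every column uniform-ish
        # use a genuinely uniform column: all 20 residues once per column
        rows = ["".join(AMINO_ACIDS[(i + j) % 20] for j in range(5))
                for i in range(20)]
        pssm = build_pssm(rows, pseudocount_weight=0.0)
        assert np.allclose(pssm.scores, 0.0, atol=1e-9)

    def test_conserved_column_closed_form(self):
        pssm = build_pssm(["C", "C", "C"], pseudocount_weight=1e-9)
        c_idx = AMINO_ACIDS.index("C")
        assert pssm.scores[0, c_idx] == pytest.approx(np.log2(1 / 0.05), abs=1e-3)

    def test_majority_gap_columns_dropped_and_recorded(self):
        rows = ["A-C", "A-C", "AWC"]
        pssm = build_pssm(rows)
        assert pssm.length == 2
        assert pssm.dropped_columns == [1]

    def test_ragged_and_empty_rejected(self):
        with pytest.raises(ValueError):
            build_pssm([])
        with pytest.raises(ValueError):
            build_pssm(["AA", "AAA"])
        with pytest.raises(ValueError):
            build_pssm(["A"])

    def test_seed_scores_beat_shuffled_null(self, rng):
        seeds = []
        base = _random_protein(rng, 60)
        for _ in range(4):
            chars = list(base)
            for pos in rng.choice(60, size=6, replace=False):
                chars[pos] = AMINO_ACIDS[int(rng.integers(20))]
            seeds.append("".join(chars))
        pssm = build_pssm(seeds)
        for seed_seq in seeds:
            own = pssm.score_window(seed_seq)
            null = []
            for _ in range(100):
                perm = rng.permutation(list(seed_seq))
                null.append(pssm.score_window("".join(perm)))
            assert own > np.mean(null)

    def test_consensus_is_single_mutant_optimum(self, rng):
        seeds = [_random_protein(rng, 40) for _ in range(2)]
        seeds.append(seeds[0])
        pssm = build_pssm(seeds)
        cons = pssm.consensus
        base = pssm.score_window(cons)
        for pos in range(0, 40, 7):
            for aa in "AW":
                if aa == cons[pos]:
                    continue
                mutant = cons[:pos] + aa + cons[pos + 1:]
                assert pssm.score_window(mutant) <= base


class TestScan:
    def test_consensus_scores_maximally_at_origin(self, rng):
        seeds = [_random_protein(rng, 30) for _ in range(3)]
        pssm = build_pssm(seeds)
        windows = scan(pssm, pssm.consensus, threshold=0.0)
        assert windows and windows[0].start == 0
        assert windows[0].score == pytest.approx(
            pssm.scores.max(axis=1).sum())

    def test_protein_shorter_than_pssm_yields_nothing(self, rng):
        pssm = build_pssm([_random_protein(rng, 30) for _ in range(2)])
        assert scan(pssm, "ACDEF", threshold=-1e9) == []

    def test_random_background_rarely_crosses_threshold(self, rng):
        pssm = build_pssm([_random_protein(rng, 50) for _ in range(3)])
        hit_count = 0
        for _ in range(100):
            prot = _random_protein(rng, 500)
            hit_count += len(scan(pssm, prot, threshold=10.0))
        assert hit_count <= 1  # expected hit count far below one per corpus

    def test_overlapping_windows_merged_to_best(self, rng):
        pssm = build_pssm([_random_protein(rng, 20) for _ in range(2)])
        cons = pssm.consensus
        prot = _random_protein(rng, 40) + cons + _random_protein(rng, 40)
        windows = scan(pssm, prot, threshold=0.0)
        starts = [w.start for w in windows]
        assert len(starts) == len(set(starts))
        for a, b in zip(windows, windows[1:]):
            assert a.end <= b.start


def _plant(ortholog: str, block: str, pos: int) -> tuple[str, str]:
    """Insert block at pos, nudging boundary residues so the optimal
    alignment (hence the insertion placement) is unique."""
    def different(a):
        return "W" if a != "W" else "Y"
    # a right-shifted placement scores equally iff block[0] == ortholog[pos],
    # a left-shifted one iff block[-1] == ortholog[pos-1]; break both ties
    block = different(ortholog[pos]) + block[1:-1] + different(ortholog[pos - 1])
    return ortholog[:pos] + block + ortholog[pos:], block


class TestExtractInsertion:
    def test_planted_block_recovered_exactly(self, rng):
        ortholog = _random_protein(rng, 500)
        host, _ = _plant(ortholog, _random_protein(rng, 400), 250)
        found = extract_insertion(host, ortholog)
        assert [(b.start, b.end) for b in found] == [(250, 650)]
        assert found[0].anchored

    def test_identical_sequences_yield_nothing(self, rng):
        seq = _random_protein(rng, 300)
        assert extract_insertion(seq, seq) == []

    def test_two_planted_blocks_recovered(self, rng):
        ortholog = _random_protein(rng, 600)
        with_b2, _ = _plant(ortholog, _random_protein(rng, 500), 400)
        host, _ = _plant(with_b2, _random_protein(rng, 150), 100)
        found = extract_insertion(host, ortholog)
        assert sorted(b.length for b in found) == [150, 500]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            extract_insertion("", "ACD")

    def test_coordinates_robust_to_flank_mutation(self, rng):
        # under the simulator's substitution process coordinates should be
        # within 2 residues of truth in the overwhelming majority of cells
        ok = total = 0
        for seed in range(12):
            truth = run_simulation(SimulationConfig(seed=seed, missing_frac=0.0))
            for (g, a), (s, e) in truth.coordinates.items():
                host = truth.proteins[(g, a)]
                orth = truth.reference_orthologs[a]
                blocks = extract_insertion(host, orth)
                total += 1
                for b in blocks:
                    rs, re_ = refine_termini(host, b.start, b.end)
                    if abs(rs - s) <= 2 and abs(re_ - e) <= 2:
                        ok += 1
                        break
        assert total >= 30
        assert ok / total >= 0.9


class TestSizeFilter:
    @pytest.mark.parametrize("length,keep", [
        (400, True),   # inside the 100-700 aa envelope inteins occupy
        (100, True), (700, True),
        (99, False), (701, False), (0, False),
    ])
    def test_envelope(self, length, keep):
        assert size_filter(length) is keep

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            size_filter(-1)


class TestSplicingMotifs:
    def test_canonical_intein_passes(self):
        rep = verify_splicing_motifs("C" + "A" * 50 + "HN", "S")
        assert rep.passed and not rep.provisional

    def test_both_termini_wrong_fails(self):
        rep = verify_splicing_motifs("M" + "A" * 50 + "KK", "S")
        assert not rep.n_terminal_ok and not rep.c_terminal_ok
        assert not rep.passed

    def test_unknown_plus_one_is_provisional(self):
        rep = verify_splicing_motifs("S" + "A" * 50 + "HQ", None)
        assert rep.passed and rep.provisional
        assert rep.plus_one_ok is None

    def test_terminal_single_residue_accepted(self):
        assert verify_splicing_motifs("A" + "W" * 20 + "N", "T").passed
        assert not verify_splicing_motifs("A" + "W" * 20 + "D", "T").passed

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            verify_splicing_motifs("", "S")


class TestDetectionOnSimulatedData:
    def test_planted_inteins_recovered(self):
        recovered = total = 0
        for seed in range(20):
            truth = run_simulation(SimulationConfig(
                seed=seed, missing_frac=0.0, n_taxa=8, n_alleles=2))
            hits = detect_inteins(truth.proteins, truth.reference_orthologs,
                                  truth.seed_alignments)
            found = {(h.genome_id, h.allele_id): (h.insertion_start,
                                                  h.insertion_end)
                     for h in hits}
            for cell, (s, e) in truth.coordinates.items():
                total += 1
                got = found.get(cell)
                if got and got[0] < e and s < got[1]:  # overlap with truth
                    recovered += 1
        assert total >= 40
        assert recovered / total >= 0.95


def _divergent_copy(rng, seq, n_mut, keep=()):
    chars = list(seq)
    positions = [p for p in range(len(seq)) if p not in keep]
    for pos in rng.choice(positions, size=n_mut, replace=False):
        old = chars[pos]
        new = AMINO_ACIDS[int(rng.integers(20))]
        while new == old:
            new = AMINO_ACIDS[int(rng.integers(20))]
        chars[pos] = new
    return "".join(chars)


class TestIterateDetection:
    def _fixture(self, rng):
        ortholog = _random_protein(rng, 300)
        ortholog = ortholog[:150] + "S" + ortholog[151:]  # +1 nucleophile
        ancestor = "C" + _random_protein(rng, 197) + "HN"
        keep = (0, 198, 199)
        intermediate = _divergent_copy(rng, ancestor, 60, keep)
        divergent = _divergent_copy(rng, intermediate, 60, keep)
        seeds = {"al": [ancestor,
                        _divergent_copy(rng, ancestor, 8, keep),
                        _divergent_copy(rng, ancestor, 8, keep)]}
        proteins = {
            ("g1", "al"): ortholog[:150] + intermediate + ortholog[150:],
            ("g2", "al"): ortholog[:150] + divergent + ortholog[150:],
        }
        return proteins, seeds, {"al": ortholog}

    def test_fixed_point_when_round_one_finds_everything(self, rng):
        proteins, seeds, orths = self._fixture(rng)
        cfg = DetectionConfig(pssm_score_threshold=-1e9)
        res = iterate_detection(proteins, seeds, orths, cfg, max_rounds=4)
        assert res.converged
        assert {(h.genome_id, h.allele_id) for h in res.hits} == \
            {("g1", "al"), ("g2", "al")}

    def test_seed_enrichment_recovers_divergent_intein(self, rng):
        proteins, seeds, orths = self._fixture(rng)
        pssm0 = build_pssm(seeds["al"])
        host2 = proteins[("g2", "al")]
        host1 = proteins[("g1", "al")]
        div_score = pssm0.score_window(host2, 150)
        inter_score = pssm0.score_window(host1, 150)
        assert div_score < inter_score
        threshold = (div_score + inter_score) / 2
        cfg = DetectionConfig(pssm_score_threshold=threshold)
        one_round = iterate_detection(proteins, seeds, orths, cfg, max_rounds=1)
        assert {(h.genome_id) for h in one_round.hits} == {"g1"}
        refined = iterate_detection(proteins, seeds, orths, cfg, max_rounds=4)
        assert {(h.genome_id) for h in refined.hits} == {"g1", "g2"}

    def test_empty_corpus_is_vacuous(self, rng):
        _, seeds, orths = self._fixture(rng)
        res = iterate_detection({}, seeds, orths, max_rounds=3)
        assert res.hits == [] and res.converged
        assert res.seeds["al"] == seeds["al"]

    def test_requires_seed_alignments(self):
        with pytest.raises(ValueError):
            iterate_detection({}, {}, {})
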