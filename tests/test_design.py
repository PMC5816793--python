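"""Candidate enumeration, Tm/complexity filters, selection, composition, layout."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as mt

from cazyarray.catalog import build_consensus, cluster_by_identity
from cazyarray.design import (DesignParams, assemble_array, apply_thermo_screens,
                              complexity_score, compose_goarrays,
                              enumerate_candidates, melting_temperature,
                              samples_per_slide, select_probes,
                              _max_min_gap_selection)
from cazyarray.simulate import random_coding_sequence

from conftest import make_gene


class TestEnumerate:
    def test_window_count_on_30nt_domain(self, rng):
        gene = make_gene("g", random_coding_sequence(rng, 60), domain=(10, 40))
        cands = enumerate_candidates(gene, DesignParams())
        assert len(cands) == 6  # 30 - 25 + 1

    def test_nonconserved_column_excludes_overlapping_windows(self, rng):
        seq = random_coding_sequence(rng, 100)
        mutated = seq[:50] + ("A" if seq[50] != "A" else "C") + seq[51:]
        genes = [make_gene("a", seq), make_gene("b", mutated)]
        (group,) = cluster_by_identity(genes, 0.96)
        build_consensus(group, genes)
        cands = enumerate_candidates(group, DesignParams())
        assert all(c.start + 25 <= 50 or c.start > 50 for c in cands)
        # brute-force window count: all offsets avoiding column 50
        expected = sum(1 for s in range(0, 76) if s + 25 <= 50 or s > 50)
        assert len(cands) == expected

    def test_candidate_count_matches_exhaustive_oracle(self, rng):
        gene = make_gene("g", random_coding_sequence(rng, 500), domain=(20, 480))
        cands = enumerate_candidates(gene, DesignParams())
        assert len(cands) == (480 - 20) - 25 + 1
        for c in cands[:: 37]:
            assert gene.coding_sequence[c.start : c.start + 25] == c.sequence

    def test_short_domain_raises(self, rng):
        gene = make_gene("g", random_coding_sequence(rng, 60), domain=(10, 30))
        with pytest.raises(ValueError, match="shorter than probe length"):
            enumerate_candidates(gene, DesignParams())


class TestMeltingTemperature:
    def test_reverse_complement_symmetry(self, rng):
        for _ in range(5):
            s = random_coding_sequence(rng, 25)
            rc = str(Seq(s).reverse_complement())
            assert melting_temperature(s) == pytest.approx(melting_temperature(rc), abs=1e-6)

    def test_at_rich_below_gc_rich(self):
        assert melting_temperature("A" * 25) < melting_temperature("GC" * 12 + "G")

    def test_matches_reference_nn_model(self, rng):
        s = random_coding_sequence(rng, 25)
        assert melting_temperature(s) == pytest.approx(
            mt.Tm_NN(s, Na=50, dnac1=250, dnac2=0)
        )

    def test_accepted_probes_within_tm_window(self, pure_culture_bundle):
        params = pure_culture_bundle.design_params
        for p in pure_culture_bundle.probes25:
            assert params.tm_min <= p.tm <= params.tm_max

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTN" * 5)


class TestComplexity:
    def test_homopolymer_fails_threshold(self):
        assert complexity_score("A" * 25) == 1
        params = DesignParams()
        (cand,) = apply_thermo_screens(
            [_candidate("A" * 25)], params
        )
        assert "complexity_fail" in cand.screen_flags

    def test_matches_exhaustive_trimer_tally(self, rng):
        for _ in range(20):
            s = random_coding_sequence(rng, 25)
            oracle = len({s[i : i + 3] for i in range(23)})
            assert complexity_score(s) == oracle

    def test_diverse_sequence_passes(self, rng):
        s = "ACGTAGCTTGCAACGGATCCTGACT"
        assert complexity_score(s) >= 10


def _candidate(seq, start=0, source="g"):
    from cazyarray.design import ProbeCandidate
    return ProbeCandidate(sequence=seq, source_id=source, start=start,
                          tm=55.0, complexity=complexity_score(seq), gene_ids=("g",))


class TestSelection:
    def test_two_survivors_both_selected(self):
        cands = [_candidate("ACGT" * 6 + "A", 0), _candidate("TGCA" * 6 + "T", 40)]
        probes, under = select_probes(cands, DesignParams())
        assert len(probes) == 2 and not under

    def test_single_survivor_selected_but_flagged(self):
        probes, under = select_probes([_candidate("ACGT" * 6 + "A", 5)], DesignParams())
        assert len(probes) == 1 and under

    def test_zero_survivors_is_reported_not_crash(self):
        c = _candidate("A" * 25)
        c.screen_flags.add("complexity_fail")
        probes, under = select_probes([c], DesignParams())
        assert probes == [] and under

    def test_spacing_matches_exhaustive_optimum(self, rng):
        """Selection min-gap equals the brute-force optimum on small instances."""
        for _ in range(15):
            starts = sorted(rng.choice(200, size=10, replace=False).tolist())
            k = int(rng.integers(2, 6))
            chosen_idx = _max_min_gap_selection(starts, k)
            got = min(np.diff([starts[i] for i in chosen_idx]))
            best = max(
                min(np.diff(combo))
                for combo in itertools.combinations(starts, k)
            )
            assert got == best

    def test_caps_at_probes_max(self, rng):
        cands = [_candidate(random_coding_sequence(rng, 25), s) for s in range(0, 500, 5)]
        probes, _ = select_probes(cands, DesignParams(probes_max=20))
        assert len(probes) == 20


class TestComposite:
    def _probes(self, rng, n):
        cands = [_candidate(random_coding_sequence(rng, 25), s) for s in range(0, n * 30, 30)]
        probes, _ = select_probes(cands, DesignParams())
        return probes

    def test_construction_and_length(self, rng):
        p1, p2 = self._probes(rng, 2)
        (comp,) = compose_goarrays([p1, p2], DesignParams(), np.random.default_rng(0))
        assert comp.sequence == p1.sequence + comp.spacer + p2.sequence
        assert len(comp.sequence) == 54

    @pytest.mark.parametrize("n", [2, 4, 6])
    def test_pairing_policy_counts(self, rng, n):
        probes = self._probes(rng, n)
        chained = compose_goarrays(probes, DesignParams(pairing_policy="chained"),
                                   np.random.default_rng(0))
        allp = compose_goarrays(probes, DesignParams(pairing_policy="all_pairs"),
                                np.random.default_rng(0))
        assert len(chained) == n - 1
        assert len(allp) == n * (n - 1) // 2

    def test_every_composite_is_54nt(self, two_condition_bundle):
        assert all(len(c.sequence) == 54 for c in two_condition_bundle.composites)

    def test_spacer_redrawn_under_screen(self, rng):
        probes = self._probes(rng, 2)
        seen = []

        def screen(seq):
            seen.append(seq)
            return len(seen) > 2  # reject the first two spacer draws

        (comp,) = compose_goarrays(probes, DesignParams(), np.random.default_rng(0),
                                   screen=screen)
        assert len(seen) == 3 and len(comp.sequence) == 54

    def test_self_pairing_opt_in(self, rng):
        (probe,) = self._probes(rng, 1)
        none = compose_goarrays([probe], DesignParams(), np.random.default_rng(0))
        assert none == []
        (selfpair,) = compose_goarrays(
            [probe], DesignParams(allow_self_pairing=True), np.random.default_rng(0)
        )
        assert selfpair.left_id == selfpair.right_id


class TestArrayAssembly:
    def test_triplicate_placement_reproducible(self, rng):
        probes = [_candidate(random_coding_sequence(rng, 25), s) for s in range(0, 300, 30)]
        selected, _ = select_probes(probes, DesignParams())
        d1 = assemble_array(selected, [], capacity=100, seed=5)
        d2 = assemble_array(selected, [], capacity=100, seed=5)
        assert len(d1.slots) == 3 * len(selected)
        assert d1.slots.equals(d2.slots)

    def test_seed_changes_placement_not_counts(self, rng):
        probes, _ = select_probes(
            [_candidate(random_coding_sequence(rng, 25), s) for s in range(0, 300, 30)],
            DesignParams(),
        )
        d1 = assemble_array(probes, [], capacity=500, seed=1)
        d2 = assemble_array(probes, [], capacity=500, seed=2)
        assert not d1.slots["slot_index"].equals(d2.slots["slot_index"])
        c1 = d1.slots["probe_id"].value_counts().sort_index()
        c2 = d2.slots["probe_id"].value_counts().sort_index()
        assert c1.equals(c2) and (c1 == 3).all()

    def test_placement_is_injective_within_capacity(self, two_condition_bundle):
        slots = two_condition_bundle.design.slots
        assert slots["slot_index"].is_unique
        assert slots["slot_index"].max() < two_condition_bundle.design.capacity
        assert two_condition_bundle.design.capacity == 15000

    def test_capacity_overflow_raises_with_count(self, rng):
        probes, _ = select_probes(
            [_candidate(random_coding_sequence(rng, 25), s) for s in range(0, 300, 30)],
            DesignParams(),
        )
        with pytest.raises(ValueError, match="overflow"):
            assemble_array(probes, [], capacity=10, seed=0)

    def test_slide_format(self):
        assert samples_per_slide() == 16


class TestDesignParams:
    def test_inverted_tm_window_rejected(self):
        with pytest.raises(ValueError, match="tm_min"):
            DesignParams(tm_min=70, tm_max=60)

    def test_probe_bounds_validated(self):
        with pytest.raises(ValueError):
            DesignParams(probes_min=5, probes_max=2)
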