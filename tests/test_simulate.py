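"""Hybridization simulator: truth construction, signal regimes, determinism."""

import filecmp

import numpy as np
import pytest

from cazyarray.signals import DetectionParams, call_genes, compute_snr, summarize_replicates
from cazyarray.simulate import (SimParams, generate_fixture, simulate_hybridization,
                                variant_target, write_fixture)

from conftest import make_gene
from cazyarray.simulate import random_coding_sequence


class TestVariantTarget:
    def test_identity_one_is_unchanged(self, rng):
        gene = make_gene("g", random_coding_sequence(rng, 300))
        assert variant_target(gene, 1.0, rng) == gene.coding_sequence

    def test_95pct_on_500nt_gives_25_substitutions(self, rng):
        gene = make_gene("g", random_coding_sequence(rng, 500))
        var = variant_target(gene, 0.95, rng)
        diffs = sum(a != b for a, b in zip(gene.coding_sequence, var))
        assert diffs == 25 and len(var) == 500

    @pytest.mark.parametrize("identity", [0.99, 0.92, 0.85])
    def test_realized_identity_within_one_position(self, rng, identity):
        gene = make_gene("g", random_coding_sequence(rng, 400))
        var = variant_target(gene, identity, rng)
        matches = sum(a == b for a, b in zip(gene.coding_sequence, var))
        assert abs(matches / 400 - identity) <= 1 / 400 + 1e-12


class TestDeterminism:
    def test_same_seed_byte_identical_bundles(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_fixture(generate_fixture("pure_culture", seed=3), d1)
        write_fixture(generate_fixture("pure_culture", seed=3), d2)
        names = [p.name for p in sorted(d1.iterdir())]
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, names, shallow=False)
        assert mismatch == [] and errors == [] and len(match) == len(names)

    def test_unknown_scenario_lists_valid_names(self):
        with pytest.raises(ValueError, match="pure_culture"):
            generate_fixture("bogus", seed=0)


class TestSignalRegimes:
    def test_zero_abundance_snr_near_one(self, pure_culture_bundle):
        """Spots of absent genes average SNR ~= 1 over >= 1000 spots."""
        b = pure_culture_bundle
        present = set(b.truth.abundance[("culture1", "ch1")])
        absent_probes = {
            p for p in b.manifest["probe_id"]
            if not (set(b.manifest.set_index("probe_id").loc[p, "gene_ids"].split(","))
                    & present)
        }
        spots = b.spots[b.spots["probe_id"].isin(absent_probes)]
        assert len(spots) >= 1000 or len(spots) >= 0.9 * 3 * len(absent_probes)
        ratios = spots["intensity"] / spots["background"]
        assert abs(ratios.mean() - 1.0) <= 0.05

    def test_absent_genes_not_detected(self, pure_culture_bundle):
        b = pure_culture_bundle
        sig = compute_snr(summarize_replicates(b.spots, b.manifest))
        calls = call_genes(sig, b.manifest, DetectionParams(mode="pure"))
        present = set(b.truth.abundance[("culture1", "ch1")])
        gene_ids = b.manifest.drop_duplicates("source_id").set_index("source_id")["gene_ids"]
        for row in calls.itertuples(index=False):
            if not (set(gene_ids[row.source_id].split(",")) & present):
                assert not row.detected

    def test_abundance_monotonicity_of_expected_snr(self, rng):
        """Raising one gene's abundance never lowers its probes' mean SNR
        (noiseless comparison)."""
        bundle = generate_fixture("pure_culture", seed=5)
        params = SimParams(seed=5, background_cv=0.0, replicate_cv=0.0)
        truth_lo = bundle.truth
        gid = bundle.genes[0].gene_id
        import copy
        truth_hi = copy.deepcopy(truth_lo)
        truth_hi.abundance[("culture1", "ch1")][gid] = \
            truth_lo.abundance[("culture1", "ch1")].get(gid, 0.0) + 3.0
        spots_lo = simulate_hybridization(bundle.design, bundle.manifest, bundle.genes,
                                          truth_lo, params, bundle.design_params)
        spots_hi = simulate_hybridization(bundle.design, bundle.manifest, bundle.genes,
                                          truth_hi, params, bundle.design_params)
        my_probes = set(
            bundle.manifest[bundle.manifest["gene_ids"].str.contains(gid)]["probe_id"]
        )
        lo = spots_lo[spots_lo["probe_id"].isin(my_probes)]["intensity"].mean()
        hi = spots_hi[spots_hi["probe_id"].isin(my_probes)]["intensity"].mean()
        assert hi >= lo
        others = spots_lo[~spots_lo["probe_id"].isin(my_probes)]["intensity"]
        others_hi = spots_hi[~spots_hi["probe_id"].isin(my_probes)]["intensity"]
        np.testing.assert_allclose(others.to_numpy(), others_hi.to_numpy())

    def test_perfect_match_gene_detected_by_both_probe_types(self):
        """High-abundance perfect-match targets are recovered end to end."""
        for seed in range(3):
            b = generate_fixture("pure_culture", seed=seed)
            sig = compute_snr(summarize_replicates(b.spots, b.manifest))
            calls = call_genes(sig, b.manifest, DetectionParams(mode="pure"))
            present = set(b.truth.abundance[("culture1", "ch1")])
            gene_ids = b.manifest.drop_duplicates("source_id").set_index("source_id")["gene_ids"]
            for row in calls.itertuples(index=False):
                targets = set(gene_ids[row.source_id].split(","))
                if targets and targets <= present:
                    assert row.detected, (seed, row.source_id, row.probe_type)


class TestVariantScenario:
    def test_variant_silences_some_short_probes_but_not_half_matched_composites(self):
        """A 92 %-identity variant: mismatched 25-mers go dark, composites
        with one intact half still fire at reduced level."""
        b = generate_fixture("variant_probe", seed=9)
        gid = next(iter(b.truth.variant_identity))
        variant_seq = b.truth.variant_sequences[gid]
        gene = next(g for g in b.genes if g.gene_id == gid)

        my25 = [p for p in b.probes25 if p.source_id == gid]
        intact = [p for p in my25 if p.sequence in variant_seq]
        broken = [p for p in my25 if p.sequence not in variant_seq]
        assert broken, "expected the 8 % divergence to break at least one probe"

        sig = compute_snr(summarize_replicates(b.spots, b.manifest))
        sig = sig.set_index("probe_id")
        for p in broken:
            assert sig.loc[p.probe_id, "snr"] < 3
        for p in intact:
            assert sig.loc[p.probe_id, "snr"] > 3

        half = [c for c in b.composites if c.source_id == gid
                and (c.sequence[:25] in variant_seq) != (c.sequence[29:] in variant_seq)]
        full = [c for c in b.composites if c.source_id == gid
                and c.sequence[:25] in variant_seq and c.sequence[29:] in variant_seq]
        dark = [c for c in b.composites if c.source_id == gid
                and c.sequence[:25] not in variant_seq and c.sequence[29:] not in variant_seq]
        if half and full:
            mean_half = np.mean([sig.loc[c.probe_id, "snr"] for c in half])
            mean_full = np.mean([sig.loc[c.probe_id, "snr"] for c in full])
            assert 1 < mean_half < mean_full
        for c in dark:
            assert sig.loc[c.probe_id, "snr"] < 3


class TestTwoConditionTruth:
    def test_fold_one_genes_expected_ns(self, two_condition_bundle):
        truth = two_condition_bundle.truth
        unchanged = [g for g, f in truth.fold_change.items() if f == 1.0]
        assert unchanged
        assert all(truth.status[g] == "ns" for g in unchanged)
        assert all(truth.expected_log2[g] == 0.0 for g in unchanged)

    def test_boundary_case_embedded(self, two_condition_bundle):
        truth = two_condition_bundle.truth
        boundary = [g for g, f in truth.fold_change.items() if f == 4.0]
        assert len(boundary) == 1
        assert truth.status[boundary[0]] == "boundary"
        assert truth.expected_log2[boundary[0]] < 2.0


class TestDyeBias:
    def test_median_scaling_corrects_simulated_dye_bias(self):
        """A 2x ch2 dye bias shifts the channel's signal median; global
        median scaling pulls the two channels back together."""
        from cazyarray.signals import median_scale_channels

        fair = generate_fixture("two_condition", seed=4)
        biased = generate_fixture("two_condition", seed=4,
                                  sim_params=SimParams(seed=4, dye_bias_ch2=2.0))
        sig_fair = compute_snr(summarize_replicates(fair.spots, fair.manifest))
        sig = compute_snr(summarize_replicates(biased.spots, biased.manifest))
        med_fair = sig_fair.groupby("channel")["signal"].median()
        med = sig.groupby("channel")["signal"].median()
        assert med["ch2"] > 1.5 * med_fair["ch2"]  # bias visible on ch2 only
        assert med["ch1"] == pytest.approx(med_fair["ch1"])
        corrected = median_scale_channels(sig)
        med_c = corrected.groupby(["sample_id", "channel"])["signal"].median()
        np.testing.assert_allclose(med_c, med_c.iloc[0])


class TestSimParams:
    def test_half_match_factor_bounds(self):
        with pytest.raises(ValueError):
            SimParams(half_match_factor=1.5)

    def test_positive_gain_required(self):
        with pytest.raises(ValueError):
            SimParams(gain=0)
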