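"""Hybridization simulator: synthetic catalogs, probe/array manifests, spot
tables and ground truth for end-to-end testing of the analysis pipeline.

The signal model reproduces the qualitative regimes established by
validation hybridizations of targets of increasing complexity:

* a 25-mer probe binds all-or-nothing — it fires only when it matches the
  (possibly variant) expressed sequence within ``mismatch_tolerance``
  substitutions (default 0, the observed behavior of short probes);
* a 54-mer composite fires fully when both 25-mer halves match, at a
  reduced ``half_match_factor`` when exactly one half matches, and not at
  all when neither does — preserving the ordering full > half > none
  without claiming a calibrated attenuation;
* spot intensity = background draw + gain x abundance x match factor x
  multiplicative replicate noise, with lognormal background and noise.

Scenarios (``pure_culture``, ``two_condition``, ``complex_community``,
``variant_probe``) bundle a synthetic catalog, a probe design run, an
array layout, simulated spot tables and a truth table; the same seed
always yields byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np
import pandas as pd

from . import io as _io
from .catalog import ConsensusGroup, TargetGene, group_catalog, write_catalog
from .design import (ArrayDesign, CompositeProbe, DesignParams, Probe25,
                     apply_thermo_screens, assemble_array, compose_goarrays,
                     enumerate_candidates, probe_manifest, select_probes,
                     write_array_manifest, write_probe_manifest)

SCENARIOS = ("pure_culture", "two_condition", "complex_community", "variant_probe")

_BASES = "ACGT"


@dataclass
class SimParams:
    """Signal-model parameters.

    gain: fluorescence units per abundance unit (a gene at abundance 1 on
    background 100 yields SNR ~= 11 at the default gain 1000).
    background_mean / background_cv: lognormal local-background model.
    replicate_cv: multiplicative spot-to-spot noise.
    mismatch_tolerance: max substitutions for a 25-mer to still bind.
    half_match_factor: fraction of full composite signal with one matching
    half (any value in (0,1); only the ordering full > half > none is
    meaningful).
    abundance_floor: smallest abundance treated as reliably detectable.
    """

    seed: int = 0
    gain: float = 1000.0
    background_mean: float = 100.0
    background_cv: float = 0.15
    replicate_cv: float = 0.1
    mismatch_tolerance: int = 0
    half_match_factor: float = 0.4
    abundance_floor: float = 0.2
    #: linear dye-bias multiplier on ch2 signal (1.0 = no bias); for
    #: exercising the optional normalization flag downstream
    dye_bias_ch2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gain", "background_mean", "abundance_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.half_match_factor < 1):
            raise ValueError("half_match_factor must be in (0, 1)")
        if self.background_cv < 0 or self.replicate_cv < 0 or self.mismatch_tolerance < 0:
            raise ValueError("noise/tolerance parameters must be non-negative")

    def asdict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Ground truth for one simulated experiment.

    ``abundance`` maps (sample_id, channel) -> {gene_id: abundance}; a
    missing or zero entry means the transcript is absent. ``fold_change``
    and ``expected_log2`` describe condition pairs (ch1/ch2): the expected
    value is the analytically attainable log2 SNR ratio
    log2((1 + g*aA/b) / (1 + g*aB/b)), which differs from log2(fold)
    because the additive background compresses ratios. ``status`` labels
    each gene up/down/ns, or "boundary" when the expected value sits within
    0.3 of a +/-2 threshold (its noisy call is a coin flip by
    construction). ``variant_identity``/``variant_sequences`` describe
    spiked sequence variants replacing the catalog sequence.
    """

    abundance: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    fold_change: dict[str, float] = field(default_factory=dict)
    expected_log2: dict[str, float] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)
    variant_identity: dict[str, float] = field(default_factory=dict)
    variant_sequences: dict[str, str] = field(default_factory=dict)


@dataclass
class FixtureBundle:
    """Everything one scenario produces, in memory."""

    scenario: str
    seed: int
    genes: list[TargetGene]
    groups: list[ConsensusGroup]
    probes25: list[Probe25]
    composites: list[CompositeProbe]
    design: ArrayDesign
    manifest: pd.DataFrame
    spots: pd.DataFrame
    truth: SimTruth
    sim_params: SimParams
    design_params: DesignParams


# ---------------------------------------------------------------------------
# Sequence helpers


def random_coding_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def variant_target(gene: TargetGene, identity: float, rng: np.random.Generator) -> str:
    """Mutated copy of the coding sequence at the requested identity.

    Substitutions (no indels) are placed uniformly at random; the count is
    round((1 - identity) * length). identity 1.0 returns the sequence
    unchanged.
    """
    if not (0 < identity <= 1):
        raise ValueError("identity must be in (0, 1]")
    seq = list(gene.coding_sequence)
    n_sub = round((1 - identity) * len(seq))
    if n_sub == 0:
        return gene.coding_sequence
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    for pos in positions:
        alternatives = [b for b in _BASES if b != seq[pos]]
        seq[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(seq)


def _match_factor_25(probe_seq: str, target_seq: str, tolerance: int) -> float:
    res = edlib.align(probe_seq, target_seq, mode="HW", task="distance", k=tolerance)
    return 1.0 if res["editDistance"] != -1 else 0.0


def _match_factor(probe_seq: str, probe_type: str, target_seq: str,
                  params: SimParams, probe_length: int, spacer_length: int) -> float:
    if probe_type == "probe25":
        return _match_factor_25(probe_seq, target_seq, params.mismatch_tolerance)
    left = probe_seq[:probe_length]
    right = probe_seq[probe_length + spacer_length:]
    hits = (_match_factor_25(left, target_seq, params.mismatch_tolerance)
            + _match_factor_25(right, target_seq, params.mismatch_tolerance))
    if hits == 2:
        return 1.0
    if hits == 1:
        return params.half_match_factor
    return 0.0


def expected_log2_ratio(fold: float, base_abundance: float, params: SimParams) -> float:
    """Analytically expected log2 SNR ratio for a fold change (ch1/ch2)."""
    g_over_b = params.gain / params.background_mean
    return math.log2((1 + g_over_b * base_abundance * fold)
                     / (1 + g_over_b * base_abundance))


# ---------------------------------------------------------------------------
# Core simulation


def simulate_hybridization(
    design: ArrayDesign,
    manifest: pd.DataFrame,
    genes: Sequence[TargetGene],
    truth: SimTruth,
    params: SimParams,
    design_params: DesignParams | None = None,
) -> pd.DataFrame:
    """Simulate a spot table for every (sample, channel) in the truth.

    Control spots carry no target signal and are not emitted (quality-
    control interpretation is out of scope); every probe spot in the array
    design yields one row per sample/channel. Deterministic for a fixed
    ``params.seed``.
    """
    design_params = design_params or DesignParams()
    by_id = {g.gene_id: g for g in genes}
    expressed_seq = {
        g.gene_id: truth.variant_sequences.get(g.gene_id, g.coding_sequence) for g in genes
    }

    probe_rows = manifest.drop_duplicates("probe_id").set_index("probe_id")
    probe_targets: dict[str, list[tuple[str, float]]] = {}
    for pid, row in probe_rows.iterrows():
        gene_ids = str(row["gene_ids"]).split(",")
        factors = []
        for gid in gene_ids:
            if gid not in by_id:
                raise ValueError(f"probe {pid} targets unknown gene {gid}")
            mf = _match_factor(row["sequence"], row["type"], expressed_seq[gid],
                               params, design_params.probe_length,
                               design_params.composite_spacer_length)
            factors.append((gid, mf))
        probe_targets[pid] = factors

    spot_slots = design.slots[design.slots["category"].isin(["probe25", "composite"])]
    rng = np.random.default_rng(params.seed)
    sigma_bg = math.sqrt(math.log(1 + params.background_cv ** 2))
    mu_bg = math.log(params.background_mean) - sigma_bg ** 2 / 2
    sigma_rep = math.sqrt(math.log(1 + params.replicate_cv ** 2))

    frames = []
    for (sample_id, channel) in sorted(truth.abundance):
        abundances = truth.abundance[(sample_id, channel)]
        gain = params.gain * (params.dye_bias_ch2 if channel == "ch2" else 1.0)
        signal_level = np.array([
            gain * sum(abundances.get(gid, 0.0) * mf
                       for gid, mf in probe_targets[pid])
            for pid in spot_slots["probe_id"]
        ])
        n = len(spot_slots)
        bg_spot = rng.lognormal(mu_bg, sigma_bg, size=n) if sigma_bg else np.full(n, params.background_mean)
        bg_local = rng.lognormal(mu_bg, sigma_bg, size=n) if sigma_bg else np.full(n, params.background_mean)
        noise = (rng.lognormal(-sigma_rep ** 2 / 2, sigma_rep, size=n)
                 if sigma_rep else np.ones(n))
        frames.append(pd.DataFrame({
            "sample_id": sample_id,
            "channel": channel,
            "probe_id": spot_slots["probe_id"].to_numpy(),
            "replicate_index": spot_slots["replicate_index"].to_numpy(),
            "intensity": bg_spot + signal_level * noise,
            "background": bg_local,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Synthetic catalogs


_FAMILY_CYCLE = ["GH5", "GH9", "GH10", "GH11", "GH43", "GH48", "CE1", "CE6"]
_TAXON_CYCLE = ["bacteria", "bacteria", "bacteria", "bacteria", "protozoa", "fungi"]


def _synthetic_catalog(rng: np.random.Generator, n_genes: int,
                       gene_length: int = 360, domain_margin: int = 12) -> list[TargetGene]:
    """Random catalog spread across the eight families and three taxa."""
    genes = []
    for i in range(n_genes):
        taxon = _TAXON_CYCLE[i % len(_TAXON_CYCLE)]
        genes.append(TargetGene(
            gene_id=f"simG{i:03d}",
            protein_accession=f"SIMP{i:05d}",
            organism=f"{taxon.capitalize()} sim-sp. {i % 7 + 1}",
            taxon_group=taxon,
            cazy_family=_FAMILY_CYCLE[i % len(_FAMILY_CYCLE)],
            coding_sequence=random_coding_sequence(rng, gene_length),
            domain_start=domain_margin,
            domain_end=gene_length - domain_margin,
        ))
    return genes


def _design_for_catalog(
    genes: Sequence[TargetGene], rng: np.random.Generator, design_params: DesignParams,
) -> tuple[list[ConsensusGroup], list[Probe25], list[CompositeProbe], ArrayDesign, pd.DataFrame]:
    """Run the full probe-design pipeline on a synthetic catalog (no
    background screening — backgrounds are a design-time concern the
    simulator does not model)."""
    groups = group_catalog(genes, threshold=0.96)
    probes25: list[Probe25] = []
    composites: list[CompositeProbe] = []
    for grp in groups:
        source = grp if not grp.is_singleton else next(
            g for g in genes if g.gene_id == grp.member_ids[0]
        )
        candidates = apply_thermo_screens(enumerate_candidates(source, design_params),
                                          design_params)
        probes, _ = select_probes(candidates, design_params)
        probes25.extend(probes)
        if probes:
            composites.extend(compose_goarrays(probes, design_params, rng))
    design = assemble_array(
        probes25, composites,
        controls={"positive_control": 10, "negative_control": 10, "quality_control": 5},
        params=design_params, seed=design_params.seed,
    )
    manifest = probe_manifest(probes25, composites)
    return groups, probes25, composites, design, manifest


# ---------------------------------------------------------------------------
# Scenarios


def generate_fixture(scenario: str, seed: int, out_dir: str | Path | None = None,
                     sim_params: SimParams | None = None,
                     design_params: DesignParams | None = None) -> FixtureBundle:
    """Build a self-contained scenario bundle; optionally write it to disk.

    Scenario conditions:

    * ``pure_culture`` — 20 genes including one 98 %-identity pair (one
      consensus group), a single sample with ~60 % of targets expressed at
      high abundance.
    * ``two_condition`` — 50 distinct genes, 3 replicate two-color
      hybridizations (ch1 = condition A, ch2 = condition B), embedded fold
      changes: 8x up-regulated genes, one exact 4-fold boundary case,
      1/8x down-regulated genes, and unchanged genes at fold 1.
    * ``complex_community`` — 60 genes across bacteria/protozoa/fungi with
      30 % of genes absent (abundance 0), one sample.
    * ``variant_probe`` — 6 genes, one expressed as a 92 %-identity variant
      of its catalog sequence.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; valid: {list(SCENARIOS)}")
    sim_params = sim_params or SimParams(seed=seed)
    design_params = design_params or DesignParams(seed=seed, probes_max=6)
    rng = np.random.default_rng(seed)

    truth = SimTruth()
    if scenario == "pure_culture":
        genes = _synthetic_catalog(rng, 20)
        # one near-identical pair: re-derive gene 19 from gene 18 at 98 % identity
        dup_src = genes[18]
        genes[19] = TargetGene(
            gene_id=genes[19].gene_id, protein_accession=genes[19].protein_accession,
            organism=dup_src.organism, taxon_group=dup_src.taxon_group,
            cazy_family=dup_src.cazy_family,
            coding_sequence=variant_target(dup_src, 0.98, rng),
            domain_start=dup_src.domain_start, domain_end=dup_src.domain_end,
        )
        present = [g.gene_id for i, g in enumerate(genes) if i % 5 != 4]
        truth.abundance[("culture1", "ch1")] = {gid: 5.0 for gid in present}
    elif scenario == "two_condition":
        genes = _synthetic_catalog(rng, 50)
        base = 2.0
        folds = {}
        for i, g in enumerate(genes):
            fold = 8.0 if i < 8 else 4.0 if i == 8 else 0.125 if i < 12 else 1.0
            folds[g.gene_id] = fold
        for rep in range(1, 4):
            truth.abundance[(f"rep{rep}", "ch1")] = {
                gid: base * fold for gid, fold in folds.items()
            }
            truth.abundance[(f"rep{rep}", "ch2")] = {gid: base for gid in folds}
        for gid, fold in folds.items():
            exp = expected_log2_ratio(fold, base, sim_params)
            truth.fold_change[gid] = fold
            truth.expected_log2[gid] = exp
            if abs(exp - 2.0) < 0.3 or abs(exp + 2.0) < 0.3:
                truth.status[gid] = "boundary"
            elif exp > 2.0:
                truth.status[gid] = "up"
            elif exp < -2.0:
                truth.status[gid] = "down"
            else:
                truth.status[gid] = "ns"
    elif scenario == "complex_community":
        genes = _synthetic_catalog(rng, 60)
        absent = set(rng.choice([g.gene_id for g in genes], size=18, replace=False))
        abundances = {}
        for g in genes:
            if g.gene_id in absent:
                continue
            abundances[g.gene_id] = float(np.clip(rng.lognormal(0.7, 0.6), 0.5, None))
        truth.abundance[("rumen1", "ch1")] = abundances
    else:  # variant_probe
        genes = _synthetic_catalog(rng, 6)
        variant_gene = genes[0]
        truth.variant_identity[variant_gene.gene_id] = 0.92
        truth.variant_sequences[variant_gene.gene_id] = variant_target(
            variant_gene, 0.92, rng
        )
        truth.abundance[("clone1", "ch1")] = {g.gene_id: 5.0 for g in genes}

    groups, probes25, composites, design, manifest = _design_for_catalog(
        genes, rng, design_params
    )
    spots = simulate_hybridization(design, manifest, genes, truth, sim_params, design_params)
    bundle = FixtureBundle(
        scenario=scenario, seed=seed, genes=list(genes), groups=groups,
        probes25=probes25, composites=composites, design=design,
        manifest=manifest, spots=spots, truth=truth,
        sim_params=sim_params, design_params=design_params,
    )
    if out_dir is not None:
        write_fixture(bundle, out_dir)
    return bundle


def write_fixture(bundle: FixtureBundle, out_dir: str | Path) -> Path:
    """Write a scenario bundle to disk; byte-identical for identical seeds."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_catalog(bundle.genes, out / "catalog.fasta", out / "annotations.tsv")
    write_probe_manifest(bundle.manifest, out / "probes.tsv",
                         seed=bundle.seed, params=bundle.design_params)
    write_array_manifest(bundle.design, out / "array.tsv")
    _io.write_table(bundle.spots, out / "spots.tsv", seed=bundle.seed,
                    params=bundle.sim_params.asdict())

    ab_rows = [
        {"sample_id": s, "channel": c, "gene_id": gid, "abundance": a}
        for (s, c), m in sorted(bundle.truth.abundance.items())
        for gid, a in sorted(m.items())
    ]
    _io.write_table(pd.DataFrame(ab_rows,
                                 columns=["sample_id", "channel", "gene_id", "abundance"]),
                    out / "truth_abundance.tsv", seed=bundle.seed)
    gene_rows = [
        {
            "gene_id": g.gene_id,
            "fold_change": bundle.truth.fold_change.get(g.gene_id, float("nan")),
            "expected_log2": bundle.truth.expected_log2.get(g.gene_id, float("nan")),
            "status": bundle.truth.status.get(g.gene_id, ""),
            "variant_identity": bundle.truth.variant_identity.get(g.gene_id, 1.0),
        }
        for g in bundle.genes
    ]
    _io.write_table(pd.DataFrame(gene_rows,
                                 columns=["gene_id", "fold_change", "expected_log2",
                                          "status", "variant_identity"]),
                    out / "truth_genes.tsv", seed=bundle.seed)
    return out
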