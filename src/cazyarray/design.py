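"""Probe design: candidate enumeration, thermodynamic filters, selection,
composite (GoArrays-style) probe assembly, and array layout.

The design strategy follows the short/long dual-probe approach used for
functional gene arrays: specific 25-mer probes are enumerated inside the
catalytic domain of each target (or inside fully conserved columns of a
consensus group), filtered on melting temperature (46–64 °C, unified
nearest-neighbor model), sequence complexity (>= 10 distinct overlapping
trinucleotides) and cross-hybridization screens, then 2–20 probes are
selected spread along the target. Pairs of selected 25-mers are
concatenated with a 4-nt spacer into 54-mer composite probes, which trade
some specificity for sensitivity. Probes are spotted in triplicate at
seed-randomized positions on a 15K-format subarray alongside control spots.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from .catalog import CONSENSUS_GAP, ConsensusGroup, TargetGene
from . import io as _io

logger = logging.getLogger(__name__)

#: Slide format: 8 subarrays of ~15K spots, two-color labeling => 16 samples/slide.
SUBARRAYS_PER_SLIDE = 8
CHANNELS_PER_SUBARRAY = 2
SUBARRAY_CAPACITY = 15000
#: Layout grid for a subarray (rows x cols >= capacity).
ARRAY_COLS = 150

CONTROL_CATEGORIES = ("positive_control", "negative_control", "quality_control")

_VALID_BASES = frozenset("ACGT")


def samples_per_slide() -> int:
    """Biological samples analyzable on one slide (subarrays x color channels)."""
    return SUBARRAYS_PER_SLIDE * CHANNELS_PER_SUBARRAY


@dataclass
class DesignParams:
    """Tunable probe-design parameters.

    Defaults encode the published design regime: 25-mer probes with Tm in
    [46, 64] °C and complexity >= 10; cross-hybridization rejection at
    >85 % identity together with a >15-base exact stretch against any
    non-target; rDNA hits below e-value 1e-5 rejected; 2–20 probes per
    target; composites of two 25-mers joined by a 4-nt spacer; triplicate
    spotting.
    """

    probe_length: int = 25
    tm_min: float = 46.0
    tm_max: float = 64.0
    complexity_threshold: int = 10
    crosshyb_identity_max: float = 0.85
    crosshyb_stretch_max: int = 15
    crosshyb_rule: str = "conjunction"  # or "disjunction"
    rdna_evalue_max: float = 1e-5
    probes_min: int = 2
    probes_max: int = 20
    composite_spacer_length: int = 4
    pairing_policy: str = "chained"  # or "all_pairs"
    allow_self_pairing: bool = False
    replicate_spots: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tm_min >= self.tm_max:
            raise ValueError(f"tm_min ({self.tm_min}) must be < tm_max ({self.tm_max})")
        if self.probes_min > self.probes_max:
            raise ValueError("probes_min must be <= probes_max")
        for name in ("probe_length", "complexity_threshold", "crosshyb_stretch_max",
                     "probes_min", "probes_max", "composite_spacer_length", "replicate_spots"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.crosshyb_rule not in ("conjunction", "disjunction"):
            raise ValueError(f"crosshyb_rule must be conjunction|disjunction")
        if self.pairing_policy not in ("chained", "all_pairs"):
            raise ValueError("pairing_policy must be chained|all_pairs")

    def asdict(self) -> dict:
        return asdict(self)


@dataclass
class ProbeCandidate:
    """A 25-mer window on a target or consensus source, before/after screening."""

    sequence: str
    source_id: str
    start: int
    tm: float
    complexity: int
    gene_ids: tuple[str, ...]
    screen_flags: set[str] = field(default_factory=set)

    @property
    def passed(self) -> bool:
        return not self.screen_flags


@dataclass
class Probe25:
    """A selected, screen-clean 25-mer probe."""

    probe_id: str
    sequence: str
    source_id: str
    start: int
    tm: float
    complexity: int
    gene_ids: tuple[str, ...]
    rank: int


@dataclass
class CompositeProbe:
    """A 54-mer composite: two same-source 25-mers joined by a 4-nt spacer."""

    probe_id: str
    left_id: str
    right_id: str
    spacer: str
    sequence: str
    source_id: str
    gene_ids: tuple[str, ...]


@dataclass
class ArrayDesign:
    """Randomized triplicate spot layout for one subarray.

    ``slots`` columns: slot_index, row, col, probe_id, replicate_index,
    category (probe25 | composite | positive_control | negative_control |
    quality_control).
    """

    slots: pd.DataFrame
    capacity: int
    seed: int


# ---------------------------------------------------------------------------
# Thermodynamics and complexity


def melting_temperature(sequence: str) -> float:
    """Duplex melting temperature (°C) under the unified nearest-neighbor model.

    Fixed conditions for bit-stable results: 50 mM monovalent salt, 250 nM
    probe strand, no formamide.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("sequence too short for a nearest-neighbor Tm")
    if set(seq) - _VALID_BASES:
        raise ValueError(f"non-ACGT characters in {sequence!r}")
    return float(_mt.Tm_NN(seq, Na=50, dnac1=250, dnac2=0))


def complexity_score(sequence: str) -> int:
    """Sequence complexity = number of distinct overlapping trinucleotides.

    Ranges from 1 (homopolymer) to 23 on a 25-mer; low-complexity probes
    (score below the threshold, default 10) are rejected.
    """
    seq = sequence.upper()
    if set(seq) - _VALID_BASES:
        raise ValueError(f"non-ACGT characters in {sequence!r}")
    return len({seq[i : i + 3] for i in range(len(seq) - 2)})


# ---------------------------------------------------------------------------
# Candidate enumeration and screening


def enumerate_candidates(
    source: TargetGene | ConsensusGroup, params: DesignParams
) -> list[ProbeCandidate]:
    """All admissible probe windows on a target gene or consensus group.

    A window is admissible when it lies entirely inside the catalytic
    domain and, for consensus groups, covers only conserved columns. Tm and
    complexity are computed here; screen flags are not yet set.
    """
    L = params.probe_length
    if isinstance(source, TargetGene):
        seq = source.coding_sequence
        source_id = source.gene_id
        gene_ids = (source.gene_id,)
        dstart, dend = source.domain_start, source.domain_end
        mask = np.ones(len(seq), dtype=bool)
    else:
        seq = source.consensus_sequence
        source_id = source.group_id
        gene_ids = tuple(source.member_ids)
        dstart, dend = source.domain_start, source.domain_end
        mask = source.conserved_mask

    if dend - dstart < L:
        raise ValueError(
            f"{source_id}: catalytic domain ({dend - dstart} nt) shorter than probe length {L}"
        )

    out: list[ProbeCandidate] = []
    for start in range(dstart, dend - L + 1):
        if not mask[start : start + L].all():
            continue
        window = seq[start : start + L]
        if CONSENSUS_GAP in window:
            continue
        out.append(
            ProbeCandidate(
                sequence=window,
                source_id=source_id,
                start=start,
                tm=melting_temperature(window),
                complexity=complexity_score(window),
                gene_ids=gene_ids,
            )
        )
    return out


def apply_thermo_screens(
    candidates: Iterable[ProbeCandidate], params: DesignParams
) -> list[ProbeCandidate]:
    """Flag candidates outside the Tm window or below the complexity threshold."""
    out = []
    for c in candidates:
        if not (params.tm_min <= c.tm <= params.tm_max):
            c.screen_flags.add("tm_fail")
        if c.complexity < params.complexity_threshold:
            c.screen_flags.add("complexity_fail")
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# Selection


def _max_min_gap_selection(starts: Sequence[int], k: int) -> list[int]:
    """Indices of k starts maximizing the minimum pairwise distance.

    Exact for sorted positions: binary search on the gap with a greedy
    left-to-right feasibility check anchored at the leftmost position
    (an optimal selection can always include it).
    """
    n = len(starts)
    if k >= n:
        return list(range(n))
    if k == 1:
        return [0]

    def picks(gap: int) -> list[int]:
        chosen = [0]
        last = starts[0]
        for i in range(1, n):
            if starts[i] - last >= gap:
                chosen.append(i)
                last = starts[i]
        return chosen

    lo, hi = 0, starts[-1] - starts[0]
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if len(picks(mid)) >= k:
            lo = mid
        else:
            hi = mid - 1
    return picks(lo)[:k]


def select_probes(
    candidates: Sequence[ProbeCandidate], params: DesignParams
) -> tuple[list[Probe25], bool]:
    """Select up to ``probes_max`` screen-clean probes spread along the source.

    Returns ``(probes, under_covered)`` where ``under_covered`` is True when
    fewer than ``probes_min`` survivors were available (the source is kept
    and flagged, not dropped). Raises nothing for zero survivors — the
    caller receives an empty list and the flag.
    """
    survivors = sorted((c for c in candidates if c.passed), key=lambda c: c.start)
    if not survivors:
        return [], True
    starts = [c.start for c in survivors]
    idx = _max_min_gap_selection(starts, min(params.probes_max, len(survivors)))
    probes = [
        Probe25(
            probe_id=f"{survivors[i].source_id}_p{rank:02d}",
            sequence=survivors[i].sequence,
            source_id=survivors[i].source_id,
            start=survivors[i].start,
            tm=survivors[i].tm,
            complexity=survivors[i].complexity,
            gene_ids=survivors[i].gene_ids,
            rank=rank,
        )
        for rank, i in enumerate(idx)
    ]
    under_covered = len(probes) < params.probes_min
    if under_covered:
        logger.warning("%s: only %d probe(s), below minimum %d",
                       probes[0].source_id, len(probes), params.probes_min)
    return probes, under_covered


# ---------------------------------------------------------------------------
# Composite probes


def compose_goarrays(
    probes: Sequence[Probe25],
    params: DesignParams,
    rng: np.random.Generator,
    screen: Callable[[str], bool] | None = None,
    max_spacer_draws: int = 20,
) -> list[CompositeProbe]:
    """Concatenate same-source 25-mer pairs into 54-mer composite probes.

    Pairing policy "chained" joins rank i with rank i+1 (n-1 composites);
    "all_pairs" joins every pair (n(n-1)/2). The 4-nt spacer is drawn from
    *rng*; if a *screen* callable is given (sequence -> pass bool) and the
    54-mer fails it, the spacer is redrawn up to *max_spacer_draws* times
    before the composite is dropped with a log entry. A lone probe pairs
    with itself only when ``allow_self_pairing`` is set.
    """
    if not probes:
        raise ValueError("compose_goarrays needs at least one probe")
    ordered = sorted(probes, key=lambda p: p.rank)
    if params.pairing_policy == "chained":
        pairs = list(zip(ordered, ordered[1:]))
    else:
        pairs = list(itertools.combinations(ordered, 2))
    if not pairs and len(ordered) == 1 and params.allow_self_pairing:
        pairs = [(ordered[0], ordered[0])]

    bases = np.array(list("ACGT"))
    out: list[CompositeProbe] = []
    for k, (left, right) in enumerate(pairs):
        seqs = None
        for _ in range(max_spacer_draws):
            spacer = "".join(rng.choice(bases, size=params.composite_spacer_length))
            candidate = left.sequence + spacer + right.sequence
            if screen is None or screen(candidate):
                seqs = (spacer, candidate)
                break
        if seqs is None:
            logger.warning("composite %s+%s: no spacer passed screening; dropped",
                           left.probe_id, right.probe_id)
            continue
        spacer, seq = seqs
        out.append(
            CompositeProbe(
                probe_id=f"{left.source_id}_c{k:02d}",
                left_id=left.probe_id,
                right_id=right.probe_id,
                spacer=spacer,
                sequence=seq,
                source_id=left.source_id,
                gene_ids=left.gene_ids,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Array assembly


def assemble_array(
    probes25: Sequence[Probe25],
    composites: Sequence[CompositeProbe],
    controls: dict[str, int] | None = None,
    capacity: int = SUBARRAY_CAPACITY,
    params: DesignParams | None = None,
    seed: int = 0,
) -> ArrayDesign:
    """Randomized triplicate layout of probes and controls on one subarray.

    Every probe occupies ``replicate_spots`` slots; control categories are
    interspersed. Placement is a seed-determined permutation of slot
    indices, so two designs with the same seed are identical and designs
    with different seeds differ only in placement, never in spot counts.
    """
    params = params or DesignParams()
    controls = dict(controls or {})
    unknown = set(controls) - set(CONTROL_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown control categories: {sorted(unknown)}")

    entries: list[tuple[str, int, str]] = []
    for p in probes25:
        for r in range(params.replicate_spots):
            entries.append((p.probe_id, r, "probe25"))
    for c in composites:
        for r in range(params.replicate_spots):
            entries.append((c.probe_id, r, "composite"))
    for category in CONTROL_CATEGORIES:
        for i in range(controls.get(category, 0)):
            entries.append((f"{category}_{i:03d}", 0, category))

    if len(entries) > capacity:
        raise ValueError(
            f"array capacity exceeded: {len(entries)} spots for {capacity} slots "
            f"(overflow {len(entries) - capacity})"
        )

    rng = np.random.default_rng(seed)
    slot_indices = rng.permutation(capacity)[: len(entries)]
    slots = pd.DataFrame(
        {
            "slot_index": slot_indices,
            "row": slot_indices // ARRAY_COLS,
            "col": slot_indices % ARRAY_COLS,
            "probe_id": [e[0] for e in entries],
            "replicate_index": [e[1] for e in entries],
            "category": [e[2] for e in entries],
        }
    ).sort_values("slot_index", kind="stable").reset_index(drop=True)
    return ArrayDesign(slots=slots, capacity=capacity, seed=seed)


# ---------------------------------------------------------------------------
# Manifest I/O

PROBE_MANIFEST_COLUMNS = [
    "probe_id", "type", "source_id", "gene_ids", "start", "sequence", "tm", "complexity",
]


def probe_manifest(
    probes25: Sequence[Probe25], composites: Sequence[CompositeProbe]
) -> pd.DataFrame:
    """Combined probe manifest table for 25-mers and composites."""
    rows = [
        {
            "probe_id": p.probe_id, "type": "probe25", "source_id": p.source_id,
            "gene_ids": ",".join(p.gene_ids), "start": p.start,
            "sequence": p.sequence, "tm": round(p.tm, 3), "complexity": p.complexity,
        }
        for p in probes25
    ] + [
        {
            "probe_id": c.probe_id, "type": "composite", "source_id": c.source_id,
            "gene_ids": ",".join(c.gene_ids), "start": -1,
            "sequence": c.sequence, "tm": float("nan"), "complexity": -1,
        }
        for c in composites
    ]
    return pd.DataFrame(rows, columns=PROBE_MANIFEST_COLUMNS)


def write_probe_manifest(df: pd.DataFrame, path: str | Path, seed: int | None = None,
                         params: DesignParams | None = None) -> None:
    _io.write_table(df, path, seed=seed, params=params.asdict() if params else None)


def read_probe_manifest(path: str | Path) -> pd.DataFrame:
    df = _io.read_table(path)
    missing = [c for c in PROBE_MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe manifest missing columns: {missing}")
    return df


def write_array_manifest(design: ArrayDesign, path: str | Path) -> None:
    _io.write_table(design.slots, path, seed=design.seed,
                    params={"capacity": design.capacity})


def read_array_manifest(path: str | Path) -> pd.DataFrame:
    return _io.read_table(path)
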