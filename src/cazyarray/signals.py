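"""From spot intensities to probe SNRs and gene-level detection calls.

Each probe is spotted in triplicate; the probe signal is the median of its
replicate intensities and the probe SNR is that signal divided by the
median local background. Short (25-mer) and composite (54-mer) probes are
treated independently: a probe is positive when its SNR reaches the
type-specific threshold, and a gene (or consensus group) is called
expressed when at least 65 % of its probes of that type are positive. The
gene SNR is the arithmetic mean of the SNRs of all probes of the type,
positive or not.

Two threshold regimes are built in: "pure" samples (PCR products, genomic
DNA, pure-culture RNA) use SNR >= 3 for 25-mers and >= 6 for composites;
"complex" community RNA uses SNR >= 2 for both types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .catalog import TargetGene

logger = logging.getLogger(__name__)

SPOT_COLUMNS = ["sample_id", "channel", "probe_id", "replicate_index", "intensity", "background"]

CALL_COLUMNS = [
    "sample_id", "channel", "source_id", "probe_type",
    "n_probes", "n_positive", "detected", "gene_snr",
]


@dataclass
class DetectionParams:
    """SNR thresholds and the positive-probe fraction for gene calls.

    ``mode="pure"`` defaults to thresholds (3, 6) for (25-mer, composite);
    ``mode="complex"`` to (2, 2). Explicit thresholds override the mode
    defaults.
    """

    mode: str = "pure"
    snr_threshold_25: float | None = None
    snr_threshold_54: float | None = None
    positive_fraction: float = 0.65
    restrict_to_composite: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("pure", "complex"):
            raise ValueError("mode must be 'pure' or 'complex'")
        defaults = {"pure": (3.0, 6.0), "complex": (2.0, 2.0)}[self.mode]
        if self.snr_threshold_25 is None:
            self.snr_threshold_25 = defaults[0]
        if self.snr_threshold_54 is None:
            self.snr_threshold_54 = defaults[1]
        if self.snr_threshold_25 <= 0 or self.snr_threshold_54 <= 0:
            raise ValueError("SNR thresholds must be positive")
        if not (0 < self.positive_fraction <= 1):
            raise ValueError("positive_fraction must be in (0, 1]")

    def threshold_for(self, probe_type: str) -> float:
        return self.snr_threshold_25 if probe_type == "probe25" else self.snr_threshold_54

    def asdict(self) -> dict:
        return asdict(self)


def read_spot_table(path: str | Path) -> pd.DataFrame:
    df = _io.read_table(path)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spot table missing columns: {missing}")
    if (df["intensity"] < 0).any():
        raise ValueError("negative intensities in spot table")
    return df


def summarize_replicates(spots: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Replicate-median probe signals per sample and channel.

    Returns one row per (sample_id, channel, probe_id) with ``signal`` and
    ``background`` as medians across replicates and the probe type joined
    from the manifest. Probes present in *spots* but absent from the
    manifest raise; probes with fewer replicates than the manifest's
    replicate count are summarized anyway with a log entry.
    """
    known = set(manifest["probe_id"])
    orphans = sorted(set(spots["probe_id"]) - known)
    if orphans:
        raise ValueError(f"spot table contains probes absent from the manifest: {orphans}")

    expected = int(spots.groupby(["sample_id", "channel", "probe_id"]).size().max())
    grouped = (
        spots.groupby(["sample_id", "channel", "probe_id"], sort=True)
        .agg(signal=("intensity", "median"), background=("background", "median"),
             n_replicates=("intensity", "size"))
        .reset_index()
    )
    short = grouped[grouped["n_replicates"] < expected]
    if len(short):
        logger.info("%d probe summaries built from fewer than %d replicates",
                    len(short), expected)
    types = manifest.drop_duplicates("probe_id")[["probe_id", "type"]].rename(
        columns={"type": "probe_type"}
    )
    out = grouped.merge(types, on="probe_id", how="left")
    return out[["sample_id", "channel", "probe_id", "probe_type",
                "signal", "background", "n_replicates"]]


def compute_snr(probe_signals: pd.DataFrame) -> pd.DataFrame:
    """Attach ``snr = signal / background``; rows with background <= 0 are
    excluded with a log entry (a dead spot is evidence of nothing)."""
    df = probe_signals.copy()
    dead = df["background"] <= 0
    if dead.any():
        logger.warning("excluding %d probe signals with non-positive background",
                       int(dead.sum()))
        df = df[~dead].copy()
    df["snr"] = df["signal"] / df["background"]
    return df


def median_scale_channels(probe_signals: pd.DataFrame) -> pd.DataFrame:
    """Optional global median scaling between channels (off by default).

    Rescales each (sample, channel)'s signals and backgrounds so that
    every channel's median signal matches the overall median — a coarse
    correction for dye bias. The method applies no normalization by
    default; this flag exists for two-color runs with a visible global
    imbalance.
    """
    df = probe_signals.copy()
    medians = df.groupby(["sample_id", "channel"])["signal"].transform("median")
    target = df["signal"].median()
    df["signal"] = df["signal"] * (target / medians)
    if "snr" in df.columns:
        df["snr"] = df["signal"] / df["background"]
    return df


def call_from_counts(n_positive: int, n_probes: int, positive_fraction: float = 0.65) -> bool:
    """The gene-detection rule on bare counts: positive fraction >= 65 %."""
    if n_probes <= 0:
        raise ValueError("n_probes must be positive")
    if n_positive > n_probes:
        raise ValueError("n_positive cannot exceed n_probes")
    return n_positive / n_probes >= positive_fraction


def call_genes(
    probe_signals: pd.DataFrame,
    manifest: pd.DataFrame,
    params: DetectionParams | None = None,
) -> pd.DataFrame:
    """Gene/group detection calls per sample, channel and probe type.

    A probe is positive when its SNR reaches the type-specific threshold;
    a target is detected when the positive fraction reaches
    ``positive_fraction``. ``gene_snr`` averages the SNRs of all probes of
    the type. Targets with zero probes of a type yield no row for that
    type.
    """
    params = params or DetectionParams()
    df = probe_signals if "snr" in probe_signals.columns else compute_snr(probe_signals)
    sources = manifest.drop_duplicates("probe_id")[["probe_id", "source_id"]]
    df = df.merge(sources, on="probe_id", how="left")
    if df["source_id"].isna().any():
        orphans = sorted(df.loc[df["source_id"].isna(), "probe_id"].unique())
        raise ValueError(f"probes without a manifest source: {orphans}")

    thresholds = df["probe_type"].map(
        {"probe25": params.snr_threshold_25, "composite": params.snr_threshold_54}
    )
    df = df.assign(positive=df["snr"] >= thresholds)
    calls = (
        df.groupby(["sample_id", "channel", "source_id", "probe_type"], sort=True)
        .agg(n_probes=("snr", "size"), n_positive=("positive", "sum"),
             gene_snr=("snr", "mean"))
        .reset_index()
    )
    calls["n_positive"] = calls["n_positive"].astype(int)
    calls["detected"] = calls["n_positive"] / calls["n_probes"] >= params.positive_fraction
    if params.restrict_to_composite:
        calls = calls[calls["probe_type"] == "composite"].reset_index(drop=True)
    return calls[CALL_COLUMNS]


def export_calls(
    calls: pd.DataFrame, genes: Sequence[TargetGene], source_map: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Join calls with catalog annotation (family, organism, taxon group).

    Group-level calls are annotated by their first member gene's family
    (group members share a family by construction of near-identical sets).
    *source_map* optionally maps source_id -> gene_ids (comma-joined) for
    group sources; by default source_id is taken as a gene_id.
    """
    by_id = {g.gene_id: g for g in genes}

    def representative(source_id: str) -> TargetGene:
        if source_id in by_id:
            return by_id[source_id]
        if source_map is not None:
            row = source_map[source_map["source_id"] == source_id]
            if len(row):
                first = str(row.iloc[0]["gene_ids"]).split(",")[0]
                if first in by_id:
                    return by_id[first]
        raise ValueError(f"call for id {source_id!r} absent from catalog")

    annotated = calls.copy()
    reps = [representative(s) for s in annotated["source_id"]]
    annotated["cazy_family"] = [r.cazy_family for r in reps]
    annotated["organism"] = [r.organism for r in reps]
    annotated["taxon_group"] = [r.taxon_group for r in reps]
    return annotated


def write_calls(calls: pd.DataFrame, path: str | Path,
                params: DetectionParams | None = None) -> None:
    _io.write_table(calls, path, params=params.asdict() if params else None)


def read_calls(path: str | Path) -> pd.DataFrame:
    return _io.read_table(path)
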