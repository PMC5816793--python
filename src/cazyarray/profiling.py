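"""Differential expression and composition profiling of detected transcripts.

Two-condition comparisons use the gene SNR (mean probe SNR per target and
probe type): for each replicate hybridization pair the log2 ratio of
condition-A to condition-B gene SNR is computed, then averaged across
replicates with its standard error. A target is up-regulated when the mean
log2 ratio strictly exceeds the up threshold (default 2, i.e. >4-fold),
down-regulated below the symmetric down threshold.

Composition profiles are presence-based: each detected target counts once
toward its CAZyme family and its taxon, regardless of SNR magnitude.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import TargetGene
from .signals import export_calls

logger = logging.getLogger(__name__)

DIFF_COLUMNS = [
    "source_id", "probe_type", "log2_ratio_mean", "sem", "n_replicates", "status",
]


@dataclass
class ProfileSummary:
    """Presence-based composition: detected-target counts and percentages."""

    by_family: pd.DataFrame  # columns: cazy_family, count, pct
    by_taxon: pd.DataFrame   # columns: taxon_group, count, pct
    scope: str = "all"


def differential_expression(
    calls_a: Sequence[pd.DataFrame],
    calls_b: Sequence[pd.DataFrame],
    up_threshold: float = 2.0,
    down_threshold: float | None = None,
    probe_type: str = "composite",
) -> pd.DataFrame:
    """Per-target mean log2 SNR ratio (A/B) with SEM and up/down/ns status.

    *calls_a* and *calls_b* are per-replicate call tables (paired by list
    index, as for co-hybridized two-color pairs). Only targets detected in
    at least one condition in at least one replicate are reported; targets
    with a non-positive gene SNR in any replicate are skipped with a log
    entry. Status uses strict inequalities: ``up`` iff mean > up_threshold,
    ``down`` iff mean < down_threshold (default -up_threshold).
    """
    if len(calls_a) != len(calls_b) or not calls_a:
        raise ValueError("need the same, nonzero number of replicate call sets per condition")
    if down_threshold is None:
        down_threshold = -up_threshold

    def prep(df: pd.DataFrame) -> pd.DataFrame:
        sub = df[df["probe_type"] == probe_type]
        return sub.set_index("source_id")[["gene_snr", "detected"]]

    reps_a = [prep(df) for df in calls_a]
    reps_b = [prep(df) for df in calls_b]
    targets = sorted(set().union(*(set(r.index) for r in reps_a + reps_b)))

    rows = []
    for tid in targets:
        detected_any = any(
            tid in r.index and bool(r.loc[tid, "detected"]) for r in reps_a + reps_b
        )
        if not detected_any:
            continue
        ratios = []
        skip = False
        for ra, rb in zip(reps_a, reps_b):
            if tid not in ra.index or tid not in rb.index:
                skip = True
                break
            snr_a, snr_b = float(ra.loc[tid, "gene_snr"]), float(rb.loc[tid, "gene_snr"])
            if snr_a <= 0 or snr_b <= 0:
                skip = True
                break
            ratios.append(math.log2(snr_a / snr_b))
        if skip or not ratios:
            logger.info("target %s skipped: missing or non-positive gene SNR", tid)
            rows.append({"source_id": tid, "probe_type": probe_type,
                         "log2_ratio_mean": np.nan, "sem": np.nan,
                         "n_replicates": len(ratios), "status": "condition-exclusive"})
            continue
        mean = float(np.mean(ratios))
        sem = float(np.std(ratios, ddof=1) / math.sqrt(len(ratios))) if len(ratios) > 1 else 0.0
        status = "up" if mean > up_threshold else "down" if mean < down_threshold else "ns"
        rows.append({"source_id": tid, "probe_type": probe_type,
                     "log2_ratio_mean": mean, "sem": sem,
                     "n_replicates": len(ratios), "status": status})
    return pd.DataFrame(rows, columns=DIFF_COLUMNS)


def profile_composition(
    calls: pd.DataFrame,
    genes: Sequence[TargetGene],
    scope: str = "all",
    probe_type: str = "composite",
    source_map: pd.DataFrame | None = None,
) -> ProfileSummary:
    """Family and taxon composition of detected targets (presence-based).

    *scope* restricts to a eukaryote subset ("fungi" or "protozoa") before
    computing percentages; "all" keeps everything. SNR magnitudes are
    deliberately ignored: a detected target counts once.
    """
    if scope not in ("all", "fungi", "protozoa"):
        raise ValueError("scope must be all|fungi|protozoa")
    detected = calls[(calls["detected"]) & (calls["probe_type"] == probe_type)]
    detected = detected.drop_duplicates("source_id")
    annotated = export_calls(detected, genes, source_map=source_map)
    if scope != "all":
        annotated = annotated[annotated["taxon_group"] == scope]

    def tally(col: str) -> pd.DataFrame:
        counts = annotated.groupby(col, sort=True).size().rename("count").reset_index()
        total = counts["count"].sum()
        counts["pct"] = 100.0 * counts["count"] / total if total else 0.0
        return counts

    return ProfileSummary(by_family=tally("cazy_family"), by_taxon=tally("taxon_group"),
                          scope=scope)


def compare_profiles(summary_x: ProfileSummary, summary_y: ProfileSummary) -> pd.DataFrame:
    """Per-family share of method X vs method Y.

    share_x = pct_x / (pct_x + pct_y) * 100 (and complement); 50 % means
    both methods estimate the family's contribution equally. Families
    absent from both summaries are excluded with a note; fully disjoint
    family sets raise.
    """
    x = summary_x.by_family.set_index("cazy_family")["pct"]
    y = summary_y.by_family.set_index("cazy_family")["pct"]
    families = sorted(set(x.index) | set(y.index))
    if not (set(x.index) & set(y.index)) and x.size and y.size:
        raise ValueError("profiles have disjoint family sets; nothing comparable")
    rows = []
    for fam in families:
        px, py = float(x.get(fam, 0.0)), float(y.get(fam, 0.0))
        if px + py == 0:
            logger.info("family %s absent from both profiles; excluded", fam)
            continue
        share_x = 100.0 * px / (px + py)
        rows.append({"cazy_family": fam, "pct_x": px, "pct_y": py,
                     "share_x": share_x, "share_y": 100.0 - share_x})
    return pd.DataFrame(rows, columns=["cazy_family", "pct_x", "pct_y", "share_x", "share_y"])


def plot_composition(summary: ProfileSummary, path: str | Path) -> None:
    """Render the family composition as a bar chart image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(summary.by_family["cazy_family"], summary.by_family["pct"], color="#4878b0")
    ax.set_ylabel("detected transcripts (%)")
    ax.set_title(f"CAZyme family composition ({summary.scope})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
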