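"""Cross-hybridization and rDNA specificity screens.

A short probe risks cross-hybridizing with a non-target transcript when it
is too similar to it. Two ungapped criteria are evaluated against every
background sequence on both strands, at every alignment offset of the
probe:

* percent identity of the best 25-nt ungapped alignment (> 85 % fails), and
* the longest run of consecutive matching bases, the "similarity stretch"
  (> 15 nt, i.e. >= 16, fails).

The default rule is their conjunction (both must hold to reject); a
disjunction mode is available. Probes are additionally screened against
rRNA gene (rDNA) sequences — either from precomputed tabular alignment hits
(12-column BLAST-style) or with the built-in ungapped local aligner scored
+1/-2 with a Karlin–Altschul e-value — and rejected when any hit has
e-value below 1e-5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.optimize import brentq

from .design import DesignParams

logger = logging.getLogger(__name__)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

BLAST_TABULAR_COLUMNS = [
    "query", "subject", "identity", "length", "mismatches", "gaps",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

#: Ungapped local alignment scores for the rDNA screen.
RDNA_MATCH_SCORE = 1
RDNA_MISMATCH_SCORE = -2
#: Karlin–Altschul K for the ungapped +1/-2 scheme (configured constant).
RDNA_KA_K = 0.46


@dataclass(frozen=True)
class ScreenReport:
    """Outcome of a specificity screen for one probe."""

    passed: bool
    best_identity: float
    best_stretch: int
    best_hit: str | None


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    if (out < 0).any():
        raise ValueError("non-ACGT character in sequence")
    return out


def _longest_true_run(rows: np.ndarray) -> np.ndarray:
    """Per-row longest run of True in a 2-D boolean array."""
    n, m = rows.shape
    runs = np.zeros((n, m), dtype=np.int16)
    runs[:, 0] = rows[:, 0]
    for j in range(1, m):
        runs[:, j] = np.where(rows[:, j], runs[:, j - 1] + 1, 0)
    return runs.max(axis=1)


def _best_ungapped(probe: np.ndarray, subject: np.ndarray) -> tuple[float, int]:
    """Best identity fraction and longest match stretch of *probe* against
    all full-length ungapped offsets on *subject* (one strand)."""
    L = probe.size
    if subject.size < L:
        return 0.0, 0
    windows = np.lib.stride_tricks.sliding_window_view(subject, L)
    eq = windows == probe
    identities = eq.mean(axis=1)
    stretches = _longest_true_run(eq)
    return float(identities.max()), int(stretches.max())


def specificity_screen(
    probe_sequence: str,
    background: Sequence[tuple[str, str]],
    params: DesignParams | None = None,
) -> ScreenReport:
    """Screen one probe against non-target background sequences.

    *background* is a sequence of ``(id, sequence)`` pairs; it must exclude
    the probe's own target (group) sequences. Both strands of every
    background sequence are scanned at all ungapped offsets. The report
    records the hit maximizing identity (stretch breaking ties).

    An empty background passes with a logged warning.
    """
    params = params or DesignParams()
    if not background:
        logger.warning("specificity screen: empty background, probe passes by default")
        return ScreenReport(True, 0.0, 0, None)

    probe = _encode(probe_sequence)
    best_identity, best_stretch, best_hit = 0.0, 0, None
    failed = False
    for hit_id, seq in background:
        for strand_seq in (seq, str(Seq(seq).reverse_complement())):
            ident, stretch = _best_ungapped(probe, _encode(strand_seq))
            if (ident, stretch) > (best_identity, best_stretch):
                best_identity, best_stretch, best_hit = ident, stretch, hit_id
            over_identity = ident > params.crosshyb_identity_max
            over_stretch = stretch > params.crosshyb_stretch_max
            if params.crosshyb_rule == "conjunction":
                failed = failed or (over_identity and over_stretch)
            else:
                failed = failed or over_identity or over_stretch
    return ScreenReport(not failed, best_identity, best_stretch, best_hit)


# ---------------------------------------------------------------------------
# rDNA screen


@lru_cache(maxsize=None)
def _ka_lambda(match: int = RDNA_MATCH_SCORE, mismatch: int = RDNA_MISMATCH_SCORE) -> float:
    """Karlin–Altschul lambda for uniform base composition.

    Solves sum_ij p_i p_j exp(lambda * s_ij) = 1 with p = 1/4 per base.
    """
    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-6, 10.0))


def _best_local_score(probe: np.ndarray, subject: np.ndarray) -> int:
    """Best ungapped local alignment score (+1/-2) over all diagonals."""
    L = probe.size
    if subject.size < 1:
        return 0
    best = 0
    # full-overlap diagonals
    if subject.size >= L:
        windows = np.lib.stride_tricks.sliding_window_view(subject, L)
        scores = np.where(windows == probe, RDNA_MATCH_SCORE, RDNA_MISMATCH_SCORE)
        # vectorized Kadane along axis 1
        running = np.zeros(scores.shape[0], dtype=np.int32)
        best_rows = np.zeros(scores.shape[0], dtype=np.int32)
        for j in range(L):
            running = np.maximum(running + scores[:, j], scores[:, j])
            best_rows = np.maximum(best_rows, running)
        best = int(best_rows.max())
    # partial-overlap diagonals at the subject edges
    for k in range(1, L):
        for p_seg, s_seg in (
            (probe[L - k :], subject[:k]),
            (probe[:k], subject[subject.size - k :]),
        ):
            sc = np.where(p_seg == s_seg, RDNA_MATCH_SCORE, RDNA_MISMATCH_SCORE)
            run = bst = 0
            for v in sc:
                run = max(run + int(v), int(v))
                bst = max(bst, run)
            best = max(best, bst)
    return best


def rdna_evalue(probe_sequence: str, rdna: Sequence[tuple[str, str]]) -> float:
    """Smallest Karlin–Altschul e-value of the probe against rDNA sequences.

    E = K * m * n * exp(-lambda * S) with m the probe length, n the total
    rDNA length over both strands, and S the best ungapped local score.
    """
    probe = _encode(probe_sequence)
    total_n = 2 * sum(len(s) for _, s in rdna)
    best_score = 0
    for _, seq in rdna:
        for strand_seq in (seq, str(Seq(seq).reverse_complement())):
            best_score = max(best_score, _best_local_score(probe, _encode(strand_seq)))
    lam = _ka_lambda()
    return RDNA_KA_K * probe.size * total_n * math.exp(-lam * best_score)


def parse_tabular_hits(path: str | Path) -> pd.DataFrame:
    """Parse 12-column BLAST-style tabular hits; parse errors carry line numbers."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                rows.append(
                    {
                        "query": fields[0], "subject": fields[1],
                        "identity": float(fields[2]), "length": int(fields[3]),
                        "mismatches": int(fields[4]), "gaps": int(fields[5]),
                        "qstart": int(fields[6]), "qend": int(fields[7]),
                        "sstart": int(fields[8]), "send": int(fields[9]),
                        "evalue": float(fields[10]), "bitscore": float(fields[11]),
                    }
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field ({exc})") from exc
    return pd.DataFrame(rows, columns=BLAST_TABULAR_COLUMNS)


def rdna_screen(
    probe_id: str,
    probe_sequence: str,
    params: DesignParams | None = None,
    rdna: Sequence[tuple[str, str]] | None = None,
    hits: pd.DataFrame | None = None,
) -> bool:
    """True when the probe passes the rDNA screen (no hit below the e-value cap).

    Provide either *rdna* sequences (built-in aligner) or a precomputed
    *hits* table keyed by probe id.
    """
    params = params or DesignParams()
    if hits is not None:
        mine = hits[hits["query"] == probe_id]
        return not bool((mine["evalue"] < params.rdna_evalue_max).any())
    if rdna is None:
        raise ValueError("rdna_screen needs either rdna sequences or a hits table")
    if not rdna:
        return True
    return rdna_evalue(probe_sequence, rdna) >= params.rdna_evalue_max


def screen_candidates(
    candidates: Iterable,
    params: DesignParams,
    background: Sequence[tuple[str, str]] = (),
    rdna: Sequence[tuple[str, str]] | None = None,
    rdna_hits: pd.DataFrame | None = None,
) -> None:
    """Apply specificity and rDNA screens in place, setting screen flags."""
    for c in candidates:
        if background:
            report = specificity_screen(c.sequence, background, params)
            if not report.passed:
                c.screen_flags.add("crosshyb_fail")
        if rdna is not None or rdna_hits is not None:
            probe_key = f"{c.source_id}@{c.start}"
            if not rdna_screen(probe_key, c.sequence, params, rdna=rdna, hits=rdna_hits):
                c.screen_flags.add("rdna_fail")
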