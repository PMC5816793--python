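"""Target gene catalog: validation, identity clustering, consensus building.

The array targets coding sequences from eight CAZyme families (GH5, GH9,
GH10, GH11, GH43, GH48, CE1, CE6) across rumen bacteria, protozoa and
anaerobic fungi. Probes are placed only inside the catalytic-domain region
of each coding sequence. Sequences sharing more than 96 % global identity
cannot be distinguished by 25-mer probes and are collapsed into consensus
groups; probes for a group are restricted to fully conserved columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The eight CAZyme families targeted by the array.
TARGET_FAMILIES = frozenset({"GH5", "GH9", "GH10", "GH11", "GH43", "GH48", "CE1", "CE6"})

#: Taxonomic groups represented in the catalog.
TAXON_GROUPS = frozenset({"bacteria", "protozoa", "fungi"})

#: Placeholder character for non-conserved consensus columns (never a probe base).
CONSENSUS_GAP = "N"

PROBE_LENGTH = 25

ANNOTATION_COLUMNS = [
    "gene_id",
    "protein_accession",
    "organism",
    "taxon_group",
    "cazy_family",
    "domain_start",
    "domain_end",
    "coordinate_convention",
]

_VALID_BASES = frozenset("ACGT")


class CatalogError(ValueError):
    """Raised when catalog records fail validation; carries per-record messages."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("catalog validation failed:\n" + "\n".join(self.errors))


@dataclass(frozen=True)
class TargetGene:
    """One targeted CAZyme coding sequence with its catalytic-domain interval.

    ``domain_start``/``domain_end`` are 0-based half-open coordinates on
    ``coding_sequence``; probes are designed only inside this interval.
    """

    gene_id: str
    protein_accession: str
    organism: str
    taxon_group: str
    cazy_family: str
    coding_sequence: str
    domain_start: int
    domain_end: int

    @property
    def catalytic_domain(self) -> str:
        return self.coding_sequence[self.domain_start : self.domain_end]

    def validation_errors(self) -> list[str]:
        errs = []
        if self.cazy_family not in TARGET_FAMILIES:
            errs.append(
                f"{self.gene_id}: family {self.cazy_family!r} not in targeted set "
                f"{sorted(TARGET_FAMILIES)}"
            )
        if self.taxon_group not in TAXON_GROUPS:
            errs.append(f"{self.gene_id}: taxon_group {self.taxon_group!r} invalid")
        bad = set(self.coding_sequence) - _VALID_BASES
        if bad:
            errs.append(f"{self.gene_id}: non-ACGT characters {sorted(bad)}")
        if not (0 <= self.domain_start < self.domain_end <= len(self.coding_sequence)):
            errs.append(
                f"{self.gene_id}: catalytic domain [{self.domain_start}, {self.domain_end}) "
                f"outside sequence of length {len(self.coding_sequence)}"
            )
        elif self.domain_end - self.domain_start < PROBE_LENGTH:
            errs.append(
                f"{self.gene_id}: catalytic domain shorter than probe length {PROBE_LENGTH}"
            )
        return errs


@dataclass
class ConsensusGroup:
    """A set of targets with pairwise identity above the grouping threshold.

    ``consensus_sequence`` carries :data:`CONSENSUS_GAP` at non-conserved
    columns; ``conserved_mask`` is True exactly where all aligned members
    agree. ``domain_start``/``domain_end`` are the catalytic-domain interval
    of the seed member, in consensus coordinates.
    """

    group_id: str
    member_ids: list[str]
    identity_threshold: float
    consensus_sequence: str = ""
    conserved_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    domain_start: int = 0
    domain_end: int = 0

    @property
    def is_singleton(self) -> bool:
        return len(self.member_ids) == 1


# ---------------------------------------------------------------------------
# Catalog I/O


def load_catalog(fasta_path: str | Path, annotations_path: str | Path) -> list[TargetGene]:
    """Load and validate the target catalog from FASTA + annotation TSV.

    The annotation table must contain one row per FASTA record and vice
    versa. Domain coordinates are converted to internal 0-based half-open
    per the table's ``coordinate_convention`` column (``0-based-half-open``
    or ``1-based-inclusive``). Raises :class:`CatalogError` with one message
    per offending record; no silent masking or dropping.
    """
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    ann = pd.read_csv(annotations_path, sep="\t", comment="#", dtype=str)
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise CatalogError([f"annotation table missing columns: {missing_cols}"])

    errors: list[str] = []
    ann_ids = list(ann["gene_id"])
    if len(set(ann_ids)) != len(ann_ids):
        dups = sorted({g for g in ann_ids if ann_ids.count(g) > 1})
        errors.append(f"duplicate annotation rows for: {dups}")
    for gid in records:
        if gid not in set(ann_ids):
            errors.append(f"{gid}: FASTA record has no annotation row")
    for gid in ann_ids:
        if gid not in records:
            errors.append(f"{gid}: annotation row has no FASTA record")
    if errors:
        raise CatalogError(errors)

    genes: list[TargetGene] = []
    for row in ann.itertuples(index=False):
        start, end = int(row.domain_start), int(row.domain_end)
        conv = row.coordinate_convention
        if conv == "1-based-inclusive":
            start, end = start - 1, end
        elif conv != "0-based-half-open":
            errors.append(f"{row.gene_id}: unknown coordinate_convention {conv!r}")
            continue
        gene = TargetGene(
            gene_id=row.gene_id,
            protein_accession=row.protein_accession,
            organism=row.organism,
            taxon_group=row.taxon_group,
            cazy_family=row.cazy_family,
            coding_sequence=records[row.gene_id],
            domain_start=start,
            domain_end=end,
        )
        errs = gene.validation_errors()
        if errs:
            errors.extend(errs)
        else:
            genes.append(gene)
    if errors:
        raise CatalogError(errors)
    return genes


def write_catalog(
    genes: Iterable[TargetGene], fasta_path: str | Path, annotations_path: str | Path
) -> None:
    """Write a catalog back to FASTA + annotation TSV (0-based half-open)."""
    genes = list(genes)
    recs = [
        SeqRecord(Seq(g.coding_sequence), id=g.gene_id, description="") for g in genes
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")
    rows = [
        {
            "gene_id": g.gene_id,
            "protein_accession": g.protein_accession,
            "organism": g.organism,
            "taxon_group": g.taxon_group,
            "cazy_family": g.cazy_family,
            "domain_start": g.domain_start,
            "domain_end": g.domain_end,
            "coordinate_convention": "0-based-half-open",
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        annotations_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Identity and clustering


def _cigar_matches(cigar: str) -> tuple[int, int]:
    """(matches, alignment_length) from an edlib extended cigar string."""
    matches = aln_len = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            aln_len += n
            if ch == "=":
                matches += n
    return matches, aln_len


def pairwise_identity(a: str, b: str) -> float:
    """Global pairwise identity = matches / alignment length.

    Gap columns count as mismatches. Computed from an edlib
    Needleman–Wunsch alignment with an extended cigar.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    res = edlib.align(a, b, mode="NW", task="path")
    matches, aln_len = _cigar_matches(res["cigar"])
    return matches / aln_len


def cluster_by_identity(
    genes: Sequence[TargetGene], threshold: float = 0.96
) -> list[ConsensusGroup]:
    """Single-linkage partition of the catalog on strict identity > *threshold*.

    Deterministic for a fixed input order: groups are ordered by their first
    member's position in the input, members keep input order. Returned
    groups are incomplete (no consensus yet); pass multi-member groups to
    :func:`build_consensus`. Singleton groups are completed in place.
    """
    if not genes:
        raise ValueError("empty catalog: nothing to cluster")
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")

    n = len(genes)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if pairwise_identity(genes[i].coding_sequence, genes[j].coding_sequence) > threshold:
                parent[find(j)] = find(i)

    members_by_root: dict[int, list[int]] = {}
    for i in range(n):
        members_by_root.setdefault(find(i), []).append(i)

    groups: list[ConsensusGroup] = []
    for k, root in enumerate(sorted(members_by_root, key=lambda r: members_by_root[r][0])):
        idxs = members_by_root[root]
        group = ConsensusGroup(
            group_id=f"grp{k:03d}" if len(idxs) > 1 else genes[idxs[0]].gene_id,
            member_ids=[genes[i].gene_id for i in idxs],
            identity_threshold=threshold,
        )
        if len(idxs) == 1:
            g = genes[idxs[0]]
            group.consensus_sequence = g.coding_sequence
            group.conserved_mask = np.ones(len(g.coding_sequence), dtype=bool)
            group.domain_start, group.domain_end = g.domain_start, g.domain_end
        groups.append(group)
    return groups


def build_consensus(group: ConsensusGroup, genes: Sequence[TargetGene]) -> ConsensusGroup:
    """Fill in the consensus sequence and conserved mask of a group.

    The longest member (first in member order on ties) seeds the coordinate
    frame; every other member is globally aligned to it. A column is
    conserved iff every member carries the seed's base there; member
    insertions relative to the seed mark the preceding seed column
    non-conserved. Raises if a member pair falls below the group's identity
    threshold (discovered late).
    """
    by_id = {g.gene_id: g for g in genes}
    members = [by_id[mid] for mid in group.member_ids]
    if len(members) == 1:
        g = members[0]
        group.consensus_sequence = g.coding_sequence
        group.conserved_mask = np.ones(len(g.coding_sequence), dtype=bool)
        group.domain_start, group.domain_end = g.domain_start, g.domain_end
        return group

    seed = max(members, key=lambda g: len(g.coding_sequence))
    seed_seq = seed.coding_sequence
    conserved = np.ones(len(seed_seq), dtype=bool)

    for member in members:
        if member is seed:
            continue
        ident = pairwise_identity(seed_seq, member.coding_sequence)
        if ident <= group.identity_threshold:
            raise ValueError(
                f"group {group.group_id}: pair ({seed.gene_id}, {member.gene_id}) "
                f"identity {ident:.4f} <= threshold {group.identity_threshold}"
            )
        res = edlib.align(member.coding_sequence, seed_seq, mode="NW", task="path")
        # walk the cigar: query = member, target = seed
        spos = 0
        num = ""
        for ch in res["cigar"]:
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch == "=":
                spos += n
            elif ch == "X":
                conserved[spos : spos + n] = False
                spos += n
            elif ch == "D":  # gap in member (seed bases unmatched)
                conserved[spos : spos + n] = False
                spos += n
            elif ch == "I":  # member insertion: flag flanking seed column
                conserved[max(spos - 1, 0)] = False
                if spos < len(seed_seq):
                    conserved[spos] = False

    group.consensus_sequence = "".join(
        b if keep else CONSENSUS_GAP for b, keep in zip(seed_seq, conserved)
    )
    group.conserved_mask = conserved
    group.domain_start, group.domain_end = seed.domain_start, seed.domain_end
    n_cons = int(conserved.sum())
    logger.info(
        "group %s: %d members, consensus %d nt, %d conserved (%.1f%%)",
        group.group_id, len(members), len(seed_seq), n_cons, 100 * n_cons / len(seed_seq),
    )
    return group


def group_catalog(
    genes: Sequence[TargetGene], threshold: float = 0.96
) -> list[ConsensusGroup]:
    """Cluster the catalog and build consensus for every group."""
    groups = cluster_by_identity(genes, threshold)
    for grp in groups:
        if not grp.is_singleton:
            build_consensus(grp, genes)
    return groups
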