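"""Positional clustering of amplicons — the unit of copy-number calling.

Targeted multiplex-PCR panels are dense inside small target regions and
empty between them, so no segmentation is attempted inside a cluster; each
cluster is assumed to carry one homogeneous copy-number state.

The partition is built per chromosome by recursive splitting at the largest
coordinate gap between adjacent primers.  A split at the largest gap is
accepted when both resulting clusters keep at least ``min_split`` (10)
members OR the gap exceeds ``gap_large`` (250 kbp); clusters smaller than
``small_cluster`` (100) members are additionally only ever split at gaps of
at least ``gap_small`` (100 kbp).  Recursion stops when no gap qualifies.

Alternatively ("no-cluster" mode) clusters are taken verbatim from gene
annotation labels, one cluster per distinct (chrom, gene).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .io_counts import CountTable, PrimerCount

GAP_LARGE = 250_000
GAP_SMALL = 100_000
SMALL_CLUSTER = 100
MIN_SPLIT = 10


@dataclass
class Cluster:
    """A positional group of primers sharing one putative copy-number state.

    ``members`` is the full set X (sorted by position); ``kept`` is the
    post-outlier subset X' filled by the statistics stage (initially all
    members).
    """

    id: str
    chrom: str
    members: list[PrimerCount]
    kept: list[PrimerCount] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have members")
        if any(p.site.chrom != self.chrom for p in self.members):
            raise ValueError("all members must share the cluster chromosome")
        self.members = sorted(self.members, key=lambda p: p.site.pos)
        if not self.kept:
            self.kept = list(self.members)

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def span(self) -> tuple[int, int]:
        return (self.members[0].site.pos, self.members[-1].site.pos)


def _split_point(
    positions: list[int],
    gap_large: int = GAP_LARGE,
    gap_small: int = GAP_SMALL,
    small_cluster: int = SMALL_CLUSTER,
    min_split: int = MIN_SPLIT,
) -> int | None:
    """Index after which to split, or None if no gap qualifies.

    Candidate = the largest gap between adjacent positions; ties go to the
    leftmost occurrence.
    """
    n = len(positions)
    if n < 2:
        return None
    gaps = [positions[i + 1] - positions[i] for i in range(n - 1)]
    i = max(range(n - 1), key=lambda j: gaps[j])
    gap = gaps[i]
    left, right = i + 1, n - (i + 1)
    qualifies = (left >= min_split and right >= min_split) or gap > gap_large
    if n < small_cluster:
        qualifies = qualifies and gap >= gap_small
    return i if qualifies else None


def assign_clusters(
    table: CountTable | Iterable[PrimerCount],
    gap_large: int = GAP_LARGE,
    gap_small: int = GAP_SMALL,
    small_cluster: int = SMALL_CLUSTER,
    min_split: int = MIN_SPLIT,
) -> list[Cluster]:
    """Partition the primers of *table* into positional clusters.

    Every primer belongs to exactly one cluster; output is sorted by
    (chrom, span start) and cluster ids are ``"<chrom>:c<k>"`` numbered per
    chromosome.
    """
    by_chrom: dict[str, list[PrimerCount]] = {}
    for p in table:
        by_chrom.setdefault(p.site.chrom, []).append(p)

    clusters: list[Cluster] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda p: p.site.pos)
        stack = [members]
        done: list[list[PrimerCount]] = []
        while stack:
            cur = stack.pop()
            i = _split_point([p.site.pos for p in cur], gap_large, gap_small, small_cluster, min_split)
            if i is None:
                done.append(cur)
            else:
                # right pushed first so the left child is processed next (depth-first, left to right)
                stack.append(cur[i + 1 :])
                stack.append(cur[: i + 1])
        done.sort(key=lambda ms: ms[0].site.pos)
        for k, ms in enumerate(done, start=1):
            clusters.append(Cluster(f"{chrom}:c{k}", chrom, ms))
    clusters.sort(key=lambda c: (c.chrom, c.span[0]))
    return clusters


def assign_clusters_by_gene(table: CountTable | Iterable[PrimerCount]) -> list[Cluster]:
    """One cluster per distinct (chrom, gene) label ("no-cluster" mode)."""
    by_gene: dict[tuple[str, str], list[PrimerCount]] = {}
    for p in table:
        if not p.site.gene:
            raise ValueError(
                f"primer {p.site.chrom}:{p.site.pos} has no gene label; "
                "gene annotation (6th count-file column) is required in no-cluster mode"
            )
        by_gene.setdefault((p.site.chrom, p.site.gene), []).append(p)
    clusters = [
        Cluster(f"{chrom}:{gene}", chrom, members) for (chrom, gene), members in by_gene.items()
    ]
    clusters.sort(key=lambda c: (c.chrom, c.span[0]))
    return clusters


def write_bed(clusters: list[Cluster], path: str | Path) -> None:
    """Export cluster spans as BED (0-based half-open) for inspection."""
    with open(path, "w") as fh:
        for c in clusters:
            start, end = c.span
            fh.write(f"{c.chrom}\t{start - 1}\t{end}\t{c.id}\n")
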