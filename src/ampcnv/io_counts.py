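"""Per-primer read-count tables: parsing, pairing and control averaging.

The on-disk format is a minimal TSV, one row per primer site::

    chrom <TAB> pos <TAB> direction <TAB> name <TAB> count [<TAB> gene]

``pos`` is the 1-based genomic coordinate of the primer 5' end, ``direction``
is ``+`` or ``-``, and lines starting with ``#`` are comments.  The optional
``gene`` column supplies cluster labels for gene-annotation ("no-cluster")
mode.  Sample and control must be enriched with the identical primer panel;
sites are matched by ``(chrom, pos, direction)`` because primer names are
free text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

_DIRECTIONS = {"+": "+", "-": "-", "plus": "+", "minus": "-"}


class CountFileError(ValueError):
    """Raised for malformed count files or mismatched panels."""


@dataclass(frozen=True, order=True)
class PrimerSite:
    """One primer location on the genome.

    Attributes
    ----------
    chrom : str
        Chromosome name (non-empty).
    pos : int
        1-based coordinate of the primer 5' end.
    direction : str
        ``"+"`` or ``"-"``.
    name : str
        Free-text amplicon/primer label (not used for matching).
    gene : str or None
        Optional gene/cluster label, required only in no-cluster mode.
    """

    chrom: str
    pos: int
    direction: str
    name: str = field(compare=False, default="")
    gene: str | None = field(compare=False, default=None)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.direction not in ("+", "-"):
            raise ValueError(f"direction must be '+' or '-', got {self.direction!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.direction)


@dataclass
class PrimerCount:
    """Paired sample/control counts at one primer site.

    ``weight`` is the sum of the two counts (the information content of the
    ratio); ``r`` and ``x`` are the raw and median-normalized log2 ratios,
    filled in by :func:`ampcnv.normalization.normalize`.
    """

    site: PrimerSite
    c_sample: float
    c_control: float
    r: float | None = None
    x: float | None = None

    def __post_init__(self) -> None:
        if self.c_sample < 0 or self.c_control < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def weight(self) -> float:
        return self.c_sample + self.c_control

    def swapped(self) -> "PrimerCount":
        """Sample/control-swapped copy (ratios reset)."""
        return PrimerCount(self.site, self.c_control, self.c_sample)


@dataclass
class CountTable:
    """An ordered sample-vs-control comparison over one primer panel.

    Invariants: primers unique by ``(chrom, pos, direction)`` and sorted by
    ``(chrom, pos)``.
    """

    primers: list[PrimerCount]
    sample_id: str = "sample"
    control_id: str = "control"
    sample_sex: str = "unknown"
    control_sex: str = "unknown"

    def __post_init__(self) -> None:
        self.primers = sorted(self.primers, key=lambda p: (p.site.chrom, p.site.pos, p.site.direction))
        keys = [p.site.key for p in self.primers]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate primer sites in table")

    def __len__(self) -> int:
        return len(self.primers)

    def __iter__(self):
        return iter(self.primers)


def read_count_file(path: str | Path) -> list[tuple[PrimerSite, int]]:
    """Read a per-primer count TSV.

    Returns one ``(PrimerSite, count)`` record per data row, in file order.
    Raises :class:`CountFileError` naming the file and line for malformed
    rows (wrong column count, non-integer or negative count, pos < 1).
    """
    path = Path(path)
    records: list[tuple[PrimerSite, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise CountFileError(
                    f"{path}:{lineno}: expected >=5 tab-separated columns, got {len(fields)}"
                )
            chrom, pos_s, direction, name, count_s = fields[:5]
            gene = fields[5].strip() or None if len(fields) > 5 else None
            try:
                pos = int(pos_s)
            except ValueError:
                raise CountFileError(f"{path}:{lineno}: non-integer position {pos_s!r}") from None
            if direction not in _DIRECTIONS:
                raise CountFileError(f"{path}:{lineno}: bad direction {direction!r}")
            try:
                count = int(count_s)
            except ValueError:
                raise CountFileError(f"{path}:{lineno}: non-integer count {count_s!r}") from None
            if count < 0:
                raise CountFileError(f"{path}:{lineno}: negative count {count}")
            try:
                site = PrimerSite(chrom, pos, _DIRECTIONS[direction], name, gene)
            except ValueError as exc:
                raise CountFileError(f"{path}:{lineno}: {exc}") from None
            records.append((site, count))
    return records


def write_count_file(records: Iterable[tuple[PrimerSite, float]], path: str | Path) -> None:
    """Write records in the count-TSV dialect (inverse of :func:`read_count_file`)."""
    with open(path, "w") as fh:
        fh.write("# chrom\tpos\tdirection\tname\tcount\tgene\n")
        for site, count in records:
            count_s = str(int(count)) if float(count) == int(count) else repr(float(count))
            gene = site.gene or ""
            fh.write(f"{site.chrom}\t{site.pos}\t{site.direction}\t{site.name}\t{count_s}\t{gene}\n")


def pair_counts(
    sample: Sequence[tuple[PrimerSite, float]],
    control: Sequence[tuple[PrimerSite, float]],
    sample_id: str = "sample",
    control_id: str = "control",
    sample_sex: str = "unknown",
    control_sex: str = "unknown",
) -> CountTable:
    """Match sample and control records into a :class:`CountTable`.

    Only sites present in *both* inputs (matched by chrom/pos/direction) are
    kept; unmatched sites are dropped with a WARN log.  Zero overlap raises
    :class:`CountFileError` — identical primer pools are mandatory.
    """
    if not sample or not control:
        raise CountFileError("sample and control lists must be non-empty")
    smap = {site.key: (site, cnt) for site, cnt in sample}
    cmap = {site.key: (site, cnt) for site, cnt in control}
    shared = set(smap) & set(cmap)
    if not shared:
        raise CountFileError("panels do not match: no overlapping primer sites")
    for key in sorted(set(smap) - shared):
        logger.warning("dropping sample-only site %s:%d%s", *key)
    for key in sorted(set(cmap) - shared):
        logger.warning("dropping control-only site %s:%d%s", *key)
    primers = []
    for key in shared:
        site, c_s = smap[key]
        _, c_c = cmap[key]
        primers.append(PrimerCount(site, float(c_s), float(c_c)))
    return CountTable(primers, sample_id, control_id, sample_sex, control_sex)


def combine_controls(
    controls: Sequence[Sequence[tuple[PrimerSite, float]]],
) -> list[tuple[PrimerSite, float]]:
    """Average several control count lists into one synthetic control.

    Per site the counts are averaged arithmetically and kept fractional
    (rounding would bias low-count primers).  All controls must cover the
    identical panel.
    """
    if not controls:
        raise CountFileError("need at least one control")
    first = controls[0]
    keys = [site.key for site, _ in first]
    keyset = set(keys)
    sums: dict[tuple, Fraction] = {site.key: Fraction(0) for site, _ in first}
    sites = {site.key: site for site, _ in first}
    for ci, ctl in enumerate(controls):
        cmap = {site.key: cnt for site, cnt in ctl}
        if set(cmap) != keyset:
            missing = sorted(keyset.symmetric_difference(cmap))[0]
            raise CountFileError(
                f"control #{ci + 1} panel mismatch at site {missing[0]}:{missing[1]}{missing[2]}"
            )
        for key in keys:
            sums[key] += Fraction(cmap[key])
    k = len(controls)
    out = []
    for key in keys:
        mean = sums[key] / k
        out.append((sites[key], float(mean) if mean.denominator != 1 else int(mean)))
    return out
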