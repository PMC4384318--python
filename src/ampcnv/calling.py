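"""Whole-comparison CNV calling: normalize, cluster, test, threshold, VCF.

The driver runs the full per-comparison pipeline deterministically: median
normalization of the paired counts, positional (or gene-label) clustering,
per-cluster outlier pruning and weighted t-statistics, and a Q >= 50
threshold on the dispersion-corrected score.  Results serialize to VCF 4.2
with symbolic <DUP>/<DEL> alleles, Q in QUAL, PASS/q50 in FILTER, and copy
number, confidence bounds, precision score and primer counts in INFO.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import __version__
from .clustering import (
    GAP_LARGE,
    GAP_SMALL,
    MIN_SPLIT,
    SMALL_CLUSTER,
    Cluster,
    assign_clusters,
    assign_clusters_by_gene,
)
from .cluster_stats import (
    ClusterStatistics,
    CopyNumberEstimate,
    compute_statistics,
    copy_number,
    remove_outliers,
)
from .io_counts import CountTable, PrimerSite, pair_counts
from .normalization import NormalizationResult, normalize

GAIN = "gain"
LOSS = "loss"
NO_CHANGE = "no_change"
UNCALLABLE = "uncallable"


@dataclass(frozen=True)
class CallerConfig:
    """All tunable thresholds of the caller, with their defaults."""

    q_threshold: float = 50.0
    alpha: float = 0.05
    sw_alpha: float = 0.05
    min_cluster: int = 10
    sample_sex: str = "unknown"
    control_sex: str = "unknown"
    no_cluster: bool = False
    gap_large: int = GAP_LARGE
    gap_small: int = GAP_SMALL
    small_cluster: int = SMALL_CLUSTER
    min_split: int = MIN_SPLIT
    emit_nochange: bool = True


@dataclass
class CnvCall:
    """One reportable cluster result."""

    cluster: Cluster
    status: str
    passed: bool
    estimate: CopyNumberEstimate | None = None
    stats: ClusterStatistics | None = None
    reason: str | None = None

    @property
    def n_primers(self) -> int:
        return self.cluster.n

    @property
    def n_kept(self) -> int:
        return self.cluster.n_kept


def _is_x(chrom: str) -> bool:
    return chrom.lstrip("chr").upper() == "X"


def _is_y(chrom: str) -> bool:
    return chrom.lstrip("chr").upper() == "Y"


def control_copies(chrom: str, control_sex: str = "unknown") -> int | None:
    """Copies of *chrom* in the control: 2 for autosomes, sex-dependent for X/Y.

    Returns None when the sex is unknown for a sex chromosome (uncallable).
    """
    if _is_x(chrom):
        return {"female": 2, "male": 1}.get(control_sex)
    if _is_y(chrom):
        return {"female": 0, "male": 1}.get(control_sex)
    return 2


def call_cluster(cluster: Cluster, config: CallerConfig = CallerConfig()) -> CnvCall:
    """Prune outliers, compute statistics, and classify one cluster.

    Uncallable when n < 3 (Shapiro-Wilk minimum), when fewer than
    ``min_cluster`` primers survive pruning, or when the control carries
    zero copies (chrY in a female) or unknown X/Y sex.
    """
    n_c = control_copies(cluster.chrom, config.control_sex)
    if n_c is None:
        return CnvCall(cluster, UNCALLABLE, False, reason="sex_unknown")
    if n_c == 0:
        return CnvCall(cluster, UNCALLABLE, False, reason="control_zero_copies")
    if cluster.n < 3:
        return CnvCall(cluster, UNCALLABLE, False, reason="too_few_primers")
    remove_outliers(cluster, config.sw_alpha)
    if cluster.n_kept < config.min_cluster:
        return CnvCall(cluster, UNCALLABLE, False, reason="too_few_kept_primers")
    stats = compute_statistics(cluster, alpha=config.alpha)
    est = copy_number(stats.mu_star, stats.se, n_c)
    passed = stats.q_score >= config.q_threshold
    if not passed:
        status = NO_CHANGE
    elif est.n_sample > est.n_control:
        status = GAIN
    else:
        status = LOSS
    return CnvCall(cluster, status, passed, estimate=est, stats=stats)


def call_table(
    table: CountTable, config: CallerConfig = CallerConfig()
) -> tuple[list[CnvCall], NormalizationResult]:
    """Normalize, cluster and call an already-paired comparison table."""
    _, norm = normalize(table)
    if config.no_cluster:
        clusters = assign_clusters_by_gene(table)
    else:
        clusters = assign_clusters(
            table, config.gap_large, config.gap_small, config.small_cluster, config.min_split
        )
    calls = [call_cluster(c, config) for c in clusters]
    calls.sort(key=lambda c: (c.cluster.chrom, c.cluster.span[0]))
    return calls, norm


def call_all(
    sample_counts: Sequence[tuple[PrimerSite, float]],
    control_counts: Sequence[tuple[PrimerSite, float]],
    config: CallerConfig = CallerConfig(),
) -> list[CnvCall]:
    """End-to-end driver from raw (site, count) lists to sorted calls."""
    table = pair_counts(
        sample_counts,
        control_counts,
        sample_sex=config.sample_sex,
        control_sex=config.control_sex,
    )
    calls, _ = call_table(table, config)
    return calls


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ampcnv-{version}
##ALT=<ID=DUP,Description="Copy number gain relative to control">
##ALT=<ID=DEL,Description="Copy number loss relative to control">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the cluster span">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=CN,Number=1,Type=Float,Description="Estimated copy number of the sample">
##INFO=<ID=CNMIN,Number=1,Type=Float,Description="Lower confidence bound of CN">
##INFO=<ID=CNMAX,Number=1,Type=Float,Description="Upper confidence bound of CN">
##INFO=<ID=PREC,Number=1,Type=Float,Description="Precision score P = -10 ln(SE)">
##INFO=<ID=NP,Number=1,Type=Integer,Description="Total primers in cluster (n)">
##INFO=<ID=NEP,Number=1,Type=Integer,Description="Primers kept after outlier removal (n')">
##INFO=<ID=REASON,Number=1,Type=String,Description="Why a cluster was not callable">
##FILTER=<ID=q{qthr},Description="Q score below {qthr}">
##FILTER=<ID=nocall,Description="Cluster not callable">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _fmt(v: float) -> str:
    return f"{v:.4g}"


def write_vcf(
    calls: Iterable[CnvCall],
    out: str | Path,
    config: CallerConfig = CallerConfig(),
    sample_id: str = "sample",
) -> None:
    """Serialize calls as VCF 4.2.

    One record per cluster: POS is the cluster span start, ALT is <DUP>,
    <DEL> or '.', QUAL holds Q rounded to 2 decimals, FILTER is PASS when
    Q >= the threshold and ``q<threshold>`` otherwise; uncallable clusters
    get FILTER ``nocall`` plus a REASON tag.  No-change records can be
    suppressed via ``config.emit_nochange``.
    """
    qthr = int(config.q_threshold) if config.q_threshold == int(config.q_threshold) else config.q_threshold
    lines = [_VCF_HEADER.format(version=__version__, qthr=qthr)]
    for call in calls:
        if call.status == NO_CHANGE and not config.emit_nochange:
            continue
        start, end = call.cluster.span
        info = [f"END={end}", "SVTYPE=CNV", f"NP={call.n_primers}", f"NEP={call.n_kept}"]
        if call.status == UNCALLABLE:
            alt, qual, filt = ".", ".", "nocall"
            info.append(f"REASON={call.reason}")
        else:
            est, st = call.estimate, call.stats
            alt = {GAIN: "<DUP>", LOSS: "<DEL>", NO_CHANGE: "."}[call.status]
            qual = f"{st.q_score:.2f}"
            filt = "PASS" if call.passed else f"q{qthr}"
            info[2:2] = [
                f"CN={_fmt(est.n_sample)}",
                f"CNMIN={_fmt(est.n_min)}",
                f"CNMAX={_fmt(est.n_max)}",
                f"PREC={_fmt(st.p_score) if st.p_score is not None else '.'}",
            ]
        lines.append(
            f"{call.cluster.chrom}\t{start}\t{call.cluster.id}\tN\t{alt}\t{qual}\t{filt}\t{';'.join(info)}\n"
        )
    Path(out).write_text("".join(lines))
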