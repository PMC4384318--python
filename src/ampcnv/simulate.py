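"""Seeded simulation of multiplex-PCR amplicon count data with known truth.

The generator emulates the structure of targeted-enrichment (MPE) read
counts that the caller assumes:

* a panel of gene clusters scattered across chromosomes, each a run of
  amplicons 120-180 bp long at roughly even spacing;
* a per-amplicon amplification efficiency, lognormal in scale and SHARED
  between sample and control — the dominant source of depth variation in
  multiplex PCR, and the reason ratios are informative while raw depths
  are not;
* negative-binomial counts around ``depth * efficiency * copies/2``
  (variance m + m^2/k with NB size k), i.e. overdispersed relative to
  Poisson;
* integer copy-number truth planted per cluster;
* occasional sample-only efficiency shifts (rate ``outlier_rate``)
  emulating primer-binding-site variants and failed reactions — the true
  outliers the Shapiro-Wilk pruning exists for;
* optionally a small per-cluster log2 amplification bias between sample
  and control libraries (``cluster_bias_sd``), a systematic region-level
  batch effect that is NOT a copy-number change; it creates the
  low-dispersion false-positive regime the dispersion factor phi corrects.

Everything is reproducible from the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calling import CnvCall, UNCALLABLE
from .io_counts import PrimerSite


@dataclass(frozen=True)
class ClusterSpec:
    """Layout of one simulated cluster: where it sits and how dense it is."""

    chrom: str
    start: int
    n_amplicons: int
    spacing: int = 300

    def __post_init__(self) -> None:
        if self.n_amplicons < 1 or self.spacing <= 0:
            raise ValueError("need n_amplicons >= 1 and spacing > 0")


@dataclass(frozen=True)
class PanelSpec:
    """A simulated primer panel: a list of cluster layouts."""

    clusters: tuple[ClusterSpec, ...]
    amplicon_len: tuple[int, int] = (120, 180)

    @staticmethod
    def regular(
        n_clusters: int,
        n_amplicons: int = 40,
        spacing: int = 300,
        chroms: Sequence[str] | None = None,
    ) -> "PanelSpec":
        """A uniform panel: clusters spread round-robin over autosomes,
        2 Mbp apart so the positional clustering rules recover them."""
        if chroms is None:
            chroms = [f"chr{i}" for i in range(1, 23)]
        specs = []
        per_chrom: dict[str, int] = {}
        for i in range(n_clusters):
            chrom = chroms[i % len(chroms)]
            k = per_chrom.get(chrom, 0)
            specs.append(ClusterSpec(chrom, 1_000_000 + k * 2_000_000, n_amplicons, spacing))
            per_chrom[chrom] = k + 1
        return PanelSpec(tuple(specs))


@dataclass(frozen=True)
class SimulationSpec:
    """Noise model and planted truth for one simulated comparison.

    Attributes
    ----------
    depth : float
        Target median per-amplicon count for a diploid region (500-2000x is
        the realistic operating range for MPE panels).
    efficiency_sd : float
        SD of the per-amplicon log2 efficiency shared by sample and control.
    dispersion : float
        Negative-binomial size parameter k (variance = m + m^2/k); smaller
        means noisier counts.
    outlier_rate : float
        Fraction of amplicons with a sample-only efficiency shift.
    outlier_log2_sd : float
        SD of that shift on the log2 scale (drawn symmetric, |shift|>=1).
    cluster_bias_sd : float
        SD of a per-cluster sample-vs-control log2 bias (default 0 = off).
    truth : mapping cluster-index -> (N_C, N_S)
        Planted copy numbers; clusters not listed are (2, 2).
    seed : int
    """

    depth: float = 1000.0
    efficiency_sd: float = 0.15
    dispersion: float = 100.0
    outlier_rate: float = 0.02
    outlier_log2_sd: float = 1.5
    cluster_bias_sd: float = 0.0
    truth: Mapping[int, tuple[int, int]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.outlier_rate < 1 / 3:
            raise ValueError("outlier_rate must be in [0, 1/3)")


def _nb(rng: np.random.Generator, mean: np.ndarray, k: float) -> np.ndarray:
    """Negative-binomial draws with mean ``mean`` and size ``k``."""
    mean = np.maximum(mean, 1e-9)
    return rng.negative_binomial(k, k / (k + mean))


def simulate_comparison(
    panel: PanelSpec, spec: SimulationSpec
) -> tuple[
    list[tuple[PrimerSite, int]],
    list[tuple[PrimerSite, int]],
    dict[str, tuple[int, int]],
]:
    """Generate (sample counts, control counts, truth) for one comparison.

    The truth table maps a cluster label ``g<i>`` (also written into the
    sites' gene field) to its planted ``(N_C, N_S)``.
    """
    rng = np.random.default_rng(spec.seed)
    sample: list[tuple[PrimerSite, int]] = []
    control: list[tuple[PrimerSite, int]] = []
    truth: dict[str, tuple[int, int]] = {}
    for ci, cl in enumerate(panel.clusters):
        n_c, n_s = spec.truth.get(ci, (2, 2))
        label = f"g{ci}"
        truth[label] = (n_c, n_s)
        bias = rng.normal(0.0, spec.cluster_bias_sd) if spec.cluster_bias_sd > 0 else 0.0
        eff = 2.0 ** rng.normal(0.0, spec.efficiency_sd, cl.n_amplicons)
        mean_c = spec.depth * eff * (n_c / 2.0)
        out_mult = np.ones(cl.n_amplicons)
        hit = rng.random(cl.n_amplicons) < spec.outlier_rate
        if hit.any():
            shift = rng.normal(0.0, spec.outlier_log2_sd, int(hit.sum()))
            shift = np.sign(shift) * np.maximum(np.abs(shift), 1.0)
            out_mult[hit] = 2.0**shift
        mean_s = spec.depth * eff * (n_s / 2.0) * out_mult * 2.0**bias
        cnt_c = _nb(rng, mean_c, spec.dispersion)
        cnt_s = _nb(rng, mean_s, spec.dispersion)
        for ai in range(cl.n_amplicons):
            pos = cl.start + ai * cl.spacing
            site = PrimerSite(cl.chrom, pos, "+", f"{label}_a{ai}", gene=label)
            sample.append((site, int(cnt_s[ai])))
            control.append((site, int(cnt_c[ai])))
    return sample, control, truth


@dataclass(frozen=True)
class CallMetrics:
    """Confusion counts of calls against planted truth.

    A call is positive iff it passed the Q threshold; a positive counts as
    true positive when its direction (gain/loss) agrees with the planted
    change — an exact copy-number match is NOT required.  Rates are None
    when their denominator is zero.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def tpr(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def tnr(self) -> float | None:
        neg = self.tn + self.fp
        return self.tn / neg if neg else None


def _truth_label(cluster_gene: str, truth: Mapping[str, tuple[int, int]]) -> int:
    """-1 loss, 0 unchanged, +1 gain, from the planted (N_C, N_S)."""
    n_c, n_s = truth[cluster_gene]
    return (n_s > n_c) - (n_s < n_c)


def _call_gene(call: CnvCall) -> str:
    genes = {p.site.gene for p in call.cluster.members}
    if len(genes) != 1:
        raise ValueError(f"cluster {call.cluster.id} spans several truth labels: {genes}")
    return genes.pop()


def evaluate_calls(
    calls: Iterable[CnvCall], truth: Mapping[str, tuple[int, int]]
) -> CallMetrics:
    """Score callable clusters against the planted truth (uncallable skipped)."""
    tp = tn = fp = fn = 0
    for call in calls:
        if call.status == UNCALLABLE:
            continue
        gene = _call_gene(call)
        if gene not in truth:
            raise KeyError(f"no truth entry for cluster {call.cluster.id} ({gene})")
        expected = _truth_label(gene, truth)
        if call.passed:
            observed = 1 if call.estimate.n_sample > call.estimate.n_control else -1
            if observed == expected:
                tp += 1
            else:
                fp += 1
        else:
            if expected == 0:
                tn += 1
            else:
                fn += 1
    return CallMetrics(tp, tn, fp, fn)


def roc_points(
    scores: Sequence[float], labels: Sequence[bool]
) -> list[tuple[float, float]]:
    """ROC staircase (FPR, TPR) over all score thresholds, (0,0) to (1,1).

    ``labels`` marks the truly changed clusters; a cluster is predicted
    positive when its score is >= the threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative truth label")
    order = np.argsort(-scores, kind="stable")
    pts = [(0.0, 0.0)]
    tp = fp = 0
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    for i in range(len(order)):
        if sorted_labels[i]:
            tp += 1
        else:
            fp += 1
        if i + 1 == len(order) or sorted_scores[i + 1] != sorted_scores[i]:
            pts.append((fp / n_neg, tp / n_pos))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def roc_auc(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under an ROC staircase."""
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    return float(np.trapezoid(ys, xs))
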