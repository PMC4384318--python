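"""Median normalization of per-primer log2 ratios.

For each primer the raw ratio is ``r_i = log2(C_Si / C_Ci)``; the panel-wide
median ``r~`` is subtracted to give the normalized ratio ``x_i = r_i - r~``.
The median is a robust estimate of the unchanged (diploid-vs-diploid)
baseline provided fewer than half of all primers sit in CNV-affected
regions.  The median is taken over the WHOLE comparison, never per cluster.

Zero counts make the ratio undefined; a continuity correction of 0.5 is
added to any count that is exactly zero (that side only) so that primers in
homozygous deletions — the most informative ones — stay in the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_counts import CountTable


@dataclass(frozen=True)
class NormalizationResult:
    """Summary of one normalization pass.

    Attributes
    ----------
    global_median : float
        The panel-wide median raw log2 ratio ``r~``.
    n_used : int
        Number of primers entering the median.
    n_zero_adjusted : int
        Primers where a zero count received the 0.5 continuity correction.
    """

    global_median: float
    n_used: int
    n_zero_adjusted: int


def raw_log2_ratio(c_sample: float, c_control: float) -> float:
    """log2(sample/control) for strictly positive counts."""
    if c_sample < 0 or c_control < 0:
        raise ValueError("counts must be non-negative")
    if c_sample == 0 or c_control == 0:
        raise ValueError("zero count: apply the continuity correction first")
    return math.log2(c_sample / c_control)


def normalize(table: CountTable) -> tuple[CountTable, NormalizationResult]:
    """Fill ``r`` and ``x`` for every primer in *table* (in place).

    Returns the table and a :class:`NormalizationResult`.  After the call the
    median of all ``x_i`` is zero (up to the even-n median convention: mean
    of the two central values).
    """
    if len(table) == 0:
        raise ValueError("cannot normalize an empty table")
    n_zero = 0
    for p in table:
        c_s, c_c = p.c_sample, p.c_control
        if c_s == 0 or c_c == 0:
            n_zero += 1
            c_s = c_s or 0.5
            c_c = c_c or 0.5
        p.r = raw_log2_ratio(c_s, c_c)
    r_tilde = float(np.median([p.r for p in table]))
    for p in table:
        p.x = p.r - r_tilde
    return table, NormalizationResult(r_tilde, len(table), n_zero)
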