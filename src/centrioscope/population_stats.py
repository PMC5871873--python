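"""Per-cell and per-line statistics for centriole number and length screens.

A mitotic cell is *amplified* when it carries more than four centrioles
and a centriole is *overly long* when it measures strictly more than
500 nm (twice the centrin-measured length of a normal centriole).  The
per-line outputs mirror a screening bar graph: percentage of amplified
cells, percentage of cells with at least one overly long centriole,
pooled mean centriole length and the variance-to-mean ratio (VMR) of the
pooled lengths.  Cut-offs for calling a line defective are derived from
control (non-cancerous) lines as mean + 2·sd of their per-line
percentages; a Pearson chi-square test probes whether amplification and
over-elongation co-occur more often than independence predicts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .image_model import CellRecord


@dataclass(frozen=True)
class CutoffModel:
    """A defect-calling cut-off derived from control lines.

    The mean and sd of the control percentages are rounded to integer
    percent (the precision at which screen percentages are reported)
    before combining, so ``cutoff = round(mean) + 2·round(sd)``.
    """

    control_values: tuple[float, ...]
    mean: float
    sd: float
    cutoff: float


@dataclass(frozen=True)
class LineSummary:
    """Per-cell-line statistics over a set of mitotic cell records."""

    line_id: str
    n_cells: int
    pct_amplified: float
    pct_overlong: float
    mean_length_nm: float
    vmr: float
    n_centrioles_measured: int


@dataclass(frozen=True)
class IndependenceResult:
    """Pearson chi-square test of amplification × over-elongation."""

    table: np.ndarray          # 2×2 observed centriole counts
    expected: np.ndarray
    chi2: float
    df: int
    p: float
    observed_pct_overlong: dict[str, float]   # per amplification stratum
    expected_pct_overlong: dict[str, float]


def summarize_cell(
    lengths_nm: Sequence[float], cell_id: str = "", curation_status: str = "auto"
) -> CellRecord:
    """Classify one cell from its centriole length list."""
    return CellRecord(
        cell_id=cell_id, lengths_nm=list(lengths_nm), curation_status=curation_status
    )


def vmr(lengths_nm: Sequence[float], ddof: int = 1) -> float:
    """Variance-to-mean ratio of a length sample, in nm.

    Sample variance (n−1 denominator by default) divided by the mean; a
    dispersion index that is degree-1 homogeneous under rescaling.
    """
    x = np.asarray(lengths_nm, dtype=np.float64)
    if x.size < 2:
        raise ValueError("VMR requires at least 2 values")
    m = x.mean()
    if m <= 0:
        raise ValueError("VMR requires a positive mean")
    return float(x.var(ddof=ddof) / m)


def _round_half_up(x: float) -> float:
    return math.floor(x + 0.5)


def control_cutoff(control_pcts: Sequence[float]) -> CutoffModel:
    """Defect cut-off from control-line percentages: mean + 2·sd.

    With controls averaging 7% ± 3 the amplification cut-off is 13%;
    with 1% ± 2 the over-elongation cut-off is 5%.
    """
    x = np.asarray(control_pcts, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 control lines")
    mean = _round_half_up(float(x.mean()))
    sd = _round_half_up(float(x.std(ddof=1)))
    return CutoffModel(
        control_values=tuple(float(v) for v in x),
        mean=mean,
        sd=sd,
        cutoff=mean + 2 * sd,
    )


def summarize_line(
    records: Sequence[CellRecord], line_id: str = "", per_cell_mean: bool = False
) -> LineSummary:
    """Aggregate cell records of one line.

    ``pct_overlong`` is the percentage of cells containing at least one
    overly long centriole.  Length statistics pool all measured
    centrioles by default; ``per_cell_mean=True`` instead averages
    per-cell mean lengths.
    """
    if not records:
        raise ValueError("no records")
    n = len(records)
    pct_amp = 100.0 * sum(r.amplified for r in records) / n
    pct_over = 100.0 * sum(r.n_overlong >= 1 for r in records) / n
    pooled = [v for r in records for v in r.lengths_nm]
    if per_cell_mean:
        cell_means = [float(np.mean(r.lengths_nm)) for r in records if r.lengths_nm]
        mean_len = float(np.mean(cell_means)) if cell_means else float("nan")
    else:
        mean_len = float(np.mean(pooled)) if pooled else float("nan")
    line_vmr = vmr(pooled) if len(pooled) >= 2 and np.mean(pooled) > 0 else 0.0
    return LineSummary(
        line_id=line_id,
        n_cells=n,
        pct_amplified=pct_amp,
        pct_overlong=pct_over,
        mean_length_nm=mean_len,
        vmr=line_vmr,
        n_centrioles_measured=len(pooled),
    )


def independence_test(
    cells: Iterable[tuple[bool, int, int]], yates: bool = False
) -> IndependenceResult:
    """Chi-square test of centriole over-elongation × cell amplification.

    ``cells`` yields ``(amplified, n_overlong_centrioles, n_centrioles)``
    per cell.  The unit of the test is the centriole: the 2×2 table
    cross-classifies every measured centriole by whether its cell is
    amplified and whether the centriole itself exceeds 500 nm.  Expected
    counts come from the margins; the statistic is Pearson's
    X² = Σ(O−E)²/E with df 1 (optionally Yates-corrected) and the p-value
    is the upper chi-square tail.
    """
    table = np.zeros((2, 2), dtype=np.float64)  # rows: not-amp/amp; cols: normal/overlong
    for amplified, n_over, n_total in cells:
        if n_over > n_total:
            raise ValueError("more overlong centrioles than centrioles")
        r = 1 if amplified else 0
        table[r, 1] += n_over
        table[r, 0] += n_total - n_over
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    if total == 0 or (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate margins in 2×2 table")
    expected = np.outer(row, col) / total
    diff = np.abs(table - expected)
    if yates:
        diff = np.clip(diff - 0.5, 0.0, None)
    chi2 = float((diff ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    obs = {
        "no_amplification": 100.0 * table[0, 1] / row[0],
        "amplification": 100.0 * table[1, 1] / row[1],
    }
    exp = {
        "no_amplification": 100.0 * expected[0, 1] / row[0],
        "amplification": 100.0 * expected[1, 1] / row[1],
    }
    return IndependenceResult(
        table=table, expected=expected, chi2=chi2, df=1, p=p,
        observed_pct_overlong=obs, expected_pct_overlong=exp,
    )


def independence_test_per_cell(
    cells: Iterable[tuple[bool, int, int]], yates: bool = False
) -> IndependenceResult:
    """Per-cell variant: cross-classify cells (amplified × has overlong)."""
    collapsed = [(amp, int(n_over >= 1), 1) for amp, n_over, _ in cells]
    return independence_test(collapsed, yates=yates)


def proportion_z_test(
    x1: int, n1: int, x2: int, n2: int, tail: str = "two-sided"
) -> tuple[float, float]:
    """Pooled two-proportion z test.

    ``tail`` is ``"two-sided"``, ``"larger"`` (p1 > p2) or ``"smaller"``.
    Returns ``(z, p)``.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled <= 0 or pooled >= 1:
        raise ValueError("degenerate pooled proportion")
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    if tail == "two-sided":
        p = 2 * stats.norm.sf(abs(z))
    elif tail == "larger":
        p = stats.norm.sf(z)
    elif tail == "smaller":
        p = stats.norm.cdf(z)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float(z), float(p)
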