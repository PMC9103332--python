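"""Knockdown quantification from band/fluorescence intensity tables.

Target intensities are normalized per replicate to a reference gene
(tubulin-style), the knockdown is summarized as a percent reduction of the
treated group mean relative to control, and the two groups are compared
with a two-sided Mann–Whitney U test (exact null distribution for small
tie-free samples, normal approximation with tie and continuity corrections
otherwise).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

GROUPS = ("control", "treated")
GENES = ("target", "reference")

EXACT_LIMIT = 400  # exact null used when n1*n2 <= this and there are no ties


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the (replicate, group, gene, intensity) long-format contract."""
    required = {"replicate", "group", "gene", "intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"intensity table missing columns {sorted(missing)}")
    bad_group = set(table["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown groups {sorted(bad_group)}")
    bad_gene = set(table["gene"]) - set(GENES)
    if bad_gene:
        raise ValueError(f"unknown genes {sorted(bad_gene)}")
    if (table["intensity"] < 0).any():
        raise ValueError("negative intensities")
    for rep, sub in table.groupby("replicate"):
        genes = sorted(sub["gene"])
        if genes != sorted(GENES):
            raise ValueError(
                f"replicate {rep!r}: needs exactly one target and one "
                f"reference measurement, found {genes}"
            )
        ref = sub.loc[sub["gene"] == "reference", "intensity"].iloc[0]
        if ref <= 0:
            raise ValueError(f"replicate {rep!r}: reference intensity must be > 0")
    return table


def read_table(path) -> pd.DataFrame:
    return validate_table(pd.read_csv(path, sep="\t"))


def relative_levels(table: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate target/reference ratio, with group labels preserved."""
    validate_table(table)
    wide = table.pivot_table(
        index=["replicate", "group"], columns="gene", values="intensity",
        aggfunc="first",
    ).reset_index()
    wide["ratio"] = wide["target"] / wide["reference"]
    return wide[["replicate", "group", "ratio"]]


def percent_reduction(control: Sequence[float], treated: Sequence[float]) -> float:
    """100 * (1 - mean(treated) / mean(control))."""
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if control.size == 0 or treated.size == 0:
        raise ValueError("both groups must be non-empty")
    mc = control.mean()
    if mc <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (1.0 - treated.mean() / mc)


# ---------------------------------------------------------------------------
# Mann–Whitney U


def u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """U for x over y: number of (x_i, y_j) pairs with x_i > y_j, ties 0.5."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def _exact_u_counts(n: int, m: int) -> np.ndarray:
    """Count of arrangements yielding each U value under the tie-free null.

    Uses the classical recurrence c(u; n, m) = c(u-m; n-1, m) + c(u; n, m-1),
    equivalent to enumerating all C(n+m, n) group assignments.
    """
    table: list[list[Optional[np.ndarray]]] = [
        [None] * (m + 1) for _ in range(n + 1)
    ]
    for i in range(n + 1):
        for j in range(m + 1):
            arr = np.zeros(i * j + 1, dtype=float)
            if i == 0 or j == 0:
                arr[0] = 1.0
            else:
                left = table[i - 1][j]   # c(u - j; i-1, j)
                down = table[i][j - 1]   # c(u; i, j-1)
                for u in range(i * j + 1):
                    v = 0.0
                    if u - j >= 0 and u - j < left.size:
                        v += left[u - j]
                    if u < down.size:
                        v += down[u]
                    arr[u] = v
            table[i][j] = arr
    return table[n][m]


@dataclass
class MannWhitneyResult:
    u: float
    p: float
    method: str
    note: Optional[str] = None


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    Exact p-value from the full null distribution of U when the samples are
    tie-free and n1*n2 <= 400 (the small-replicate regime of band-intensity
    experiments); otherwise the normal approximation with tie correction and
    continuity correction.  If every value in both groups is identical the
    test is degenerate and p = 1 is reported with a note.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    u = u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return MannWhitneyResult(u, 1.0, "degenerate",
                                 "all values identical across both groups")
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and n1 * n2 <= EXACT_LIMIT:
        counts = _exact_u_counts(n1, n2)
        total = counts.sum()
        u_int = int(round(u))
        u_min = min(u_int, n1 * n2 - u_int)
        p = min(1.0, 2.0 * counts[: u_min + 1].sum() / total)
        return MannWhitneyResult(u, float(p), "exact")
    # Normal approximation with tie and continuity corrections.
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    mu = n1 * n2 / 2.0
    if sigma2 <= 0:
        return MannWhitneyResult(u, 1.0, "degenerate",
                                 "zero variance under ties")
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * (1.0 - _norm_cdf(z)))
    return MannWhitneyResult(u, p, "normal_approx")


def _norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


# ---------------------------------------------------------------------------
# Summary


@dataclass
class ExpressionSummary:
    control_ratios: list[float]
    treated_ratios: list[float]
    control_mean: float
    control_sd: float
    treated_mean: float
    treated_sd: float
    percent_reduction: float
    u: float
    p: float
    method: str
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_control": len(self.control_ratios),
                "n_treated": len(self.treated_ratios),
                "control_mean": self.control_mean,
                "control_sd": self.control_sd,
                "treated_mean": self.treated_mean,
                "treated_sd": self.treated_sd,
                "percent_reduction": self.percent_reduction,
                "mann_whitney_u": self.u,
                "p_value": self.p,
                "method": self.method,
                "notes": self.notes,
            },
            indent=2,
        )


def summarize(table: pd.DataFrame) -> ExpressionSummary:
    """Full knockdown summary from a long-format intensity table."""
    ratios = relative_levels(table)
    ctl = ratios.loc[ratios["group"] == "control", "ratio"].to_numpy()
    trt = ratios.loc[ratios["group"] == "treated", "ratio"].to_numpy()
    if ctl.size == 0 or trt.size == 0:
        raise ValueError("need at least one replicate in each group")
    mw = mann_whitney(trt, ctl)
    notes = [mw.note] if mw.note else []
    return ExpressionSummary(
        control_ratios=ctl.tolist(),
        treated_ratios=trt.tolist(),
        control_mean=float(ctl.mean()),
        control_sd=float(ctl.std(ddof=1)) if ctl.size > 1 else 0.0,
        treated_mean=float(trt.mean()),
        treated_sd=float(trt.std(ddof=1)) if trt.size > 1 else 0.0,
        percent_reduction=percent_reduction(ctl, trt),
        u=mw.u,
        p=mw.p,
        method=mw.method,
        notes=notes,
    )
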