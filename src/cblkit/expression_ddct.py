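"""Relative qPCR expression by the comparative-Ct (Livak 2^-ddCt) method.

Per replicate, dCt = Ct_target - Ct_reference pairs the target gene with
the reference gene measured in the same (condition, timepoint,
replicate).  ddCt subtracts the calibrator condition's mean dCt for the
same gene, and the relative quantity is RQ = 2^-ddCt, so log2(RQ) =
-ddCt exactly.  Replicate scatter is summarized as the standard error of
dCt on the cycle scale, with RQ error bars 2^-(ddCt +/- SE); significance
comes from a two-sided two-sample t-test of replicate dCt against the
calibrator's replicate dCt (the method's standard companion test;
flagged at 0.05 and 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

REQUIRED_COLUMNS = ("gene", "condition", "timepoint", "replicate", "ct")

#: Acceptable primer efficiency window, percent, inclusive.
EFFICIENCY_RANGE = (90.0, 105.0)

__all__ = [
    "CtTable",
    "ExpressionResult",
    "relative_expression",
    "results_to_frame",
    "primer_efficiency_filter",
    "EFFICIENCY_RANGE",
]


@dataclass(frozen=True)
class CtTable:
    """Long-format replicate Ct measurements plus the analysis anchors.

    ``data`` columns: gene, condition, timepoint, replicate, ct.  The
    reference gene must be measured in every (condition, timepoint) with
    the same replicate indices as each target; Ct values must lie in the
    open interval (0, 45) cycles.
    """

    data: pd.DataFrame
    reference_gene: str
    calibrator_condition: str

    def __post_init__(self) -> None:
        missing = set(REQUIRED_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        ct = self.data["ct"]
        if not ((ct > 0) & (ct < 45)).all():
            raise ValueError("Ct values must lie in (0, 45) cycles")
        if self.reference_gene not in set(self.data["gene"]):
            raise ValueError(f"reference gene {self.reference_gene!r} not in table")
        if self.calibrator_condition not in set(self.data["condition"]):
            raise ValueError(
                f"calibrator condition {self.calibrator_condition!r} not in table"
            )


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    condition: str
    timepoint: str
    delta_ct: tuple[float, ...]  # per replicate
    delta_delta_ct: float
    rq: float
    se: Optional[float]  # SE of replicate dCt; None when r < 2
    rq_low: Optional[float]  # 2^-(ddCt + SE)
    rq_high: Optional[float]  # 2^-(ddCt - SE)
    p_value: Optional[float]
    significance: Optional[float]  # None | 0.05 | 0.01


def _delta_ct_replicates(
    df: pd.DataFrame, gene: str, condition, timepoint, reference_gene: str
) -> np.ndarray:
    sel = (df["condition"] == condition) & (df["timepoint"] == timepoint)
    target = df[sel & (df["gene"] == gene)].set_index("replicate")["ct"]
    ref = df[sel & (df["gene"] == reference_gene)].set_index("replicate")["ct"]
    if target.empty:
        raise ValueError(f"no Ct rows for {gene!r} at ({condition!r}, {timepoint!r})")
    if not set(target.index) <= set(ref.index):
        raise ValueError(
            f"reference gene missing replicates for ({condition!r}, {timepoint!r})"
        )
    return (target - ref.loc[target.index]).to_numpy(dtype=float)


def _calibrator_delta_ct(
    df: pd.DataFrame, gene: str, timepoint, table: CtTable
) -> np.ndarray:
    """Calibrator dCt replicates for a gene: same timepoint when measured
    there, otherwise the calibrator condition pooled over its timepoints."""
    calib = df[(df["condition"] == table.calibrator_condition) & (df["gene"] == gene)]
    if timepoint in set(calib["timepoint"]):
        return _delta_ct_replicates(
            df, gene, table.calibrator_condition, timepoint, table.reference_gene
        )
    out = []
    for tp in sorted(set(calib["timepoint"]), key=str):
        out.append(_delta_ct_replicates(
            df, gene, table.calibrator_condition, tp, table.reference_gene
        ))
    if not out:
        raise ValueError(f"no calibrator measurements for gene {gene!r}")
    return np.concatenate(out)


def relative_expression(table: CtTable) -> list[ExpressionResult]:
    """2^-ddCt relative expression for every target (gene, condition, timepoint)."""
    df = table.data
    results = []
    targets = df[df["gene"] != table.reference_gene]
    for (gene, condition, timepoint), _ in targets.groupby(
        ["gene", "condition", "timepoint"], sort=True
    ):
        dct = _delta_ct_replicates(df, gene, condition, timepoint, table.reference_gene)
        calib_dct = _calibrator_delta_ct(df, gene, timepoint, table)
        ddct = float(dct.mean() - calib_dct.mean())
        rq = float(2.0 ** (-ddct))
        r = len(dct)
        if r >= 2:
            se = float(dct.std(ddof=1) / np.sqrt(r))
            rq_low = float(2.0 ** (-(ddct + se)))
            rq_high = float(2.0 ** (-(ddct - se)))
        else:
            se = rq_low = rq_high = None
        is_calibrator_row = (
            condition == table.calibrator_condition
            and np.array_equal(dct, calib_dct)
        )
        if r >= 2 and len(calib_dct) >= 2 and not is_calibrator_row:
            if dct.std(ddof=1) == 0.0 and calib_dct.std(ddof=1) == 0.0:
                # degenerate noiseless replicates: the test reduces to an
                # exact comparison of means
                p = 1.0 if dct.mean() == calib_dct.mean() else 0.0
            else:
                p = float(ttest_ind(dct, calib_dct).pvalue)
            significance = 0.01 if p < 0.01 else (0.05 if p < 0.05 else None)
        else:
            p = significance = None
        results.append(ExpressionResult(
            gene=gene, condition=condition, timepoint=timepoint,
            delta_ct=tuple(float(x) for x in dct),
            delta_delta_ct=ddct, rq=rq, se=se,
            rq_low=rq_low, rq_high=rq_high,
            p_value=p, significance=significance,
        ))
    return results


def results_to_frame(results: list[ExpressionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "gene": r.gene, "condition": r.condition, "timepoint": r.timepoint,
            "n_replicates": len(r.delta_ct), "delta_delta_ct": r.delta_delta_ct,
            "rq": r.rq, "se_delta_ct": r.se, "rq_low": r.rq_low, "rq_high": r.rq_high,
            "p_value": r.p_value,
            "significance": {None: "", 0.05: "*", 0.01: "**"}[r.significance],
        })
    return pd.DataFrame(rows)


def primer_efficiency_filter(eff_table: Mapping[str, float]) -> set[str]:
    """Genes whose primer efficiency lies in the 90-105% window, inclusive."""
    lo, hi = EFFICIENCY_RANGE
    return {gene for gene, eff in eff_table.items() if lo <= eff <= hi}
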