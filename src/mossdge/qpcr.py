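"""qPCR quantification: standard curves, reference stability, ddCt folds.

Relative quantification follows the delta-delta-Ct scheme: per
biological replicate, dCq = Cq(target) - Cq(reference); the
between-condition difference ddCq = dCq(treated) - dCq(control) gives a
fold change of E^(-ddCq) with amplification factor E (2 at 100%
efficiency). Technical replicates are averaged before any
biological-replicate statistics. The external spike-in dilution series
(tenfold steps) yields a standard curve Cq = slope * log10(template) +
intercept whose slope determines the amplification efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class StandardCurve:
    slope: float  # cycles per log10(template)
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Fractional efficiency E; 1.0 means perfect doubling per cycle."""
        if self.slope >= 0:
            return float("nan")
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def valid(self) -> bool:
        return self.slope < 0 and 0 < self.efficiency <= 1.1


def fit_standard_curve(dilutions, cq_values) -> StandardCurve:
    """Least-squares line of Cq on log10(dilution)."""
    d = np.asarray(dilutions, dtype=float)
    c = np.asarray(cq_values, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 dilution points")
    if np.any(d <= 0):
        raise ValueError("dilutions must be positive")
    x = np.log10(d)
    if np.allclose(x, x[0]):
        raise ValueError("dilutions have no variance")
    res = stats.linregress(x, c)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def _tech_averaged(table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates within gene x condition x bio_rep."""
    required = {"gene", "condition", "bio_rep", "cq"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Cq table is missing columns: {sorted(missing)}")
    return (
        table.groupby(["gene", "condition", "bio_rep"], as_index=False)["cq"]
        .mean()
    )


def reference_stability(
    cq_table: pd.DataFrame, candidates: list[str]
) -> pd.DataFrame:
    """Rank candidate reference genes by cross-condition stability.

    The stability score is the standard deviation, across conditions, of
    the replicate-mean Cq; lower is more stable (rank 1).
    """
    avg = _tech_averaged(cq_table[cq_table["gene"].isin(candidates)])
    conditions = sorted(avg["condition"].unique())
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions to assess stability")
    rows = []
    for gene in candidates:
        sub = avg[avg["gene"] == gene]
        per_cond = sub.groupby("condition")["cq"].mean()
        if set(per_cond.index) != set(conditions):
            raise ValueError(
                f"candidate {gene!r} is missing conditions "
                f"{sorted(set(conditions) - set(per_cond.index))}"
            )
        rows.append({"gene": gene, "stability_sd": float(per_cond.std(ddof=1))})
    out = pd.DataFrame(rows).sort_values(
        ["stability_sd", "gene"], kind="stable"
    )
    out["rank"] = range(1, len(out) + 1)
    return out.reset_index(drop=True)


def ddct_fold_change(
    cq_table: pd.DataFrame,
    target: str,
    reference: str,
    control: str = "control",
    treated: str = "treated",
    efficiency: float | None = None,
) -> tuple[float, float]:
    """Fold change of ``target`` relative to ``reference`` (mean, SEM).

    Per biological replicate: ddCq = (Cq_t - Cq_ref)_treated -
    (Cq_t - Cq_ref)_control; fold = E^(-ddCq) with E = 2 unless a
    standard-curve efficiency is supplied (then E = 1 + efficiency).
    The replicate structure must match between target and reference.
    """
    base = 2.0 if efficiency is None else 1.0 + efficiency
    if base <= 1.0:
        raise ValueError("amplification factor must be > 1")
    avg = _tech_averaged(cq_table)

    def dcq(condition: str) -> pd.Series:
        t = avg[(avg["gene"] == target) & (avg["condition"] == condition)]
        r = avg[(avg["gene"] == reference) & (avg["condition"] == condition)]
        t = t.set_index("bio_rep")["cq"]
        r = r.set_index("bio_rep")["cq"]
        if t.empty or not t.index.equals(r.index):
            raise ValueError(
                f"unmatched replicate structure for {target!r} vs "
                f"{reference!r} in condition {condition!r}"
            )
        return t - r

    d_control = dcq(control)
    d_treated = dcq(treated)
    if not d_control.index.equals(d_treated.index):
        raise ValueError("unmatched biological replicates across conditions")
    ddcq = d_treated - d_control
    folds = base ** (-ddcq)
    mean = float(folds.mean())
    sem = float(folds.std(ddof=1) / np.sqrt(len(folds))) if len(folds) > 1 else float("nan")
    return mean, sem
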