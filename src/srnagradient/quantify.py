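"""Expression analytics: 2^-ddCt qPCR quantification, one-way ANOVA,
cross-site trend classification, and miRNA/target anti-correlation.

The qPCR model is the standard relative-quantification scheme for
stem-loop assays: per replicate, dCt = Ct(gene) - Ct(reference gene,
e.g. U6 snRNA), paired by replicate index; ddCt subtracts the mean dCt of
a calibrator condition; fold change = 2^-ddCt.  The replicate SE is
carried on the log2 (dCt) scale and back-transformed asymmetrically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

TREND_CLASSES = ("monotone_down", "monotone_up", "peak", "valley", "flat")


@dataclass
class QpcrMeasurement:
    """Replicate Ct values of one gene and of the reference, per condition."""

    gene: str
    gene_ct: dict[str, list[float]]  # condition -> replicate Ct
    reference_ct: dict[str, list[float]]

    def __post_init__(self) -> None:
        for cond, cts in self.gene_ct.items():
            ref = self.reference_ct.get(cond)
            if ref is None:
                raise ValueError(f"missing reference Ct for condition {cond!r}")
            if len(ref) != len(cts):
                raise ValueError(f"replicate count mismatch in condition {cond!r}")
            for v in list(cts) + list(ref):
                if not (math.isfinite(v) and v > 0):
                    raise ValueError(f"invalid Ct value {v!r} in {cond!r}")


@dataclass
class QpcrResult:
    gene: str
    condition: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float
    se_log2: float  # SE of ddCt (log2-fold scale)
    fold_low: float
    fold_high: float
    anova_p: float = float("nan")


def _sem(values: Sequence[float]) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def ddct(meas: QpcrMeasurement, calibrator: str,
         paired: bool = True) -> list[QpcrResult]:
    """Relative expression per condition by the 2^-ddCt method.

    Replicate dCt values are paired by index (plate-paired) unless
    ``paired=False``, in which case condition means are differenced.  The
    calibrator condition has fold change exactly 1.  An across-condition
    one-way ANOVA p-value on the replicate dCt values is attached to every
    result.
    """
    if calibrator not in meas.gene_ct:
        raise ValueError(f"calibrator condition {calibrator!r} absent")
    dct: dict[str, list[float]] = {}
    for cond, cts in meas.gene_ct.items():
        ref = meas.reference_ct[cond]
        if paired:
            dct[cond] = [g - r for g, r in zip(cts, ref)]
        else:
            mean_ref = float(np.mean(ref))
            dct[cond] = [g - mean_ref for g in cts]
    cal_mean = float(np.mean(dct[calibrator]))
    cal_sem = _sem(dct[calibrator])
    _, p = anova_1way(list(dct.values()))
    results = []
    for cond, values in dct.items():
        mean = float(np.mean(values))
        ddc = mean - cal_mean
        if cond == calibrator:
            ddc = 0.0  # exact by definition
            se = cal_sem
        else:
            se = math.sqrt(_sem(values) ** 2 + cal_sem ** 2)
        fold = 2.0 ** (-ddc)
        results.append(QpcrResult(
            meas.gene, cond, mean, ddc, fold, se,
            fold_low=2.0 ** (-(ddc + se)), fold_high=2.0 ** (-(ddc - se)),
            anova_p=p,
        ))
    return results


def ddct_from_table(table: pd.DataFrame, calibrator: str,
                    paired: bool = True) -> pd.DataFrame:
    """ddCt over a long-format Ct table.

    Columns: gene, condition, replicate, ct, is_reference (truthy marks
    the reference gene rows, e.g. U6).  One output row per gene x
    condition.
    """
    ref_rows = table[table["is_reference"].astype(bool)]
    gene_rows = table[~table["is_reference"].astype(bool)]
    reference_ct = {
        cond: grp.sort_values("replicate")["ct"].tolist()
        for cond, grp in ref_rows.groupby("condition")
    }
    out = []
    for gene, grp in gene_rows.groupby("gene", sort=False):
        gene_ct = {
            cond: g.sort_values("replicate")["ct"].tolist()
            for cond, g in grp.groupby("condition")
        }
        meas = QpcrMeasurement(gene, gene_ct,
                               {c: reference_ct[c] for c in gene_ct})
        for res in ddct(meas, calibrator, paired=paired):
            out.append({
                "gene": res.gene, "condition": res.condition,
                "delta_ct": res.delta_ct, "delta_delta_ct": res.delta_delta_ct,
                "fold_change": res.fold_change, "se_log2": res.se_log2,
                "fold_low": res.fold_low, "fold_high": res.fold_high,
                "anova_p": res.anova_p,
            })
    return pd.DataFrame(out)


def anova_1way(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Degenerate input (zero variance both within and between groups)
    returns F = 0, p = 1 by convention.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrays)
    if not math.isfinite(f):
        return float("inf"), 0.0
    return float(f), float(p)


@dataclass
class TrendProfile:
    name: str
    values: tuple[float, float, float]
    trend_class: str = field(init=False, default="flat")


def classify_trend(values: Sequence[float], rel_tolerance: float = 0.1,
                   name: str = "") -> TrendProfile:
    """Classify a 3-point ordered profile (e.g. wet -> dry sites).

    A step is a change only if it exceeds ``rel_tolerance`` relative to
    the step's start value.  down/down -> monotone_down, up/up ->
    monotone_up, up/down -> peak, down/up -> valley, flat/flat -> flat; a
    flat step next to a directional one inherits that direction.
    """
    if len(values) != 3:
        raise ValueError("exactly 3 ordered values required")
    v = tuple(float(x) for x in values)
    if any(x < 0 for x in v):
        raise ValueError("negative expression values")

    def step(a: float, b: float) -> int:
        if a == b == 0:
            return 0
        base = a if a > 0 else max(a, b)
        if abs(b - a) <= rel_tolerance * base:
            return 0
        return 1 if b > a else -1

    d1, d2 = step(v[0], v[1]), step(v[1], v[2])
    if d1 == d2 == 0:
        cls = "flat"
    elif d1 >= 0 and d2 >= 0:
        cls = "monotone_up"
    elif d1 <= 0 and d2 <= 0:
        cls = "monotone_down"
    elif d1 > 0 > d2:
        cls = "peak"
    else:
        cls = "valley"
    profile = TrendProfile(name, v)
    profile.trend_class = cls
    return profile


def classify_trend_table(matrix: pd.DataFrame, order: Sequence[str],
                         rel_tolerance: float = 0.1) -> pd.DataFrame:
    """Trend class per row of an expression matrix, columns in site order."""
    rows = []
    for name, row in matrix.iterrows():
        profile = classify_trend([row[c] for c in order], rel_tolerance, str(name))
        rows.append({"name": name,
                     **{c: row[c] for c in order},
                     "trend_class": profile.trend_class})
    return pd.DataFrame(rows)


def anticorrelation(mirna_series: Sequence[float],
                    target_series: Sequence[float]) -> tuple[float, str]:
    """Pearson r between miRNA and target expression, with a sign verdict.

    Returns (r, verdict) where verdict is "negative", "non-negative", or
    "undefined" when either series has zero variance.
    """
    x = np.asarray(mirna_series, dtype=float)
    y = np.asarray(target_series, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("series must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), "undefined"
    r, _ = stats.pearsonr(x, y)
    return float(r), ("negative" if r < 0 else "non-negative")
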