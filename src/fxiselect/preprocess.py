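"""Cohort exclusions, normality transforms, stratification, descriptives.

Exclusion rules: subjects with active malignancy and subjects with severe
FXI deficiency (FXI:C < 20%) are removed before any modelling. Protein
columns are transformed towards normality by choosing, per protein, the
transform among {identity, sqrt, ln} that minimizes absolute skewness.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: FXI:C stratum bounds, % activity: low < 70, normal 70-150 (inclusive), high > 150
STRATUM_LOW_BOUND = 70.0
STRATUM_HIGH_BOUND = 150.0
SEVERE_DEFICIENCY_CUTOFF = 20.0

TRANSFORMS = ("identity", "sqrt", "ln")


@dataclass
class TransformLog:
    """Per-protein transform choice and the shift constant applied."""

    choices: dict[str, str] = field(default_factory=dict)
    shifts: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"choices": self.choices, "shifts": self.shifts},
                indent=2,
                sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TransformLog":
        d = json.loads(Path(path).read_text())
        return cls(choices=d["choices"], shifts=d["shifts"])


def apply_exclusions(cohort: pd.DataFrame) -> pd.DataFrame:
    """Drop active-malignancy rows, FXI:C < 20% rows and rows missing FXI:C.

    Idempotent. Exclusion counts are logged and stored in
    ``result.attrs["exclusions"]``.
    """
    if "fxi_c" not in cohort or "active_malignancy" not in cohort:
        raise KeyError("cohort must contain 'fxi_c' and 'active_malignancy'")
    n0 = len(cohort)
    missing = cohort["fxi_c"].isna()
    if missing.any():
        warnings.warn(
            f"dropping {int(missing.sum())} subjects with missing FXI:C",
            stacklevel=2,
        )
    kept = cohort[~missing]
    malignant = kept["active_malignancy"].astype(bool)
    kept = kept[~malignant]
    severe = kept["fxi_c"] < SEVERE_DEFICIENCY_CUTOFF
    kept = kept[~severe]
    counts = {
        "input": n0,
        "missing_fxi_c": int(missing.sum()),
        "active_malignancy": int(malignant.sum()),
        "severe_deficiency": int(severe.sum()),
        "retained": len(kept),
    }
    logger.info("exclusions: %s", counts)
    out = kept.copy()
    out.attrs["exclusions"] = counts
    return out


def _candidate(x: np.ndarray, name: str) -> tuple[np.ndarray, float]:
    """Transformed column and the shift constant used (0 when none needed)."""
    if name == "identity":
        return x, 0.0
    shift = 0.0
    if x.min() <= 0:
        shift = -x.min() + 1.0
    xs = x + shift
    if name == "sqrt":
        return np.sqrt(xs), shift
    return np.log(xs), shift


def normality_transform(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, TransformLog]:
    """Per protein, pick the |skewness|-minimizing transform.

    Missing entries are median-imputed per protein first. Constant columns
    keep the identity transform with a warning.
    """
    out = {}
    log = TransformLog()
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        if np.isnan(x).any():
            med = np.nanmedian(x)
            x = np.where(np.isnan(x), med, x)
        if np.ptp(x) == 0 or len(x) < 3:
            warnings.warn(f"constant column {col!r}: identity kept", stacklevel=2)
            out[col] = x
            log.choices[col] = "identity"
            log.shifts[col] = 0.0
            continue
        best_name, best_vals, best_shift, best_skew = None, None, 0.0, np.inf
        for name in TRANSFORMS:
            vals, shift = _candidate(x, name)
            sk = abs(stats.skew(vals))
            if sk < best_skew:
                best_name, best_vals, best_shift, best_skew = name, vals, shift, sk
        out[col] = best_vals
        log.choices[col] = best_name
        log.shifts[col] = best_shift
    return pd.DataFrame(out, index=matrix.index), log


def stratify_fxi(values) -> pd.Series:
    """Label FXI:C values: low (< 70), normal (70-150 inclusive), high (> 150)."""
    v = pd.Series(values, dtype=float)
    if (v <= 0).any() or v.isna().any():
        raise ValueError("nonpositive or missing FXI:C; apply exclusions first")
    labels = pd.Series("normal", index=v.index)
    labels[v < STRATUM_LOW_BOUND] = "low"
    labels[v > STRATUM_HIGH_BOUND] = "high"
    return labels


def _is_flag(s: pd.Series) -> bool:
    vals = s.dropna().unique()
    return s.dtype == bool or set(np.asarray(vals).tolist()) <= {0, 1}


def baseline_table(
    cohort: pd.DataFrame,
    strata: pd.Series,
    columns: list[str] | None = None,
    skew_cutoff: float = 1.0,
) -> pd.DataFrame:
    """Stratified descriptive table.

    Flags are shown as ``% (n)``; continuous variables as ``mean ± SD`` when
    roughly normal (|skew| <= ``skew_cutoff``) else ``median (Q1/Q3)``.
    """
    if columns is None:
        columns = [
            c
            for c in cohort.columns
            if c not in ("subject_id", "timepoint") and cohort[c].dtype != object
        ]
    order = ["low", "normal", "high"]
    rows = {}
    for col in columns:
        s = cohort[col]
        row = {}
        for stratum in order:
            sub = s[strata == stratum]
            if len(sub) == 0:
                warnings.warn(f"empty stratum {stratum!r}", stacklevel=2)
                row[stratum] = "NA"
                continue
            if _is_flag(s):
                n = int(sub.sum())
                row[stratum] = f"{100.0 * n / len(sub):.1f}% ({n})"
            else:
                vals = sub.astype(float)
                if abs(stats.skew(vals)) <= skew_cutoff:
                    row[stratum] = f"{vals.mean():.1f} ± {vals.std(ddof=1):.2f}"
                else:
                    q1, med, q3 = vals.quantile([0.25, 0.5, 0.75])
                    row[stratum] = f"{med:.2f} ({q1:.2f}/{q3:.2f})"
        rows[col] = row
    table = pd.DataFrame(rows).T
    counts = strata.value_counts()
    table.columns = pd.Index(
        [f"{s} (n={int(counts.get(s, 0))})" for s in order], name="stratum"
    )
    return table


def paired_fxi_test(
    acute: pd.Series, followup: pd.Series, pairing: list | None = None
) -> dict:
    """Classical paired t-test of FXI:C between timepoints.

    ``acute``/``followup`` are indexed by subject id (or ``pairing`` gives
    the subjects to align on). Returns t, two-sided p, df and per-timepoint
    means of the complete pairs.
    """
    a = pd.Series(acute, dtype=float)
    f = pd.Series(followup, dtype=float)
    if pairing is not None:
        a = a.loc[pairing]
        f = f.loc[pairing]
    else:
        common = a.index.intersection(f.index)
        a, f = a.loc[common], f.loc[common]
    mask = a.notna() & f.notna()
    a, f = a[mask], f[mask]
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 complete pairs")
    diff = a.to_numpy() - f.to_numpy()
    if np.allclose(diff, diff[0]) and diff.std(ddof=1) == 0:
        if diff[0] == 0:
            return {
                "t": 0.0,
                "p": 1.0,
                "df": n - 1,
                "mean_acute": float(a.mean()),
                "mean_followup": float(f.mean()),
                "n_pairs": n,
            }
        raise ValueError("zero variance of nonzero paired differences")
    t, p = stats.ttest_rel(a, f)
    return {
        "t": float(t),
        "p": float(p),
        "df": n - 1,
        "mean_acute": float(a.mean()),
        "mean_followup": float(f.mean()),
        "n_pairs": n,
    }
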