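"""Detection-rate statistics for slow-change validation experiments.

Observer responses arrive as a coder-filled CSV (one row per trial): a
yes/no "noticed anything" answer plus boolean codes — assigned by a human
reading the free-text description — for whether the slow change, each quick
change, or an unidentifiable change was reported.  This module ingests those
tables, aggregates them into per-condition detection counts, and computes
the tests used to validate stimulus batteries: detection proportions, a
two-proportion z test, a paired t test, a one-way repeated-measures ANOVA,
and a Pearson correlation.

Free-text coding itself is deliberately manual and out of scope: the coding
criterion ("any mention of a change in the slowly changing element counts")
requires judgment a program should not fake.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateError

QUICK_COLUMNS = ("quick1_detected", "quick2_detected", "quick3_detected")

RESPONSE_COLUMNS = (
    "participant_id",
    "trial_index",
    "stimulus_id",
    "noticed_any",
    "free_text",
    "slow_detected",
    *QUICK_COLUMNS,
    "unidentified",
)


def _as_bool(series: pd.Series) -> pd.Series:
    """Coerce yes/no/true/false/1/0 (or blank = missing) to nullable booleans."""
    mapping = {
        "yes": True, "y": True, "true": True, "1": True, 1: True, True: True,
        "no": False, "n": False, "false": False, "0": False, 0: False, False: False,
    }

    def conv(v):
        if pd.isna(v) or v == "":
            return pd.NA
        key = v.strip().lower() if isinstance(v, str) else v
        if key not in mapping:
            raise ValueError(f"cannot interpret {v!r} as yes/no")
        return mapping[key]

    return series.map(conv).astype("boolean")


def load_responses(path: str | Path) -> pd.DataFrame:
    """Load and validate a coded-response CSV.

    Quick-change columns may be blank where a stimulus has fewer than three
    quick changes; blank cells are "no opportunity", not "not detected".
    A detection code set on a trial whose ``noticed_any`` is "no" is a
    coding inconsistency and rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("participant_id", "trial_index", "stimulus_id", "noticed_any") if c not in df.columns]
    if missing:
        raise ValueError(f"response table is missing columns: {missing}")
    for col in ("noticed_any", "slow_detected", "unidentified", *QUICK_COLUMNS):
        if col in df.columns:
            df[col] = _as_bool(df[col])
        else:
            df[col] = pd.array([pd.NA] * len(df), dtype="boolean")
    if "free_text" not in df.columns:
        df["free_text"] = ""

    code_cols = ["slow_detected", "unidentified", *QUICK_COLUMNS]
    coded = df[code_cols].fillna(False).any(axis=1)
    bad = coded & ~df["noticed_any"].fillna(False)
    if bad.any():
        rows = df.index[bad].tolist()
        raise ValueError(
            f"rows {rows}: a change is coded as detected although noticed_any is 'no'"
        )
    return df


def aggregate_detection(df: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Collapse trials into a detection table grouped by ``by`` columns.

    Quick-change opportunities are counted per trial as the number of
    non-blank quick columns, so marginal counts are conserved under any
    regrouping.
    """
    work = df.copy()
    work["n_trials"] = 1
    work["n_slow_detected"] = work["slow_detected"].fillna(False).astype(int)
    work["n_quick_change_opportunities"] = sum(
        work[c].notna().astype(int) for c in QUICK_COLUMNS
    )
    work["n_quick_detected"] = sum(
        work[c].fillna(False).astype(int) for c in QUICK_COLUMNS
    )
    out = (
        work.groupby(by, dropna=False)[
            ["n_trials", "n_slow_detected", "n_quick_change_opportunities", "n_quick_detected"]
        ]
        .sum()
        .reset_index()
    )
    return out


def trial_position_rates(df: pd.DataFrame) -> pd.DataFrame:
    """Slow-change detection rate at each trial position.

    Each participant contributes at most one trial per position; duplicate
    (participant, position) rows are rejected rather than double-counted.
    """
    dup = df.duplicated(subset=["participant_id", "trial_index"])
    if dup.any():
        raise ValueError(
            "a participant appears more than once at one trial position: "
            f"rows {df.index[dup].tolist()}"
        )
    return aggregate_detection(df, by=["trial_index"])


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def detection_proportion(detected: int, total: int) -> float:
    """detected / total; raises on an empty denominator."""
    if total <= 0:
        raise DegenerateError("detection proportion undefined for total = 0")
    if not 0 <= detected <= total:
        raise ValueError(f"need 0 <= detected <= total, got {detected}/{total}")
    return detected / total


def round_proportion(p: float, ndigits: int = 3) -> float:
    """Reporting helper: proportions are conventionally printed to 3 decimals."""
    return round(p, ndigits)


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-sample z test for proportions; two-sided p.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with the pooled p = (x1+x2)/(n1+n2).
    """
    p1 = detection_proportion(x1, n1)
    p2 = detection_proportion(x2, n2)
    pooled = (x1 + x2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        raise DegenerateError(
            f"pooled proportion {pooled} is degenerate; the z statistic is undefined"
        )
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def paired_t(a, b, tail: str = "two") -> tuple[float, int, float]:
    """Paired t test on the differences ``a - b``; df = n - 1.

    ``tail="one"`` reports the one-sided p in the direction of the observed
    effect (i.e. half the two-sided p); both conventions are exposed because
    adjacent-vs-distant color-pair comparisons are directional by design.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired_t needs two equal-length vectors with n >= 2")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            # identical vectors carry no evidence of a difference
            return 0.0, a.size - 1, 1.0 if tail == "two" else 0.5
        raise DegenerateError("zero variance of paired differences")
    res = sps.ttest_rel(a, b)
    t = float(res.statistic)
    df = a.size - 1
    p = float(res.pvalue)
    if tail == "one":
        p /= 2.0
    return t, df, p


def rm_anova_oneway(values) -> tuple[float, int, int, float]:
    """One-way repeated-measures ANOVA on a complete subject x level matrix.

    F = MS_level / MS_residual with the level-by-subject interaction as the
    error term; df = (k - 1, (k - 1)(n - 1)).  For a 5-level factor measured
    on 11 subjects this gives df = (4, 40).
    """
    y = np.asarray(values, dtype=np.float64)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need a complete subjects x levels matrix, at least 2 x 2")
    if not np.isfinite(y).all():
        raise ValueError("matrix must be complete (no missing cells)")
    n, k = y.shape
    grand = y.mean()
    ss_level = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subject = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_resid = ss_total - ss_level - ss_subject
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_resid = ss_resid / df2
    if ms_resid <= 1e-300:
        raise DegenerateError("zero residual mean square; F is undefined")
    f = (ss_level / df1) / ms_resid
    p = float(sps.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def pearson_r(x, y) -> tuple[float, float, float]:
    """Sample Pearson correlation with its two-sided p (t approximation,
    df = n - 2).  Returns (r, r^2, p)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson_r needs two equal-length vectors with n >= 3")
    if np.allclose(x.std(), 0.0) or np.allclose(y.std(), 0.0):
        raise DegenerateError("correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def summarize(df: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Detection table plus slow/quick proportions rounded for reporting."""
    table = aggregate_detection(df, by)
    table["slow_proportion"] = [
        round_proportion(detection_proportion(d, t)) if t else np.nan
        for d, t in zip(table["n_slow_detected"], table["n_trials"])
    ]
    table["quick_proportion"] = [
        round_proportion(detection_proportion(d, t)) if t else np.nan
        for d, t in zip(table["n_quick_detected"], table["n_quick_change_opportunities"])
    ]
    return table


def plot_detection_bars(table: pd.DataFrame, label_col: str, out_path: str | Path):
    """Bar chart of slow-change detection proportions per condition (one bar
    per group), in the layout customary for these validation summaries."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(table) + 2, 4))
    ax.bar(table[label_col].astype(str), table["slow_proportion"], color="#4878cf")
    ax.set_ylabel("proportion of slow changes detected")
    ax.set_ylim(0, 1)
    ax.set_xlabel(label_col)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)
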