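"""Class-level population summaries and condition comparisons.

Class percentages use class-specific tested denominators (responders
positive for a class divided by responders tested with that class's probes);
stacked shares renormalize the raw percentages to 100%.  Inflammation
(PGE2) effects use two-tailed paired t-tests per class; genotype effects use
Welch's t-test (one-tailed for heat attenuation, two-tailed for spontaneous
activity).  Holm-Sidak step-down correction is applied across classes.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .classify import CLASSES


class StatsError(ValueError):
    pass


def holm_sidak(pvals: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values.

    For sorted p-values the i-th adjusted value is
    ``1 - (1 - p_(i))**(m - i + 1)`` with running-maximum monotonicity
    enforcement; a single test is returned unchanged.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):  # p == 1 is legitimate (log1p(-1))
        return multipletests(pvals, method="holm-sidak")[1]


def _paired_t(baseline: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    d = post - baseline
    if np.allclose(d, 0.0):
        return 0.0, 1.0  # identical conditions: no evidence by construction
    res = sps.ttest_rel(post, baseline)
    return float(res.statistic), float(res.pvalue)


def paired_condition_test(
    baseline: Mapping[str, Sequence[float]],
    post: Mapping[str, Sequence[float]],
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Two-tailed paired t-test per class, Holm-Sidak adjusted across classes.

    ``baseline`` and ``post`` map class labels to per-cell metric vectors
    paired by position (longitudinally tracked cells).  Classes with fewer
    than ``min_pairs`` complete pairs are skipped with a warning; pairs with
    a missing value are excluded and the exclusion count reported.
    """
    rows = []
    for cls in baseline:
        if cls not in post:
            warnings.warn(f"class {cls}: no post-condition data, skipped", stacklevel=2)
            continue
        b = np.asarray(baseline[cls], dtype=float)
        p = np.asarray(post[cls], dtype=float)
        if b.shape != p.shape:
            raise StatsError(f"class {cls}: baseline/post vectors differ in length")
        ok = np.isfinite(b) & np.isfinite(p)
        n_excluded = int((~ok).sum())
        b, p = b[ok], p[ok]
        if b.size < min_pairs:
            warnings.warn(
                f"class {cls}: only {b.size} complete pairs (<{min_pairs}), skipped",
                stacklevel=2,
            )
            continue
        t, pv = _paired_t(b, p)
        rows.append(
            {
                "class": cls,
                "n_pairs": int(b.size),
                "n_excluded": n_excluded,
                "mean_baseline": float(b.mean()),
                "mean_post": float(p.mean()),
                "t": t,
                "p_raw": pv,
            }
        )
    df = pd.DataFrame(rows, columns=[
        "class", "n_pairs", "n_excluded", "mean_baseline", "mean_post", "t", "p_raw",
    ])
    df["p_adj"] = holm_sidak(df["p_raw"].to_numpy()) if len(df) else []
    return df


def genotype_test(
    wt: Mapping[str, Sequence[float]],
    ko: Mapping[str, Sequence[float]],
    alternative: str = "two-sided",
    min_n: int = 2,
) -> pd.DataFrame:
    """Welch's t-test per class between independent wild-type and knockout groups.

    ``alternative='ko_less'`` tests attenuation in the knockout (one-tailed,
    KO < WT); ``'two-sided'`` is the default.  Welch-Satterthwaite degrees of
    freedom; Holm-Sidak across classes.  Classes with a group smaller than
    ``min_n`` are skipped with a warning.
    """
    if alternative not in ("two-sided", "ko_less"):
        raise StatsError("alternative must be 'two-sided' or 'ko_less'")
    rows = []
    for cls in wt:
        if cls not in ko:
            warnings.warn(f"class {cls}: no knockout data, skipped", stacklevel=2)
            continue
        a = np.asarray(wt[cls], dtype=float)
        b = np.asarray(ko[cls], dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size < min_n or b.size < min_n:
            warnings.warn(f"class {cls}: group size < {min_n}, skipped", stacklevel=2)
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            t, pv = 0.0, 1.0 if alternative == "two-sided" else 0.5
        else:
            res = sps.ttest_ind(
                b, a, equal_var=False,
                alternative="less" if alternative == "ko_less" else "two-sided",
            )
            t, pv = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "class": cls,
                "n_wt": int(a.size),
                "n_ko": int(b.size),
                "mean_wt": float(a.mean()),
                "mean_ko": float(b.mean()),
                "t": t,
                "p_raw": pv,
            }
        )
    df = pd.DataFrame(rows, columns=["class", "n_wt", "n_ko", "mean_wt", "mean_ko", "t", "p_raw"])
    df["p_adj"] = holm_sidak(df["p_raw"].to_numpy()) if len(df) else []
    return df


def class_percentages(
    cells: pd.DataFrame, classes: Sequence[str] = CLASSES
) -> pd.DataFrame:
    """Per-class raw percentage and 100%-renormalized stacked share.

    ``cells`` needs columns ``class_label``, ``responding`` (bool) and
    ``tested_classes`` (iterable of class labels probed for that cell).  The
    raw percentage for class c = responders positive for c / responders
    tested for c; because not every class is tested in every animal these
    need not sum to 100, so stacked shares renormalize them.  Classes with
    zero tested responders are omitted with a warning.
    """
    required = {"class_label", "responding", "tested_classes"}
    if not required <= set(cells.columns):
        raise StatsError(f"cells frame must have columns {sorted(required)}")
    responders = cells[cells["responding"].astype(bool)]
    rows = []
    for cls in classes:
        tested = responders["tested_classes"].map(lambda s, c=cls: c in s)
        n_tested = int(tested.sum())
        if n_tested == 0:
            warnings.warn(f"class {cls}: zero tested responders, omitted", stacklevel=2)
            continue
        n_pos = int(((responders["class_label"] == cls) & tested).sum())
        rows.append({"class": cls, "n_positive": n_pos, "n_tested": n_tested,
                     "pct_raw": 100.0 * n_pos / n_tested})
    df = pd.DataFrame(rows, columns=["class", "n_positive", "n_tested", "pct_raw"])
    total = df["pct_raw"].sum()
    df["share_pct"] = 100.0 * df["pct_raw"] / total if total > 0 else 0.0
    return df


def recruitment_by_temperature(
    heat_responses: pd.DataFrame,
    cells: pd.DataFrame,
    classes: Sequence[str] = CLASSES,
) -> pd.DataFrame:
    """Class x temperature matrix of responsive fractions.

    ``heat_responses`` needs columns ``cell_id``, ``temperature``,
    ``responsive``; ``cells`` maps ``cell_id`` to ``class_label`` (already
    gated to the cheek-responsive population by the caller).  A class with
    no cells yields a row of missing values, not zeros.
    """
    temps = sorted(heat_responses["temperature"].dropna().unique())
    merged = heat_responses.merge(
        cells[["cell_id", "class_label"]], on="cell_id", how="inner"
    )
    mat = pd.DataFrame(index=list(classes), columns=temps, dtype=float)
    for cls in classes:
        sub = merged[merged["class_label"] == cls]
        if sub.empty:
            continue  # leave NaN
        for temp in temps:
            at = sub[sub["temperature"] == temp]
            if len(at):
                mat.loc[cls, temp] = at["responsive"].astype(bool).mean()
    mat.index.name = "class"
    return mat
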