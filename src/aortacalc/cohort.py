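"""Population-level analysis: standard vs extended TAC, prevalence, groups.

The key contrast is between a *standard* cardiac scan, which sees only the
proximal ascending and distal descending aorta (segments 1 and 5), and the
*extended* scan that also covers the distal ascending aorta, the arch and the
proximal descending aorta (segments 2-4).  Subjects split into three groups:

* Group 1 — free of calcium (CAC = 0 and extended TAC = 0)
* Group 2 — detected by the standard method (CAC > 0 or standard TAC > 0)
* Group 3 — reclassification candidates: detected only by the extended scan
  (CAC = 0, standard TAC = 0, extended TAC > 0)

Percentages are reported as nearest integers (half away from zero) to match
printed-table conventions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .framingham import framingham_risk
from .synthcohort import SEGMENT_COLUMNS

__all__ = [
    "round_pct",
    "derive_tac",
    "classify_group",
    "prevalence_by_segment",
    "detection_overlap",
    "lesion_distribution",
    "age_tertile_prevalence",
    "add_framingham_risk",
    "group_comparisons",
]


def round_pct(x) -> np.ndarray | int:
    """Nearest-integer percentage, half away from zero."""
    arr = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return arr.astype(int) if isinstance(arr, np.ndarray) else int(arr)


def derive_tac(df: pd.DataFrame) -> pd.DataFrame:
    """Add ``standard_tac`` (segments 1+5) and ``extended_tac`` (all five)."""
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"missing segment score columns: {missing}")
    out = df.copy()
    out["standard_tac"] = df["tac_s1"] + df["tac_s5"]
    out["extended_tac"] = df[SEGMENT_COLUMNS].sum(axis=1)
    return out


def classify_group(df: pd.DataFrame) -> pd.Series:
    """Group labels 1/2/3 (see module docstring); exhaustive and exclusive."""
    if "standard_tac" not in df.columns:
        df = derive_tac(df)
    g = np.where(
        (df["cac"] == 0) & (df["extended_tac"] == 0),
        1,
        np.where((df["cac"] > 0) | (df["standard_tac"] > 0), 2, 3),
    )
    return pd.Series(g, index=df.index, name="group")


def prevalence_by_segment(df: pd.DataFrame) -> pd.DataFrame:
    """Count and integer percent of subjects with a positive score per segment."""
    if len(df) == 0:
        raise ValueError("empty cohort")
    n = len(df)
    rows = []
    for i, col in enumerate(SEGMENT_COLUMNS, start=1):
        k = int((df[col] > 0).sum())
        rows.append({"segment": i, "n_pos": k, "pct": round_pct(100.0 * k / n)})
    return pd.DataFrame(rows)


def detection_overlap(df: pd.DataFrame) -> dict:
    """Standard-vs-extended detection split, as counts and integer percents of n."""
    df = derive_tac(df)
    n = len(df)
    std = df["standard_tac"] > 0
    arch = (df[["tac_s2", "tac_s3", "tac_s4"]] > 0).any(axis=1)
    out_counts = {
        "extended_pos": int((df["extended_tac"] > 0).sum()),
        "standard_pos": int(std.sum()),
        "only_standard": int((std & ~arch).sum()),
        "only_extended": int((~std & arch).sum()),
        "both": int((std & arch).sum()),
        "cac_pos": int((df["cac"] > 0).sum()),
        "cac_and_extended": int(((df["cac"] > 0) & (df["extended_tac"] > 0)).sum()),
        "neither": int(((df["cac"] == 0) & (df["extended_tac"] == 0)).sum()),
    }
    return {
        "n": n,
        "counts": out_counts,
        "pct": {k: round_pct(100.0 * v / n) for k, v in out_counts.items()},
    }


def lesion_distribution(
    segment_counts: np.ndarray, segment_lengths_cm: np.ndarray
) -> pd.DataFrame:
    """Per-segment lesion totals, shares of the overall total, and counts per cm.

    ``segment_lengths_cm`` is the cohort-average length of each segment.  With
    zero lesions overall the shares are reported as zeros and flagged.
    """
    counts = np.asarray(segment_counts, dtype=float)
    lengths = np.asarray(segment_lengths_cm, dtype=float)
    total = counts.sum()
    if total == 0:
        warnings.warn("no lesions: shares undefined, reported as zeros", stacklevel=2)
        shares = np.zeros(5, dtype=int)
    else:
        shares = round_pct(100.0 * counts / total)
    return pd.DataFrame(
        {
            "segment": np.arange(1, 6),
            "count": counts.astype(int),
            "share_pct": shares,
            "per_cm": np.where(lengths > 0, counts / np.where(lengths > 0, lengths, 1), 0.0),
        }
    )


def age_tertile_prevalence(df: pd.DataFrame) -> pd.DataFrame:
    """Any-segment and per-segment TAC prevalence by empirical age tertile.

    Tertile cut points come from the cohort itself: subjects are stably
    sorted by (age, id) and split into three near-equal groups (sizes differ
    by at most 1), so ties cannot create unbalanced tertiles.
    """
    if len(df) < 3:
        raise ValueError("need at least 3 subjects for tertiles")
    df = derive_tac(df)
    order = df.sort_values(["age", "id"], kind="mergesort").index
    rows = []
    for t, idx in enumerate(np.array_split(np.asarray(order), 3), start=1):
        sub = df.loc[idx]
        row = {
            "tertile": t,
            "n": len(sub),
            "age_min": float(sub["age"].min()),
            "age_max": float(sub["age"].max()),
            "any_pct": round_pct(100.0 * (sub["extended_tac"] > 0).mean()),
        }
        for i, col in enumerate(SEGMENT_COLUMNS, start=1):
            row[f"s{i}_pct"] = round_pct(100.0 * (sub[col] > 0).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def add_framingham_risk(df: pd.DataFrame) -> pd.DataFrame:
    """Add the 10-year Framingham risk (%) column ``frs``."""
    out = df.copy()
    out["frs"] = [
        framingham_risk(
            age=row.age,
            male=bool(row.male),
            total_chol_mmol=row.total_chol_mmol,
            hdl_mmol=row.hdl_mmol,
            sbp_mmhg=row.sbp_mmhg,
            smoker=bool(row.smoker),
            diabetes=bool(row.diabetes),
        )
        for row in df.itertuples()
    ]
    return out


_CATEGORICAL = ["male", "hypertension", "hypercholesterolemia", "smoker", "diabetes"]


def group_comparisons(df: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Three-group comparison report (layout mirrors a stratified table).

    Continuous variables (age, Framingham risk) are compared with one-way
    ANOVA plus Tukey's HSD post-hoc test; categorical variables with a
    chi-square test over the 2x3 table plus pairwise 2x2 chi-square tests
    with a Bonferroni factor of 3.  Groups with fewer than 2 subjects are
    skipped with a warning.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = derive_tac(df)
    if "frs" not in df.columns:
        df = add_framingham_risk(df)
    df = df.assign(group=classify_group(df))
    present = [g for g in (1, 2, 3) if (df["group"] == g).sum() >= 2]
    skipped = [g for g in (1, 2, 3) if g not in present]
    if skipped:
        warnings.warn(f"groups {skipped} have < 2 subjects; comparisons skipped",
                      stacklevel=2)
    report: dict = {
        "group_n": {g: int((df["group"] == g).sum()) for g in (1, 2, 3)},
        "continuous": {},
        "categorical": {},
        "alpha": alpha,
    }
    for var in ("age", "frs"):
        samples = [df.loc[df["group"] == g, var].to_numpy() for g in present]
        entry = {
            "mean": {g: float(s.mean()) for g, s in zip(present, samples)},
            "sd": {g: float(s.std(ddof=1)) for g, s in zip(present, samples)},
        }
        if len(present) >= 2:
            entry["anova_p"] = float(stats.f_oneway(*samples).pvalue)
            tuk = pairwise_tukeyhsd(
                df.loc[df["group"].isin(present), var].to_numpy(),
                df.loc[df["group"].isin(present), "group"].to_numpy(),
                alpha=alpha,
            )
            entry["tukey"] = {
                (int(a), int(b)): {"p": float(p), "reject": bool(r)}
                for (a, b), p, r in zip(
                    [(g1, g2) for i, g1 in enumerate(tuk.groupsunique)
                     for g2 in tuk.groupsunique[i + 1:]],
                    tuk.pvalues,
                    tuk.reject,
                )
            }
        report["continuous"][var] = entry
    for var in _CATEGORICAL:
        if var not in df.columns:
            continue
        counts = {g: int(df.loc[df["group"] == g, var].sum()) for g in (1, 2, 3)}
        entry: dict = {"n_pos": counts}
        table = np.array(
            [[counts[g], report["group_n"][g] - counts[g]] for g in present]
        )
        if (len(present) >= 2 and table.sum(axis=1).min() > 0
                and table.sum(axis=0).min() > 0):
            entry["chi2_p"] = float(stats.chi2_contingency(table).pvalue)
            pairwise = {}
            for i, g1 in enumerate(present):
                for g2 in present[i + 1:]:
                    t2 = np.array([table[present.index(g1)], table[present.index(g2)]])
                    p = float(stats.chi2_contingency(t2).pvalue)
                    pairwise[(g1, g2)] = min(p * 3.0, 1.0)  # Bonferroni, 3 comparisons
            entry["pairwise_bonferroni_p"] = pairwise
        report["categorical"][var] = entry
    return report
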