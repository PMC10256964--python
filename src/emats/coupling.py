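"""Splicing-expression coupling and RBP knock-down residual analysis.

The coupling statistic is the Spearman correlation between a splicing
event's per-sample PSI values and its host gene's per-sample TPM
values, computed only when at least 70 paired observations survive the
constitutive filter (observations with PSI exactly 0 or 1 dropped).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MIN_PAIRS = 70

STAR_THRESHOLDS = [
    (1e-5, "*****"),
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
]


@dataclass
class CouplingRecord:
    event_id: str
    event_class: str
    gene_id: str
    rho: float
    n_pairs: int


def significance_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


def spearman_coupling(
    psi_by_sample: Mapping[str, Optional[float]],
    tpm_by_sample: Mapping[str, float],
    min_pairs: int = MIN_PAIRS,
    event_id: str = "",
    event_class: str = "SE",
    gene_id: str = "",
    drop_mode: str = "per_observation",
) -> Optional[CouplingRecord]:
    """Spearman rho between an event's PSI and its gene's TPM.

    Samples present in both maps are paired; missing PSI values are
    dropped. With the default ``drop_mode="per_observation"``,
    observations whose PSI is exactly 0 or exactly 1 (constitutive
    exclusion/inclusion) are removed individually;
    ``drop_mode="per_event"`` instead discards the whole event only
    when its PSI is constant at 0 or at 1 across all samples. Returns
    None when fewer than *min_pairs* pairs survive.
    """
    shared = sorted(set(psi_by_sample) & set(tpm_by_sample))
    psi, tpm = [], []
    for s in shared:
        p = psi_by_sample[s]
        t = tpm_by_sample[s]
        if p is None or t is None:
            continue
        p, t = float(p), float(t)
        if np.isnan(p) or np.isnan(t):
            continue
        psi.append(p)
        tpm.append(t)
    psi_arr = np.asarray(psi)
    tpm_arr = np.asarray(tpm)
    if drop_mode == "per_observation":
        keep = (psi_arr != 0.0) & (psi_arr != 1.0)
        psi_arr, tpm_arr = psi_arr[keep], tpm_arr[keep]
    elif drop_mode == "per_event":
        if len(psi_arr) and (np.all(psi_arr == 0.0) or np.all(psi_arr == 1.0)):
            return None
    else:
        raise ValueError(f"unknown drop_mode {drop_mode!r}")
    if len(psi_arr) < min_pairs:
        return None
    rho = stats.spearmanr(psi_arr, tpm_arr).statistic
    return CouplingRecord(
        event_id=event_id,
        event_class=event_class,
        gene_id=gene_id,
        rho=float(rho),
        n_pairs=int(len(psi_arr)),
    )


def merge_rho_gene_level(
    records: Sequence[CouplingRecord],
    how: str = "mean",
    by_class: bool = False,
) -> pd.DataFrame:
    """Merge event-level rho values per gene (optionally per event class)."""
    if how not in ("mean", "median"):
        raise ValueError(f"unknown merge {how!r}")
    if not records:
        cols = ["gene_id", "rho", "n_events"]
        if by_class:
            cols.insert(1, "event_class")
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "event_class": [r.event_class for r in records],
            "rho": [r.rho for r in records],
        }
    )
    keys = ["gene_id", "event_class"] if by_class else ["gene_id"]
    out = (
        df.groupby(keys, as_index=False)
        .agg(rho=("rho", how), n_events=("rho", "size"))
        .sort_values(keys)
        .reset_index(drop=True)
    )
    return out


def bin_by_quantiles(
    values: Sequence[float], k: int, degenerate: str = "error"
) -> np.ndarray:
    """Assign each value to one of *k* equal-probability quantile bins.

    Ties are broken by rank order (first occurrence gets the lower
    bin), so bin sizes differ by at most one. All-equal input either
    raises (default) or lands in a single bin (``degenerate="single"``).
    """
    arr = np.asarray(values, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(arr) == 0:
        return np.array([], dtype=int)
    if np.all(arr == arr[0]):
        if degenerate == "single":
            return np.zeros(len(arr), dtype=int)
        raise ValueError("all values identical; no quantile bins exist")
    order = np.argsort(arr, kind="mergesort")  # stable: ties by position
    ranks = np.empty(len(arr), dtype=int)
    ranks[order] = np.arange(len(arr))
    return (ranks * k) // len(arr)


def compare_emats_vs_other(
    rho_emats: Sequence[float], rho_other: Sequence[float]
) -> dict:
    """Two-sided independent (Welch) t-test of EMATS vs other rho values."""
    a = np.asarray(rho_emats, dtype=float)
    b = np.asarray(rho_other, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "mean_emats": float(a.mean()),
        "mean_other": float(b.mean()),
        "t": float(t),
        "p": float(p),
        "stars": significance_stars(float(p)),
        "n_emats": int(len(a)),
        "n_other": int(len(b)),
    }


# ---------------------------------------------------------------------------
# RBP knock-down analysis
# ---------------------------------------------------------------------------


@dataclass
class RbpExperiment:
    rbp: str
    frac_up_genes: float
    frac_down_genes: float
    frac_up_se: float
    frac_down_se: float
    residual_up: float = np.nan
    residual_down: float = np.nan


def rbp_fractions(
    rbp: str,
    diff_gene_table: pd.DataFrame,
    diff_se_table: pd.DataFrame,
    totals: tuple[int, int],
    alpha: float = 0.05,
) -> RbpExperiment:
    """Fractions of significantly up/down genes and skipped exons.

    A record is significant when its adjusted p-value is strictly
    below *alpha*; it is up (down) when the knock-down minus control
    difference is strictly positive (negative). Fractions are taken
    against the total number of genes/exons the respective tool
    reported, not against the significant subset.
    """
    total_genes, total_se = totals
    if total_genes <= 0 or total_se <= 0:
        raise ValueError("totals must be positive")

    def frac(table: pd.DataFrame, sign: int, total: int) -> float:
        sig = table["padj"] < alpha
        direction = table["delta"] > 0 if sign > 0 else table["delta"] < 0
        return float((sig & direction).sum()) / total

    return RbpExperiment(
        rbp=rbp,
        frac_up_genes=frac(diff_gene_table, +1, total_genes),
        frac_down_genes=frac(diff_gene_table, -1, total_genes),
        frac_up_se=frac(diff_se_table, +1, total_se),
        frac_down_se=frac(diff_se_table, -1, total_se),
    )


def residual_selection(
    experiments: Sequence[RbpExperiment], k: int = 17
) -> dict:
    """Select the RBPs with the largest regression residuals.

    Gene fractions are regressed on skipped-exon fractions by ordinary
    least squares, separately for the up and down directions; each
    experiment's residual magnitude is |observed - fitted|. The union
    of the top-*k* per regression is returned (deduplicated), with
    ties broken alphabetically for determinism; *k* larger than the
    number of experiments returns everything.
    """
    if not experiments:
        return {"selected": [], "fit_up": None, "fit_down": None}
    df = pd.DataFrame(
        {
            "rbp": [e.rbp for e in experiments],
            "x_up": [e.frac_up_se for e in experiments],
            "y_up": [e.frac_up_genes for e in experiments],
            "x_down": [e.frac_down_se for e in experiments],
            "y_down": [e.frac_down_genes for e in experiments],
        }
    )

    def top(xcol: str, ycol: str, rescol: str):
        x, y = df[xcol].to_numpy(), df[ycol].to_numpy()
        if np.all(x == x[0]):  # vertical scatter: fit the mean
            fitted = np.full_like(y, y.mean())
            fit = {"slope": np.nan, "intercept": float(y.mean()), "r": np.nan}
        else:
            res = stats.linregress(x, y)
            fitted = res.intercept + res.slope * x
            fit = {
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "r": float(res.rvalue),
            }
        resid = np.abs(y - fitted)
        # collapse numerical dust so exactly-collinear input ties at zero
        resid[resid < 1e-12] = 0.0
        df[rescol] = resid
        ranked = df.sort_values(
            [rescol, "rbp"], ascending=[False, True], kind="mergesort"
        )
        return list(ranked["rbp"].head(k)), fit

    top_up, fit_up = top("x_up", "y_up", "residual_up")
    top_down, fit_down = top("x_down", "y_down", "residual_down")
    for e in experiments:
        row = df.loc[df.rbp == e.rbp].iloc[0]
        e.residual_up = float(row["residual_up"])
        e.residual_down = float(row["residual_down"])
    selected = sorted(set(top_up) | set(top_down))
    return {"selected": selected, "fit_up": fit_up, "fit_down": fit_down}
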