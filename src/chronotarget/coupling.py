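"""Clock-gene coupling of candidate genes across a temporal axis.

Pairwise Pearson correlation between candidate genes (e.g., rhythmic cancer
driver genes) and the 15-gene circadian clock panel, summarized with the
R-squared tiers used to call coupling: R^2 >= 0.3 counts as a significant
correlation, R^2 above 0.6 as a strong one. The axis the correlation runs
over (time points in an organoid time course, samples in a tumor cohort) is
the caller's choice — any shared column axis works.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "gene_gene_correlation",
    "coupling_summary",
    "concordance_trend",
    "build_coupling_network",
]


def _replicate_average(matrix: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns (``CT8_r1``/``CT8_r2`` -> ``CT8``)."""
    base = [str(c).rsplit("_r", 1)[0] if "_r" in str(c) else str(c) for c in matrix.columns]
    return matrix.T.groupby(base, sort=False).mean().T


def gene_gene_correlation(
    matrix: pd.DataFrame, set_a: Sequence[str], set_b: Sequence[str]
) -> pd.DataFrame:
    """Long-format coupling table over set_a x set_b.

    Columns: candidate, clock_gene, r, r2, n, p. Pearson r across the
    (replicate-averaged) columns. Zero-variance series yield NaN cells,
    excluded from downstream summaries.
    """
    missing = (set(set_a) | set(set_b)) - set(matrix.index)
    if missing:
        raise KeyError(f"genes absent from matrix: {sorted(missing)[:5]}")
    avg = _replicate_average(matrix)
    if avg.shape[1] < 3:
        raise ValueError("need >= 3 shared time points")
    rows = []
    for a in set_a:
        x = avg.loc[a].to_numpy(dtype=float)
        for b in set_b:
            y = avg.loc[b].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append(dict(candidate=a, clock_gene=b, r=np.nan, r2=np.nan,
                                 n=len(x), p=np.nan))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append(dict(candidate=a, clock_gene=b, r=float(r), r2=float(r**2),
                             n=len(x), p=float(p)))
    return pd.DataFrame(rows)


def coupling_summary(
    coupling: pd.DataFrame, r2_sig: float = 0.3, r2_strong: float = 0.6
) -> dict:
    """Per-candidate coupling tiers and marginal counts.

    Boundary semantics follow the calling convention: the significance tier
    uses R^2 >= r2_sig; the strong tier is reported under both >= and
    strict > conventions (``n_strong_ge`` / ``n_strong_gt`` globally).

    Returns a dict with ``per_candidate`` (n_clock_sig, n_clock_strong,
    max_abs_r, strongest_partner, tier), ``per_clock`` (count of coupled
    candidates per clock gene), and global pair counts.
    """
    valid = coupling.dropna(subset=["r"])
    per_candidate = []
    for cand, grp in coupling.groupby("candidate", sort=True):
        g = grp.dropna(subset=["r"])
        if g.empty:
            per_candidate.append(dict(candidate=cand, n_clock_sig=0, n_clock_strong=0,
                                      max_abs_r=np.nan, strongest_partner="", tier="none"))
            continue
        sig = g[g["r2"] >= r2_sig]
        strong = g[g["r2"] >= r2_strong]
        i_best = g["r"].abs().idxmax()
        best_r = float(g.loc[i_best, "r"])
        if not strong.empty:
            tier = "strong-positive" if float(strong.loc[strong["r2"].idxmax(), "r"]) >= 0 else "strong-negative"
        elif not sig.empty:
            tier = "significant"
        else:
            tier = "none"
        per_candidate.append(dict(candidate=cand, n_clock_sig=len(sig),
                                  n_clock_strong=len(strong), max_abs_r=abs(best_r),
                                  strongest_partner=str(g.loc[i_best, "clock_gene"]),
                                  tier=tier))
    per_clock = (
        valid[valid["r2"] >= r2_sig].groupby("clock_gene").size()
        .reindex(sorted(coupling["clock_gene"].unique()), fill_value=0)
    )
    return dict(
        per_candidate=pd.DataFrame(per_candidate).set_index("candidate"),
        per_clock=per_clock,
        n_pairs_sig=int((valid["r2"] >= r2_sig).sum()),
        n_pairs_strong_ge=int((valid["r2"] >= r2_strong).sum()),
        n_pairs_strong_gt=int((valid["r2"] > r2_strong).sum()),
    )


def concordance_trend(coupling_a: pd.DataFrame, coupling_b: pd.DataFrame) -> pd.DataFrame:
    """Per-candidate agreement of coupling profiles between two cohorts.

    For each candidate present in both, regress its clock-coupling vector
    in cohort B on the one in cohort A: OLS slope, Pearson r, and the
    two-tailed t-test p on r.
    """
    piv_a = coupling_a.pivot(index="candidate", columns="clock_gene", values="r")
    piv_b = coupling_b.pivot(index="candidate", columns="clock_gene", values="r")
    if set(piv_a.columns) != set(piv_b.columns):
        raise ValueError("cohorts must share the same clock-gene columns")
    piv_b = piv_b[piv_a.columns]
    rows = []
    for cand in piv_a.index:
        if cand not in piv_b.index:
            warnings.warn(f"candidate {cand} missing in cohort B; skipped", stacklevel=2)
            continue
        x = piv_a.loc[cand].to_numpy(dtype=float)
        y = piv_b.loc[cand].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            rows.append(dict(candidate=cand, slope=np.nan, r=np.nan, p=np.nan, n=len(x)))
            continue
        res = stats.linregress(x, y)
        rows.append(dict(candidate=cand, slope=float(res.slope), r=float(res.rvalue),
                         p=float(res.pvalue), n=len(x)))
    return pd.DataFrame(rows).set_index("candidate")


def build_coupling_network(coupling: pd.DataFrame, r2_min: float = 0.6) -> pd.DataFrame:
    """Bipartite candidate-clock edge list for pairs with R^2 strictly above
    ``r2_min``, annotated with the correlation sign."""
    strong = coupling.dropna(subset=["r"])
    strong = strong[strong["r2"] > r2_min].copy()
    strong["sign"] = np.where(strong["r"] >= 0, "+", "-")
    return strong[["candidate", "clock_gene", "r", "r2", "sign"]].reset_index(drop=True)
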