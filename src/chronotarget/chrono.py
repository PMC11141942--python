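"""Chrono-efficacy: dose-response fitting, temporal drug-efficacy statistics,
the rhythmic-hub rhythmicity score, and target prioritization.

Drug response at each treatment time is summarized by the area under the
fitted four-parameter logistic (4PL) viability curve over the log-dose
window — normalized by the window width, so the AUC reads as mean fitted
viability (1 = no kill). Temporal fluctuation in efficacy is tested with a
one-way ANOVA on per-replicate AUCs followed by Tukey's HSD. A gene set's
rhythmicity score is the per-time-point mean of max-normalized expression;
its Pearson correlation with the AUC series quantifies how tightly efficacy
tracks target-pathway expression. The final prioritization intersects
rhythmic genes with cancer drivers, shortlists by network centrality (MCC),
orders by clock coupling, and annotates druggability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .rhythm import cosinor_fit, parse_time_columns
from .synthdata import four_pl

__all__ = [
    "FourPLFit",
    "fit_dose_response",
    "temporal_efficacy",
    "rhythmicity_score",
    "efficacy_expression_correlation",
    "temporal_amplitude",
    "prioritize_targets",
]


@dataclass
class FourPLFit:
    top: float
    bottom: float
    ic50: float
    hill: float
    auc: float
    rss: float
    converged: bool
    extrapolated: bool  # ic50 more than 10x outside the tested dose range


def _auc_from_curve(top, bottom, ic50, hill, log_lo, log_hi, n_grid=257) -> float:
    grid = np.logspace(log_lo, log_hi, n_grid)
    v = four_pl(grid, top, bottom, ic50, hill)
    return float(np.trapezoid(v, np.log10(grid)) / (log_hi - log_lo))


def fit_dose_response(doses: np.ndarray, viabilities: np.ndarray) -> FourPLFit:
    """Least-squares 4PL fit v(d) = bottom + (top-bottom)/(1+(d/ic50)^hill).

    Fitted on log10 dose with multi-start initialization over candidate
    IC50s spanning the tested range. AUC is the mean fitted viability over
    the log-dose window. If no start converges, the fit is flagged and the
    AUC falls back to the trapezoid over the raw points.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if len(np.unique(d)) < 5:
        raise ValueError("need >= 5 dose levels")
    if np.any(d <= 0):
        raise ValueError("doses must be > 0")
    if np.log10(d.max() / d.min()) < 2:
        raise ValueError("doses must span >= 2 log10 units")
    order = np.argsort(d)
    d, v = d[order], v[order]
    log_lo, log_hi = np.log10(d.min()), np.log10(d.max())

    def model(logd, top, bottom, logc, hill):
        return four_pl(10.0**logd, top, bottom, 10.0**logc, hill)

    best = None
    for logc0 in np.linspace(log_lo, log_hi, 5):
        for hill0 in (0.5, 1.0, 2.0):
            try:
                popt, _ = optimize.curve_fit(
                    model, np.log10(d), v,
                    p0=[float(v.max()), float(v.min()), logc0, hill0],
                    bounds=([-0.5, -0.5, log_lo - 3, 0.05], [2.0, 2.0, log_hi + 3, 20.0]),
                    maxfev=2000,
                )
            except RuntimeError:
                continue
            rss = float(np.sum((model(np.log10(d), *popt) - v) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
    if best is None:
        auc = float(np.trapezoid(v, np.log10(d)) / (log_hi - log_lo))
        return FourPLFit(top=float(v.max()), bottom=float(v.min()), ic50=np.nan,
                         hill=np.nan, auc=auc, rss=np.nan, converged=False,
                         extrapolated=True)
    popt, rss = best
    top, bottom, logc, hill = popt
    if bottom > top:  # enforce bottom <= top by flipping hill sign convention
        top, bottom, hill = bottom, top, -hill
    ic50 = float(10.0**logc)
    extrapolated = not (d.min() / 10.0 <= ic50 <= d.max() * 10.0)
    auc = _auc_from_curve(top, bottom, ic50, hill, log_lo, log_hi)
    return FourPLFit(top=float(top), bottom=float(bottom), ic50=ic50,
                     hill=float(hill), auc=auc, rss=rss, converged=True,
                     extrapolated=extrapolated)


def temporal_efficacy(panel: pd.DataFrame, anova: bool = True) -> dict:
    """Per-time-point AUCs and the across-time ANOVA.

    ``panel`` is long-format with columns time_h, dose, replicate,
    viability. A 4PL curve is fitted per (time, replicate); the one-way
    ANOVA runs on replicate AUCs across time points, followed by Tukey HSD.
    With a single replicate the AUC series is returned and the ANOVA is
    skipped with a warning.
    """
    required = {"time_h", "dose", "replicate", "viability"}
    if not required <= set(panel.columns):
        raise ValueError(f"panel must have columns {sorted(required)}")
    rows = []
    for (t, rep), grp in panel.groupby(["time_h", "replicate"], sort=True):
        fit = fit_dose_response(grp["dose"].to_numpy(), grp["viability"].to_numpy())
        rows.append(dict(time_h=float(t), replicate=int(rep), auc=fit.auc,
                         ic50=fit.ic50, converged=fit.converged))
    fits = pd.DataFrame(rows)
    auc_series = fits.groupby("time_h")["auc"].mean()
    out = dict(fits=fits, auc_series=auc_series, F=np.nan, p=np.nan, tukey=None)
    n_rep = fits.groupby("time_h")["replicate"].nunique().min()
    if not anova:
        return out
    if n_rep < 2:
        warnings.warn("single replicate: ANOVA skipped", stacklevel=2)
        return out
    if fits["time_h"].nunique() < 3:
        warnings.warn("fewer than 3 time points: ANOVA skipped", stacklevel=2)
        return out
    groups = [g["auc"].to_numpy() for _, g in fits.groupby("time_h")]
    if all(np.allclose(g, groups[0][0]) for g in groups):
        out["F"], out["p"] = 0.0, 1.0
        return out
    f_stat, p = stats.f_oneway(*groups)
    out["F"], out["p"] = float(f_stat), float(p)
    tk = pairwise_tukeyhsd(fits["auc"].to_numpy(), fits["time_h"].astype(str).to_numpy())
    out["tukey"] = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return out


def rhythmicity_score(matrix: pd.DataFrame, gene_set: Iterable[str]) -> pd.Series:
    """Cumulative rhythmicity score of a gene set over time.

    Each member gene is divided by its own maximum over the time course,
    then the normalized series are averaged per time point. The score lies
    in (0, 1] and hits 1 at a time point only if every member peaks there.
    Genes with an all-zero series are dropped with a warning.
    """
    genes = [g for g in gene_set]
    if not genes:
        raise ValueError("empty gene set")
    missing = set(genes) - set(matrix.index)
    if missing:
        raise KeyError(f"genes absent from matrix: {sorted(missing)[:5]}")
    sub = matrix.loc[genes]
    t, _ = parse_time_columns(sub.columns)
    # replicate-average onto the unique time grid
    collapsed = sub.T.groupby(t, sort=True).mean().T
    maxes = collapsed.max(axis=1)
    zero = maxes <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} genes with max 0 dropped from score", stacklevel=2)
        collapsed = collapsed.loc[~zero]
        maxes = maxes[~zero]
    if collapsed.empty:
        raise ValueError("no gene with positive expression in the set")
    normalized = collapsed.div(maxes, axis=0)
    score = normalized.mean(axis=0)
    score.index.name = "time_h"
    score.name = "score"
    return score


def efficacy_expression_correlation(expr_series: pd.Series, auc_series: pd.Series) -> dict:
    """Pearson correlation between an expression (or score) series and the
    per-time AUC series on their shared time points."""
    joined = pd.concat([expr_series.rename("x"), auc_series.rename("y")], axis=1, join="inner").dropna()
    if len(joined) < 4:
        raise ValueError("need >= 4 shared time points")
    x, y = joined["x"].to_numpy(dtype=float), joined["y"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return dict(r=np.nan, r2=np.nan, p=np.nan, n=len(joined), defined=False)
    r, p = stats.pearsonr(x, y)
    return dict(r=float(r), r2=float(r**2), p=float(p), n=len(joined), defined=True)


def temporal_amplitude(series: np.ndarray, t: np.ndarray, period: float = 24.0) -> dict:
    """Amplitude of a temporal series by two estimators: the cosinor
    amplitude at the given period, and half the peak-to-trough range."""
    y = np.asarray(series, dtype=float)
    if len(y) < 4:
        raise ValueError("need >= 4 time points")
    fit = cosinor_fit(y, np.asarray(t, dtype=float), period)
    return dict(amp_cosinor=fit["amplitude"], amp_peak_trough=float((y.max() - y.min()) / 2.0))


def prioritize_targets(
    rhythm_table: pd.DataFrame,
    cdg_list: Iterable[str],
    centrality_table: pd.DataFrame,
    coupling_per_candidate: pd.DataFrame,
    drug_table: pd.DataFrame | None = None,
    shortlist_k: int = 17,
) -> pd.DataFrame:
    """Rank chronotherapy candidate targets.

    Pipeline: (1) rhythmic genes are intersected with the cancer-driver
    list (the r-CDG set); (2) the set is shortlisted by MCC rank (top
    ``shortlist_k``); (3) shortlisted genes are ordered by their strongest
    absolute clock-gene correlation, descending; (4) drugs from the
    drug-gene table are annotated. Ties break by MCC then gene id, so the
    output is a deterministic function of its inputs.
    """
    rhythmic = set(rhythm_table.index[rhythm_table["rhythmic"].astype(bool)])
    r_cdg = sorted(rhythmic & set(cdg_list))
    if not r_cdg:
        warnings.warn("no rhythmic cancer driver gene found", stacklevel=2)
        return pd.DataFrame(columns=["rank", "mcc", "mcc_rank", "max_abs_r", "drugs"])
    in_net = [g for g in r_cdg if g in centrality_table.index]
    dropped = set(r_cdg) - set(in_net)
    if dropped:
        warnings.warn(f"{len(dropped)} r-CDGs absent from the network; dropped", stacklevel=2)
    sub = centrality_table.loc[in_net, ["mcc", "degree"]].copy()
    sub.index.name = "gene"
    sub = sub.sort_values(["mcc", "degree"], ascending=False, kind="stable")
    sub["mcc_rank"] = np.arange(1, len(sub) + 1)
    shortlist = sub.head(shortlist_k).copy()
    coup = coupling_per_candidate["max_abs_r"] if "max_abs_r" in coupling_per_candidate else None
    shortlist["max_abs_r"] = [
        float(coup.get(g, np.nan)) if coup is not None else np.nan for g in shortlist.index
    ]
    shortlist = (
        shortlist.reset_index()
        .sort_values(["max_abs_r", "mcc", "gene"], ascending=[False, False, True],
                     kind="stable", na_position="last")
        .set_index("gene")
    )
    drugs_by_gene: dict[str, str] = {}
    if drug_table is not None and len(drug_table):
        for gene, grp in drug_table.groupby("gene"):
            drugs_by_gene[str(gene)] = ",".join(sorted(set(map(str, grp["drug"]))))
    shortlist["drugs"] = [drugs_by_gene.get(str(g), "") for g in shortlist.index]
    shortlist.insert(0, "rank", np.arange(1, len(shortlist) + 1))
    shortlist.index.name = "gene"
    return shortlist
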