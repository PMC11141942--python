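"""Overrepresentation statistics and set algebra for rhythmic gene sets.

Hypergeometric upper-tail enrichment of a query gene list against named
pathway collections (GMT format), Benjamini-Hochberg corrected across the
collection, plus Venn-style overlap accounting for up to six sets. The
universe defaults to whatever gene background the caller supplies — the
standard anti-bias choice is the set of genes surviving expression filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import itertools
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_gmt",
    "write_gmt",
    "hypergeometric_enrichment",
    "pathway_enrichment",
    "set_overlap_stats",
]


def read_gmt(path) -> dict[str, dict]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = dict(description=parts[1], genes=set(g for g in parts[2:] if g))
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(map(str, genes))]) + "\n")


@dataclass
class EnrichmentRow:
    name: str
    k: int  # overlap
    K: int  # set size in universe
    n: int  # query size
    N: int  # universe size
    p: float
    fdr: float = float("nan")


def hypergeometric_enrichment(
    query: Iterable[str], gene_set: Iterable[str], universe: Iterable[str],
    name: str = "set", depletion: bool = False,
) -> EnrichmentRow:
    """Upper-tail hypergeometric test P(X >= k) of the query/set overlap.

    Ids outside the universe are dropped with a warning. With
    ``depletion=True``, the lower tail P(X <= k) is returned instead.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    s = set(gene_set)
    dropped = (q | s) - uni
    if dropped:
        warnings.warn(f"{len(dropped)} ids outside the universe dropped", stacklevel=2)
    q &= uni
    s &= uni
    N, K, n, k = len(uni), len(s), len(q), len(q & s)
    if depletion:
        p = float(stats.hypergeom.cdf(k, N, K, n))
    else:
        # P(X >= k) via the survival function at k-1 (exact log-gamma arithmetic)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentRow(name=name, k=k, K=K, n=n, N=N, p=min(max(p, 0.0), 1.0))


def pathway_enrichment(
    query: Iterable[str],
    collection: Mapping[str, Mapping],
    universe: Iterable[str],
    min_size: int = 10,
    max_size: int = 250,
) -> pd.DataFrame:
    """Hypergeometric enrichment over a pathway collection.

    Sets are restricted to the universe first; those with fewer than
    ``min_size`` or more than ``max_size`` members are excluded. BH FDR is
    computed across the surviving sets and the table is sorted by p.
    """
    if not collection:
        raise ValueError("empty collection")
    uni = set(universe)
    rows: list[EnrichmentRow] = []
    for set_name, entry in collection.items():
        genes = set(entry["genes"] if isinstance(entry, Mapping) else entry) & uni
        if len(genes) < min_size or len(genes) > max_size:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append(hypergeometric_enrichment(query, genes, uni, name=set_name))
    if not rows:
        warnings.warn("no gene set survived the size filter", stacklevel=2)
        return pd.DataFrame(columns=["name", "k", "K", "n", "N", "p", "fdr"])
    df = pd.DataFrame([vars(r) for r in rows])
    df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def set_overlap_stats(sets: Mapping[str, Iterable[str]], universe: Iterable[str] | None = None) -> dict:
    """Venn region counts and percentages for 2-6 named sets.

    Returns ``regions`` — one entry per exclusive Venn region keyed by
    "A&B"-style labels, with count and percentage of the union — and
    ``pairwise`` overlap stats (count; percentage of each member set,
    one-decimal rounded).
    """
    names = list(sets)
    if not 2 <= len(names) <= 6:
        raise ValueError("set_overlap_stats supports 2-6 sets")
    s = {name: set(v) for name, v in sets.items()}
    union = set.union(*s.values())
    regions = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(s[c] for c in combo))
            rest = [s[o] for o in names if o not in combo]
            exclusive = inside - set.union(*rest) if rest else inside
            label = "&".join(combo)
            regions[label] = dict(
                count=len(exclusive),
                pct_of_union=round(100.0 * len(exclusive) / len(union), 1) if union else 0.0,
            )
    pairwise = {}
    for a, b in itertools.combinations(names, 2):
        k = len(s[a] & s[b])
        pairwise[f"{a}&{b}"] = dict(
            count=k,
            pct_of_first=round(100.0 * k / len(s[a]), 1) if s[a] else 0.0,
            pct_of_second=round(100.0 * k / len(s[b]), 1) if s[b] else 0.0,
        )
    out = dict(regions=regions, pairwise=pairwise, union_size=len(union))
    if universe is not None:
        uni = set(universe)
        out["universe_size"] = len(uni)
        out["pct_of_universe"] = {
            name: round(100.0 * len(v & uni) / len(uni), 1) if uni else 0.0
            for name, v in s.items()
        }
    return out
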