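"""Gene-region overlap and enrichment tests.

Regions (QTL support intervals or regional-heritability blocks) are
named sets of genomic segments in bp; genes are single positions (the
midpoint of the gene span). Containment uses the half-open
``[start, end)`` convention. Enrichment of a gene subset within the
regions is tested by resampling the subset among all genes (without
replacement), and category enrichment by Fisher's exact test with the
conventional minimum-likelihood two-sided rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "genes_in_regions",
    "region_enrichment_permutation",
    "fisher_enrichment",
    "regions_from_table",
]

GENE_CATEGORIES = ("OR", "GR", "IR", "OBP", "CSP", "SNMP", "other")


def regions_from_table(df: pd.DataFrame, units: str = "bp") -> pd.DataFrame:
    """Normalize a region table to (name, chrom, start, end) in bp.

    ``units='Mb'`` converts coordinates given in megabases (two-decimal
    tables round-trip exactly at the 10 kb grain). Multi-segment
    regions are rows sharing a name.
    """
    out = df.copy()
    if units == "Mb":
        out["start"] = np.round(out["start"] * 1e6).astype(np.int64)
        out["end"] = np.round(out["end"] * 1e6).astype(np.int64)
    if (out["start"] >= out["end"]).any():
        bad = out[out["start"] >= out["end"]]["name"].tolist()
        raise ValueError(f"regions with start >= end: {bad}")
    return out[["name", "chrom", "start", "end"]]


def genes_in_regions(
    genes: pd.DataFrame,
    regions: pd.DataFrame,
    map_df: pd.DataFrame | None = None,
) -> tuple[dict[str, list[str]], list[str], pd.DataFrame]:
    """Genes contained in each region, plus the deduplicated union.

    ``genes`` needs columns gene, chrom, bp; ``regions`` columns name,
    chrom, start, end (bp, half-open). When ``map_df`` is given each
    gene is annotated with its nearest mapped marker (bp distance) and
    that marker's cM. Returns (per-region gene lists, union gene list,
    annotated gene table).
    """
    unmatched = sorted(set(regions["chrom"]) - set(genes["chrom"]))
    if unmatched:
        raise ValueError(f"region chromosomes not in gene table: {unmatched}")
    per_region: dict[str, list[str]] = {}
    in_union = np.zeros(len(genes), dtype=bool)
    gb = genes["bp"].to_numpy()
    gc = genes["chrom"].to_numpy()
    for name, seg in regions.groupby("name", sort=False):
        hit = np.zeros(len(genes), dtype=bool)
        for _, s in seg.iterrows():
            hit |= (gc == s["chrom"]) & (gb >= s["start"]) & (gb < s["end"])
        per_region[name] = genes.loc[hit, "gene"].tolist()
        in_union |= hit
    annotated = genes.copy()
    annotated["in_regions"] = in_union
    if map_df is not None:
        nearest_mk, nearest_cm = [], []
        for _, g in genes.iterrows():
            sub = map_df[map_df["chrom"] == g["chrom"]]
            if len(sub) == 0:
                nearest_mk.append("")
                nearest_cm.append(np.nan)
                continue
            j = (sub["bp"] - g["bp"]).abs().idxmin()
            nearest_mk.append(sub.loc[j, "marker"])
            nearest_cm.append(float(sub.loc[j, "cM"]))
        annotated["nearest_marker"] = nearest_mk
        annotated["nearest_cM"] = nearest_cm
    union = annotated.loc[annotated["in_regions"], "gene"].tolist()
    return per_region, union, annotated


def region_enrichment_permutation(
    genes: pd.DataFrame,
    subset: list[str] | pd.Index,
    regions: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Over-representation of a gene subset within regions.

    The null resamples ``len(subset)`` genes without replacement from
    the full gene table ``n_perm`` times and counts how many fall in
    the (merged) regions. p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    subset = list(subset)
    if len(subset) == 0:
        raise ValueError("subset is empty")
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    missing = set(subset) - set(genes["gene"])
    if missing:
        raise ValueError(f"subset genes not in gene table: {sorted(missing)}")
    _per, _union, annotated = genes_in_regions(genes, regions)
    in_region = annotated.set_index("gene")["in_regions"]
    observed = int(in_region.loc[subset].sum())
    flags = in_region.to_numpy()
    rng = np.random.default_rng(seed)
    k = len(subset)
    null = np.empty(n_perm, dtype=np.int64)
    for b in range(n_perm):
        null[b] = flags[rng.choice(len(flags), size=k, replace=False)].sum()
    expected = float(null.mean())
    sd = float(null.std(ddof=0))
    z = (observed - expected) / sd if sd > 0 else np.nan
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return {
        "observed": observed,
        "expected": expected,
        "sd": sd,
        "z": float(z) if np.isfinite(z) else np.nan,
        "p": float(p),
        "n_perm": n_perm,
        "subset_size": k,
    }


def fisher_enrichment(table: np.ndarray | list[list[int]]) -> dict:
    """Fisher's exact test on a 2x2 table.

    Two-sided p sums all tables in the hypergeometric support whose
    point probability does not exceed the observed table's (the
    minimum-likelihood rule); the one-sided (greater) tail and the
    conditional-ML odds ratio are also reported. A zero margin yields
    p = 1 with the odds ratio undefined.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer cells")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return {"p_two_sided": 1.0, "p_greater": 1.0, "p_less": 1.0,
                "odds_ratio": np.nan, "flags": ["zero_margin"]}
    _or_sample, p_two = stats.fisher_exact(t, alternative="two-sided")
    _, p_greater = stats.fisher_exact(t, alternative="greater")
    _, p_less = stats.fisher_exact(t, alternative="less")
    orr = stats.contingency.odds_ratio(t, kind="conditional")
    return {
        "p_two_sided": float(p_two),
        "p_greater": float(p_greater),
        "p_less": float(p_less),
        "odds_ratio": float(orr.statistic),
        "flags": [],
    }
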