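"""Marker QC and de-novo linkage-map construction under male achiasmy.

In this cross all recombination observed in the F2 comes from the F1
mother; the father transmits one intact haplotype per chromosome. With
known coupling phase (the F1 haplotypes are the two pure race
haplotypes) the two-locus F2 likelihood collapses to a backcross-like
form: genotype pairs are either *parental* (maternal gamete
non-recombinant), *recombinant*, phase-*uninformative*, or *impossible*
(e.g. AA at one marker and BB at a linked marker, which would require a
paternal switch). The maximum-likelihood female recombination fraction
is then simply ``r = n_rec / (n_par + n_rec)``, and
``LOD = n_par*log10(2(1-r)) + n_rec*log10(2r)``.

Impossible cells are excluded from the likelihood and surface as
diagnostics for genotyping errors or apparent male recombination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import AA, AB, BB, MISSING, Founders

__all__ = [
    "filter_markers",
    "estimate_rf",
    "pairwise_rf",
    "group_markers",
    "threshold_scan",
    "order_markers",
    "build_genetic_map",
    "error_lod_flag",
]


# --------------------------------------------------------------------------
# QC filters

@dataclass
class QCReport:
    removed: dict[str, list[str]] = field(default_factory=dict)
    flags: dict[str, list[str]] = field(default_factory=dict)

    def drop(self, marker: str, rule: str) -> None:
        self.removed.setdefault(rule, []).append(marker)

    def flag(self, marker: str, note: str) -> None:
        self.flags.setdefault(marker, []).append(note)

    def counts(self) -> dict[str, int]:
        return {rule: len(v) for rule, v in self.removed.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [(m, rule) for rule, ms in self.removed.items() for m in ms]
        return pd.DataFrame(rows, columns=["marker", "rule"])


def _is_informative(f0: np.ndarray, f1: np.ndarray) -> tuple[bool, bool]:
    """Apply the parentage rule on the available (non-missing) genotypes.

    Requires both F0s of one race homozygous for one allele, both F0s of
    the other race homozygous for the other, and both F1s heterozygous.
    Returns (informative, had_missing_parentage).
    """
    race1, race2 = f0[:2], f0[2:]
    had_missing = bool((f0 == MISSING).any() or (f1 == MISSING).any())
    r1 = race1[race1 != MISSING]
    r2 = race2[race2 != MISSING]
    f1v = f1[f1 != MISSING]
    for r in (r1, r2):
        if r.size and (np.any(r == AB) or np.unique(r).size > 1):
            return False, had_missing
    if r1.size and r2.size and r1[0] == r2[0]:
        return False, had_missing
    if np.any(f1v != AB):
        return False, had_missing
    return True, had_missing


def _distortion_pvalue(column: np.ndarray, is_x: bool) -> float:
    """Chi-square test against 1:2:1 (autosome) or 1:1 AA:AB (X)."""
    obs = column[column != MISSING]
    n = obs.size
    if n == 0:
        return np.nan
    if is_x:
        counts = np.array([(obs == AA).sum(), (obs == AB).sum()], dtype=float)
        expected = np.array([0.5, 0.5]) * counts.sum()
        if counts.sum() == 0:
            return np.nan
        chi2 = ((counts - expected) ** 2 / expected).sum()
        return float(stats.chi2.sf(chi2, df=1))
    counts = np.array(
        [(obs == AA).sum(), (obs == AB).sum(), (obs == BB).sum()], dtype=float
    )
    expected = np.array([0.25, 0.5, 0.25]) * n
    chi2 = ((counts - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(chi2, df=2))


def filter_markers(
    genotypes: pd.DataFrame,
    founders: Founders,
    distortion_p: float = 0.001,
    x_name: str = "X",
    collapse_redundant: bool = True,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the marker QC chain and return retained genotype columns.

    Order of rules: (1) parentage/informativeness, (2) all-missing F2
    columns, (3) segregation distortion at ``distortion_p``, (4)
    redundancy collapse keeping, per identical-signature group, the
    marker with least missing data.
    """
    report = QCReport()
    mk = founders.markers.set_index("marker")
    col_of = {m: j for j, m in enumerate(founders.markers["marker"])}
    retained: list[str] = []
    for marker in genotypes.columns:
        j = col_of[marker]
        ok, had_missing = _is_informative(founders.f0[:, j], founders.f1[:, j])
        if had_missing:
            report.flag(marker, "imputed_parentage")
        if not ok:
            report.drop(marker, "uninformative")
            continue
        col = genotypes[marker].to_numpy()
        if np.all(col == MISSING):
            report.drop(marker, "no_data")
            continue
        p = _distortion_pvalue(col, mk.loc[marker, "chrom"] == x_name)
        if np.isnan(p) or p < distortion_p:
            report.drop(marker, "distorted")
            continue
        retained.append(marker)

    if collapse_redundant and retained:
        retained = _collapse_redundant(genotypes, retained, report)
    return genotypes[retained], report


def _collapse_redundant(
    genotypes: pd.DataFrame, markers: list[str], report: QCReport
) -> list[str]:
    """Keep one marker per identical F2 signature (missing-tolerant).

    Two markers are redundant when they agree at every jointly observed
    individual; the representative is the one with the least missing
    data (first by input order on ties).
    """
    order = sorted(markers, key=lambda m: ((genotypes[m].to_numpy() == MISSING).sum(),
                                           markers.index(m)))
    kept: list[str] = []
    kept_cols: list[np.ndarray] = []
    dropped: set[str] = set()
    for m in order:
        col = genotypes[m].to_numpy()
        redundant = False
        for kc in kept_cols:
            both = (col != MISSING) & (kc != MISSING)
            if both.any() and np.all(col[both] == kc[both]):
                redundant = True
                break
        if redundant:
            report.drop(m, "redundant")
            dropped.add(m)
        else:
            kept.append(m)
            kept_cols.append(col)
    return [m for m in markers if m not in dropped]


# --------------------------------------------------------------------------
# Recombination fractions

# cell classification codes: 0 = parental, 1 = recombinant, 2 = uninformative,
# 3 = impossible
_CELLS_AUT = np.array([[0, 1, 3],
                       [1, 0, 1],
                       [3, 1, 0]])
_CELLS_X = np.array([[0, 1, 3],
                     [1, 0, 3],
                     [3, 3, 3]])
_CELLS_MIXED = np.array([[0, 1, 3],     # rows: autosomal marker genotype
                         [2, 2, 3],     # het autosome carries no phase info
                         [1, 0, 3]])


def _cell_table(is_x_i: bool, is_x_j: bool) -> np.ndarray:
    if is_x_i and is_x_j:
        return _CELLS_X
    if not is_x_i and not is_x_j:
        return _CELLS_AUT
    return _CELLS_MIXED if not is_x_i else _CELLS_MIXED.T


def _rf_from_counts(n_par, n_rec):
    """Closed-form ML under the achiasmatic two-locus model."""
    n = n_par + n_rec
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(n > 0, n_rec / np.maximum(n, 1), 0.5)
    r = np.minimum(r, 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = n_par * np.log10(np.maximum(2 * (1 - r), 1e-300)) + np.where(
            n_rec > 0, n_rec * np.log10(np.maximum(2 * r, 1e-300)), 0.0
        )
    return r, np.maximum(lod, 0.0)


def estimate_rf(
    gi: np.ndarray,
    gj: np.ndarray,
    is_x_i: bool = False,
    is_x_j: bool = False,
    min_support: int = 10,
) -> tuple[float, float, list[str]]:
    """Female recombination fraction and LOD for one marker pair.

    Returns (r_hat, LOD, flags); flags may include ``low_support`` (fewer
    than ``min_support`` jointly informative F2s) and ``conflict`` when
    genotype pairs fall in cells impossible under male achiasmy.
    """
    cells = _cell_table(is_x_i, is_x_j)
    ok = (gi != MISSING) & (gj != MISSING)
    cls = cells[gi[ok], gj[ok]]
    n_par = int((cls == 0).sum())
    n_rec = int((cls == 1).sum())
    r, lod = _rf_from_counts(np.array(n_par), np.array(n_rec))
    flags = []
    if n_par + n_rec < min_support:
        flags.append("low_support")
    if (cls == 3).any():
        flags.append("conflict")
    return float(r), float(lod), flags


def pairwise_rf(
    genotypes: pd.DataFrame, is_x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs r and LOD via indicator cross-products.

    ``is_x`` is a boolean vector per marker column. Returns (R, LOD)
    square matrices; diagonals are (0, n_typed*log10 2).
    """
    g = genotypes.to_numpy()
    ind = [(g == code).astype(np.float64) for code in (AA, AB, BB)]
    counts = {}
    for a in range(3):
        for b in range(3):
            counts[a, b] = ind[a].T @ ind[b]

    m = g.shape[1]
    n_par = np.zeros((m, m))
    n_rec = np.zeros((m, m))
    pair_kind = np.empty((m, m), dtype=object)
    masks = {
        "aut": np.outer(~is_x, ~is_x),
        "x": np.outer(is_x, is_x),
        "mix_a": np.outer(~is_x, is_x),
        "mix_b": np.outer(is_x, ~is_x),
    }
    tables = {
        "aut": _CELLS_AUT,
        "x": _CELLS_X,
        "mix_a": _CELLS_MIXED,
        "mix_b": _CELLS_MIXED.T,
    }
    for kind, mask in masks.items():
        table = tables[kind]
        for a in range(3):
            for b in range(3):
                if table[a, b] == 0:
                    n_par[mask] += counts[a, b][mask]
                elif table[a, b] == 1:
                    n_rec[mask] += counts[a, b][mask]
    r, lod = _rf_from_counts(n_par, n_rec)
    np.fill_diagonal(r, 0.0)
    return r, lod


# --------------------------------------------------------------------------
# Grouping

@dataclass
class LinkageGroupSet:
    groups: list[list[str]]
    singletons: list[str]
    lod_limit: float

    def sizes(self) -> list[int]:
        return [len(g) for g in self.groups]


def group_markers(
    lod: np.ndarray,
    markers: list[str],
    lod_limit: float,
    size_limit: int = 1,
    join_lod: float | None = None,
) -> LinkageGroupSet:
    """Single-linkage grouping at ``LOD >= lod_limit``.

    Groups smaller than ``size_limit`` are dissolved into singletons;
    singletons are then re-attached to the group holding their best LOD
    when that LOD reaches ``join_lod``. Output is invariant to marker
    input order (groups sorted by size then lexicographic anchor).
    """
    if lod_limit <= 0:
        raise ValueError("lod_limit must be > 0")
    m = len(markers)
    adj = lod >= lod_limit
    np.fill_diagonal(adj, False)
    labels = _connected_components(adj)
    comps: dict[int, list[int]] = {}
    for j, lab in enumerate(labels):
        comps.setdefault(lab, []).append(j)
    groups = []
    singles: list[int] = []
    for idxs in comps.values():
        if len(idxs) < max(size_limit, 2):
            singles.extend(idxs)
        else:
            groups.append(idxs)
    groups.sort(key=lambda idxs: (-len(idxs), min(markers[j] for j in idxs)))
    if join_lod is not None and groups:
        still_single = []
        for j in sorted(singles, key=lambda j: markers[j]):
            best_lod, best_g = -np.inf, None
            for gi, idxs in enumerate(groups):
                glod = lod[j, idxs].max()
                if glod > best_lod:
                    best_lod, best_g = glod, gi
            if best_lod >= join_lod:
                groups[best_g].append(j)
            else:
                still_single.append(j)
        singles = still_single
    return LinkageGroupSet(
        groups=[sorted(markers[j] for j in idxs) for idxs in groups],
        singletons=sorted(markers[j] for j in singles),
        lod_limit=lod_limit,
    )


def _connected_components(adj: np.ndarray) -> np.ndarray:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    _n, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def threshold_scan(
    lod: np.ndarray, markers: list[str], limits: np.ndarray, size_limit: int = 1
) -> pd.DataFrame:
    """Group count per LOD threshold (to locate the 4-group plateau)."""
    rows = []
    for lim in limits:
        gs = group_markers(lod, markers, float(lim), size_limit=size_limit)
        rows.append((float(lim), len(gs.groups), len(gs.singletons)))
    return pd.DataFrame(rows, columns=["lod_limit", "n_groups", "n_singletons"])


# --------------------------------------------------------------------------
# Ordering

def _chain_order(r: np.ndarray, start: int) -> list[int]:
    """Greedy nearest-neighbour chain on the r matrix."""
    m = r.shape[0]
    used = np.zeros(m, dtype=bool)
    order = [start]
    used[start] = True
    while len(order) < m:
        d_head = np.where(used, np.inf, r[order[0]])
        d_tail = np.where(used, np.inf, r[order[-1]])
        if d_tail.min() <= d_head.min():
            j = int(d_tail.argmin())
            order.append(j)
        else:
            j = int(d_head.argmin())
            order.insert(0, j)
        used[j] = True
    return order


def _tour_cost(r: np.ndarray, order: list[int]) -> float:
    idx = np.asarray(order)
    return float(r[idx[:-1], idx[1:]].sum())


def _two_opt(r: np.ndarray, order: list[int], max_rounds: int = 50) -> list[int]:
    """2-opt refinement on the open path (O(1) move evaluation)."""
    order = list(order)
    m = len(order)
    for _ in range(max_rounds):
        improved = False
        for i in range(m - 1):
            for k in range(i + 1, m):
                if i == 0 and k == m - 1:
                    continue  # whole-path reversal, no cost change
                left = r[order[i - 1], order[i]] if i > 0 else 0.0
                left_new = r[order[i - 1], order[k]] if i > 0 else 0.0
                right = r[order[k], order[k + 1]] if k < m - 1 else 0.0
                right_new = r[order[i], order[k + 1]] if k < m - 1 else 0.0
                if left_new + right_new < left + right - 1e-12:
                    order[i:k + 1] = order[i:k + 1][::-1]
                    improved = True
        if not improved:
            break
    return order


def order_markers(
    r: np.ndarray,
    markers: list[str],
    n_runs: int = 10,
    seed: int = 0,
    rank_tolerance: int = 2,
    physical_bp: np.ndarray | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Order a linkage group and remove rank-unstable markers.

    Runs greedy chaining + 2-opt ``n_runs`` times from randomized start
    markers; markers whose rank range across runs exceeds
    ``rank_tolerance`` are flagged and removed. Orientation is fixed by
    physical position when available, else by a lexicographic anchor.
    Returns (ordered marker ids, consistency report).
    """
    m = len(markers)
    if m < 3:
        raise ValueError("group must have >= 3 markers")
    rng = np.random.default_rng(seed)
    runs = []
    for _run in range(n_runs):
        start = int(rng.integers(m))
        order = _two_opt(r, _chain_order(r, start))
        runs.append(order)

    ref_rank = np.empty(m)
    ref_rank[np.asarray(runs[0])] = np.arange(m)
    ranks = np.empty((n_runs, m))
    for k, order in enumerate(runs):
        rk = np.empty(m)
        rk[np.asarray(order)] = np.arange(m)
        # align to run 0 up to reversal
        if np.corrcoef(rk, ref_rank)[0, 1] < 0:
            rk = m - 1 - rk
        ranks[k] = rk
    rank_range = ranks.max(axis=0) - ranks.min(axis=0)
    report = pd.DataFrame(
        {"marker": markers, "rank_range": rank_range,
         "unstable": rank_range > rank_tolerance}
    )
    if np.allclose(r[np.triu_indices(m, 1)], 0.0):
        report["unstable"] = False
        report["flag"] = "co-segregating"
        return sorted(markers), report

    keep = ~report["unstable"].to_numpy()
    best = min(runs, key=lambda o: _tour_cost(r, o))
    order = [j for j in best if keep[j]]
    # orientation
    pos = np.arange(len(order), dtype=float)
    if physical_bp is not None:
        bp = np.asarray(physical_bp, dtype=float)[order]
        rho = stats.spearmanr(pos, bp).statistic
        if np.isfinite(rho) and rho < 0:
            order = order[::-1]
    else:
        names = [markers[j] for j in order]
        if names[0] > names[-1]:
            order = order[::-1]
    return [markers[j] for j in order], report


# --------------------------------------------------------------------------
# Map distances

def haldane_cm(r: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: d = -50 ln(1 - 2r) cM."""
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r, dtype=float))


def inverse_haldane(d_cm: np.ndarray | float) -> np.ndarray | float:
    """r = (1 - exp(-2d/100)) / 2."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def build_genetic_map(
    ordered_groups: dict[str, list[str]],
    genotypes: pd.DataFrame,
    is_x_by_marker: dict[str, bool] | None = None,
    max_gap_cm: float = 50.0,
) -> pd.DataFrame:
    """Cumulative Haldane cM positions from adjacent r estimates.

    ``r >= 0.5`` between adjacent markers is capped at ``max_gap_cm`` and
    flagged; co-segregating markers (r = 0) share a map position.
    """
    rows = []
    for group, markers in ordered_groups.items():
        pos = 0.0
        prev = None
        for mk in markers:
            flag = ""
            if prev is not None:
                xi = bool(is_x_by_marker.get(prev, False)) if is_x_by_marker else False
                xj = bool(is_x_by_marker.get(mk, False)) if is_x_by_marker else False
                r, _lod, _fl = estimate_rf(
                    genotypes[prev].to_numpy(), genotypes[mk].to_numpy(), xi, xj
                )
                if r >= 0.5:
                    d = max_gap_cm
                    flag = "capped"
                else:
                    d = float(haldane_cm(r))
                    if d > max_gap_cm:
                        d = max_gap_cm
                        flag = "capped"
                pos += d
            rows.append((mk, group, len(rows), pos, flag))
            prev = mk
    df = pd.DataFrame(rows, columns=["marker", "group", "order", "cM", "flag"])
    # restart order index within groups
    df["order"] = df.groupby("group").cumcount()
    return df


# --------------------------------------------------------------------------
# Error-LOD screening

def error_lod_flag(
    genotypes: pd.DataFrame,
    map_df: pd.DataFrame,
    threshold: float = 5.0,
    epsilon: float = 0.001,
    x_name: str = "X",
) -> tuple[pd.DataFrame, list[str]]:
    """Per-genotype error LOD from the genotype-probability HMM.

    error LOD = log10 of the posterior odds that the observed call is
    wrong, divided by the prior odds epsilon/(1-epsilon). Markers whose
    maximum error LOD exceeds ``threshold`` are listed for removal;
    chromosomes with fewer than 3 markers are flagged ``too_sparse``.
    """
    from .scan import calc_genoprob

    eps = max(epsilon, 1e-4)
    gp = calc_genoprob(genotypes, map_df, step=0.0, epsilon=eps, x_name=x_name)
    records = []
    flagged: list[str] = []
    for chrom, dat in gp.chromosomes.items():
        mk_ids = dat["marker_ids"]
        if len(mk_ids) < 3:
            for mk in mk_ids:
                records.append((mk, chrom, np.nan, "too_sparse"))
            continue
        probs = dat["probs"]  # (n, P, C) on markers only (step=0)
        codes = genotypes[mk_ids].to_numpy()
        for j, mk in enumerate(mk_ids):
            obs = codes[:, j]
            typed = obs != MISSING
            if not typed.any():
                records.append((mk, chrom, np.nan, "no_data"))
                continue
            p_obs = probs[typed, j, :][np.arange(typed.sum()), obs[typed]]
            q = np.clip(1.0 - p_obs, 1e-300, 1 - 1e-15)
            elod = np.log10(q / (1 - q) * (1 - eps) / eps)
            mx = float(elod.max())
            note = ""
            if mx > threshold:
                flagged.append(mk)
                note = "high_error"
            records.append((mk, chrom, mx, note))
    report = pd.DataFrame(records, columns=["marker", "chrom", "max_error_lod", "flag"])
    return report, flagged
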