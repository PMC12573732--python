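"""Single-QTL genome scans for the achiasmatic F2.

Genotype probabilities come from a hidden-Markov model whose hidden
state is the pair (maternal founder allele, paternal haplotype): the
maternal component switches between positions with Haldane probability
while the paternal haplotype is constant along a chromosome (no
crossing over in males). On the X the father is hemizygous, so only two
genotype classes (AA, AB) occur.

Two scan statistics are provided. The *nonparametric* scan generalizes
the Kruskal-Wallis rank statistic to soft genotype assignments,
``LOD = H / (2 ln 10)``, and reduces exactly to the standard H at a
fully informative typed marker. The *two-part* scan models a phenotype
with a point mass at its maximum (e.g. clones alive through the whole
assay): per genotype class a spike probability pi_g and, among
non-spike individuals, a Normal(mu_g, sigma); fitted by EM over the
genotype mixture. Significance uses genome-wide permutation thresholds
(95th percentile of the permuted maxima) and peaks are reported with
1.5-LOD support intervals and the variance-explained transform
``PVE = 1 - 10^(-(2/n) LOD)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .linkage import inverse_haldane
from .simulate import MISSING

LN10 = np.log(10.0)

__all__ = [
    "GenoProb",
    "calc_genoprob",
    "scan_nonparametric",
    "scan_twopart",
    "scan_permutation_threshold",
    "lod_interval",
    "variance_explained",
    "find_peaks",
]


# --------------------------------------------------------------------------
# Genotype probabilities

@dataclass
class GenoProb:
    """Posterior genotype-class probabilities on an evaluation grid.

    ``chromosomes[name]`` holds ``positions`` (cM), ``is_marker``,
    ``marker_ids`` (per grid position, "" at pseudo-positions),
    ``n_classes`` (3 autosome / 2 X) and ``probs`` of shape
    (individuals, positions, 3); the third class column is zero on X.
    """

    individuals: list[str]
    chromosomes: dict[str, dict]
    epsilon: float
    step: float

    @property
    def n(self) -> int:
        return len(self.individuals)

    def positions_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, dat in self.chromosomes.items():
            for p, ismk in zip(dat["positions"], dat["is_marker"]):
                rows.append((chrom, float(p), bool(ismk)))
        return pd.DataFrame(rows, columns=["chrom", "pos", "is_marker"])


def _emission_matrix(epsilon: float) -> np.ndarray:
    """P(observed | true) with single-step confusion at rate epsilon."""
    e = epsilon
    return np.array(
        [
            [1 - e, e, 0.0],
            [e / 2, 1 - e, e / 2],
            [0.0, e, 1 - e],
        ]
    )


def _grid(marker_cm: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Marker positions merged with pseudo-positions every ``step`` cM."""
    if step <= 0:
        return marker_cm.copy(), np.ones(len(marker_cm), dtype=bool)
    lo, hi = marker_cm[0], marker_cm[-1]
    pseudo = np.arange(np.ceil(lo / step) * step, hi, step)
    pos = np.concatenate([marker_cm, pseudo])
    ismk = np.concatenate(
        [np.ones(len(marker_cm), dtype=bool), np.zeros(len(pseudo), dtype=bool)]
    )
    order = np.argsort(pos, kind="stable")
    pos, ismk = pos[order], ismk[order]
    keep = np.ones(len(pos), dtype=bool)
    for i in range(1, len(pos)):
        if pos[i] - pos[i - 1] < 1e-9 and not ismk[i]:
            keep[i] = False  # pseudo-position colliding with a marker
    return pos[keep], ismk[keep]


def calc_genoprob(
    genotypes: pd.DataFrame,
    map_df: pd.DataFrame,
    step: float = 1.0,
    epsilon: float = 0.001,
    x_name: str = "X",
) -> GenoProb:
    """Forward-backward genotype-class posteriors on markers + grid.

    ``map_df`` needs columns marker, chrom, cM (cM non-decreasing within
    chromosome). With ``epsilon`` = 0 the posterior at a typed marker is
    1 on the observed class.
    """
    if not 0 <= epsilon < 0.5:
        raise ValueError("epsilon must be in [0, 0.5)")
    chrom_col = "chrom" if "chrom" in map_df.columns else "group"
    emit = _emission_matrix(epsilon)
    n = len(genotypes)
    out: dict[str, dict] = {}
    for chrom, sub in map_df.groupby(chrom_col, sort=False):
        sub = sub[sub["marker"].isin(genotypes.columns)]
        if len(sub) == 0:
            continue
        mk_cm = sub["cM"].to_numpy(dtype=float)
        if np.any(np.diff(mk_cm) < -1e-9):
            raise ValueError(f"map positions not sorted on {chrom}")
        mk_ids = sub["marker"].tolist()
        pos, ismk = _grid(mk_cm, step)
        obs = np.full((n, len(pos)), MISSING, dtype=np.int8)
        mk_slot = np.searchsorted(pos, mk_cm)
        # align marker order with grid slots (stable for shared positions)
        slot_of_marker = {}
        used = set()
        for j, p in enumerate(mk_cm):
            s = int(mk_slot[j])
            while s in used or not ismk[s] or abs(pos[s] - p) > 1e-9:
                s += 1
            used.add(s)
            slot_of_marker[mk_ids[j]] = s
        grid_marker_ids = [""] * len(pos)
        for mk, s in slot_of_marker.items():
            grid_marker_ids[s] = mk
            obs[:, s] = genotypes[mk].to_numpy()

        is_x = str(chrom) == x_name
        probs = _forward_backward(obs, pos, emit, is_x)
        out[str(chrom)] = {
            "positions": pos,
            "is_marker": ismk,
            "marker_ids": [grid_marker_ids[s] if ismk[s] else ""
                           for s in range(len(pos))],
            "grid_marker_list": mk_ids,
            "n_classes": 2 if is_x else 3,
            "probs": probs,
        }
    return GenoProb(
        individuals=list(genotypes.index),
        chromosomes=out,
        epsilon=epsilon,
        step=step,
    )


def _forward_backward(
    obs: np.ndarray, pos: np.ndarray, emit: np.ndarray, is_x: bool
) -> np.ndarray:
    """Posterior over genotype classes; hidden state = (maternal, paternal).

    Runs the 2-state maternal chain conditional on each paternal
    haplotype (weight 1/2 each on autosomes; fixed haplotype on X) and
    mixes the chains by their marginal likelihoods.
    """
    n, P = obs.shape
    r = inverse_haldane(np.diff(pos))
    paternal = (0,) if is_x else (0, 1)
    post = np.zeros((n, P, 3))
    log_mix = np.full((n, len(paternal)), -np.inf)
    cond_post = []
    for hi, h in enumerate(paternal):
        # emission prob of each maternal state m: class = m + h
        e = np.ones((n, P, 2))
        typed = obs != MISSING
        for m in (0, 1):
            cls = m + h
            e[:, :, m] = np.where(typed, emit[cls, np.clip(obs, 0, 2)], 1.0)
        alpha = np.empty((n, P, 2))
        c = np.empty((n, P))
        a = 0.5 * e[:, 0, :]
        s = a.sum(axis=1)
        dead = s <= 0
        if dead.any():
            # observation impossible under this chain: skip its emission but
            # record a vanishing likelihood so chain mixing is correct
            a[dead] = 0.5
            s[dead] = 1.0
        alpha[:, 0, :] = a / s[:, None]
        c[:, 0] = np.where(dead, 1e-300, s)
        for t in range(1, P):
            rt = r[t - 1]
            T = np.array([[1 - rt, rt], [rt, 1 - rt]])
            a = (alpha[:, t - 1, :] @ T) * e[:, t, :]
            s = a.sum(axis=1)
            dead = s <= 0
            if dead.any():
                a[dead] = (alpha[dead, t - 1, :] @ T)
                s[dead] = a[dead].sum(axis=1)
            alpha[:, t, :] = a / s[:, None]
            c[:, t] = np.where(dead, 1e-300, s)
        beta = np.ones((n, 2))
        post_h = np.empty((n, P, 2))
        post_h[:, P - 1, :] = alpha[:, P - 1, :]
        for t in range(P - 2, -1, -1):
            rt = r[t]
            T = np.array([[1 - rt, rt], [rt, 1 - rt]])
            b = (beta * e[:, t + 1, :]) @ T.T
            sb = b.sum(axis=1)
            dead = sb <= 0
            if dead.any():  # same emission skip as the forward pass
                b[dead] = beta[dead] @ T.T
                sb[dead] = b[dead].sum(axis=1)
            beta = b / sb[:, None]
            pt = alpha[:, t, :] * beta
            post_h[:, t, :] = pt / np.maximum(pt.sum(axis=1, keepdims=True), 1e-300)
        log_mix[:, hi] = np.log(np.maximum(c, 1e-300)).sum(axis=1)
        cond_post.append(post_h)
    log_mix -= log_mix.max(axis=1, keepdims=True)
    w = np.exp(log_mix)
    w /= w.sum(axis=1, keepdims=True)
    for hi, h in enumerate(paternal):
        for m in (0, 1):
            post[:, :, m + h] += w[:, hi, None] * cond_post[hi][:, :, m]
    return post


# --------------------------------------------------------------------------
# Scan results

@dataclass
class ScanResult:
    trait: str
    model: str
    table: pd.DataFrame  # chrom, pos, is_marker, lod [, lod_spike, lod_quant]
    n: int
    threshold: float | None = None
    peaks: list[dict] = field(default_factory=list)

    def max_lod(self) -> float:
        return float(self.table["lod"].max())


def _subset_probs(gp: GenoProb, trait: pd.Series):
    """Align trait with individuals, dropping missing phenotypes."""
    y = trait.reindex(gp.individuals).to_numpy(dtype=float)
    keep = np.isfinite(y)
    return y[keep], keep


# --------------------------------------------------------------------------
# Nonparametric (rank) scan

def _kw_lod(probs: np.ndarray, ranks: np.ndarray, tie_corr: float) -> np.ndarray:
    """Probability-weighted Kruskal-Wallis H / (2 ln 10) per position."""
    N = len(ranks)
    S = np.einsum("ipc,i->pc", probs, ranks)
    ng = probs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        H = 12.0 / (N * (N + 1)) * np.where(ng > 1e-12, S * S / np.maximum(ng, 1e-12),
                                            0.0).sum(axis=1) - 3.0 * (N + 1)
    if tie_corr > 0:
        H = H / tie_corr
    return np.maximum(H / (2 * LN10), 0.0)


def _tie_correction(y: np.ndarray) -> float:
    N = len(y)
    _vals, counts = np.unique(y, return_counts=True)
    c = 1.0 - float(((counts ** 3 - counts).sum()) / (N ** 3 - N))
    return c


def scan_nonparametric(gp: GenoProb, trait: pd.Series, name: str | None = None
                       ) -> ScanResult:
    """Rank-based single-QTL scan (soft Kruskal-Wallis), LOD = H/(2 ln 10)."""
    y, keep = _subset_probs(gp, trait)
    if np.unique(y).size < 2:
        table = gp.positions_frame()
        table["lod"] = 0.0
        import warnings

        warnings.warn("constant trait: LOD is 0 everywhere")
        return ScanResult(name or str(trait.name), "nonparametric", table, len(y))
    ranks = stats.rankdata(y)
    tie = _tie_correction(y)
    rows = []
    for chrom, dat in gp.chromosomes.items():
        probs = dat["probs"][keep][:, :, : dat["n_classes"]]
        lod = _kw_lod(probs, ranks, tie)
        for p, ismk, ld in zip(dat["positions"], dat["is_marker"], lod):
            rows.append((chrom, float(p), bool(ismk), float(ld)))
    table = pd.DataFrame(rows, columns=["chrom", "pos", "is_marker", "lod"])
    return ScanResult(name or str(trait.name), "nonparametric", table, len(y))


# --------------------------------------------------------------------------
# Two-part (spike) scan

def _twopart_null_ll(z: np.ndarray, y: np.ndarray) -> float:
    """Closed-form null: shared spike probability and Normal."""
    n = len(y)
    k = z.sum()
    ll = 0.0
    if 0 < k < n:
        pi = k / n
        ll += k * np.log(pi) + (n - k) * np.log(1 - pi)
    ynz = y[~z]
    if ynz.size >= 2 and ynz.std() > 0:
        sd = ynz.std()
        ll += float(np.sum(stats.norm.logpdf(ynz, ynz.mean(), sd)))
    return float(ll)


def _twopart_em(
    probs: np.ndarray,
    z: np.ndarray,
    y: np.ndarray,
    free_spike: bool,
    free_mean: bool,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> np.ndarray:
    """EM over the genotype mixture, vectorized across positions.

    ``probs``: (n, P, C) prior genotype probabilities. Returns the
    maximized log-likelihood per position for the model where the spike
    probability and/or the non-spike mean are genotype specific.
    """
    n, P, C = probs.shape
    nz = ~z
    ynz = y[nz]
    # initial values from prior-weighted moments
    w = probs.copy()  # responsibilities, start at priors
    ll_old = np.full(P, -np.inf)
    pi = np.clip(
        np.einsum("ipc,i->pc", w, z.astype(float)) / np.maximum(w.sum(axis=0), 1e-12),
        1e-6, 1 - 1e-6,
    )
    mu = np.tile(ynz.mean() if ynz.size else 0.0, (P, C))
    sd = np.tile(max(ynz.std(), 1e-6) if ynz.size else 1.0, P)
    if free_mean and ynz.size:
        wn = w[nz]
        mu = np.einsum("ipc,i->pc", wn, ynz) / np.maximum(wn.sum(axis=0), 1e-12)
    for _it in range(max_iter):
        # E step: log density of each individual under each class
        logf = np.zeros((n, P, C))
        if z.any():
            logf[z] = np.log(pi)[None, :, :]
        if nz.any():
            resid = (ynz[:, None, None] - mu[None, :, :]) / sd[None, :, None]
            logf[nz] = (
                np.log1p(-pi)[None, :, :]
                - 0.5 * resid ** 2
                - np.log(sd)[None, :, None]
                - 0.5 * np.log(2 * np.pi)
            )
        a = np.log(np.maximum(probs, 1e-300)) + logf
        amax = a.max(axis=2, keepdims=True)
        lik = np.exp(a - amax)
        tot = lik.sum(axis=2, keepdims=True)
        ll = (np.log(tot[:, :, 0]) + amax[:, :, 0]).sum(axis=0)
        w = lik / tot
        # M step
        wsum = np.maximum(w.sum(axis=0), 1e-12)
        if free_spike:
            pi = np.clip(
                np.einsum("ipc,i->pc", w, z.astype(float)) / wsum, 1e-9, 1 - 1e-9
            )
        else:
            k = float(z.sum())
            pi = np.full((P, C), np.clip(k / n, 1e-9, 1 - 1e-9))
        if nz.any():
            wn = w[nz]
            wnsum = np.maximum(wn.sum(axis=0), 1e-12)
            if free_mean:
                mu = np.einsum("ipc,i->pc", wn, ynz) / wnsum
            else:
                mu = np.tile(
                    (np.einsum("ipc,i->pc", wn, ynz).sum(axis=1)
                     / wnsum.sum(axis=1))[:, None],
                    (1, C),
                )
            var = np.einsum("ipc,ipc->p", wn, (ynz[:, None, None] - mu[None]) ** 2)
            sd = np.sqrt(np.maximum(var / wnsum.sum(axis=1), 1e-12))
        if np.all(np.abs(ll - ll_old) < tol * (1 + np.abs(ll))):
            ll_old = ll
            break
        ll_old = ll
    return ll_old


def scan_twopart(
    gp: GenoProb,
    trait: pd.Series,
    spike_at_upper: bool = True,
    name: str | None = None,
) -> ScanResult:
    """Two-part spike scan; joint LOD is the scan statistic.

    The trait is split into the point mass at its maximum (minimum when
    ``spike_at_upper`` is false) and the continuous remainder. Reports
    the joint LOD plus spike-only and quantitative-only component LODs.
    """
    y, keep = _subset_probs(gp, trait)
    spike_val = y.max() if spike_at_upper else y.min()
    z = y == spike_val
    all_spike = bool(z.all())
    ll0 = _twopart_null_ll(z, y)
    rows = []
    for chrom, dat in gp.chromosomes.items():
        probs = dat["probs"][keep][:, :, : dat["n_classes"]]
        P = probs.shape[1]
        if all_spike:
            ll_full = ll_spike = np.full(P, ll0)
            ll_quant = np.full(P, ll0)
        else:
            ll_spike = _twopart_em(probs, z, y, free_spike=True, free_mean=False)
            ll_quant = _twopart_em(probs, z, y, free_spike=False, free_mean=True)
            ll_full = _twopart_em(probs, z, y, free_spike=True, free_mean=True)
        lod = np.maximum((ll_full - ll0) / LN10, 0.0)
        lod_s = np.maximum((ll_spike - ll0) / LN10, 0.0)
        lod_q = np.maximum((ll_quant - ll0) / LN10, 0.0)
        for i, (p, ismk) in enumerate(zip(dat["positions"], dat["is_marker"])):
            rows.append((chrom, float(p), bool(ismk), float(lod[i]),
                         float(lod_s[i]), float(lod_q[i])))
    table = pd.DataFrame(
        rows, columns=["chrom", "pos", "is_marker", "lod", "lod_spike", "lod_quant"]
    )
    return ScanResult(name or str(trait.name), "two-part", table, len(y))


# --------------------------------------------------------------------------
# Thresholds, intervals, PVE

def scan_permutation_threshold(
    gp: GenoProb,
    trait: pd.Series,
    model: str = "nonparametric",
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    spike_at_upper: bool = True,
) -> tuple[float, np.ndarray]:
    """Genome-wide permutation threshold (empirical quantile, type 7).

    Permutes trait values across individuals, rescans, and records the
    genome-wide maximum LOD; the threshold is the (1 - alpha) quantile
    of the permuted maxima.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    y = trait.reindex(gp.individuals)
    scan_fn = {
        "nonparametric": lambda t: scan_nonparametric(gp, t),
        "two-part": lambda t: scan_twopart(gp, t, spike_at_upper=spike_at_upper),
    }[model]
    maxima = np.empty(n_perm)
    vals = y.to_numpy()
    for b in range(n_perm):
        perm = pd.Series(rng.permutation(vals), index=gp.individuals)
        maxima[b] = scan_fn(perm).max_lod()
    thr = float(np.quantile(maxima, 1 - alpha, method="linear"))
    return thr, maxima


def lod_interval(
    scan: ScanResult, chrom: str, peak_pos: float | None = None, drop: float = 1.5
) -> tuple[float, float]:
    """1.5-LOD support interval, expanded to the flanking markers.

    Returns the widest contiguous cM interval around the peak where
    ``LOD >= peak - drop``, then widens each end to the nearest marker
    at or beyond it (clipped at the chromosome ends).
    """
    if drop <= 0:
        raise ValueError("drop must be > 0")
    sub = scan.table[scan.table["chrom"] == chrom].reset_index(drop=True)
    pos = sub["pos"].to_numpy()
    lod = sub["lod"].to_numpy()
    if peak_pos is None:
        pk = int(lod.argmax())
    else:
        pk = int(np.abs(pos - peak_pos).argmin())
    lo = hi = pk
    cut = lod[pk] - drop
    while lo > 0 and lod[lo - 1] >= cut:
        lo -= 1
    while hi < len(lod) - 1 and lod[hi + 1] >= cut:
        hi += 1
    ismk = sub["is_marker"].to_numpy()
    i = lo
    while i > 0 and not ismk[i]:
        i -= 1
    lo = i if ismk[i] else lo
    j = hi
    while j < len(lod) - 1 and not ismk[j]:
        j += 1
    hi = j if ismk[j] else hi
    return float(pos[lo]), float(pos[hi])


def variance_explained(lod: float | np.ndarray, n: int) -> float | np.ndarray:
    """Proportion of phenotypic variance: 1 - 10^(-(2/n) LOD)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1.0 - 10.0 ** (-(2.0 / n) * np.asarray(lod, dtype=float))


def find_peaks(scan: ScanResult, threshold: float, drop: float = 1.5) -> list[dict]:
    """Per-chromosome maxima above threshold with support intervals."""
    peaks = []
    for chrom, sub in scan.table.groupby("chrom", sort=False):
        i = sub["lod"].idxmax()
        if sub.loc[i, "lod"] >= threshold:
            lo, hi = lod_interval(scan, chrom, float(sub.loc[i, "pos"]), drop)
            peaks.append(
                {
                    "chrom": chrom,
                    "pos": float(sub.loc[i, "pos"]),
                    "lod": float(sub.loc[i, "lod"]),
                    "interval": (lo, hi),
                    "pve": float(variance_explained(sub.loc[i, "lod"], scan.n)),
                }
            )
    scan.threshold = threshold
    scan.peaks = peaks
    return peaks
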