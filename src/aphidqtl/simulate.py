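"""Synthetic F2 intercross generator.

Emulates the mapping design of a pea-aphid host-race cross: two
homozygous, divergent grandparental (F0) genomes per race, double
heterozygous F1 parents, and an F2 family in which all recombination
comes from the female parent (aphid males have achiasmatic meiosis).
The X chromosome is modelled with a hemizygous father contributing a
single fixed haplotype, so X markers segregate in two genotype classes.

Genotypes are coded ``0`` (AA), ``1`` (AB), ``2`` (BB) with ``-1`` for
missing; the A allele is the alfalfa-race allele throughout.

Phenotypes mirror the study's assay structure: acceptance as the
proportion of probing observations among observations alive (17
observation timepoints x 4 clonal replicates), survival as mean
time-steps alive with a point mass at the maximum, and survival counts
out of 4 trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

# Genotype codes
AA, AB, BB, MISSING = 0, 1, 2, -1
GENO_LABELS = {AA: "AA", AB: "AB", BB: "BB", MISSING: "NA"}
LABEL_TO_CODE = {v: k for k, v in GENO_LABELS.items()}

#: (name, genetic length cM, physical length Mb) of the four aphid chromosomes
DEFAULT_CHROMOSOMES = (
    ("A1", 172.0, 160.0),
    ("A2", 112.0, 130.0),
    ("A3", 114.0, 135.0),
    ("X", 204.0, 133.0),
)

#: Heritability presets for the four assayed traits (genome-wide estimates)
TRAIT_H2 = {
    "acceptance_pea": 0.097,
    "acceptance_alfalfa": 0.299,
    "survival_pea": 0.388,
    "survival_alfalfa": 0.148,
}


@dataclass
class CrossConfig:
    """Parameters of the simulated F2 cross.

    Parameters
    ----------
    n_f2
        Number of F2 clones (the study genotyped 192).
    chromosomes
        Tuples of (name, genetic length in cM, physical length in Mb).
    n_markers
        Markers per chromosome (single int, or one per chromosome).
    error_rate
        Symmetric single-step genotyping error rate (AA<->AB, AB<->hom).
    missing_rate
        Per-genotype missing probability.
    frac_uninformative
        Fraction of markers monomorphic across the two races.
    frac_f0_het
        Fraction of markers with a heterozygous F0 (fails parentage QC).
    frac_distorted
        Fraction of markers with injected segregation distortion.
    distortion_probs
        Genotype frequencies used for distorted autosomal markers.
    seed
        Seed of the generator; identical seeds give identical output.
    """

    n_f2: int = 192
    chromosomes: Sequence[tuple[str, float, float]] = DEFAULT_CHROMOSOMES
    n_markers: int | Sequence[int] = 120
    error_rate: float = 0.001
    missing_rate: float = 0.02
    frac_uninformative: float = 0.0
    frac_f0_het: float = 0.0
    frac_distorted: float = 0.0
    distortion_probs: tuple[float, float, float] = (0.40, 0.50, 0.10)
    x_distortion_probs: tuple[float, float] = (0.75, 0.25)
    x_name: str = "X"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f2 < 2:
            raise ValueError("n_f2 must be >= 2")
        for name, cm, mb in self.chromosomes:
            if cm <= 0 or mb <= 0:
                raise ValueError(f"chromosome {name}: lengths must be > 0")
        for attr in ("error_rate", "missing_rate", "frac_uninformative",
                     "frac_f0_het", "frac_distorted"):
            v = getattr(self, attr)
            if not 0 <= v < 1:
                raise ValueError(f"{attr} must be in [0, 1)")

    def markers_per_chromosome(self) -> list[int]:
        if isinstance(self.n_markers, int):
            return [self.n_markers] * len(self.chromosomes)
        ns = list(self.n_markers)
        if len(ns) != len(self.chromosomes):
            raise ValueError("n_markers must match number of chromosomes")
        return ns


@dataclass
class Founders:
    """Grandparental and F1 genomes with the marker map.

    ``markers`` has columns marker, chrom, bp, cM plus QC-truth flags.
    F0 rows are ordered (race1_a, race1_b, race2_a, race2_b) with race 1
    carrying the A (alfalfa) allele; F1 rows are (mother, father).
    """

    markers: pd.DataFrame
    f0: np.ndarray  # (4, M) int8 genotype codes
    f1: np.ndarray  # (2, M) int8


class TruthRecord:
    """Ground truth of the simulated cross.

    Stores maternal crossover positions, maternal founder alleles at the
    markers, the (constant per chromosome) paternal haplotype labels, and
    any phenotype architecture used downstream.
    """

    def __init__(self, config: CrossConfig, markers: pd.DataFrame):
        self.config = config
        self.markers = markers
        self.chrom_info = {c[0]: (c[1], c[2]) for c in config.chromosomes}
        self.maternal_start: dict[str, np.ndarray] = {}
        self.crossovers: dict[str, list[np.ndarray]] = {}
        self.paternal_hap: dict[str, np.ndarray] = {}
        self.maternal_alleles: dict[str, np.ndarray] = {}  # (n, m_c)
        self.true_genotypes: pd.DataFrame | None = None
        self.phenotype_truth: dict[str, dict] = {}

    def maternal_allele_at(self, chrom: str, pos_cm: float) -> np.ndarray:
        """Maternal founder allele (0=A, 1=B) for every F2 at a cM position."""
        n = self.config.n_f2
        out = np.empty(n, dtype=np.int8)
        start = self.maternal_start[chrom]
        for i in range(n):
            k = int(np.searchsorted(self.crossovers[chrom][i], pos_cm))
            out[i] = (start[i] + k) % 2
        return out

    def genotype_at(self, chrom: str, pos_cm: float) -> np.ndarray:
        """True genotype code (0/1/2) for every F2 at an arbitrary position."""
        m = self.maternal_allele_at(chrom, pos_cm)
        return (m + self.paternal_hap[chrom]).astype(np.int8)

    def to_json(self) -> str:
        payload = {
            "n_f2": self.config.n_f2,
            "chromosomes": list(self.chrom_info.keys()),
            "maternal_start": {c: v.tolist() for c, v in self.maternal_start.items()},
            "crossovers": {
                c: [np.round(x, 6).tolist() for x in v]
                for c, v in self.crossovers.items()
            },
            "paternal_hap": {c: v.tolist() for c, v in self.paternal_hap.items()},
            "phenotype_truth": self.phenotype_truth,
        }
        return json.dumps(payload, indent=1)


def _marker_table(config: CrossConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Collinear truth map: bp uniform per chromosome, cM proportional."""
    rows = []
    for (name, cm_len, mb_len), n_mark in zip(
        config.chromosomes, config.markers_per_chromosome()
    ):
        bp = np.sort(rng.choice(int(mb_len * 1e6), size=n_mark, replace=False)) + 1
        cm = bp / (mb_len * 1e6) * cm_len
        for j in range(n_mark):
            rows.append((f"{name}_m{j:04d}", name, int(bp[j]), float(cm[j])))
    df = pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cM"])
    m = len(df)
    for frac, col in [
        (config.frac_uninformative, "uninformative"),
        (config.frac_f0_het, "f0_het"),
        (config.frac_distorted, "distorted"),
    ]:
        flag = np.zeros(m, dtype=bool)
        k = int(round(frac * m))
        if k:
            flag[rng.choice(m, size=k, replace=False)] = True
        df[col] = flag
    return df


def simulate_founders(config: CrossConfig) -> Founders:
    """Generate F0 genomes for the two races and the F1 pair.

    Informative markers are fixed AA|AA in race 1 (alfalfa) and BB|BB in
    race 2 (pea), making both F1s heterozygous with known coupling phase.
    Markers flagged uninformative are monomorphic (AA) in both races;
    markers flagged ``f0_het`` carry a heterozygous F0 to exercise the
    parentage filter.
    """
    rng = np.random.default_rng(config.seed)
    markers = _marker_table(config, rng)
    m = len(markers)
    f0 = np.empty((4, m), dtype=np.int8)
    f0[0] = f0[1] = AA
    f0[2] = f0[3] = BB
    f1 = np.full((2, m), AB, dtype=np.int8)

    uninf = markers["uninformative"].to_numpy()
    f0[:, uninf] = AA
    f1[:, uninf] = AA

    het = markers["f0_het"].to_numpy()
    f0[0, het] = AB  # one race-1 grandparent heterozygous
    return Founders(markers=markers, f0=f0, f1=f1)


def simulate_f2_genotypes(
    founders: Founders, config: CrossConfig, seed: int | None = None
) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw the F2 family.

    Each F2 inherits a recombinant maternal gamete (crossovers from a
    no-interference Poisson process on the cM scale, i.e. Haldane
    consistent) and one intact paternal F1 haplotype per chromosome
    (fair coin on autosomes; a single fixed haplotype on X, the father
    being hemizygous). Genotyping errors are then applied symmetrically
    at rate epsilon and missing codes injected.

    Returns the observed genotype matrix (individuals x markers, int8
    codes with -1 = missing) and the :class:`TruthRecord`.
    """
    markers = founders.markers
    for chrom, sub in markers.groupby("chrom", sort=False):
        if not sub["cM"].is_monotonic_increasing:
            raise ValueError(f"marker map not sorted by cM on chromosome {chrom}")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_f2
    truth = TruthRecord(config, markers)
    ids = [f"o{i + 1}" for i in range(n)]
    cols = {}
    true_cols = {}

    for name, cm_len, _mb in config.chromosomes:
        sub = markers[markers["chrom"] == name]
        pos = sub["cM"].to_numpy()
        start = rng.integers(0, 2, size=n).astype(np.int8)
        xovers = []
        mat = np.empty((n, len(sub)), dtype=np.int8)
        for i in range(n):
            k = rng.poisson(cm_len / 100.0)
            xo = np.sort(rng.uniform(0.0, cm_len, size=k))
            xovers.append(xo)
            switches = np.searchsorted(xo, pos)
            mat[i] = (start[i] + switches) % 2
        if name == config.x_name:
            pat = np.zeros(n, dtype=np.int8)  # hemizygous father: fixed A haplotype
        else:
            pat = rng.integers(0, 2, size=n).astype(np.int8)
        geno = mat + pat[:, None]

        truth.maternal_start[name] = start
        truth.crossovers[name] = xovers
        truth.paternal_hap[name] = pat
        truth.maternal_alleles[name] = mat

        # uninformative markers are monomorphic whatever was inherited
        geno[:, sub["uninformative"].to_numpy()] = AA
        # injected segregation distortion: iid skewed draws
        dist_idx = np.flatnonzero(sub["distorted"].to_numpy())
        for j in dist_idx:
            if name == config.x_name:
                geno[:, j] = rng.choice([AA, AB], size=n,
                                        p=config.x_distortion_probs)
            else:
                geno[:, j] = rng.choice([AA, AB, BB], size=n,
                                        p=config.distortion_probs)
        for j, mk in enumerate(sub["marker"]):
            true_cols[mk] = geno[:, j].copy()
        cols[name] = (sub["marker"].tolist(), geno)

    true_df = pd.DataFrame(true_cols, index=ids).astype(np.int8)
    truth.true_genotypes = true_df

    obs = true_df.to_numpy().copy()
    if config.error_rate > 0:
        err = rng.random(obs.shape) < config.error_rate
        flip = rng.integers(0, 2, size=obs.shape)
        new = obs.copy()
        new[obs == AA] = AB
        new[obs == BB] = AB
        het = obs == AB
        new[het] = np.where(flip[het] == 0, AA, BB)
        obs = np.where(err, new, obs)
    if config.missing_rate > 0:
        obs[rng.random(obs.shape) < config.missing_rate] = MISSING
    geno_df = pd.DataFrame(obs.astype(np.int8), index=ids,
                           columns=true_df.columns)
    return geno_df, truth


@dataclass
class PhenotypeModel:
    """Genetic architecture and assay structure for one trait family.

    ``architecture`` lists QTLs as (chromosome, position cM, additive
    effect a, dominance effect d) on the liability scale (genotype codes
    -1/0/+1 for AA/AB/BB; the dominance deviation applies to AB). The
    environmental variance is derived from the target broad-sense
    heritability ``h2`` of clone means unless ``env_var`` is given.

    Survival is generated from a per-step cloglog hazard shifted by the
    same genetic value; ``base_step_hazard`` sets the per-observation
    death probability of an average clone.
    """

    name: str = "trait"
    architecture: Sequence[tuple[str, float, float, float]] = ()
    polygenic_var: float = 0.0
    h2: float | None = None
    env_var: float | None = None
    n_timepoints: int = 17
    n_replicates: int = 4
    base_step_hazard: float = 0.01
    hazard_beta: float = 1.0
    acceptance_intercept: float = 0.0

    def genetic_variance(self) -> float:
        """Theoretical genetic variance of the architecture in an F2."""
        v = float(self.polygenic_var)
        for _c, _pos, a, d in self.architecture:
            v += a * a / 2.0 + d * d / 4.0
        return v

    def environmental_variance(self) -> float:
        if self.env_var is not None:
            return float(self.env_var)
        vg = self.genetic_variance()
        if self.h2 is None:
            return 1.0
        if not 0 < self.h2 < 1:
            raise ValueError("target h2 must be in (0, 1)")
        if vg == 0:
            raise ValueError("architecture has zero genetic variance; "
                             "cannot scale to a target h2")
        return vg * (1.0 - self.h2) / self.h2


def _genetic_values(
    truth: TruthRecord, model: PhenotypeModel, rng: np.random.Generator
) -> np.ndarray:
    """Sum of QTL effects plus a genomically structured polygenic value."""
    n = truth.config.n_f2
    g = np.zeros(n)
    for chrom, pos, a, d in model.architecture:
        if chrom not in truth.chrom_info:
            raise ValueError(f"QTL chromosome {chrom!r} not in the map")
        if not 0 <= pos <= truth.chrom_info[chrom][0]:
            raise ValueError(f"QTL position {pos} cM off chromosome {chrom}")
        x = truth.genotype_at(chrom, pos).astype(float) - 1.0  # -1/0/+1
        g += a * x + d * (x == 0.0)
    if model.polygenic_var > 0:
        assert truth.true_genotypes is not None
        z = truth.true_genotypes.to_numpy().astype(float) - 1.0
        z = z - z.mean(axis=0)
        sd = z.std(axis=0)
        keep = sd > 0
        z = z[:, keep] / sd[keep]
        w = rng.standard_normal(z.shape[1])
        u = z @ w
        u *= np.sqrt(model.polygenic_var) / max(u.std(), 1e-12)
        g += u
    return g


def simulate_phenotypes(
    truth: TruthRecord,
    model: PhenotypeModel,
    seed: int = 0,
    mode: str = "direct",
) -> pd.DataFrame:
    """Generate phenotypes for every F2 clone.

    Two modes:

    ``direct``
        Clone mean = QTL effects + polygenic value + Gaussian noise
        scaled so the expected heritability of clone means equals the
        target ``h2``. The raw clone mean is returned as ``liability``;
        ``acceptance`` is its logistic transform (a monotone map into
        [0, 1]), ``survival_steps`` truncates the latent value at the
        17-step maximum (spike at the upper bound), and
        ``survival_count`` counts replicate-level survivals out of 4.

    ``mechanistic``
        Replicates and observation timepoints are simulated explicitly:
        per step, death via a cloglog hazard shifted by the genetic
        value; probing among alive observations via a clone-level
        logistic liability. Acceptance = probing obs / alive obs pooled
        over replicates (missing if no alive observation), survival =
        mean time-steps alive, count = replicates alive at the end.
    """
    if mode not in ("direct", "mechanistic"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    n = truth.config.n_f2
    ids = [f"o{i + 1}" for i in range(n)]
    g = _genetic_values(truth, model, rng)
    sigma_e = np.sqrt(model.environmental_variance())
    T, R = model.n_timepoints, model.n_replicates

    truth.phenotype_truth[model.name] = {
        "mode": mode,
        "h2_target": model.h2,
        "genetic_variance": model.genetic_variance(),
        "environmental_variance": sigma_e ** 2,
        "genetic_values": np.round(g, 6).tolist(),
    }

    if mode == "direct":
        liab = g + sigma_e * rng.standard_normal(n)
        scale = max(np.sqrt(model.genetic_variance() + sigma_e ** 2), 1e-12)
        z = (liab - liab.mean()) / scale
        acceptance = 1.0 / (1.0 + np.exp(-z))
        # spike at the maximum: clones above the cutoff survive all steps
        cutoff = 0.0
        steps = np.minimum(float(T), T + 4.0 * (z - cutoff))
        steps = np.clip(steps, 0.0, float(T))
        rep = g[:, None] + sigma_e * rng.standard_normal((n, R))
        count = (rep > np.quantile(rep, 0.15)).sum(axis=1)
        return pd.DataFrame(
            {
                "liability": liab,
                "acceptance": acceptance,
                "survival_steps": steps,
                "survival_count": count.astype(int),
            },
            index=ids,
        )

    # mechanistic
    base = float(model.base_step_hazard)
    if not 0 <= base < 1:
        raise ValueError("base_step_hazard must be in [0, 1)")
    liab_clone = model.acceptance_intercept + g + sigma_e * rng.standard_normal(n)
    p_probe = 1.0 / (1.0 + np.exp(-liab_clone))
    alive_obs = np.zeros(n)
    probe_obs = np.zeros(n)
    steps_alive = np.zeros((n, R))
    alive_end = np.zeros((n, R), dtype=bool)
    if base > 0:
        log_h = np.log(-np.log1p(-base))  # cloglog of the per-step death prob
        p_death = 1.0 - np.exp(-np.exp(log_h + model.hazard_beta * g))
    else:
        p_death = np.zeros(n)
    for r in range(R):
        alive = np.ones(n, dtype=bool)
        for _t in range(T):
            died = rng.random(n) < p_death
            alive &= ~died
            steps_alive[:, r] += alive
            probing = alive & (rng.random(n) < p_probe)
            alive_obs += alive
            probe_obs += probing
        alive_end[:, r] = alive
    with np.errstate(invalid="ignore", divide="ignore"):
        acceptance = np.where(alive_obs > 0, probe_obs / alive_obs, np.nan)
    return pd.DataFrame(
        {
            "liability": liab_clone,
            "acceptance": acceptance,
            "survival_steps": steps_alive.mean(axis=1),
            "survival_count": alive_end.sum(axis=1).astype(int),
        },
        index=ids,
    )


#: Census of annotated chemosensory genes by category
DEFAULT_GENE_COUNTS = {"OR": 70, "GR": 60, "IR": 19, "OBP": 11, "CSP": 10, "SNMP": 9}


def simulate_gene_positions(
    config: CrossConfig,
    clustering: float = 0.0,
    counts: dict[str, int] | None = None,
    seed: int | None = None,
    cluster_sd_mb: float = 1.0,
    clusters_per_100mb: float = 2.0,
) -> pd.DataFrame:
    """Place categorised genes on the simulated chromosomes.

    With ``clustering`` = 0 positions are uniform; otherwise each gene is,
    with that probability, drawn around a Poisson-process cluster centre
    (Gaussian spread ``cluster_sd_mb``), emulating the tandem-array
    clustering of chemosensory genes.
    """
    counts = dict(DEFAULT_GENE_COUNTS if counts is None else counts)
    if any(v < 0 for v in counts.values()):
        raise ValueError("category counts must be >= 0")
    if not 0 <= clustering <= 1:
        raise ValueError("clustering must be in [0, 1]")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    chroms = [(c[0], c[2] * 1e6) for c in config.chromosomes]
    total_bp = sum(L for _c, L in chroms)
    centers = {}
    for name, L in chroms:
        k = rng.poisson(clusters_per_100mb * L / 1e8) + 1
        centers[name] = rng.uniform(0, L, size=k)
    rows = []
    for cat in sorted(counts):
        for j in range(counts[cat]):
            u = rng.uniform(0, total_bp)
            acc = 0.0
            for name, L in chroms:
                if u < acc + L:
                    break
                acc += L
            if clustering > 0 and rng.random() < clustering:
                c = rng.choice(centers[name])
                pos = c + rng.normal(0, cluster_sd_mb * 1e6)
                pos = float(np.clip(pos, 0, L - 1))
            else:
                pos = u - acc
            rows.append((f"{cat}{j + 1}", cat, name, int(pos) + 1))
    df = pd.DataFrame(rows, columns=["gene", "category", "chrom", "bp"])
    return df.sort_values(["chrom", "bp"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O: the rotated cross-table genotype CSV, phenotype CSV, map TSV

def write_genotype_csv(path, genotypes: pd.DataFrame, markers: pd.DataFrame) -> None:
    """Write genotypes with two extra header rows (chromosome, cM)."""
    mk = markers.set_index("marker").loc[list(genotypes.columns)]
    with open(path, "w") as fh:
        fh.write("id," + ",".join(genotypes.columns) + "\n")
        fh.write("," + ",".join(str(c) for c in mk["chrom"]) + "\n")
        fh.write("," + ",".join(f"{x:.6g}" for x in mk["cM"]) + "\n")
        for ind, row in zip(genotypes.index, genotypes.to_numpy()):
            fh.write(ind + "," + ",".join(GENO_LABELS[int(v)] for v in row) + "\n")


def read_genotype_csv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the rotated cross-table dialect back into codes + marker map."""
    raw = pd.read_csv(path, header=None, dtype=str)
    marker_ids = raw.iloc[0, 1:].tolist()
    chrom = raw.iloc[1, 1:].tolist()
    cm = raw.iloc[2, 1:].astype(float).tolist()
    body = raw.iloc[3:]
    geno = body.iloc[:, 1:].apply(
        lambda col: col.map(lambda s: LABEL_TO_CODE.get(str(s), MISSING))
    )
    geno = geno.astype(np.int8)
    geno.index = body.iloc[:, 0].tolist()
    geno.columns = marker_ids
    markers = pd.DataFrame({"marker": marker_ids, "chrom": chrom, "cM": cm})
    return geno, markers


def write_phenotype_csv(path, phenotypes: pd.DataFrame) -> None:
    phenotypes.to_csv(path, index_label="id", float_format="%.6g", na_rep="NA")


def read_phenotype_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id", na_values="NA")


def write_map_tsv(path, markers: pd.DataFrame) -> None:
    cols = [c for c in ("marker", "chrom", "bp", "cM") if c in markers.columns]
    markers[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_map_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
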