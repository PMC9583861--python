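"""Ground-truthed synthetic cohorts for end-to-end pipeline testing.

The generator emulates the statistical structure of tumor small-RNA
cohorts that the pipeline's statistics rely on:

* heavily skewed isomiR abundance — a few isoforms dominate the read
  pool, so the 95%-of-reads highly-expressed rule selects a small set;
* canonical + 5'-shifted isomiRs cut from common random hairpins, so
  adjacent pairs and merged seed regions exist;
* planted monotone-negative isomiR→gene regulation of tunable strength,
  detectable by Spearman anti-correlation;
* prediction tables in both score dialects in which planted targets pass
  the default filters and decoys do not.

Counts are negative-binomial around abundance × library size with a
per-sample lognormal modulation of each isomiR's abundance, which makes
cross-sample correlation estimable.  Everything is reproducible from a
single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import HairpinRecord, IsomiR, MatureAnnotation, build_isomir
from .targetome import MIRDB_DIALECT, TARGETSCAN_DIALECT, PredictionTable

_SHIFT_POOL = (-1, 1, 2)  # non-canonical shifts; 0 is always present


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for one synthetic study."""

    hairpins: tuple[HairpinRecord, ...]
    matures: tuple[MatureAnnotation, ...]
    isomirs: tuple[IsomiR, ...]
    genes: tuple[str, ...]
    gene_lengths: dict[str, int]
    planted_interactions: tuple[tuple[str, str, float], ...]  # (isomir name, gene, beta)
    planted_abundance: dict[str, float]
    rng_seed: int

    @property
    def isomir_names(self) -> tuple[str, ...]:
        return tuple(iso.name for iso in self.isomirs)

    def planted_targets(self, isomir_name: str) -> set[str]:
        return {g for i, g, _ in self.planted_interactions if i == isomir_name}


def beta_for_spearman(rho_s: float, noise_sd: float = 1.0) -> float:
    """Effect size giving a target population Spearman under Gaussian noise.

    For gene = baseline - beta * z + noise with z standard Gaussian, the
    pair is bivariate Gaussian with Pearson r = -beta / sqrt(beta^2 +
    noise_sd^2), and Spearman rho = (6/pi) * asin(r / 2).  Inverting gives
    the beta that plants a desired population Spearman.
    """
    if not -1.0 < rho_s < 0.0:
        raise SyntheticError("rho_s must lie in (-1, 0)")
    r = 2.0 * math.sin(math.pi * abs(rho_s) / 6.0)
    return noise_sd * r / math.sqrt(1.0 - r * r)


def population_spearman(beta: float, noise_sd: float = 1.0) -> float:
    """Population Spearman implied by a planted effect (Gaussian copula)."""
    r = beta / math.sqrt(beta * beta + noise_sd * noise_sd)
    return -(6.0 / math.pi) * math.asin(r / 2.0)


def generate_truth(
    n_hairpins: int = 20,
    shifts_per_hairpin: int = 2,
    n_genes: int = 300,
    n_planted: int = 50,
    beta_range: tuple[float, float] = (0.6, 1.2),
    abundance_skew: float = 1.5,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw hairpins, isomiRs, genes and planted regulation from one seed.

    Hairpins are uniform-random RNA of 60-120 nt on alternating strands;
    one mature window of 20-24 nt per hairpin; each hairpin carries the
    canonical isomiR plus ``shifts_per_hairpin - 1`` extra shifts from
    {-1, +1, +2}.  Relative abundance weights are Pareto (power-law,
    shape ``abundance_skew``).  Each planted interaction targets a
    distinct gene (one regulator per gene) with beta uniform in
    ``beta_range``.
    """
    if min(n_hairpins, shifts_per_hairpin, n_genes) < 1 or n_planted < 0:
        raise SyntheticError("generator sizes must be positive")
    if not 0.0 < beta_range[0] <= beta_range[1] <= 3.0:
        raise SyntheticError("beta_range must lie within (0, 3]")
    if shifts_per_hairpin > 1 + len(_SHIFT_POOL):
        raise SyntheticError(f"at most {1 + len(_SHIFT_POOL)} shifts per hairpin")
    rng = np.random.default_rng(seed)

    hairpins: list[HairpinRecord] = []
    matures: list[MatureAnnotation] = []
    isomirs: list[IsomiR] = []
    cursor = 1000
    for i in range(n_hairpins):
        length = int(rng.integers(60, 121))
        seq = "".join(rng.choice(list("ACGU"), size=length))
        strand = "+" if i % 2 == 0 else "-"
        hp = HairpinRecord(
            hairpin_id=f"syn-mir-{i + 1}",
            sequence=seq,
            chrom="chrS",
            start=cursor,
            end=cursor + length - 1,
            strand=strand,
        )
        cursor += length + 200
        mat_len = int(rng.integers(20, 25))
        # leave room for shifts in {-1..+2} at both ends
        mat_start = int(rng.integers(5, length - mat_len - 3))
        mature = MatureAnnotation(
            mature_id=f"syn-miR-{i + 1}-5p",
            hairpin_id=hp.hairpin_id,
            start=mat_start,
            end=mat_start + mat_len - 1,
        )
        hairpins.append(hp)
        matures.append(mature)
        shifts = [0]
        if shifts_per_hairpin > 1:
            extra = rng.choice(_SHIFT_POOL, size=shifts_per_hairpin - 1, replace=False)
            shifts.extend(int(s) for s in extra)
        for shift in sorted(shifts):
            isomirs.append(build_isomir(hp, mature, shift))

    genes = tuple(f"GENE{j:04d}" for j in range(n_genes))
    gene_lengths = {g: int(rng.integers(500, 4001)) for g in genes}

    n_isomirs = len(isomirs)
    if n_planted > n_isomirs * n_genes:
        raise SyntheticError("n_planted exceeds the number of possible pairs")
    if n_planted > n_genes:
        raise SyntheticError("one regulator per gene: n_planted must be <= n_genes")
    target_genes = rng.choice(n_genes, size=n_planted, replace=False)
    regulators = rng.integers(0, n_isomirs, size=n_planted)
    betas = rng.uniform(beta_range[0], beta_range[1], size=n_planted)
    planted = tuple(
        (isomirs[int(r)].name, genes[int(g)], float(b))
        for r, g, b in zip(regulators, target_genes, betas)
    )

    weights = rng.pareto(abundance_skew, size=n_isomirs) + 1.0
    weights = weights / weights.sum()
    abundance = {iso.name: float(w) for iso, w in zip(isomirs, weights)}

    return SyntheticTruth(
        hairpins=tuple(hairpins),
        matures=tuple(matures),
        isomirs=tuple(isomirs),
        genes=genes,
        gene_lengths=gene_lengths,
        planted_interactions=planted,
        planted_abundance=abundance,
        rng_seed=seed,
    )


def simulate_isomir_counts(
    truth: SyntheticTruth,
    n_samples: int,
    lib_size_mean: float = 1e6,
    lib_size_sigma: float = 0.25,
    dispersion: float = 0.1,
    modulation_sd: float = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial isomiR counts (features × samples).

    Library sizes are lognormal around ``lib_size_mean``; each isomiR's
    abundance is modulated per sample by an independent lognormal factor
    (``modulation_sd`` on the natural-log scale) so expression varies
    across samples.  ``dispersion`` is the NB dispersion (gamma-Poisson);
    0 collapses to Poisson.
    """
    if n_samples < 3:
        raise SyntheticError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    names = list(truth.isomir_names)
    weights = np.array([truth.planted_abundance[n] for n in names])
    lib = rng.lognormal(mean=math.log(lib_size_mean), sigma=lib_size_sigma, size=n_samples)
    modulation = rng.lognormal(mean=0.0, sigma=modulation_sd, size=(len(names), n_samples))
    mean = weights[:, None] * modulation * lib[None, :]
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape=shape, scale=mean / shape)
    else:
        lam = mean
    counts = rng.poisson(lam)
    samples = [f"S{k + 1:03d}" for k in range(n_samples)]
    return pd.DataFrame(counts, index=names, columns=samples)


def simulate_gene_expression(
    truth: SyntheticTruth,
    isomir_log_expr: pd.DataFrame,
    noise_sd: float = 1.0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene log2 expression with planted negative regulation.

    For each planted (isomir, gene, beta) the gene's log2 profile is
    baseline(g) - beta * standardized(isomiR log expression) + Gaussian
    noise; unplanted genes are baseline + noise, independent of every
    isomiR.  Values are floored at 0 (log2 of a pseudocounted quantity).
    """
    if noise_sd <= 0:
        raise SyntheticError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    samples = list(isomir_log_expr.columns)
    n = len(samples)
    baseline = rng.normal(baseline_mean, baseline_sd, size=len(truth.genes))
    expr = np.tile(baseline[:, None], (1, n)) + rng.normal(0.0, noise_sd, size=(len(truth.genes), n))
    gene_pos = {g: j for j, g in enumerate(truth.genes)}
    for isomir, gene, beta in truth.planted_interactions:
        if isomir not in isomir_log_expr.index:
            continue
        x = isomir_log_expr.loc[isomir].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            continue
        z = (x - x.mean()) / sd
        j = gene_pos[gene]
        expr[j] = baseline[j] - beta * z + rng.normal(0.0, noise_sd, size=n)
    expr = np.maximum(expr, 0.0)
    return pd.DataFrame(expr, index=list(truth.genes), columns=samples)


def simulate_gene_counts(
    truth: SyntheticTruth,
    gene_log_expr: pd.DataFrame,
    lib_size_mean: float = 2e7,
    lib_size_sigma: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Invert log2-FPKM to Poisson read counts for the RNA-seq arm.

    count ~ Poisson(FPKM * length/1e3 * library/1e6) with FPKM = 2^x - 1;
    the monotone transform preserves the planted rank correlations.
    """
    rng = np.random.default_rng(seed)
    samples = list(gene_log_expr.columns)
    lib = rng.lognormal(math.log(lib_size_mean), lib_size_sigma, size=len(samples))
    fpkm = np.maximum(2.0 ** gene_log_expr.to_numpy(dtype=float) - 1.0, 0.0)
    lengths = np.array([truth.gene_lengths[g] for g in gene_log_expr.index], dtype=float)
    lam = fpkm * (lengths[:, None] / 1e3) * (lib[None, :] / 1e6)
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=gene_log_expr.index, columns=samples)


def generate_prediction_tables(
    truth: SyntheticTruth,
    decoys_per_isomir: int = 20,
    seed: int = 0,
) -> tuple[PredictionTable, PredictionTable]:
    """Score tables in both dialects, planted targets passing all filters.

    Planted targets get miRDB scores in [80, 100] and CWCS in
    [-1.2, -0.4]; decoy genes get miRDB scores in [20, 79] and CWCS in
    [-0.3, 0], so no decoy survives the default miRDB cut-off and planted
    targets always outrank decoys in the CWCS sort.
    """
    rng = np.random.default_rng(seed)
    mirdb_rows: list[tuple[str, str, float]] = []
    ts_rows: list[tuple[str, str, float]] = []
    gene_arr = np.array(truth.genes)
    for name in truth.isomir_names:
        planted = sorted(truth.planted_targets(name))
        for gene in planted:
            mirdb_rows.append((name, gene, float(rng.uniform(80.0, 100.0))))
            ts_rows.append((name, gene, float(rng.uniform(-1.2, -0.4))))
        pool = np.array(sorted(set(gene_arr) - set(planted)))
        k = min(decoys_per_isomir, pool.size)
        decoys = rng.choice(pool, size=k, replace=False)
        for gene in decoys:
            mirdb_rows.append((name, str(gene), float(rng.uniform(20.0, 79.0))))
            ts_rows.append((name, str(gene), float(rng.uniform(-0.3, 0.0))))
    mirdb = PredictionTable(
        pd.DataFrame(mirdb_rows, columns=["isomir", "gene", "score"]), MIRDB_DIALECT
    )
    ts = PredictionTable(
        pd.DataFrame(ts_rows, columns=["isomir", "gene", "score"]), TARGETSCAN_DIALECT
    )
    return mirdb, ts


def sample_decoy_interactions(
    truth: SyntheticTruth, n_decoys: int, seed: int = 0
) -> list[tuple[str, str]]:
    """Unplanted (isomir, gene) pairs for null/false-positive assessment."""
    rng = np.random.default_rng(seed)
    planted = {(i, g) for i, g, _ in truth.planted_interactions}
    names = truth.isomir_names
    n_free = len(names) * len(truth.genes) - len(planted)
    if n_decoys > n_free:
        raise SyntheticError("not enough unplanted pairs")
    chosen: set[tuple[str, str]] = set()
    while len(chosen) < n_decoys:
        i = names[int(rng.integers(len(names)))]
        g = truth.genes[int(rng.integers(len(truth.genes)))]
        if (i, g) not in planted:
            chosen.add((i, g))
    return sorted(chosen)
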