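"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate a two-species (human/mouse) CD4+ T-cell polarization
time course: replicated RPKM matrices over the grid 0, 0.5, 1, 2, 4, 6, 12,
24, 48, 72 h, per-time-point differential-expression tables, a multi-
chromosome gene annotation with lncRNA biotypes, and a disease lead-SNP
catalog with traits planted near chosen gene sets.

Latent expression profiles are smooth random functions: a sum of two or
three random-phase sinusoids with periods >= 24 h plus a sigmoid trend,
rescaled to zero mean and unit variance on the sampled grid.  Expression is
synthesized on the log2 scale and exponentiated (RPKM = 2^x - 1), so the
pipeline's own log2(RPKM + 1) transform recovers the latent structure
exactly.  All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TimeCourseMatrix, sample_column

__all__ = [
    "SimTruth",
    "DEFAULT_TIMEPOINTS",
    "simulate_ortholog_timecourse",
    "simulate_expression_matrix",
    "simulate_de_tables",
    "simulate_genome_annotation",
    "simulate_snp_catalog",
    "latent_profile",
]

#: the study's sampling grid, hours after activation
DEFAULT_TIMEPOINTS: tuple[float, ...] = (0, 0.5, 1, 2, 4, 6, 12, 24, 48, 72)

#: log2-scale baseline and amplitude used when mapping standardized latent
#: curves to RPKM; baseline 7 (~127 RPKM) with amplitude 2 keeps log values
#: positive for latent excursions down to -3.5 sd, so the RPKM>=0 clamp
#: almost never censors the latent structure.
LOG_BASELINE = 7.0
LOG_AMPLITUDE = 2.0


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth for one ortholog pair."""

    pair_id: str
    klass: str  # shared | shifted | divergent
    true_shift_hours: float
    base_profile_id: str

    def __post_init__(self):
        if self.klass not in ("shared", "shifted", "divergent"):
            raise ValueError(f"unknown class {self.klass!r}")
        if self.klass == "shared" and self.true_shift_hours != 0:
            raise ValueError("shared pairs must have zero shift")
        if not -24 <= self.true_shift_hours <= 24:
            raise ValueError("true shift must lie in [-24, 24] hours")


def latent_profile(rng: np.random.Generator, grid: np.ndarray):
    """Draw a smooth random latent curve, standardized on ``grid``.

    Returns a callable ``f(t_hours) -> value`` (vectorized).  The curve is a
    sum of 2-3 sinusoids with periods >= 24 h and random phases plus a
    sigmoid trend with a random midpoint, affinely rescaled so that its
    values on ``grid`` have mean 0 and sd 1.
    """
    n_sin = int(rng.integers(2, 4))
    periods = rng.uniform(24.0, 96.0, size=n_sin)
    phases = rng.uniform(0.0, 2 * np.pi, size=n_sin)
    amps = rng.uniform(0.3, 1.0, size=n_sin)
    trend_amp = rng.uniform(0.5, 2.0) * rng.choice([-1.0, 1.0])
    midpoint = rng.uniform(2.0, 48.0)
    width = rng.uniform(4.0, 24.0)

    def raw(t):
        t = np.asarray(t, dtype=float)
        val = sum(
            a * np.sin(2 * np.pi * t / p + ph)
            for a, p, ph in zip(amps, periods, phases)
        )
        return val + trend_amp / (1.0 + np.exp(-(t - midpoint) / width))

    on_grid = raw(grid)
    mu, sd = on_grid.mean(), on_grid.std()
    if sd < 1e-9:  # practically impossible, but keep the contract total
        sd = 1.0

    def f(t):
        return (raw(t) - mu) / sd

    return f


def _to_rpkm(log2_values: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 ** np.maximum(log2_values, 0.0) - 1.0, 0.0)


def simulate_ortholog_timecourse(
    n_pairs: int,
    frac_shared: float = 0.5,
    frac_shifted: float = 0.25,
    shift_set: tuple[float, ...] = (-12, -6, 6, 12),
    noise_sd: float = 0.2,
    n_replicates: int = 3,
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS,
    seed: int = 0,
    condition: str = "Th17",
):
    """Simulate paired human/mouse replicated RPKM time courses.

    Pairs are split into ``shared`` (one latent curve for both species),
    ``shifted`` (mouse follows the human latent curve evaluated at
    ``t + true_shift``) and ``divergent`` (independent latent curves), in
    proportions ``frac_shared`` / ``frac_shifted`` / remainder, with counts
    rounded to integers that sum to ``n_pairs``.

    Returns ``(human, mouse, ortholog_map, truths)`` where the matrices are
    :class:`~orthokinetics.io.TimeCourseMatrix`, the map is a two-column
    DataFrame and ``truths`` is a list of :class:`SimTruth`.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if len(timepoints) == 0:
        raise ValueError("timepoints must be non-empty")
    if not (0 <= frac_shared <= 1 and 0 <= frac_shifted <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if frac_shared + frac_shifted > 1 + 1e-12:
        raise ValueError("frac_shared + frac_shifted must be <= 1")
    grid = np.asarray(timepoints, dtype=float)
    if not (np.diff(grid) > 0).all():
        raise ValueError("timepoints must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    n_shared = int(round(frac_shared * n_pairs))
    n_shifted = int(round(frac_shifted * n_pairs))
    n_shared = min(n_shared, n_pairs)
    n_shifted = min(n_shifted, n_pairs - n_shared)
    classes = (
        ["shared"] * n_shared
        + ["shifted"] * n_shifted
        + ["divergent"] * (n_pairs - n_shared - n_shifted)
    )

    truths: list[SimTruth] = []
    rows_h, rows_m, genes_h, genes_m = [], [], [], []
    for i, klass in enumerate(classes):
        pid = f"pair{i + 1:04d}"
        hgene, mgene = f"hs_{pid}", f"mm_{pid}"
        shift = 0.0
        f_h = latent_profile(rng, grid)

        def sample(f, times):
            # noise_sd acts on the standardized (unit-variance latent) scale,
            # so replicate scatter is noise_sd relative to the profile's sd
            latent = np.repeat(f(times)[:, None], n_replicates, axis=1)
            noisy = latent + rng.normal(0.0, noise_sd, size=latent.shape)
            return LOG_BASELINE + LOG_AMPLITUDE * noisy

        log_h = sample(f_h, grid)
        if klass == "shared":
            log_m = sample(f_h, grid)
        elif klass == "shifted":
            if not shift_set:
                raise ValueError("shift_set must be non-empty when frac_shifted > 0")
            shift = float(rng.choice(np.asarray(shift_set, dtype=float)))
            log_m = sample(f_h, grid + shift)
        else:
            f_m = latent_profile(rng, grid)
            log_m = sample(f_m, grid)
        rows_h.append(_to_rpkm(log_h).ravel())
        rows_m.append(_to_rpkm(log_m).ravel())
        genes_h.append(hgene)
        genes_m.append(mgene)
        truths.append(SimTruth(pid, klass, shift, f"latent_{pid}"))

    columns = [
        sample_column(condition, t, r)
        for t in grid
        for r in range(1, n_replicates + 1)
    ]
    human = TimeCourseMatrix(
        species="human", condition=condition, timepoints=tuple(grid),
        n_replicates=n_replicates,
        values=pd.DataFrame(rows_h, index=pd.Index(genes_h, name="gene_id"),
                            columns=columns),
    )
    mouse = TimeCourseMatrix(
        species="mouse", condition=condition, timepoints=tuple(grid),
        n_replicates=n_replicates,
        values=pd.DataFrame(rows_m, index=pd.Index(genes_m, name="gene_id"),
                            columns=columns),
    )
    ortho = pd.DataFrame({"human_gene": genes_h, "mouse_gene": genes_m})
    return human, mouse, ortho, truths


def simulate_expression_matrix(
    gene_ids,
    species: str = "human",
    condition: str = "Th17",
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS,
    n_replicates: int = 3,
    noise_sd: float = 0.2,
    baseline: float = LOG_BASELINE,
    amplitude: float = LOG_AMPLITUDE,
    frac_silent: float = 0.0,
    silent_baseline: float = -6.0,
    seed: int = 0,
) -> TimeCourseMatrix:
    """Independent smooth profiles for an arbitrary gene list.

    A fraction ``frac_silent`` of genes (chosen deterministically from the
    seed) gets a log2 baseline far below zero, so their RPKM is ~0 at every
    sample — these emulate annotated-but-unexpressed genes that the
    expression filters must remove.
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("gene_ids must be non-empty")
    if not 0 <= frac_silent <= 1:
        raise ValueError("frac_silent must lie in [0, 1]")
    grid = np.asarray(timepoints, dtype=float)
    rng = np.random.default_rng(seed)
    n_silent = int(round(frac_silent * len(gene_ids)))
    silent = np.zeros(len(gene_ids), dtype=bool)
    silent[rng.choice(len(gene_ids), n_silent, replace=False)] = True
    rows = []
    for i in range(len(gene_ids)):
        f = latent_profile(rng, grid)
        base = silent_baseline if silent[i] else baseline
        latent = np.repeat(f(grid)[:, None], n_replicates, axis=1)
        noisy = latent + rng.normal(0.0, noise_sd, size=latent.shape)
        rows.append(_to_rpkm(base + amplitude * noisy).ravel())
    columns = [
        sample_column(condition, t, r)
        for t in grid
        for r in range(1, n_replicates + 1)
    ]
    return TimeCourseMatrix(
        species=species, condition=condition, timepoints=tuple(grid),
        n_replicates=n_replicates,
        values=pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id"),
                            columns=columns),
    )


def simulate_de_tables(
    n_genes: int,
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS,
    planted_top: dict[float, list[tuple[str, str, float]]] | None = None,
    null_fdr_range: tuple[float, float] = (0.05, 1.0),
    null_fc_sd: float = 0.1,
    gene_prefix: str = "g",
    gene_ids: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a per-time-point differential-expression table.

    ``planted_top`` maps a time point to ``(gene, direction, log2fc)``
    triples; planted rows get the stated |log2 FC| (signed by direction,
    'up' or 'down') and an FDR drawn below 0.05.  All other (gene, time)
    rows are nulls: FDR uniform on ``null_fdr_range`` and log2 FC ~
    N(0, ``null_fc_sd``), i.e. below both the DE and the ranking cutoffs
    with high probability.
    """
    if n_genes <= 0 and gene_ids is None:
        raise ValueError("n_genes must be positive")
    if gene_ids is None:
        gene_ids = [f"{gene_prefix}{i + 1:04d}" for i in range(n_genes)]
    universe = set(gene_ids)
    planted_top = planted_top or {}
    planted: dict[tuple[str, float], tuple[str, float]] = {}
    for t, entries in planted_top.items():
        if float(t) not in {float(x) for x in timepoints}:
            raise ValueError(f"planted timepoint {t} not in grid")
        for gene, direction, fc in entries:
            if gene not in universe:
                raise ValueError(f"planted gene {gene!r} not in gene universe")
            if direction not in ("up", "down"):
                raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
            key = (gene, float(t))
            if key in planted:
                raise ValueError(f"duplicate planted record for {key}")
            planted[key] = (direction, abs(float(fc)))

    rng = np.random.default_rng(seed)
    lo, hi = null_fdr_range
    records = []
    for t in timepoints:
        for gene in gene_ids:
            key = (gene, float(t))
            if key in planted:
                direction, fc = planted[key]
                fdr = rng.uniform(1e-6, 0.049)
                lfc = fc if direction == "up" else -fc
            else:
                fdr = rng.uniform(lo, hi)
                lfc = rng.normal(0.0, null_fc_sd)
            records.append((gene, float(t), lfc, fdr))
    return pd.DataFrame(records, columns=["gene_id", "timepoint", "log2_fc", "fdr"])


def simulate_genome_annotation(
    n_chromosomes: int = 5,
    genes_per_chromosome: int = 200,
    gene_length: int = 1000,
    spacing: int = 50000,
    biotype_fractions: dict[str, float] | None = None,
    gene_prefix: str = "g",
    seed: int = 0,
) -> pd.DataFrame:
    """Regularly spaced, non-overlapping genes on ``n_chromosomes``.

    Gene *i* (1-based) on each chromosome starts at
    ``1 + (i - 1) * (gene_length + spacing)`` (1-based inclusive
    coordinates).  Biotypes are assigned by shuffling a deterministic
    composition matching ``biotype_fractions`` (default: all ``coding``).
    """
    if n_chromosomes <= 0 or genes_per_chromosome <= 0:
        raise ValueError("counts must be positive")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    biotype_fractions = biotype_fractions or {"coding": 1.0}
    total = sum(biotype_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"biotype fractions must sum to 1, got {total}")

    n_genes = n_chromosomes * genes_per_chromosome
    # largest-remainder apportionment keeps counts exact
    raw = {b: f * n_genes for b, f in biotype_fractions.items()}
    counts = {b: int(np.floor(v)) for b, v in raw.items()}
    leftover = n_genes - sum(counts.values())
    for b in sorted(raw, key=lambda b: raw[b] - counts[b], reverse=True)[:leftover]:
        counts[b] += 1
    biotypes = [b for b in sorted(counts) for _ in range(counts[b])]
    rng = np.random.default_rng(seed)
    rng.shuffle(biotypes)

    stride = gene_length + spacing
    records = []
    idx = 0
    for c in range(1, n_chromosomes + 1):
        for i in range(1, genes_per_chromosome + 1):
            start = 1 + (i - 1) * stride
            records.append(
                dict(
                    gene_id=f"{gene_prefix}{idx + 1:05d}",
                    chrom=str(c),
                    start=start,
                    end=start + gene_length - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                    biotype=biotypes[idx],
                )
            )
            idx += 1
    return pd.DataFrame.from_records(records)


def simulate_snp_catalog(
    annotation: pd.DataFrame,
    traits: list[str],
    planted: dict[str, list[str]] | None = None,
    snps_per_trait: int = 5,
    window: int = 100_000,
    background_snps: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a disease lead-SNP catalog over ``annotation``.

    Every SNP passes the association filter (p-value < 1e-5).  For each
    trait in ``planted``, ``snps_per_trait`` SNPs are placed within
    ``window`` bp of a planted target gene; ``background_snps`` additional
    SNPs are scattered uniformly over each chromosome with traits drawn
    uniformly from ``traits``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if snps_per_trait < 0 or background_snps < 0:
        raise ValueError("SNP counts must be non-negative")
    planted = planted or {}
    ann = annotation.set_index("gene_id")
    for trait, genes in planted.items():
        missing = [g for g in genes if g not in ann.index]
        if missing:
            raise ValueError(f"planted genes not in annotation: {missing[:5]}")
        if trait not in traits:
            raise ValueError(f"planted trait {trait!r} not in traits")

    rng = np.random.default_rng(seed)
    chrom_max = annotation.groupby("chrom")["end"].max().to_dict()
    records = []
    k = 0

    def log_uniform_p():
        return 10.0 ** rng.uniform(-20.0, np.log10(1e-5) - 0.01)

    for trait in traits:
        genes = planted.get(trait, [])
        if not genes or snps_per_trait == 0:
            continue
        for _ in range(snps_per_trait):
            g = genes[int(rng.integers(len(genes)))]
            row = ann.loc[g]
            lo = max(1, int(row["start"]) - window)
            hi = int(row["end"]) + window
            pos = int(rng.integers(lo, hi + 1))
            k += 1
            records.append(
                dict(snp_id=f"rs{k:06d}", trait=trait, chrom=str(row["chrom"]),
                     pos=pos, pvalue=log_uniform_p())
            )
    chroms = sorted(chrom_max)
    for _ in range(background_snps):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, chrom_max[chrom] + 1))
        trait = traits[int(rng.integers(len(traits)))]
        k += 1
        records.append(
            dict(snp_id=f"rs{k:06d}", trait=trait, chrom=chrom, pos=pos,
                 pvalue=log_uniform_p())
        )
    return pd.DataFrame.from_records(
        records, columns=["snp_id", "trait", "chrom", "pos", "pvalue"]
    )
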