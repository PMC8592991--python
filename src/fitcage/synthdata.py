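"""Synthetic-data generators emulating a fasting-induced-torpor CAGE study.

Every input the analysis pipeline consumes can be generated here with the
statistical structure the downstream models assume:

* a random genome with non-overlapping gene models on both strands;
* per-sample CTSS tracks whose promoter tag totals are negative-binomial
  with condition-dependent log2 fold effects, spread over +/-50 bp of the
  annotated 5' end by a Dirichlet-multinomial whose concentration controls
  promoter shape (high concentration -> singleton-like, SI near 2);
* three-day physiological traces (T_B, VO2 on a 6-min grid) with circadian
  sinusoids, Gaussian noise, and torpor bouts in which VO2 drops to a
  fraction of baseline (default 0.3) while T_B relaxes toward ambient with
  first-order kinetics (tau = 0.5 h);
* KO phenotype tables drawn from the hierarchical normal/torpor model
  (global mean alpha, cell offsets beta, torpor effects gamma).

The default experimental design mirrors a study with Pre=4, Mid=8, Post=4,
HiT=4, Fed=4 and Dep=4 animals. All generators are pure functions of their
configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .physio import PhysioTrace

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CONDITIONS",
    "gen_genome",
    "gen_counts",
    "gen_ctss",
    "gen_physio",
    "gen_ko_phenotypes",
]

CONDITIONS = ("Pre", "Mid", "Post", "HiT", "Fed", "Dep")
DEFAULT_DESIGN = {"Pre": 4, "Mid": 8, "Post": 4, "HiT": 4, "Fed": 4, "Dep": 4}
GENE_LENGTH = 1000
TSS_SUPPORT = 50            # tag spread support: +/-50 bp around the 5' end
POINTS_PER_DAY = 240        # 6-min grid


@dataclass
class SimConfig:
    """Configuration of the synthetic CAGE experiment."""

    seed: int = 0
    n_genes: int = 500
    genome_length: int = 2_000_000
    design: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DESIGN))
    effect_table: dict[str, dict[str, float]] = field(default_factory=dict)
    dispersion: float = 0.2
    shape_concentration: float = 5.0
    library_size: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.genome_length < 1 or self.library_size < 1:
            raise ValueError("counts must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.shape_concentration <= 0:
            raise ValueError("shape_concentration must be positive")
        bad = set(self.design) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}; allowed: {CONDITIONS}")
        if any(n < 1 for n in self.design.values()):
            raise ValueError("each condition needs at least one sample")

    def sample_sheet(self) -> pd.DataFrame:
        rows = [
            {"sample": f"{cond}_{i + 1}", "condition": cond}
            for cond in self.design
            for i in range(self.design[cond])
        ]
        return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    """Planted truth for recovery tests."""

    torpor_specific_up: set = field(default_factory=set)
    torpor_specific_down: set = field(default_factory=set)
    bout_windows: list = field(default_factory=list)
    alpha: float | None = None
    beta: dict = field(default_factory=dict)
    gamma: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.torpor_specific_up & self.torpor_specific_down:
            raise ValueError("up/down truth sets must be disjoint")


def gen_genome(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Random single-chromosome genome plus non-overlapping gene models.

    Genes are laid out in equal slots (one gene per slot, random offset and
    strand), so the genome must be at least ``2000 * n_genes`` bp. The gene
    5' end (TSS) is the start on '+' and the end-1 on '-'. Deterministic for
    a fixed seed.
    """
    if config.genome_length < config.n_genes * 2 * GENE_LENGTH:
        raise ValueError(
            f"genome of {config.genome_length} bp too short for {config.n_genes} genes "
            f"(need >= {config.n_genes * 2 * GENE_LENGTH})"
        )
    rng = np.random.default_rng(config.seed)
    codes = rng.integers(0, 4, size=config.genome_length, dtype=np.uint8)
    seq = bytes(codes).translate(bytes.maketrans(bytes(range(4)), b"ACGT")).decode()
    slot = config.genome_length // config.n_genes
    margin = TSS_SUPPORT + 10
    rows = []
    for i in range(config.n_genes):
        lo = i * slot + margin
        hi = (i + 1) * slot - GENE_LENGTH - margin
        start = int(rng.integers(lo, max(hi, lo + 1)))
        strand = "+" if rng.random() < 0.5 else "-"
        end = start + GENE_LENGTH
        rows.append(
            {
                "gene_id": f"gene{i + 1:04d}",
                "chrom": "chr1",
                "start": start,
                "end": end,
                "strand": strand,
                "tss": start if strand == "+" else end - 1,
            }
        )
    return {"chr1": seq}, pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB with variance mu + phi*mu^2 (phi=0 -> Poisson)."""
    mean = np.maximum(mean, 1e-12)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def gen_counts(
    config: SimConfig, gene_ids: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Promoter x sample NB tag totals under the configured design.

    Baseline promoter abundances are lognormal (fixed by the seed); sample
    means are baseline x 2^effect(condition), renormalized so each library
    totals ~``library_size`` in expectation. Returns (counts, sample sheet).
    """
    if gene_ids is None:
        gene_ids = [f"gene{i + 1:04d}" for i in range(config.n_genes)]
    unknown = set(config.effect_table) - set(gene_ids)
    if unknown:
        raise ValueError(f"effect_table ids not in gene set: {sorted(unknown)[:5]}")
    for pid, effects in config.effect_table.items():
        bad = set(effects) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition in effect_table[{pid}]: {sorted(bad)}")
    rng = np.random.default_rng(config.seed + 1)
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=len(gene_ids))
    weights /= weights.sum()
    effects = np.zeros((len(gene_ids), len(CONDITIONS)))
    cond_idx = {c: j for j, c in enumerate(CONDITIONS)}
    gidx = {g: i for i, g in enumerate(gene_ids)}
    for pid, eff in config.effect_table.items():
        for cond, lfc in eff.items():
            effects[gidx[pid], cond_idx[cond]] = lfc

    sheet = config.sample_sheet()
    counts = {}
    for _, row in sheet.iterrows():
        j = cond_idx[row["condition"]]
        mu = weights * 2.0 ** effects[:, j]
        mu = mu / mu.sum() * config.library_size
        counts[row["sample"]] = _nb_draw(rng, mu, config.dispersion)
    return pd.DataFrame(counts, index=gene_ids), sheet


def _tag_profile(
    rng: np.random.Generator, concentration: float, n_pos: int
) -> np.ndarray:
    """Dirichlet positional profile over the TSS support.

    The Dirichlet mass is a Gaussian kernel centered on the TSS divided by
    the concentration, so larger concentration -> sparser draws (narrow,
    SI near 2) and smaller -> smoother (broad). Infinite concentration is a
    delta at the TSS.
    """
    center = n_pos // 2
    kernel = np.exp(-0.5 * ((np.arange(n_pos) - center) / 10.0) ** 2)
    kernel /= kernel.sum()
    if not np.isfinite(concentration) or concentration > 1e9:
        delta = np.zeros(n_pos)
        delta[center] = 1.0
        return delta
    alpha = kernel * (100.0 / concentration)
    g = rng.gamma(np.maximum(alpha, 1e-12))
    if g.sum() <= 0 or not np.isfinite(g.sum()):
        delta = np.zeros(n_pos)
        delta[center] = 1.0
        return delta
    return g / g.sum()


def gen_ctss(
    config: SimConfig,
    genome: dict[str, str],
    genes: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-sample CTSS tracks: NB promoter totals spread over +/-50 bp.

    Each gene gets one positional profile (drawn once per simulation) and
    each sample's tags for that gene are multinomial over it, so promoter
    shape is a stable per-promoter property while depth varies by sample
    and condition. Returns (sample -> CTSS track, sample sheet).
    """
    counts, sheet = gen_counts(config, genes["gene_id"].tolist())
    rng = np.random.default_rng(config.seed + 2)
    n_pos = 2 * TSS_SUPPORT + 1
    profiles = {
        g: _tag_profile(rng, config.shape_concentration, n_pos)
        for g in genes["gene_id"]
    }
    tss = dict(zip(genes["gene_id"], genes["tss"]))
    strand = dict(zip(genes["gene_id"], genes["strand"]))
    chrom = dict(zip(genes["gene_id"], genes["chrom"]))
    chrom_len = {c: len(s) for c, s in genome.items()}

    tracks: dict[str, pd.DataFrame] = {}
    for sample in counts.columns:
        recs = []
        for g in counts.index:
            total = int(counts.loc[g, sample])
            if total == 0:
                continue
            spread = rng.multinomial(total, profiles[g])
            base = tss[g] - TSS_SUPPORT
            nz = np.flatnonzero(spread)
            for off in nz:
                pos = base + int(off)
                if 0 <= pos < chrom_len[chrom[g]]:
                    recs.append((chrom[g], pos, strand[g], int(spread[off])))
        tracks[sample] = pd.DataFrame(recs, columns=["chrom", "pos", "strand", "count"])
    return tracks, sheet


def gen_physio(
    animal_id: str = "animal1",
    seed: int = 0,
    days: int = 3,
    tb_mesor: float = 37.0,
    tb_amplitude: float = 1.0,
    tb_sigma: float = 0.25,
    vo2_mesor: float = 1.8,
    vo2_amplitude: float = 0.4,
    vo2_sigma: float = 0.08,
    ta_c: float = 20.0,
    acrophase_h: float = 18.0,
    bouts: list[tuple[float, float, float]] | None = None,
    tau_h: float = 0.5,
) -> tuple[PhysioTrace, GroundTruth]:
    """Circadian T_B/VO2 trace with optional torpor bouts.

    ``bouts`` is a list of (start_h, end_h, depth): within a bout VO2 is
    multiplied by ``depth`` (default 0.3 of baseline) instantly, while T_B
    relaxes toward ambient (and recovers) with first-order kinetics of time
    constant ``tau_h``. Bouts must fall after day 1 (the baseline day) and
    not overlap. Gaussian noise on the natural scale is a synthetic-only
    simplification. 240 points/day at 6-min resolution.
    """
    if tb_sigma <= 0 or vo2_sigma <= 0:
        raise ValueError("noise scales must be positive")
    bouts = sorted(bouts or [])
    span = days * 24.0
    for i, (s, e, depth) in enumerate(bouts):
        if not (24.0 <= s < e <= span):
            raise ValueError(f"bout ({s}, {e}) must lie within days 2..{days}")
        if depth <= 0 or depth > 1:
            raise ValueError("bout depth must be in (0, 1]")
        if i and s < bouts[i - 1][1]:
            raise ValueError("bout windows must not overlap")

    rng = np.random.default_rng(seed)
    t = np.arange(days * POINTS_PER_DAY) * (24.0 / POINTS_PER_DAY)
    phase = 2 * np.pi * (t - acrophase_h) / 24.0
    tb_base = tb_mesor + tb_amplitude * np.cos(phase)
    vo2_base = vo2_mesor + vo2_amplitude * np.cos(phase)

    in_bout = np.zeros(t.size, dtype=bool)
    depth_arr = np.ones(t.size)
    for s, e, depth in bouts:
        sel = (t >= s) & (t < e)
        in_bout |= sel
        depth_arr[sel] = depth

    vo2 = vo2_base * depth_arr
    # first-order relaxation of T_B toward ambient in bouts, recovery
    # outside; one lead-in day (bout-free) removes the filter transient
    dt = 24.0 / POINTS_PER_DAY
    decay = 1.0 - np.exp(-dt / tau_h)
    lead = POINTS_PER_DAY
    target_full = np.concatenate(
        [tb_base[:lead], np.where(in_bout, ta_c + 1.0, tb_base)]
    )
    tb_full = np.empty(target_full.size)
    tb_full[0] = target_full[0]
    for i in range(1, target_full.size):
        tb_full[i] = tb_full[i - 1] + (target_full[i] - tb_full[i - 1]) * decay
    tb = tb_full[lead:]
    tb = tb + rng.normal(0, tb_sigma, t.size)
    vo2 = vo2 + rng.normal(0, vo2_sigma, t.size)
    vo2 = np.maximum(vo2, 0.0)

    trace = PhysioTrace(animal_id=animal_id, time_h=t, tb_c=tb, vo2_ml_min=vo2, ta_c=ta_c)
    truth = GroundTruth(bout_windows=[(s, e) for s, e, _ in bouts])
    return trace, truth


def gen_ko_phenotypes(
    alpha: float,
    beta: dict[tuple[str, str], float],
    gamma: dict[tuple[str, str], float],
    sigma_normal: float,
    sigma_torpor: float,
    n_per_cell: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Long-format phenotype table drawn from the hierarchical KO model.

    Y_NORMAL ~ Normal(alpha + beta[g,a], sigma_normal) and Y_TORPOR ~
    Normal(alpha + beta[g,a] + gamma[g,a], sigma_torpor), one row per
    animal x state. ``beta``/``gamma`` are keyed by (line, allele) and must
    share cells.
    """
    if sigma_normal < 0 or sigma_torpor < 0:
        raise ValueError("noise scales must be non-negative")
    if set(beta) != set(gamma):
        raise ValueError("beta and gamma must cover the same (line, allele) cells")
    if n_per_cell < 1:
        raise ValueError("need n >= 1 per cell")
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for (line, allele) in sorted(beta):
        for _ in range(n_per_cell):
            idx += 1
            animal = f"{line}-{allele}-{idx:03d}"
            mu_n = alpha + beta[(line, allele)]
            mu_t = mu_n + gamma[(line, allele)]
            rows.append(
                {"animal": animal, "line": line, "allele": allele,
                 "state": "NORMAL", "y": rng.normal(mu_n, sigma_normal)}
            )
            rows.append(
                {"animal": animal, "line": line, "allele": allele,
                 "state": "TORPOR", "y": rng.normal(mu_t, sigma_torpor)}
            )
    truth = GroundTruth(alpha=alpha, beta=dict(beta), gamma=dict(gamma))
    return pd.DataFrame(rows), truth
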