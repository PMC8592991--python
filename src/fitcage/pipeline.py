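"""End-to-end orchestration of the torpor CAGE workflow.

Stages (each toggleable): simulate -> ctss (cluster/annotate/features) ->
de (contrasts + promoter sets) -> motifs (enrichment + positional profile)
-> physio (baseline fit + torpor calls) -> phen (KO model). Every output
TSV carries a provenance header (stage, parameters, seed); reruns with the
same config are bit-identical for the deterministic stages.
"""

from __future__ import annotations

import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bayesphen, ctss, diffexp, io, motifs, physio, synthdata

__all__ = ["RunConfig", "run_pipeline"]

DEFAULT_CONTRASTS = {
    "pre_mid": ("Pre", "Mid"),
    "mid_post": ("Mid", "Post"),
    "hit_mid": ("HiT", "Mid"),
    "fed_mid": ("Fed", "Mid"),
    "mid_dep": ("Mid", "Dep"),
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "ctss", "de", "motifs", "physio", "phen")
    n_genes: int = 200
    genome_length: int = 800_000
    library_size: int = 200_000
    dispersion: float = 0.2
    max_gap: int = 20
    min_tags: float = 10
    fdr: float = 0.05
    ci: float = 0.999
    draws: int = 1000
    motif_file: Path | None = None
    n_planted: int = 10
    planted_lfc: float = 2.0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        known = {"simulate", "ctss", "de", "motifs", "physio", "phen"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}")
        if not 0 < self.fdr < 1 or not 0 < self.ci < 1:
            raise ValueError("fdr and ci must lie in (0, 1)")
        if self.motif_file is not None:
            self.motif_file = Path(self.motif_file)
            if not self.motif_file.exists():
                raise FileNotFoundError(self.motif_file)


def _provenance(cfg: RunConfig, stage: str, **extra) -> dict:
    out = {"stage": stage, "seed": cfg.seed, "produced_by": "fitcage"}
    out.update(extra)
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the toggled stages into ``cfg.outdir``; returns a result dict.

    A stage failure halts the run, leaves earlier outputs in place and
    writes a machine-readable ``error.json``.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    state: dict = {}
    try:
        for stage in ("simulate", "ctss", "de", "motifs", "physio", "phen"):
            if stage not in cfg.stages:
                continue
            t0 = time.time()
            globals()[f"_stage_{stage}"](cfg, state)
            log.append({"stage": stage, "seconds": round(time.time() - t0, 2)})
    except Exception as exc:
        (cfg.outdir / "error.json").write_text(
            json.dumps(
                {"stage": log[-1]["stage"] if log else "unknown",
                 "error": str(exc), "traceback": traceback.format_exc()},
                indent=2,
            )
        )
        raise
    (cfg.outdir / "provenance.json").write_text(
        json.dumps({"seed": cfg.seed, "stages": log,
                    "config": {k: str(v) for k, v in vars(cfg).items()}}, indent=2)
    )
    return state


def _stage_simulate(cfg: RunConfig, state: dict) -> None:
    planted = {
        f"gene{i + 1:04d}": {"Mid": cfg.planted_lfc if i % 2 == 0 else -cfg.planted_lfc}
        for i in range(cfg.n_planted)
    }
    sim = synthdata.SimConfig(
        seed=cfg.seed, n_genes=cfg.n_genes, genome_length=cfg.genome_length,
        library_size=cfg.library_size, dispersion=cfg.dispersion, effect_table=planted,
    )
    genome, genes = synthdata.gen_genome(sim)
    tracks, sheet = synthdata.gen_ctss(sim, genome, genes)
    io.write_fasta(genome, cfg.outdir / "genome.fa")
    io.write_gtf(genes, cfg.outdir / "genes.gtf")
    ctss_dir = cfg.outdir / "ctss"
    ctss_dir.mkdir(exist_ok=True)
    for sample, track in tracks.items():
        io.write_ctss_bed(track, ctss_dir / f"{sample}.ctss.bed")
    io.write_tsv(sheet, cfg.outdir / "samples.tsv", _provenance(cfg, "simulate"))
    state.update(genome=genome, genes=genes, tracks=tracks, sheet=sheet,
                 truth_up={g for g, e in planted.items() if e["Mid"] > 0},
                 truth_down={g for g, e in planted.items() if e["Mid"] < 0})


def _stage_ctss(cfg: RunConfig, state: dict) -> None:
    pooled = ctss.pool_tracks(state["tracks"])
    clusters = ctss.cluster_ctss(pooled, max_gap=cfg.max_gap, min_tags=cfg.min_tags)
    ctss.annotate_clusters(clusters, state["genes"])
    for cl in clusters:
        cl.si = ctss.shape_index(cl)
        cl.gc = ctss.gc_content(cl, state["genome"])
    io.write_cluster_bed(clusters, cfg.outdir / "promoters.bed")
    feats = pd.DataFrame(
        {
            "promoter": [c.cluster_id for c in clusters],
            "gene": [c.gene for c in clusters],
            "total_tags": [c.total_tags for c in clusters],
            "si": [c.si for c in clusters],
            "gc": [c.gc for c in clusters],
        }
    )
    io.write_tsv(feats, cfg.outdir / "promoter_features.tsv",
                 _provenance(cfg, "ctss", max_gap=cfg.max_gap, min_tags=cfg.min_tags))
    counts = ctss.count_matrix_from_tracks(clusters, state["tracks"])
    state.update(clusters=clusters, counts=counts)


def _stage_de(cfg: RunConfig, state: dict) -> None:
    matrix = diffexp.CountMatrix(state["counts"]).with_tmm()
    sheet = state["sheet"].set_index("sample")["condition"]
    groups = {c: sheet.index[sheet == c].tolist() for c in sheet.unique()}
    phi = diffexp.estimate_dispersion(matrix, sheet)
    results = {}
    for name, (a, b) in DEFAULT_CONTRASTS.items():
        if a not in groups or b not in groups:
            continue
        de = diffexp.nb_exact_test(matrix, groups[a], groups[b], phi)
        results[name] = de
        io.write_tsv(de.reset_index(names="promoter"), cfg.outdir / f"de_{name}.tsv",
                     _provenance(cfg, "de", contrast=f"{a}:{b}", phi=round(phi, 4)))
    sets = diffexp.PromoterSets()
    if {"pre_mid", "mid_post"} <= results.keys():
        sets.reversible_up, sets.reversible_down = diffexp.classify_reversible(
            results["pre_mid"], results["mid_post"], cfg.fdr)
    if {"hit_mid", "fed_mid"} <= results.keys():
        sets.hypometabolic_up, sets.hypometabolic_down = diffexp.classify_hypometabolic(
            results["hit_mid"], results["fed_mid"], cfg.fdr)
    sets.torpor_specific_up, sets.torpor_specific_down = diffexp.torpor_specific(
        (sets.reversible_up, sets.reversible_down),
        (sets.hypometabolic_up, sets.hypometabolic_down))
    if "mid_dep" in results:
        dep = diffexp.deprivation_specific(
            results["mid_dep"], cfg.fdr,
            (sets.torpor_specific_up, sets.torpor_specific_down))
        sets.deprivation_up, sets.deprivation_down = dep["up"], dep["down"]
    rows = [
        {"promoter": p, "set": name}
        for name in ("reversible_up", "reversible_down", "hypometabolic_up",
                     "hypometabolic_down", "torpor_specific_up", "torpor_specific_down",
                     "deprivation_up", "deprivation_down")
        for p in sorted(getattr(sets, name))
    ]
    io.write_tsv(pd.DataFrame(rows, columns=["promoter", "set"]),
                 cfg.outdir / "promoter_sets.tsv", _provenance(cfg, "de", fdr=cfg.fdr))
    state.update(matrix=matrix, phi=phi, de=results, sets=sets)


def _stage_motifs(cfg: RunConfig, state: dict) -> None:
    if cfg.motif_file is None:
        return
    pwms = io.read_jaspar(cfg.motif_file)
    clusters = state["clusters"]
    sets = state["sets"]
    fg_ids = sets.torpor_specific_up | sets.torpor_specific_down
    fg_clusters = [c for c in clusters if c.gene in fg_ids or c.cluster_id in fg_ids]
    if not fg_clusters:
        fg_clusters = clusters[: max(len(clusters) // 10, 1)]
    fg = motifs.extract_regions(fg_clusters, state["genome"])
    bg = motifs.extract_regions(clusters, state["genome"])
    enrich = motifs.motif_enrichment(fg, bg, pwms)
    io.write_tsv(enrich, cfg.outdir / "motif_enrichment.tsv", _provenance(cfg, "motifs"))
    prof = motifs.positional_profile(fg, pwms[0])
    io.write_tsv(
        pd.DataFrame({"offset": prof.offsets, "raw": prof.raw, "smoothed": prof.smoothed}),
        cfg.outdir / f"motif_profile_{pwms[0].motif_id}.tsv",
        _provenance(cfg, "motifs", peak_offset=prof.peak_offset),
    )
    state.update(enrichment=enrich, profile=prof)


def _stage_physio(cfg: RunConfig, state: dict) -> None:
    trace, truth = synthdata.gen_physio(
        animal_id="sim1", seed=cfg.seed, bouts=[(24 + 14.0, 24 + 18.0, 0.3)]
    )
    posts = {
        sig: physio.fit_baseline(trace, sig, draws=cfg.draws, seed=cfg.seed)
        for sig in ("tb", "vo2")
    }
    calls = physio.detect_torpor(trace, posts, ci=cfg.ci)
    min_tb, min_vo2 = physio.min_phenotype(trace, calls)
    io.write_tsv(trace.to_frame().assign(torpor=calls["torpor"]),
                 cfg.outdir / "physio_calls.tsv",
                 _provenance(cfg, "physio", ci=cfg.ci, min_tb=min_tb, min_vo2=min_vo2))
    state.update(trace=trace, calls=calls, min_phenotype=(min_tb, min_vo2))


def _stage_phen(cfg: RunConfig, state: dict) -> None:
    cells = [("021a", a) for a in ("wt", "het", "hom")]
    beta = {c: 0.0 for c in cells}
    gamma = {("021a", "wt"): -10.0, ("021a", "het"): -8.0, ("021a", "hom"): -6.0}
    table, truth = synthdata.gen_ko_phenotypes(
        alpha=37.0, beta=beta, gamma=gamma, sigma_normal=0.5, sigma_torpor=1.0,
        n_per_cell=8, seed=cfg.seed)
    draws = bayesphen.fit_ko_model(table, chains=2, draws=cfg.draws,
                                   warmup=cfg.draws, seed=cfg.seed)
    io.write_tsv(draws.summary().reset_index(), cfg.outdir / "ko_posterior.tsv",
                 _provenance(cfg, "phen", chains=2, draws=cfg.draws))
    state.update(phen_table=table, phen_draws=draws, phen_truth=truth)
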