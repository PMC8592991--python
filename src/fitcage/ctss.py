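"""CAGE TSS (CTSS) processing: tag clustering, normalization, annotation
and promoter-architecture statistics.

CAGE sequences capped 5' RNA ends, giving per-base tag counts (CTSSs) on a
stranded genome. Nearby CTSSs on one strand are grouped into *tag clusters*
(promoters); the highest pooled position is the dominant TSS. Two
architecture statistics are computed in a +/-50 bp window around the
dominant TSS:

* the shape index ``SI = 2 + sum_i p_i log2 p_i`` where ``p_i`` is the tag
  share of window position *i* — 2 for a singleton (all tags at one base),
  decreasing as initiation broadens (below -1 is conventionally "broad");
* %GC, the G+C fraction of the window sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TagCluster",
    "cluster_ctss",
    "pool_tracks",
    "tpm_normalize",
    "annotate_clusters",
    "shape_index",
    "gc_content",
    "count_matrix_from_tracks",
]

CTSS_COLUMNS = ["chrom", "pos", "strand", "count"]


@dataclass
class TagCluster:
    """A called promoter: a run of nearby same-strand CTSSs.

    ``positions``/``counts`` hold the pooled per-base signal; ``peak`` is the
    dominant TSS (argmax of pooled counts, ties broken 5'-most on the
    cluster's strand). Coordinates are 0-based half-open.
    """

    cluster_id: str
    chrom: str
    start: int
    end: int
    strand: str
    peak: int
    positions: np.ndarray
    counts: np.ndarray
    gene: str | None = None
    si: float | None = None
    gc: float | None = None

    @property
    def total_tags(self) -> float:
        return float(self.counts.sum())

    def __post_init__(self) -> None:
        if not (self.start <= self.peak < self.end):
            raise ValueError(
                f"{self.cluster_id}: peak {self.peak} outside [{self.start}, {self.end})"
            )


def _validate_ctss(ctss: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CTSS_COLUMNS if c not in ctss.columns]
    if missing:
        raise ValueError(f"CTSS table missing columns: {missing}")
    if (ctss["count"] <= 0).any():
        raise ValueError("CTSS counts must be positive")
    bad = ~ctss["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"invalid strand values: {ctss.loc[bad, 'strand'].unique()}")
    return ctss


def pool_tracks(tracks: dict[str, pd.DataFrame] | list[pd.DataFrame]) -> pd.DataFrame:
    """Sum per-sample CTSS tracks into one pooled track."""
    frames = list(tracks.values()) if isinstance(tracks, dict) else list(tracks)
    if not frames:
        return pd.DataFrame(columns=CTSS_COLUMNS)
    pooled = pd.concat(frames, ignore_index=True)
    _validate_ctss(pooled)
    pooled = (
        pooled.groupby(["chrom", "pos", "strand"], as_index=False)["count"]
        .sum()
        .sort_values(["chrom", "strand", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return pooled


def cluster_ctss(
    ctss: pd.DataFrame,
    max_gap: int = 20,
    min_tags: float = 10,
) -> list[TagCluster]:
    """Single-linkage clustering of pooled CTSSs along each strand.

    Consecutive CTSSs at most ``max_gap`` bp apart (same chrom and strand)
    join one cluster; clusters with pooled tags below ``min_tags`` are
    dropped. Output order and content are invariant to input row order.
    """
    if len(ctss) == 0:
        return []
    ctss = _validate_ctss(ctss)
    pooled = (
        ctss.groupby(["chrom", "pos", "strand"], as_index=False)["count"]
        .sum()
        .sort_values(["chrom", "strand", "pos"], kind="mergesort")
    )
    clusters: list[TagCluster] = []
    for (chrom, strand), grp in pooled.groupby(["chrom", "strand"], sort=True):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        cnt = grp["count"].to_numpy(dtype=float)
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for seg_pos, seg_cnt in zip(np.split(pos, breaks), np.split(cnt, breaks)):
            if seg_cnt.sum() < min_tags:
                continue
            top = seg_cnt == seg_cnt.max()
            # 5'-most tie-break: smallest coordinate on '+', largest on '-'
            peak = int(seg_pos[top].min() if strand == "+" else seg_pos[top].max())
            clusters.append(
                TagCluster(
                    cluster_id="",
                    chrom=chrom,
                    start=int(seg_pos[0]),
                    end=int(seg_pos[-1]) + 1,
                    strand=strand,
                    peak=peak,
                    positions=seg_pos,
                    counts=seg_cnt,
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.start, c.strand))
    for i, c in enumerate(clusters):
        c.cluster_id = f"prom{i + 1:05d}"
    return clusters


def tpm_normalize(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Scale each sample (column) to tags-per-million.

    ``library_sizes`` defaults to the column sums; each column then sums to
    exactly 1e6 (up to float rounding).
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        bad = library_sizes.index[library_sizes <= 0].tolist()
        raise ValueError(f"non-positive library size for samples: {bad}")
    return counts.div(library_sizes, axis=1) * 1e6


def annotate_clusters(
    clusters: list[TagCluster],
    genes: pd.DataFrame,
    window: int = 500,
) -> list[TagCluster]:
    """Associate each cluster with the nearest same-strand gene 5' end.

    ``genes`` needs columns gene_id, chrom, strand, tss. A cluster is
    associated with the gene whose 5' end is nearest to the cluster peak and
    at most ``window`` bp away; otherwise it stays unassociated (gene=None).
    Distance ties break on gene_id. Annotation happens in place and the list
    is returned for chaining.
    """
    required = {"gene_id", "chrom", "strand", "tss"}
    if not required.issubset(genes.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    by_key: dict[tuple[str, str], pd.DataFrame] = {
        key: grp.sort_values(["tss", "gene_id"]) for key, grp in genes.groupby(["chrom", "strand"])
    }
    for cl in clusters:
        cl.gene = None
        grp = by_key.get((cl.chrom, cl.strand))
        if grp is None:
            continue
        dist = (grp["tss"] - cl.peak).abs()
        near = dist[dist <= window]
        if len(near):
            best = near.min()
            cands = grp.loc[near[near == best].index, "gene_id"]
            cl.gene = sorted(cands)[0]
    return clusters


def shape_index(cluster: TagCluster, window: int = 50) -> float:
    """Entropy-based promoter shape index over +/-``window`` bp of the peak.

    SI = 2 + sum p_i log2 p_i; equals 2 when all tags sit on one base and
    2 - log2(N) for a uniform spread over N bases. Invariant to count scale.
    Returns NaN if the window holds no tags.
    """
    lo, hi = cluster.peak - window, cluster.peak + window
    mask = (cluster.positions >= lo) & (cluster.positions <= hi)
    c = cluster.counts[mask]
    total = c.sum()
    if total <= 0:
        return float("nan")
    p = c / total
    p = p[p > 0]
    return float(2.0 + np.sum(p * np.log2(p)))


def gc_content(cluster: TagCluster, genome: dict[str, str], window: int = 50) -> float:
    """G+C fraction of the +/-``window`` bp sequence around the peak.

    Case-insensitive; ambiguous bases (anything outside ACGT) are excluded
    from numerator and denominator. The window truncates at chromosome ends.
    """
    seq = genome[cluster.chrom]
    if not (0 <= cluster.peak < len(seq)):
        raise ValueError(
            f"{cluster.cluster_id}: peak {cluster.peak} outside {cluster.chrom} "
            f"(length {len(seq)})"
        )
    lo = max(0, cluster.peak - window)
    hi = min(len(seq), cluster.peak + window + 1)
    sub = seq[lo:hi].upper()
    gc = sum(sub.count(b) for b in "GC")
    at = sum(sub.count(b) for b in "AT")
    if gc + at == 0:
        return float("nan")
    return gc / (gc + at)


def count_matrix_from_tracks(
    clusters: list[TagCluster],
    tracks: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Per-sample tag counts within each cluster span (promoters x samples)."""
    out = pd.DataFrame(
        0.0, index=[c.cluster_id for c in clusters], columns=list(tracks.keys())
    )
    # interval lookup per (chrom, strand) via sorted positions
    for sample, track in tracks.items():
        _validate_ctss(track)
        grouped = {
            key: (grp["pos"].to_numpy(), grp["count"].to_numpy(dtype=float))
            for key, grp in track.sort_values("pos").groupby(["chrom", "strand"])
        }
        for cl in clusters:
            entry = grouped.get((cl.chrom, cl.strand))
            if entry is None:
                continue
            pos, cnt = entry
            lo = np.searchsorted(pos, cl.start, side="left")
            hi = np.searchsorted(pos, cl.end, side="left")
            out.loc[cl.cluster_id, sample] = cnt[lo:hi].sum()
    return out
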