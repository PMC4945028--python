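"""Spatial statistics of binding sites along the genome.

Neighbor-distance clustering with randomization normalization, CES proximity
classification, length-normalized metagene profiles, gene-body vs 5'-end
density ratios, ChIP/input locus enrichment, and the two-sample KS test used
for all pairwise distribution comparisons.

Distances are between peak midpoints on the same chromosome; neighbors across
chromosomes are undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from xdense.genomic_io import CoverageTrack, GeneModel, Genome, Interval


# ---------------------------------------------------------------------------
# Neighbor distances
# ---------------------------------------------------------------------------


@dataclass
class NeighborStats:
    """Mean distance of each site to the average of its n nearest neighbors."""

    category: str
    mean_distance: dict[int, float]  # n -> mean over sites of d-bar(n)
    site_count: int
    excluded: dict[int, int]  # n -> sites with too few same-chromosome neighbors


def neighbor_distances(
    peaks: Sequence[Interval],
    labels: Sequence[str] | None = None,
    n_max: int = 4,
) -> dict[str, NeighborStats]:
    """Per-category average distance to the n nearest same-chromosome neighbors.

    For each site, d-bar(n) is the mean of the distances (midpoint to midpoint)
    to its n nearest neighbors on the same chromosome; the category value is
    the mean of d-bar(n) over its sites. Sites with fewer than n neighbors are
    excluded from that n, with counts reported.
    """
    if labels is None:
        labels = ["all"] * len(peaks)
    if len(labels) != len(peaks):
        raise ValueError("labels must match peaks")
    out: dict[str, NeighborStats] = {}
    for category in dict.fromkeys(labels):
        cat_peaks = [p for p, l in zip(peaks, labels) if l == category]
        if len(cat_peaks) < 2:
            raise ValueError(f"category {category!r} has fewer than 2 peaks")
        by_chrom: dict[str, list[int]] = {}
        for p in cat_peaks:
            by_chrom.setdefault(p.chrom, []).append(p.midpoint)
        per_site: dict[int, list[float]] = {n: [] for n in range(1, n_max + 1)}
        excluded = {n: 0 for n in range(1, n_max + 1)}
        for mids in by_chrom.values():
            arr = np.sort(np.asarray(mids, dtype=float))
            for i in range(len(arr)):
                d = np.abs(np.delete(arr, i) - arr[i])
                d.sort()
                for n in range(1, n_max + 1):
                    if len(d) >= n:
                        per_site[n].append(float(d[:n].mean()))
                    else:
                        excluded[n] += 1
        mean_distance = {
            n: (float(np.mean(v)) if v else float("nan"))
            for n, v in per_site.items()
        }
        out[category] = NeighborStats(category, mean_distance, len(cat_peaks), excluded)
    return out


def randomize_and_normalize(
    peaks: Sequence[Interval],
    genome: Genome,
    labels: Sequence[str] | None = None,
    n_sets: int = 10,
    seed: int = 0,
    n_max: int = 4,
) -> dict[str, NeighborStats]:
    """Observed neighbor distances divided by the median of randomized sets.

    Each randomized set re-places the same number of peak midpoints per
    chromosome uniformly at random (per category); the normalized value for
    each n is observed d-bar(n) / median over sets of the randomized d-bar(n).
    Values below 1 indicate clustering tighter than random.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if labels is None:
        labels = ["all"] * len(peaks)
    observed = neighbor_distances(peaks, labels, n_max)
    rng = np.random.default_rng(seed)
    out: dict[str, NeighborStats] = {}
    for category, obs in observed.items():
        cat_peaks = [p for p, l in zip(peaks, labels) if l == category]
        counts: dict[str, int] = {}
        for p in cat_peaks:
            counts[p.chrom] = counts.get(p.chrom, 0) + 1
        rand_values: dict[int, list[float]] = {n: [] for n in range(1, n_max + 1)}
        for _ in range(n_sets):
            rand_peaks = []
            for chrom, n_peaks in counts.items():
                length = len(genome[chrom])
                mids = rng.integers(0, length, size=n_peaks)
                rand_peaks.extend(Interval(chrom, int(m), int(m) + 1) for m in mids)
            rstats = neighbor_distances(rand_peaks, None, n_max)["all"]
            for n in range(1, n_max + 1):
                rand_values[n].append(rstats.mean_distance[n])
        normalized = {
            n: obs.mean_distance[n] / float(np.median(rand_values[n]))
            for n in range(1, n_max + 1)
        }
        out[category] = NeighborStats(category, normalized, obs.site_count, obs.excluded)
    return out


def classify_ces_proximity(
    peaks: Sequence[Interval],
    ces: Sequence[Interval],
    x_chroms: set[str],
    x_median_distance: float | None = None,
) -> list[str]:
    """Label each peak CES / X_other / autosome.

    An X-chromosome peak is "CES" when its midpoint lies within the median
    nearest-neighbor (n=1) distance of X-chromosome peaks from any CES
    midpoint; other X peaks are "X_other"; everything else "autosome". The
    reference distance may be supplied or is computed from the X peaks.
    """
    if not ces:
        raise ValueError("empty CES list")
    x_peaks = [p for p in peaks if p.chrom in x_chroms]
    if x_median_distance is None:
        if len(x_peaks) < 2:
            raise ValueError("need >= 2 X-chromosome peaks to derive the reference")
        by_chrom: dict[str, list[int]] = {}
        for p in x_peaks:
            by_chrom.setdefault(p.chrom, []).append(p.midpoint)
        nearest = []
        for mids in by_chrom.values():
            arr = np.sort(np.asarray(mids, dtype=float))
            if len(arr) < 2:
                continue
            for i in range(len(arr)):
                d = np.abs(np.delete(arr, i) - arr[i])
                nearest.append(d.min())
        x_median_distance = float(np.median(nearest))
    ces_mids: dict[str, np.ndarray] = {}
    for c in ces:
        ces_mids.setdefault(c.chrom, []).append(c.midpoint)  # type: ignore[arg-type]
    ces_mids = {k: np.asarray(v, dtype=float) for k, v in ces_mids.items()}
    labels = []
    for p in peaks:
        if p.chrom not in x_chroms:
            labels.append("autosome")
        else:
            mids = ces_mids.get(p.chrom)
            if mids is not None and np.abs(mids - p.midpoint).min() <= x_median_distance:
                labels.append("CES")
            else:
                labels.append("X_other")
    return labels


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------


@dataclass
class MetageneProfile:
    """Binned feature frequency over [-1, 2] gene-length units around genes."""

    bin_edges: np.ndarray
    values: np.ndarray  # count / (n_genes * bin_width)
    n_genes: int
    n_incidences: int


def metagene_profile(
    features: Sequence[Interval],
    genes: Sequence[GeneModel],
    n_bins: int = 60,
) -> MetageneProfile:
    """Length-normalized profile from one gene length before the TSS to one after the TTS.

    Each feature midpoint within [TSS - L, TTS + L] of a gene (L = gene length)
    is mapped to x = signed distance from the TSS along the transcription
    direction, divided by L, so x in [-1, 2]; minus-strand genes are flipped.
    A feature is counted once per overlapping gene window.
    """
    if not genes:
        raise ValueError("no genes")
    edges = np.linspace(-1.0, 2.0, n_bins + 1)
    xs: list[float] = []
    mids_by_chrom: dict[str, np.ndarray] = {}
    for f in features:
        mids_by_chrom.setdefault(f.chrom, []).append(f.midpoint)  # type: ignore[arg-type]
    mids_by_chrom = {k: np.sort(np.asarray(v, dtype=float)) for k, v in mids_by_chrom.items()}
    for g in genes:
        mids = mids_by_chrom.get(g.chrom)
        if mids is None:
            continue
        L = g.length
        lo, hi = g.start - L, g.end + L
        sel = mids[(mids >= lo) & (mids < hi)]
        if g.strand == "+":
            x = (sel - g.tss) / L
        else:
            x = (g.tss - sel) / L
        xs.extend(x[(x >= -1.0) & (x <= 2.0)].tolist())
    counts, _ = np.histogram(xs, bins=edges)
    bin_width = 3.0 / n_bins
    values = counts / (len(genes) * bin_width)
    return MetageneProfile(edges, values, len(genes), len(xs))


def body_to_tss_ratio(
    features: Sequence[Interval],
    genes: Sequence[GeneModel],
    flank: int = 250,
    gene_groups: Sequence[str] | None = None,
    normalize_to: str | None = None,
) -> dict[str, float | None]:
    """Ratio of feature density in gene bodies to the 5' end, pooled per group.

    Body is (TSS+flank, TTS] along the transcription direction; the 5' end is
    [TSS-flank, TSS+flank]. Densities are pooled across the genes of a group
    before the ratio is taken. A group with zero 5' hits gets None (absent).
    Optionally all ratios are divided by the ``normalize_to`` group's ratio.
    """
    if gene_groups is None:
        gene_groups = ["all"] * len(genes)
    if len(gene_groups) != len(genes):
        raise ValueError("gene_groups must match genes")
    for g in genes:
        if g.length <= flank + 1:
            raise ValueError(f"gene {g.id} is not longer than flank+1")
    mids_by_chrom: dict[str, np.ndarray] = {}
    for f in features:
        mids_by_chrom.setdefault(f.chrom, []).append(f.midpoint)  # type: ignore[arg-type]
    mids_by_chrom = {k: np.sort(np.asarray(v, dtype=float)) for k, v in mids_by_chrom.items()}

    def count_in(chrom: str, lo: int, hi: int) -> int:
        # closed interval [lo, hi] on midpoints
        mids = mids_by_chrom.get(chrom)
        if mids is None:
            return 0
        return int(np.searchsorted(mids, hi, side="right") - np.searchsorted(mids, lo, side="left"))

    agg: dict[str, dict[str, float]] = {}
    for g, grp in zip(genes, gene_groups):
        d = agg.setdefault(
            grp, {"body_hits": 0, "body_len": 0, "five_hits": 0, "five_len": 0, "n": 0}
        )
        if g.strand == "+":
            body_lo, body_hi = g.start + flank + 1, g.end - 1
            five_lo, five_hi = g.start - flank, g.start + flank
        else:
            body_lo, body_hi = g.start, g.end - 2 - flank
            five_lo, five_hi = g.end - 1 - flank, g.end - 1 + flank
        d["body_hits"] += count_in(g.chrom, body_lo, body_hi)
        d["body_len"] += max(body_hi - body_lo + 1, 0)
        d["five_hits"] += count_in(g.chrom, five_lo, five_hi)
        d["five_len"] += 2 * flank
        d["n"] += 1

    ratios: dict[str, float | None] = {}
    for grp, d in agg.items():
        if d["five_hits"] == 0 or d["body_len"] == 0:
            ratios[grp] = None
            continue
        body_density = d["body_hits"] / d["body_len"]
        five_density = d["five_hits"] / d["five_len"]
        ratios[grp] = body_density / five_density
    if normalize_to is not None:
        ref = ratios.get(normalize_to)
        if ref is None:
            raise ValueError(f"reference group {normalize_to!r} has no ratio")
        ratios = {g: (None if r is None else r / ref) for g, r in ratios.items()}
    return ratios


# ---------------------------------------------------------------------------
# Locus enrichment and KS test
# ---------------------------------------------------------------------------


def locus_enrichment(
    chip: CoverageTrack,
    input_track: CoverageTrack,
    loci: Sequence[Interval],
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Depth-normalized ChIP/input tag-count ratio per locus.

    enrichment = ((chip + pc) / chip library size) / ((input + pc) / input
    library size); the pseudocount keeps zero-input loci finite.
    """
    if set(chip.values) != set(input_track.values):
        raise ValueError("chip and input tracks cover different chromosomes")
    chip_lib = chip.library_size
    input_lib = input_track.library_size
    out = np.empty(len(loci))
    for i, iv in enumerate(loci):
        c = (chip.count(iv) + pseudocount) / chip_lib
        n = (input_track.count(iv) + pseudocount) / input_lib
        out[i] = c / n
    return out


def ks_two_sample(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum ECDF difference; the p-value uses the asymptotic
    Kolmogorov distribution with the standard effective-sample-size correction
    (Stephens), or the exact small-sample distribution when
    min(n, m) <= 25 (or ``method="exact"``).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / n
    cdf_b = np.searchsorted(b, pooled, side="right") / m
    d = float(np.abs(cdf_a - cdf_b).max())
    use_exact = method == "exact" or (method == "auto" and min(n, m) <= 25)
    if use_exact:
        p = float(scipy.stats.ks_2samp(a, b, method="exact").pvalue)
    else:
        en = np.sqrt(n * m / (n + m))
        p = float(scipy.special.kolmogorov((en + 0.12 + 0.11 / en) * d))
    return d, float(min(max(p, np.finfo(float).tiny), 1.0))


def neighbor_stats_table(stats: dict[str, NeighborStats]) -> pd.DataFrame:
    rows = [
        {"category": s.category, "n": n, "value": v, "site_count": s.site_count}
        for s in stats.values()
        for n, v in sorted(s.mean_distance.items())
    ]
    return pd.DataFrame(rows)
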