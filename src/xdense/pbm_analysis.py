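"""Protein-binding-microarray probe analysis.

Covers the in-vitro side of the pipeline: thresholding the bimodal intensity
histogram, Gaussian-mixture separation of strongly bound probes, relating
binding intensity to GA-repeat length, and the flank-separation scan that
determines the minimal bound motif (how many consensus nucleotides outside the
8-bp core are needed to separate all bound from all unbound sequences).

All log-intensity work uses log2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from xdense.genomic_io import ProbeRecord, PWMRecord
from xdense import motif_model, repeat_density
from xdense.motif_model import PWMScorer, align_to_pwm


class NoBimodalityError(ValueError):
    """The intensity density has fewer than two modes."""


# ---------------------------------------------------------------------------
# Intensity thresholding and probe classes
# ---------------------------------------------------------------------------


def classify_pbm(
    probes: Sequence[ProbeRecord], threshold: float = 6500.0
) -> list[str]:
    """Label probes PBM+ / PBM- by median intensity.

    PBM+ means *strictly* above the threshold; the boundary value is PBM-.
    """
    return ["PBM+" if p.median_intensity > threshold else "PBM-" for p in probes]


def find_bimodal_threshold(intensities: Sequence[float]) -> float:
    """Threshold at the density minimum between the two strongest modes.

    A Gaussian KDE (Silverman bandwidth) is fitted to log2 intensities; the
    two highest local maxima are located and the threshold is the density
    minimum between them, reported back on the original intensity scale.
    """
    x = np.asarray(intensities, dtype=float)
    if len(x) < 50:
        raise ValueError("need >= 50 observations")
    if np.any(x <= 0):
        raise ValueError("intensities must be positive for the log transform")
    logx = np.log2(x)
    kde = gaussian_kde(logx, bw_method="silverman")
    lo, hi = logx.min(), logx.max()
    pad = 0.05 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, 1024)
    dens = kde(grid)
    interior = np.arange(1, len(grid) - 1)
    peaks = interior[(dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])]
    if len(peaks) < 2:
        raise NoBimodalityError("no bimodality: fewer than two density modes")
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    left, right = sorted(top2)
    valley = left + int(np.argmin(dens[left : right + 1]))
    return float(2.0 ** grid[valley])


def classify_mre(
    seqs: Sequence[str],
    mre_pwm: PWMRecord,
    plus_threshold: float = 1e-4,
    minus_threshold: float = 1e-3,
) -> list[str]:
    """Label sequences MRE+ / MRE- / ambiguous by best scan p-value.

    p < 1e-4 -> MRE+, p > 1e-3 -> MRE-; the unlabeled gap in between is
    reported explicitly as "ambiguous".
    """
    scorer = PWMScorer(mre_pwm)
    labels = []
    for s in seqs:
        p = motif_model.best_hit_p_value(mre_pwm, s.upper(), scorer=scorer)
        if p < plus_threshold:
            labels.append("MRE+")
        elif p > minus_threshold:
            labels.append("MRE-")
        else:
            labels.append("ambiguous")
    return labels


# ---------------------------------------------------------------------------
# Two-Gaussian mixture (EM)
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    means: np.ndarray  # sorted ascending, log2-intensity units
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    posteriors: np.ndarray  # P(higher-mean component) per observation
    n_iterations: int
    converged: bool
    strong_set: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def fit_two_gaussian_mixture(
    log_intensities: Sequence[float],
    confidence: float = 0.95,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureFit:
    """Fit a two-component Gaussian mixture to log2 intensities by EM.

    Initialization is the empirical median split (deterministic; ``seed`` is
    reserved for stochastic restarts). Convergence is declared when the
    absolute log-likelihood change drops below ``tol``; non-convergence is
    reported through ``converged``/``n_iterations`` rather than raised. The
    strong set contains observations assigned to the higher-mean component
    with posterior >= ``confidence``.
    """
    x = np.asarray(log_intensities, dtype=float)
    if len(x) < 50:
        raise ValueError("need >= 50 observations")
    if np.var(x) == 0:
        raise ValueError("zero-variance input")
    med = np.median(x)
    lowers, uppers = x[x <= med], x[x > med]
    mu = np.array([lowers.mean(), uppers.mean()])
    sd_floor = 1e-3 * max(x.std(), 1e-12)
    sd = np.maximum([lowers.std(), uppers.std()], sd_floor)
    w = np.array([0.5, 0.5])

    prev_ll = -np.inf
    n_iter = 0
    converged = False
    resp = np.zeros((len(x), 2))
    for n_iter in range(1, max_iter + 1):
        # E step
        for k in range(2):
            resp[:, k] = w[k] * _normal_pdf(x, mu[k], sd[k])
        total = resp.sum(axis=1)
        total = np.where(total > 0, total, np.finfo(float).tiny)
        ll = float(np.log(total).sum())
        resp /= total[:, None]
        # M step
        nk = resp.sum(axis=0)
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        sd = np.sqrt((resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk)
        sd = np.maximum(sd, sd_floor)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll

    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    dens = np.stack([w[k] * _normal_pdf(x, mu[k], sd[k]) for k in range(2)], axis=1)
    post_high = dens[:, 1] / np.where(dens.sum(axis=1) > 0, dens.sum(axis=1), np.finfo(float).tiny)
    strong = np.flatnonzero(post_high >= confidence)
    return MixtureFit(
        means=mu,
        sds=sd,
        weights=w,
        log_likelihood=ll,
        posteriors=post_high,
        n_iterations=n_iter,
        converged=converged,
        strong_set=strong,
    )


def _normal_pdf(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


# ---------------------------------------------------------------------------
# Quantiles and repeat-length stratification
# ---------------------------------------------------------------------------


def quantile_split(probes: Sequence[ProbeRecord], k: int = 5) -> list[str]:
    """Assign q1..qk by binding intensity; q1 is the *highest* quantile.

    Ties keep input order (stable sort), so equal intensities land in the
    lower-index quantile first; quantile sizes differ by at most 1.
    """
    n = len(probes)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} probes, got {n}")
    order = sorted(range(n), key=lambda i: -probes[i].median_intensity)
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    labels = [""] * n
    pos = 0
    for qi, size in enumerate(sizes, start=1):
        for idx in order[pos : pos + size]:
            labels[idx] = f"q{qi}"
        pos += size
    return labels


def max_repeat_units(seq: str, unit: str = "GA") -> int:
    """Length (in units) of the longest run of ``unit`` in a sequence."""
    runs = repeat_density.find_repeat_runs(seq, unit)
    return max((r.n_units for r in runs), default=0)


def intensity_by_repeat_length(
    probes: Sequence[ProbeRecord], unit: str = "GA", bin_cap: int = 11
) -> pd.DataFrame:
    """Per-repeat-length intensity distribution summaries.

    Each probe is assigned the maximal run length of ``unit`` in its variable
    region; lengths >= ``bin_cap`` are pooled into one ">=cap" bin (few probes
    carry more than 11 repeat units in a 36-bp variable region). Columns:
    repeat_units (str label), n, median, q25, q75.
    """
    rows: dict[int, list[float]] = {}
    for p in probes:
        n_units = min(max_repeat_units(p.variable_seq, unit), bin_cap)
        rows.setdefault(n_units, []).append(p.median_intensity)
    out = []
    for n_units in sorted(rows):
        vals = np.array(rows[n_units])
        label = f">={bin_cap}" if n_units == bin_cap else str(n_units)
        out.append(
            {
                "repeat_units": label,
                "units_numeric": n_units,
                "n": len(vals),
                "median": float(np.median(vals)),
                "q25": float(np.percentile(vals, 25)),
                "q75": float(np.percentile(vals, 75)),
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Flank separation scan
# ---------------------------------------------------------------------------


@dataclass
class FlankScanResult:
    overlap_matrix: np.ndarray  # (max5+1, max3+1) percent, rows = 5' extension
    minimal_window: tuple[int, int] | None
    total_motif_length: int | None
    core_width: int
    dropped: np.ndarray  # per-cell count of sequences too short for the window
    mode: str


def flank_separation_scan(
    bound_seqs: Sequence[str],
    unbound_seqs: Sequence[str],
    core_pwm: PWMRecord,
    max5: int = 10,
    max3: int = 10,
    mode: str = "type",
) -> FlankScanResult:
    """Scan 5' and 3' of the core motif for the minimal separating window.

    For each extension (a, b) the (a + core + b)-mer around each sequence's
    best core match is extracted; overlap(a, b) is the percentage of bound
    k-mers shared with unbound k-mers. The minimal window is the zero-overlap
    cell minimizing a+b (ties to smaller a); the total motif length is
    core_width + a + b.

    ``mode="type"`` intersects distinct k-mer types (default, deterministic
    and order-independent); ``mode="token"`` counts bound *sequences* whose
    k-mer also occurs among unbound sequences. Sequences too short for a given
    window are dropped from that cell, with counts reported.
    """
    if not bound_seqs or not unbound_seqs:
        raise ValueError("empty bound or unbound set")
    if mode not in ("type", "token"):
        raise ValueError(f"unknown mode {mode!r}")
    w = core_pwm.width
    bound_aln = align_to_pwm([s.upper() for s in bound_seqs], core_pwm)
    unbound_aln = align_to_pwm([s.upper() for s in unbound_seqs], core_pwm)

    overlap = np.full((max5 + 1, max3 + 1), np.nan)
    dropped = np.zeros((max5 + 1, max3 + 1), dtype=int)
    for a in range(max5 + 1):
        for b in range(max3 + 1):
            bound_kmers, b_drop = _extract(bound_aln, w, a, b)
            unbound_kmers, u_drop = _extract(unbound_aln, w, a, b)
            dropped[a, b] = b_drop + u_drop
            if not bound_kmers:
                continue
            uset = set(unbound_kmers)
            if mode == "type":
                bset = set(bound_kmers)
                overlap[a, b] = 100.0 * len(bset & uset) / len(bset)
            else:
                shared = sum(1 for km in bound_kmers if km in uset)
                overlap[a, b] = 100.0 * shared / len(bound_kmers)

    _check_monotone(overlap, mode)

    minimal = None
    zero_cells = [
        (a, b)
        for a in range(max5 + 1)
        for b in range(max3 + 1)
        if overlap[a, b] == 0.0
    ]
    if zero_cells:
        minimal = min(zero_cells, key=lambda ab: (ab[0] + ab[1], ab[0]))
    total = None if minimal is None else w + minimal[0] + minimal[1]
    return FlankScanResult(overlap, minimal, total, w, dropped, mode)


def _extract(alignments, w, a, b):
    kmers, drop = [], 0
    for aln in alignments:
        lo, hi = aln.core_start - a, aln.core_start + w + b
        if lo < 0 or hi > len(aln.oriented_seq):
            drop += 1
            continue
        kmers.append(aln.oriented_seq[lo:hi])
    return kmers, drop


def _check_monotone(overlap: np.ndarray, mode: str) -> None:
    # Token-level overlap provably cannot increase when a window grows (a bound
    # sequence shared at the larger window is shared at the smaller); at type
    # level the growing k-mer-type denominator makes this only a near-universal
    # empirical property, so violations warn instead of raising.
    eps = 1e-9
    bad = False
    with np.errstate(invalid="ignore"):
        if overlap.shape[0] > 1:
            bad |= bool(np.any(np.diff(overlap, axis=0) > eps))
        if overlap.shape[1] > 1:
            bad |= bool(np.any(np.diff(overlap, axis=1) > eps))
    if bad:
        msg = "flank-scan overlap matrix is not monotone non-increasing"
        if mode == "token":
            raise AssertionError(msg)
        warnings.warn(msg, stacklevel=3)


# ---------------------------------------------------------------------------
# Occupancy by motif class
# ---------------------------------------------------------------------------


def occupancy_by_motif_class(
    genome,
    core_pwm: PWMRecord,
    full_pwm: PWMRecord,
    chip,
    input_track,
    p_threshold: float = 1e-4,
    pseudocount: float = 1.0,
) -> dict[str, np.ndarray]:
    """ChIP enrichment distributions for core hits with and without the full motif.

    All core-motif hits are found first; those overlapping a full-motif hit are
    the "matched_flank" class and the rest "unmatched_flank". Per-hit ChIP/input
    enrichment comes from :func:`xdense.genome_landscape.locus_enrichment`.
    """
    from xdense.genome_landscape import locus_enrichment
    from xdense.genomic_io import Interval

    core_hits = motif_model.scan(core_pwm, genome, p_threshold=p_threshold)
    if not core_hits:
        raise ValueError("zero core hits")
    full_hits = motif_model.scan(full_pwm, genome, p_threshold=p_threshold)
    full_spans: dict[str, list[tuple[int, int]]] = {}
    for h in full_hits:
        full_spans.setdefault(h.chrom_or_seq_id, []).append(
            (h.offset, h.offset + full_pwm.width)
        )
    matched, unmatched = [], []
    wc = core_pwm.width
    for h in core_hits:
        span = (h.offset, h.offset + wc)
        hit_list = full_spans.get(h.chrom_or_seq_id, [])
        is_matched = any(span[0] < e and s < span[1] for s, e in hit_list)
        iv = Interval(h.chrom_or_seq_id, span[0], span[1])
        (matched if is_matched else unmatched).append(iv)
    if not matched or not unmatched:
        raise ValueError("empty hit class (matched or unmatched flank)")
    return {
        "matched_flank": locus_enrichment(chip, input_track, matched, pseudocount),
        "unmatched_flank": locus_enrichment(chip, input_track, unmatched, pseudocount),
    }
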