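"""Dinucleotide (and general short-unit) tandem repeat detection and density.

A *run* is a maximal in-phase tandem array of a repeat unit: ``AGAGAGA``
contains one maximal (GA)3 run plus flanking single letters. Runs of the
reverse-complement unit (TC for GA) are pooled by default because a repeat
tract is a strand-symmetric genomic feature. N bases break runs and remain in
density denominators; densities are per megabase of chromosome length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from xdense.genomic_io import Genome, Interval, PWMRecord, revcomp
from xdense import motif_model

MB = 1e6


@dataclass(frozen=True)
class RepeatRun:
    chrom: str
    start: int
    end: int
    unit: str  # the unit as matched (e.g. GA or TC)
    n_units: int
    strand_collapsed: bool = True

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.unit) * self.n_units:
            raise ValueError("run span inconsistent with unit count")


def find_repeat_runs(
    target: Genome | str,
    unit: str = "GA",
    min_units: int = 1,
    strand_collapsed: bool = True,
) -> list[RepeatRun]:
    """All maximal runs of >= min_units tandem copies of ``unit``.

    When ``strand_collapsed`` (default), runs of the reverse-complement unit
    are detected too and merged into the same accounting; for palindromic
    units the two scans coincide and are not double-counted.
    """
    unit = unit.upper()
    if not unit:
        raise ValueError("empty unit")
    if set(unit) - set("ACGT"):
        raise ValueError(f"non-ACGT unit {unit!r}")
    if not 1 <= len(unit) <= 6:
        raise ValueError("unit length must be 1-6")
    if len(unit) == 2 and unit[0] == unit[1]:
        warnings.warn(
            f"unit {unit!r} is a homopolymer written as a dinucleotide", stacklevel=2
        )
    units = [unit]
    rc = revcomp(unit)
    if strand_collapsed and rc != unit:
        units.append(rc)

    runs: list[RepeatRun] = []
    for chrom, seq in _iter_seqs(target):
        for u in units:
            runs.extend(
                RepeatRun(chrom, s, e, u, n, strand_collapsed)
                for s, e, n in _scan_runs(seq, u)
                if n >= min_units
            )
    runs.sort(key=lambda r: (r.chrom, r.start, r.unit))
    return runs


def _iter_seqs(target: Genome | str) -> Iterable[tuple[str, str]]:
    if isinstance(target, Genome):
        for c in target:
            yield c.name, c.sequence
    else:
        yield "seq", target.upper()


def _scan_runs(seq: str, unit: str) -> Iterable[tuple[int, int, int]]:
    m = len(unit)
    L = len(seq)
    i = 0
    while i + m <= L:
        if seq[i : i + m] == unit:
            j = i + m
            while seq[j : j + m] == unit:
                j += m
            yield i, j, (j - i) // m
            i = j - m + 1  # a different-phase start can begin inside the tail
        else:
            i += 1


def runs_to_intervals(runs: Sequence[RepeatRun]) -> list[Interval]:
    return [
        Interval(r.chrom, r.start, r.end, strand=".", score=float(r.n_units), name=r.unit)
        for r in runs
    ]


def count_by_length(runs: Sequence[RepeatRun], mode: str = "maximal") -> dict[int, int]:
    """Counts per unit-length k.

    ``maximal``: a run of n units counts only for k = n.
    ``cumulative``: a run of n units counts for every k <= n (so counts are
    non-increasing in k).
    """
    if mode not in ("maximal", "cumulative"):
        raise ValueError(f"unknown mode {mode!r}")
    if not runs:
        return {}
    max_n = max(r.n_units for r in runs)
    counts = {k: 0 for k in range(1, max_n + 1)}
    for r in runs:
        if mode == "maximal":
            counts[r.n_units] += 1
        else:
            for k in range(1, r.n_units + 1):
                counts[k] += 1
    return counts


def density(
    counts: dict[int, int],
    target_length: int,
    genome_id: str = "genome",
    target: str = "all",
    unit: str = "GA",
) -> pd.DataFrame:
    """Per-Mb densities from length-stratified counts (DensityTable rows)."""
    if target_length <= 0:
        raise ValueError("zero-length target")
    rows = [
        {
            "genome_id": genome_id,
            "target": target,
            "unit": unit,
            "length_k": k,
            "count": c,
            "density_per_mb": c / (target_length / MB),
        }
        for k, c in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["genome_id", "target", "unit", "length_k", "count", "density_per_mb"],
    )


def repeat_density_table(
    genome: Genome,
    unit: str = "GA",
    mode: str = "maximal",
    min_units: int = 1,
    strand_collapsed: bool = True,
    genome_id: str = "genome",
) -> pd.DataFrame:
    """Per-chromosome DensityTable for one unit across a genome."""
    frames = []
    for chrom in genome:
        runs = find_repeat_runs(
            chrom.sequence, unit, min_units=min_units, strand_collapsed=strand_collapsed
        )
        counts = count_by_length(runs, mode=mode)
        if counts:
            frames.append(
                density(counts, len(chrom), genome_id, chrom.name, unit)
            )
    if not frames:
        return density({}, 1, genome_id, "none", unit).iloc[0:0]
    return pd.concat(frames, ignore_index=True)


def xa_ratio(
    table: pd.DataFrame, genome: Genome, per_arm: bool = False
) -> pd.DataFrame:
    """X:autosome density ratios per unit and repeat length.

    Pooled mode: (sum X counts / sum X lengths) / (sum A counts / sum A
    lengths). Per-arm mode: one ratio per autosomal arm. Lengths with a zero
    autosomal count are absent from the result (never reported as infinity).
    """
    x_chroms = {c.name: len(c) for c in genome.by_class("X")}
    a_chroms = {c.name: len(c) for c in genome.by_class("autosome")}
    if not x_chroms:
        raise ValueError("no X-labeled chromosome")
    if not a_chroms:
        raise ValueError("no autosome-labeled chromosome")
    x_len = sum(x_chroms.values())
    rows = []
    for (unit, k), sub in table.groupby(["unit", "length_k"]):
        x_count = sub[sub.target.isin(x_chroms)]["count"].sum()
        x_dens = x_count / x_len
        if per_arm:
            for arm, alen in a_chroms.items():
                a_count = sub[sub.target == arm]["count"].sum()
                if a_count == 0:
                    continue
                rows.append(
                    {
                        "unit": unit,
                        "length_k": k,
                        "arm": arm,
                        "ratio": x_dens / (a_count / alen),
                    }
                )
        else:
            a_count = sub[sub.target.isin(a_chroms)]["count"].sum()
            if a_count == 0:
                continue
            rows.append(
                {
                    "unit": unit,
                    "length_k": k,
                    "arm": "pooled",
                    "ratio": x_dens / (a_count / sum(a_chroms.values())),
                }
            )
    return pd.DataFrame(rows, columns=["unit", "length_k", "arm", "ratio"])


def count_exact_matches(seq: str, consensus_seq: str) -> int:
    """Greedy non-overlapping left-to-right occurrences on both strands."""
    total = 0
    targets = [consensus_seq]
    rc = revcomp(consensus_seq)
    if rc != consensus_seq:
        targets.append(rc)
    for t in targets:
        i = 0
        while True:
            i = seq.find(t, i)
            if i < 0:
                break
            total += 1
            i += len(t)
    return total


def motif_hit_density(
    genome: Genome,
    motif: PWMRecord | str,
    mode: str = "exact_consensus",
    p_threshold: float = 1e-4,
    genome_id: str = "genome",
) -> tuple[pd.DataFrame, float | None]:
    """Motif-hit density per chromosome and the pooled X:A ratio.

    ``exact_consensus`` counts greedy non-overlapping exact occurrences of the
    consensus string on both strands; ``pwm_pvalue`` counts scanner hits at
    p <= p_threshold. The ratio is None when no autosomal hit exists.
    """
    if mode not in ("exact_consensus", "pwm_pvalue"):
        raise ValueError(f"unknown mode {mode!r}")
    per_chrom: dict[str, int] = {}
    if mode == "exact_consensus":
        cons = motif if isinstance(motif, str) else motif_model.consensus(motif)
        cons = cons.upper()
        if set(cons) - set("ACGT"):
            raise ValueError(f"consensus contains non-ACGT characters: {cons!r}")
        for chrom in genome:
            per_chrom[chrom.name] = count_exact_matches(chrom.sequence, cons)
    else:
        if isinstance(motif, str):
            raise ValueError("pwm_pvalue mode requires a PWMRecord")
        hits = motif_model.scan(motif, genome, p_threshold=p_threshold)
        for chrom in genome:
            per_chrom[chrom.name] = 0
        for h in hits:
            per_chrom[h.chrom_or_seq_id] += 1

    rows = [
        {
            "genome_id": genome_id,
            "target": c.name,
            "unit": "motif",
            "length_k": 0,
            "count": per_chrom[c.name],
            "density_per_mb": per_chrom[c.name] / (len(c) / MB),
        }
        for c in genome
    ]
    table = pd.DataFrame(rows)

    x = genome.by_class("X")
    a = genome.by_class("autosome")
    ratio = None
    if x and a:
        x_hits = sum(per_chrom[c.name] for c in x)
        a_hits = sum(per_chrom[c.name] for c in a)
        if a_hits > 0:
            x_dens = x_hits / sum(len(c) for c in x)
            a_dens = a_hits / sum(len(c) for c in a)
            ratio = x_dens / a_dens
    return table, ratio
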