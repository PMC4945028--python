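"""Generators for every input the pipeline consumes, with recorded ground truth.

Each generator is a pure function of (config, seed): the same pair regenerates
byte-identical output, and every generator returns a truth record holding the
planted parameters so closed-loop tests can compare recovered values against
known ground truth. A single root seed fans out to per-generator child seeds
through a stable hash, so regenerating one artifact never perturbs another.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from xdense.genomic_io import (
    ACGT,
    Chromosome,
    CoverageTrack,
    GeneModel,
    Genome,
    Interval,
    ShapeTable,
    revcomp,
)
from xdense import repeat_density

PRIMER_24NT = "CCTGTCGACTGGCACGGGAATTCG"  # constant 3' primer of every probe


def child_seed(root_seed: int, name: str) -> int:
    """Stable per-generator seed below 2**31 derived from a root seed."""
    digest = hashlib.blake2b(f"{root_seed}:{name}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(ACGT))[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# Genomes with planted repeat runs and CES
# ---------------------------------------------------------------------------


@dataclass
class ChromSpec:
    name: str
    length: int
    class_label: str = "autosome"
    arm_label: str | None = None
    # planted maximal runs: unit-count k (>= 2) -> density per Mb
    run_density_per_mb: dict[int, float] = field(default_factory=dict)
    n_ces: int = 0
    ces_width: int = 10_000
    # extra runs planted inside each CES window: k -> count per CES
    ces_extra_runs: dict[int, int] = field(default_factory=dict)


def generate_genome(
    chrom_specs: Sequence[ChromSpec],
    seed: int,
    unit: str = "GA",
) -> tuple[Genome, dict]:
    """Generate a genome with exact planted maximal repeat-run counts.

    Background bases are uniform, then sanitized so that no chance maximal run
    of the unit (or its reverse complement) of >= 2 units survives outside the
    planted sites; planted runs are spaced and guarded so each remains maximal.
    The truth record holds, per chromosome, the planted run positions by length
    and the CES intervals.
    """
    unit = unit.upper()
    rng = np.random.default_rng(child_seed(seed, "genome"))
    chroms: list[Chromosome] = []
    truth: dict = {"seed": seed, "unit": unit, "chromosomes": {}}
    ces_all: list[Interval] = []
    for spec in chrom_specs:
        counts = {
            k: int(round(d * spec.length / 1e6))
            for k, d in spec.run_density_per_mb.items()
        }
        if any(k < 2 for k in counts):
            raise ValueError("planted run lengths must be >= 2 units")
        planted_bases = sum(k * len(unit) * c for k, c in counts.items())
        planted_bases += spec.n_ces * sum(
            k * len(unit) * c for k, c in spec.ces_extra_runs.items()
        )
        if planted_bases > spec.length / 2:
            raise ValueError(f"{spec.name}: infeasible planted density")

        seq = np.array(list(_random_seq(rng, spec.length)))
        _sanitize(seq, unit)

        occupied = np.zeros(spec.length, dtype=bool)
        ces_list: list[Interval] = []
        for _ in range(spec.n_ces):
            start = _place(rng, occupied, spec.ces_width, spec.length, reserve=False)
            ces_list.append(Interval(spec.name, start, start + spec.ces_width))
        placed: dict[int, list[int]] = {}
        for k in sorted(counts, reverse=True):
            placed[k] = []
            for _ in range(counts[k]):
                pos = _plant_run(rng, seq, occupied, unit, k, 0, spec.length)
                placed[k].append(pos)
        for ces in ces_list:
            for k, per_ces in sorted(spec.ces_extra_runs.items(), reverse=True):
                placed.setdefault(k, [])
                for _ in range(per_ces):
                    pos = _plant_run(rng, seq, occupied, unit, k, ces.start, ces.end)
                    placed[k].append(pos)

        chroms.append(
            Chromosome(
                name=spec.name,
                sequence="".join(seq),
                class_label=spec.class_label,  # type: ignore[arg-type]
                arm_label=spec.arm_label,
            )
        )
        ces_all.extend(ces_list)
        truth["chromosomes"][spec.name] = {
            "length": spec.length,
            "class": spec.class_label,
            "planted_runs": {k: sorted(v) for k, v in placed.items() if v},
            "ces": [(c.start, c.end) for c in ces_list],
        }
    truth["ces"] = ces_all
    return Genome(chroms), truth


def _no_tandem_double(seq: np.ndarray, pos: int, unit: str) -> bool:
    """True if no 2-unit tandem of unit or its revcomp passes through pos."""
    m = len(unit)
    doubles = (unit * 2, revcomp(unit) * 2)
    for s in range(max(0, pos - 2 * m + 1), min(pos + 1, len(seq) - 2 * m + 1)):
        window = "".join(seq[s : s + 2 * m])
        if window in doubles:
            return False
    return True


def _sanitize(seq: np.ndarray, unit: str) -> None:
    """Mutate bases so no maximal run of unit/revcomp(unit) with >= 2 units remains.

    Single unit copies are left alone (they are unavoidable in random DNA and
    irrelevant to length->=2 ground truth); every second copy of each longer
    run is broken by a point substitution.
    """
    m = len(unit)
    for _ in range(20):
        runs = repeat_density.find_repeat_runs("".join(seq), unit, min_units=2)
        if not runs:
            return
        for r in runs:
            for copy_start in range(r.start + m, r.end, 2 * m):
                old = seq[copy_start]
                for cand in ACGT:
                    if cand == old:
                        continue
                    seq[copy_start] = cand
                    if _no_tandem_double(seq, copy_start, unit):
                        break
                else:
                    seq[copy_start] = old  # retry on the next pass
    raise RuntimeError("background sanitization did not converge")


def _place(rng, occupied: np.ndarray, width: int, length: int, reserve: bool = True,
           max_attempts: int = 10_000) -> int:
    for _ in range(max_attempts):
        start = int(rng.integers(0, length - width))
        if not occupied[start : start + width].any():
            if reserve:
                occupied[start : start + width] = True
            return start
    raise ValueError("could not place a feature; density too high")


def _plant_run(rng, seq: np.ndarray, occupied: np.ndarray, unit: str, k: int,
               lo: int, hi: int, max_attempts: int = 10_000) -> int:
    """Write a guarded maximal run of k unit copies inside [lo, hi)."""
    m = len(unit)
    span = k * m
    guard = 2 * m
    for _ in range(max_attempts):
        start = int(rng.integers(lo + guard, hi - span - guard))
        window = slice(start - guard, start + span + guard)
        if occupied[window].any():
            continue
        occupied[window] = True
        seq[start : start + span] = list(unit * k)
        for g in range(guard):
            # guards flank the run with bases that cannot extend or seed a run
            seq[start - guard + g] = _guard_base(seq, start - guard + g, unit)
            seq[start + span + g] = _guard_base(seq, start + span + g, unit)
        return start
    raise ValueError("could not place a repeat run; density too high")


def _guard_base(seq: np.ndarray, pos: int, unit: str) -> str:
    # forbid any 2-unit tandem through the guard position, so guards can
    # neither extend the planted run nor seed a new one with the background
    for cand in "TGCA":
        seq[pos] = cand
        if _no_tandem_double(seq, pos, unit):
            return cand
    raise RuntimeError("no viable guard base")  # impossible for units over ACGT


# ---------------------------------------------------------------------------
# Probe sets
# ---------------------------------------------------------------------------


@dataclass
class ProbeSetConfig:
    n_bound: int = 200
    n_unbound: int = 200
    core: str = "GAGAGAGA"
    flank5: str = "TACT"  # bound-class consensus, 4 nt 5' of the core
    flank3: str = "CGT"  # bound-class consensus, 3 nt 3' of the core
    core_start: int = 14  # within the 36-nt variable region
    base_bound: float = 7000.0
    base_unbound: float = 2500.0
    effect_per_unit: float = 400.0
    plateau_units: int = 10
    noise_sd: float = 300.0
    replicates: int = 8
    n_near_miss: int = 3  # unbound single-mutation probes of each near-miss type


def generate_probe_set(config: ProbeSetConfig, seed: int):
    """Generate a gcPBM-like probe set with a planted minimal bound motif.

    Bound probes carry consensus flanks (4 nt 5', 3 nt 3') around the core;
    unbound probes carry the same core with random non-consensus flank pairs.
    Two families of deterministic near-miss unbound probes (a bound probe with
    a single mutation just outside the 4/3 window on either side) guarantee
    that the flank-scan overlap is zero exactly when the window covers >= 4 nt
    5' and >= 3 nt 3', so the recoverable minimal window is (4, 3) by
    construction.

    Intensities follow base_class + effect * min(GA-run units, plateau) +
    Gaussian replicate noise. Returns (probes, truth).
    """
    cfg = config
    rng = np.random.default_rng(child_seed(seed, "probes"))
    w = len(cfg.core)
    if cfg.core_start < len(cfg.flank5) or cfg.core_start + w + len(cfg.flank3) > 36:
        raise ValueError("core placement leaves no room for the planted flanks")
    if 2 * cfg.n_near_miss >= cfg.n_unbound:
        raise ValueError("n_unbound too small for the near-miss probes")

    from xdense.genomic_io import ProbeRecord

    def make_variable(f5: str, f3: str) -> str:
        for _ in range(1000):
            left = _random_seq(rng, cfg.core_start - len(f5))
            right = _random_seq(rng, 36 - cfg.core_start - w - len(f3))
            var = left + f5 + cfg.core + f3 + right
            if var.count(cfg.core) == 1 and revcomp(cfg.core) not in var:
                return var
        raise RuntimeError("could not build a probe without spurious core matches")

    def intensities(base: float, n_units: int) -> list[float]:
        mean = base + cfg.effect_per_unit * min(n_units, cfg.plateau_units)
        return [float(max(v, 1.0)) for v in rng.normal(mean, cfg.noise_sd, cfg.replicates)]

    probes: list[ProbeRecord] = []
    bound_vars: list[str] = []
    for i in range(cfg.n_bound):
        var = make_variable(cfg.flank5, cfg.flank3)
        bound_vars.append(var)
        n_units = repeat_density.find_repeat_runs(var, "GA")
        nmax = max((r.n_units for r in n_units), default=0)
        probes.append(
            ProbeRecord(
                id=f"bound_{i}",
                variable_seq=var,
                full_seq=var + PRIMER_24NT,
                chip_flag="+",
                replicate_intensities=intensities(cfg.base_bound, nmax),
            )
        )

    # near-miss unbound probes: copies of bound probes mutated one base outside
    # the (4,3) window, anchoring nonzero overlap at every smaller window
    template = bound_vars[0]
    near_miss: list[str] = []
    for t in range(cfg.n_near_miss):
        tmpl = bound_vars[t % len(bound_vars)]
        pos5 = cfg.core_start - len(cfg.flank5)
        var_a = _mutate(tmpl, pos5, rng, forbidden=(cfg.core,))
        near_miss.append(var_a)
        pos3 = cfg.core_start + w + len(cfg.flank3) - 1
        var_b = _mutate(tmpl, pos3, rng, forbidden=(cfg.core,))
        near_miss.append(var_b)

    unbound_vars = list(near_miss)
    while len(unbound_vars) < cfg.n_unbound:
        f5 = _random_seq(rng, len(cfg.flank5))
        f3 = _random_seq(rng, len(cfg.flank3))
        if f5 == cfg.flank5 and f3 == cfg.flank3:
            continue
        unbound_vars.append(make_variable(f5, f3))
    for i, var in enumerate(unbound_vars):
        runs = repeat_density.find_repeat_runs(var, "GA")
        nmax = max((r.n_units for r in runs), default=0)
        probes.append(
            ProbeRecord(
                id=f"unbound_{i}",
                variable_seq=var,
                full_seq=var + PRIMER_24NT,
                chip_flag="-",
                replicate_intensities=intensities(cfg.base_unbound, nmax),
            )
        )

    truth = {
        "seed": seed,
        "config": cfg,
        "minimal_window": (len(cfg.flank5), len(cfg.flank3)),
        "total_motif_length": w + len(cfg.flank5) + len(cfg.flank3),
        "n_bound": cfg.n_bound,
        "n_unbound": cfg.n_unbound,
        "bound_template": template,
    }
    return probes, truth


def _mutate(var: str, pos: int, rng, forbidden: Sequence[str] = ()) -> str:
    old = var[pos]
    for cand in "ACGT":
        if cand == old:
            continue
        new = var[:pos] + cand + var[pos + 1 :]
        if all(new.count(f) == 1 for f in forbidden) and all(
            revcomp(f) not in new for f in forbidden
        ):
            return new
    raise RuntimeError("no viable mutation")


def generate_repeat_probe_set(
    run_lengths: Sequence[int],
    seed: int,
    n_per_length: int = 30,
    base: float = 6000.0,
    effect_per_unit: float = 400.0,
    plateau_units: int = 10,
    noise_sd: float = 100.0,
    replicates: int = 8,
):
    """Probes carrying planted GA runs of chosen lengths, for the intensity-vs-
    repeat-length analysis. Intensity = base + effect * min(k, plateau) + noise.
    """
    from xdense.genomic_io import ProbeRecord

    rng = np.random.default_rng(child_seed(seed, "repeat_probes"))
    probes = []
    for k in run_lengths:
        if 2 * k > 32:
            raise ValueError(f"run of {k} units does not fit the variable region")
        for i in range(n_per_length):
            for _ in range(1000):
                total_ctx = 36 - 2 * k
                left_n = total_ctx // 2
                left = _random_seq(rng, left_n)
                right = _random_seq(rng, total_ctx - left_n)
                var = left + "GA" * k + right
                runs = repeat_density.find_repeat_runs(var, "GA")
                if max(r.n_units for r in runs) == k and sum(
                    1 for r in runs if r.n_units == k
                ) == 1:
                    break
            else:
                raise RuntimeError("could not plant a clean run")
            mean = base + effect_per_unit * min(k, plateau_units)
            vals = [float(max(v, 1.0)) for v in rng.normal(mean, noise_sd, replicates)]
            probes.append(
                ProbeRecord(
                    id=f"rep{k}_{i}",
                    variable_seq=var,
                    full_seq=var + PRIMER_24NT,
                    replicate_intensities=vals,
                )
            )
    truth = {
        "seed": seed,
        "base": base,
        "effect_per_unit": effect_per_unit,
        "plateau_units": plateau_units,
        "noise_sd": noise_sd,
    }
    return probes, truth


# ---------------------------------------------------------------------------
# Peaks, genes, coverage, shape table
# ---------------------------------------------------------------------------


def generate_peaks(
    genome: Genome,
    n_per_chrom: dict[str, int],
    seed: int,
    mode: str = "uniform",
    ces: Sequence[Interval] = (),
    cluster_sd: float = 200.0,
    ces_fraction: float = 0.5,
    minor_fraction: float = 0.3,
    minor_sd_factor: float = 5.0,
    peak_halfwidth: int = 100,
) -> tuple[list[Interval], dict]:
    """Peak intervals with uniform or CES-clustered midpoints.

    In clustered mode, X-chromosome peaks are drawn in three tiers:
    ``ces_fraction`` Gaussian around CES midpoints (sd = ``cluster_sd``),
    ``minor_fraction`` around scattered minor cluster centers (sd larger by
    ``minor_sd_factor``), and the rest uniform — emulating the observed
    hierarchy of clustering (tightest at CES, intermediate elsewhere on X,
    none on autosomes). Non-X chromosomes are always uniform.
    """
    if mode not in ("uniform", "clustered_at_CES"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "clustered_at_CES" and not ces:
        raise ValueError("clustered mode requires CES intervals")
    rng = np.random.default_rng(child_seed(seed, "peaks"))
    peaks: list[Interval] = []
    truth = {"seed": seed, "mode": mode, "cluster_sd": cluster_sd, "n": dict(n_per_chrom)}
    for chrom_name, n in n_per_chrom.items():
        chrom = genome[chrom_name]
        length = len(chrom)
        if n > length // (2 * peak_halfwidth + 1):
            raise ValueError(f"{chrom_name}: {n} peaks exceed chromosome capacity")
        ces_mids = np.array(
            [c.midpoint for c in ces if c.chrom == chrom_name], dtype=float
        )
        use_cluster = (
            mode == "clustered_at_CES" and chrom.class_label == "X" and len(ces_mids) > 0
        )
        n_ces_peaks = int(round(ces_fraction * n)) if use_cluster else 0
        n_minor = int(round(minor_fraction * n)) if use_cluster else 0
        minor_centers = (
            rng.integers(0, length, size=max(5, n_minor // 10))
            if n_minor
            else np.array([], dtype=int)
        )

        def clipped(center: float, sd: float) -> int:
            return int(np.clip(rng.normal(center, sd),
                               peak_halfwidth, length - peak_halfwidth - 1))

        mids = []
        for i in range(n):
            if i < n_ces_peaks:
                m = clipped(ces_mids[rng.integers(0, len(ces_mids))], cluster_sd)
            elif i < n_ces_peaks + n_minor:
                m = clipped(minor_centers[rng.integers(0, len(minor_centers))],
                            cluster_sd * minor_sd_factor)
            else:
                m = int(rng.integers(peak_halfwidth, length - peak_halfwidth))
            mids.append(m)
        peaks.extend(
            Interval(chrom_name, m - peak_halfwidth, m + peak_halfwidth + 1)
            for m in mids
        )
    return peaks, truth


def generate_genes(
    genome: Genome,
    n_per_chrom: dict[str, int],
    seed: int,
    log_mean: float = np.log(3000.0),
    log_sd: float = 0.4,
    min_length: int = 600,
    max_attempts: int = 20_000,
) -> tuple[list[GeneModel], dict]:
    """Non-overlapping genes on both strands with log-normal lengths."""
    rng = np.random.default_rng(child_seed(seed, "genes"))
    genes: list[GeneModel] = []
    truth = {"seed": seed, "log_mean": log_mean, "log_sd": log_sd}
    for chrom_name, n in n_per_chrom.items():
        length = len(genome[chrom_name])
        occupied = np.zeros(length, dtype=bool)
        achieved = 0
        attempts = 0
        while achieved < n:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"{chrom_name}: placed only {achieved} of {n} non-overlapping genes"
                )
            glen = int(max(min_length, rng.lognormal(log_mean, log_sd)))
            if glen >= length:
                continue
            start = int(rng.integers(0, length - glen))
            if occupied[start : start + glen].any():
                continue
            occupied[start : start + glen] = True
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(chrom_name, start, start + glen, strand,
                          f"{chrom_name}_g{achieved}")
            )
            achieved += 1
    return genes, truth


def generate_coverage(
    genome: Genome,
    loci: Sequence[Interval],
    multipliers: Sequence[float],
    seed: int,
    base_rate: float = 0.2,
) -> tuple[CoverageTrack, CoverageTrack, dict]:
    """Poisson-sampled ChIP and input tracks with planted enrichment multipliers.

    The input track has rate ``base_rate`` per base everywhere; the ChIP rate
    is multiplied by the planted factor over each locus.
    """
    if len(loci) != len(multipliers):
        raise ValueError("need one multiplier per locus")
    rng = np.random.default_rng(child_seed(seed, "coverage"))
    chip_vals, input_vals = {}, {}
    rates = {c.name: np.full(len(c), base_rate) for c in genome}
    for iv, mult in zip(loci, multipliers):
        rates[iv.chrom][iv.start : iv.end] = base_rate * mult
    for c in genome:
        chip_vals[c.name] = rng.poisson(rates[c.name]).astype(float)
        input_vals[c.name] = rng.poisson(np.full(len(c), base_rate)).astype(float)
    truth = {"seed": seed, "base_rate": base_rate, "multipliers": list(multipliers)}
    return CoverageTrack(chip_vals), CoverageTrack(input_vals), truth


SHAPE_RANGES = {
    "MGW": (2.8, 6.2),  # Angstrom
    "ProT": (-17.0, 0.0),  # degrees
    "Roll": (-8.0, 8.0),  # degrees
    "HelT": (30.0, 40.0),  # degrees
}


def generate_shape_table(seed: int) -> ShapeTable:
    """A complete synthetic pentamer shape table with plausible value ranges."""
    from itertools import product as iproduct

    rng = np.random.default_rng(child_seed(seed, "shape"))
    mapping = {}
    for p in ("".join(t) for t in iproduct(ACGT, repeat=5)):
        mapping[p] = tuple(
            float(rng.uniform(lo, hi)) for lo, hi in SHAPE_RANGES.values()
        )
    return ShapeTable(mapping)
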