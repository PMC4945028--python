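"""Domain types and readers/writers for the standard formats the pipeline touches.

Conventions shared by every module:

* coordinates are 0-based half-open (BED native; GFF3 converted on read);
* sequences are uppercase over the alphabet ``ACGTN``;
* chromosome class labels (``X`` / ``autosome`` / ``other``) come from an
  explicit YAML side-car, never from name heuristics — cross-species chromosome
  naming is too inconsistent for guessing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import yaml
from Bio import SeqIO

VALID_BASES = set("ACGTN")
ACGT = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ACGT)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """A malformed input file; the message names the offending line or record."""


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

ClassLabel = Literal["X", "autosome", "other"]


@dataclass
class Chromosome:
    name: str
    sequence: str
    class_label: ClassLabel = "other"
    arm_label: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"chromosome {self.name!r}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"chromosome {self.name!r}: non-ACGTN characters {sorted(bad)}"
            )
        if self.class_label not in ("X", "autosome", "other"):
            raise ValueError(f"chromosome {self.name!r}: bad class {self.class_label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    """Ordered named chromosome sequences with X/autosome class labels."""

    chromosomes: list[Chromosome] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome names: {dupes}")

    def __iter__(self):
        return iter(self.chromosomes)

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def by_class(self, class_label: str) -> list[Chromosome]:
        return [c for c in self.chromosomes if c.class_label == class_label]

    def total_length(self, class_label: str | None = None) -> int:
        chroms = self.chromosomes if class_label is None else self.by_class(class_label)
        return sum(len(c) for c in chroms)


# ---------------------------------------------------------------------------
# Intervals and gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end}: need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        # floor of the midpoint: deterministic tie-break for even lengths
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand; TSS/TTS are derived, not stored."""

    chrom: str
    start: int
    end: int
    strand: str
    id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.id}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Probes, PWMs, shape table
# ---------------------------------------------------------------------------

_FLAG_VALUES = ("+", "-", "NA")


@dataclass
class ProbeRecord:
    """One genomic-context PBM probe.

    ``variable_seq`` is the 36-nt variable region; ``full_seq`` the complete
    60-nt probe (variable region followed by the 24-nt primer) when known.
    """

    id: str
    variable_seq: str
    replicate_intensities: list[float]
    chip_flag: str = "NA"
    mre_flag: str = "NA"
    full_seq: str | None = None

    def __post_init__(self) -> None:
        for flag, label in ((self.chip_flag, "chip_flag"), (self.mre_flag, "mre_flag")):
            if flag not in _FLAG_VALUES:
                raise ValueError(
                    f"probe {self.id}: {label}={flag!r}; allowed values are {_FLAG_VALUES}"
                )
        if self.full_seq is not None:
            if len(self.full_seq) != 60:
                raise ValueError(f"probe {self.id}: full_seq must be 60 nt")
            if len(self.variable_seq) != 36:
                raise ValueError(
                    f"probe {self.id}: variable_seq must be 36 nt when full_seq present"
                )
        if not self.replicate_intensities:
            raise ValueError(f"probe {self.id}: no intensities")

    @property
    def median_intensity(self) -> float:
        return float(np.median(self.replicate_intensities))


@dataclass
class PWMRecord:
    """Position frequency matrix (columns A,C,G,T), rows summing to 1."""

    freqs: np.ndarray
    pseudocount: float = 0.0
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    name: str = "motif"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4 or self.freqs.shape[0] < 1:
            raise ValueError("freqs must be a width x 4 matrix with width >= 1")
        if np.any(self.freqs < 0):
            raise ValueError("negative frequency")
        sums = self.freqs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"PWM rows must sum to 1 (sums: {sums})")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    def reverse_complement(self) -> "PWMRecord":
        return PWMRecord(
            freqs=self.freqs[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            background=self.background[::-1].copy(),
            name=self.name,
        )


PENTAMER_COLUMNS = ("MGW", "ProT", "Roll", "HelT")


class ShapeTable:
    """Pentamer -> (MGW, ProT, Roll, HelT) lookup; all 1024 pentamers required."""

    def __init__(self, mapping: dict[str, tuple[float, float, float, float]]):
        expected = 4 ** 5
        missing = _missing_pentamer(mapping)
        if missing is not None:
            raise ValueError(f"shape table missing pentamer {missing!r}")
        if len(mapping) != expected:
            extra = set(mapping) - set(_all_pentamers())
            raise ValueError(f"shape table has unexpected keys: {sorted(extra)[:5]}")
        self._map = {k: tuple(float(x) for x in v) for k, v in mapping.items()}

    def __getitem__(self, pentamer: str) -> tuple[float, float, float, float]:
        if len(pentamer) != 5:
            raise KeyError(f"not a pentamer: {pentamer!r}")
        if "N" in pentamer:
            raise KeyError(f"N-containing pentamer has no shape: {pentamer!r}")
        return self._map[pentamer]

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()


def _all_pentamers() -> list[str]:
    from itertools import product

    return ["".join(p) for p in product(ACGT, repeat=5)]


def _missing_pentamer(mapping) -> str | None:
    for p in _all_pentamers():
        if p not in mapping:
            return p
    return None


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_class_config(path: str | Path) -> dict[str, dict]:
    """Read the YAML side-car mapping chromosome name -> {class, arm}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for name, entry in raw.items():
        if isinstance(entry, str):
            entry = {"class": entry}
        out[str(name)] = {
            "class": entry.get("class", "other"),
            "arm": entry.get("arm"),
        }
    return out


def read_fasta(path: str | Path, class_config: dict[str, dict] | None = None) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Sequences are uppercased; non-ACGTN characters are rejected. Class labels
    are attached from ``class_config`` (see :func:`read_class_config`); records
    absent from the config are labeled ``other``.
    """
    class_config = class_config or {}
    chroms: list[Chromosome] = []
    seen: set[str] = set()
    with open(path) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    for rec in records:
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record name {rec.id!r}")
        seen.add(rec.id)
        cfg = class_config.get(rec.id, {})
        try:
            chroms.append(
                Chromosome(
                    name=rec.id,
                    sequence=str(rec.seq),
                    class_label=cfg.get("class", "other"),
                    arm_label=cfg.get("arm"),
                )
            )
        except ValueError as e:
            raise ParseError(f"{path}: {e}") from e
    return Genome(chroms)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in genome:
            fh.write(f">{c.name}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


def read_bed(path: str | Path) -> list[Interval]:
    """Read a BED3+ file; column 5 -> score, column 6 -> strand."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from e
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as e:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from e
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(Interval(chrom, start, end, strand=strand, score=score, name=name))
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from e
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = "." if iv.score is None else format(iv.score, "g")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_gene_models(path: str | Path, dialect: str = "BED12") -> list[GeneModel]:
    """Read gene models from BED12 or a GFF3 subset (``gene`` features only)."""
    if dialect == "BED12":
        return _read_genes_bed12(path)
    if dialect == "GFF3-gene":
        return _read_genes_gff3(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'BED12' or 'GFF3-gene'")


def _read_genes_bed12(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: BED12 gene rows need >= 6 columns")
            if f[5] not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: missing or bad strand {f[5]!r}")
            try:
                genes.append(GeneModel(f[0], int(f[1]), int(f[2]), f[5], f[3]))
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from e
    return genes


def _read_genes_gff3(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ParseError(f"{path}:{lineno}: GFF3 rows need 9 columns")
            if f[2] != "gene":
                continue
            if f[6] not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: missing or bad strand {f[6]!r}")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}")
            try:
                # GFF3 is 1-based closed: subtract 1 from start
                genes.append(GeneModel(f[0], int(f[3]) - 1, int(f[4]), f[6], gid))
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from e
    return genes


def write_gene_models_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t1\t{g.length},\t0,\n"
            )


def read_probe_table(path: str | Path, full_probe_mode: bool = False) -> list[ProbeRecord]:
    """Read a probe TSV: id, sequence, chip_flag, mre_flag, then intensity columns.

    ``full_probe_mode`` declares the sequence column to be the complete 60-nt
    probe; the 36-nt variable region is then its first 36 bases.
    """
    probes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["id", "sequence", "chip_flag", "mre_flag"]:
            raise ParseError(
                f"{path}: header must start with id, sequence, chip_flag, mre_flag"
            )
        n_int = len(header) - 4
        if n_int < 1:
            raise ParseError(f"{path}: need at least one intensity column")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(header):
                raise ParseError(f"{path}:{lineno}: column count mismatch")
            seq = f[1].upper()
            if full_probe_mode:
                if len(seq) != 60:
                    raise ParseError(
                        f"{path}:{lineno}: full-probe mode requires 60-nt sequences"
                    )
                full_seq, var_seq = seq, seq[:36]
            else:
                full_seq, var_seq = None, seq
            try:
                intensities = [float(x) for x in f[4:]]
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: non-numeric intensity") from e
            try:
                probes.append(
                    ProbeRecord(
                        id=f[0],
                        variable_seq=var_seq,
                        full_seq=full_seq,
                        chip_flag=f[2],
                        mre_flag=f[3],
                        replicate_intensities=intensities,
                    )
                )
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from e
    return probes


def write_probe_table(probes: Sequence[ProbeRecord], path: str | Path) -> None:
    n_rep = max(len(p.replicate_intensities) for p in probes)
    cols = [f"intensity_{i+1}" for i in range(n_rep)]
    with open(path, "w") as fh:
        fh.write("\t".join(["id", "sequence", "chip_flag", "mre_flag"] + cols) + "\n")
        for p in probes:
            seq = p.full_seq if p.full_seq is not None else p.variable_seq
            vals = [format(v, "g") for v in p.replicate_intensities]
            vals += [""] * (n_rep - len(vals))
            fh.write("\t".join([p.id, seq, p.chip_flag, p.mre_flag] + vals) + "\n")


def read_pwm(path: str | Path) -> list[PWMRecord]:
    """Read PWMs from MEME minimal text format.

    Rows off unity by <= 1e-4 are renormalized; larger deviations are errors.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(l.startswith("MEME version") for l in lines):
        raise ParseError(f"{path}: missing 'MEME version' line")
    background = np.full(4, 0.25)
    pwms: list[PWMRecord] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            bg = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([bg.get(b, 0.25) for b in ACGT])
            background = background / background.sum()
        elif line.startswith("MOTIF"):
            name = line.split(None, 2)[1] if len(line.split()) > 1 else f"motif_{len(pwms)+1}"
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise ParseError(f"{path}: MOTIF {name} lacks a matrix block")
                i += 1
            if i >= len(lines):
                raise ParseError(f"{path}: MOTIF {name} lacks a matrix block")
            header = lines[i]
            declared_w = None
            toks = header.replace("=", " = ").split()
            if "w" in toks:
                declared_w = int(toks[toks.index("w") + 2])
            i += 1
            rows = []
            while i < len(lines):
                s = lines[i].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                vals = s.split()
                if len(vals) != 4:
                    raise ParseError(f"{path}: matrix row with {len(vals)} values")
                rows.append([float(v) for v in vals])
                i += 1
            mat = np.array(rows)
            if declared_w is not None and mat.shape[0] != declared_w:
                raise ParseError(
                    f"{path}: MOTIF {name}: {mat.shape[0]} rows but w={declared_w}"
                )
            sums = mat.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-4):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ParseError(
                    f"{path}: MOTIF {name}: row {bad+1} sums to {sums[bad]:.6f}"
                )
            mat = mat / sums[:, None]
            pwms.append(PWMRecord(freqs=mat, background=background, name=name))
            continue
        i += 1
    if not pwms:
        raise ParseError(f"{path}: no 'letter-probability matrix' blocks found")
    return pwms


def write_pwm(pwms: Sequence[PWMRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = pwms[0].background
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {v:.6f}" for b, v in zip(ACGT, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.freqs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_shape_table(path: str | Path) -> ShapeTable:
    """Read a pentamer shape TSV: pentamer, MGW, ProT, Roll, HelT."""
    mapping: dict[str, tuple[float, float, float, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("pentamer"):
                continue
            f = line.split("\t")
            if len(f) != 5:
                raise ParseError(f"{path}:{lineno}: need pentamer + 4 numeric columns")
            p = f[0].upper()
            if p in mapping:
                raise ParseError(f"{path}:{lineno}: duplicate pentamer {p!r}")
            try:
                mapping[p] = tuple(float(x) for x in f[1:])  # type: ignore[assignment]
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: non-numeric shape value") from e
    try:
        return ShapeTable(mapping)
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from e


def write_shape_table(table: ShapeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pentamer\tMGW\tProT\tRoll\tHelT\n")
        for p, vals in sorted(table.items()):
            fh.write(p + "\t" + "\t".join(f"{v:.3f}" for v in vals) + "\n")


# ---------------------------------------------------------------------------
# Coverage tracks (bedGraph)
# ---------------------------------------------------------------------------


class CoverageTrack:
    """Per-chromosome step-function coverage held as per-base arrays.

    Suitable for the desk-scale genomes this package analyses; ``library_size``
    is the total track mass used for depth normalization.
    """

    def __init__(self, values: dict[str, np.ndarray]):
        self.values = {c: np.asarray(v, dtype=float) for c, v in values.items()}

    @property
    def library_size(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def count(self, iv: Interval) -> float:
        if iv.chrom not in self.values:
            raise KeyError(f"track has no chromosome {iv.chrom!r}")
        arr = self.values[iv.chrom]
        return float(arr[iv.start : min(iv.end, len(arr))].sum())


def read_bedgraph(path: str | Path, chrom_lengths: dict[str, int]) -> CoverageTrack:
    values = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise ParseError(f"{path}:{lineno}: bedGraph rows need 4 columns")
            chrom, start, end, val = f[0], int(f[1]), int(f[2]), float(f[3])
            if chrom not in values:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            values[chrom][start:end] = val
    return CoverageTrack(values)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, arr in track.values.items():
            if len(arr) == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Peak windows
# ---------------------------------------------------------------------------


def extract_peak_windows(
    peaks: Sequence[Interval], genome: Genome, half_width: int = 100
) -> tuple[list[str], int]:
    """Extract fixed windows of length ``2*half_width + 1`` around peak centers.

    The center is the floor of the peak midpoint. Windows that would run past a
    chromosome end are dropped; the number dropped is returned alongside.
    """
    windows: list[str] = []
    dropped = 0
    for p in peaks:
        if p.chrom not in genome:
            raise KeyError(f"peak on unknown chromosome {p.chrom!r}")
        seq = genome[p.chrom].sequence
        c = p.midpoint
        lo, hi = c - half_width, c + half_width + 1
        if lo < 0 or hi > len(seq):
            dropped += 1
            continue
        windows.append(seq[lo:hi])
    return windows, dropped
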