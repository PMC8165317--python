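"""Synthetic genomes, read sets, ribotype panels and qPCR plates.

The generator reproduces the data-generating structure the estimators
assume: a diploid genome of stated 2C size carrying a native rDNA tandem
array of known copy number plus zero or more minority foreign-ribotype
insertions; uniformly sampled short reads with i.i.d. substitution errors;
and qPCR dilution series following the exponential amplification model

    Cq = intercept - log10(copies) / log10(1 + E)

with Gaussian Cq noise.  Every generator is a pure function of its
parameters and seed, so ground truth is exact and runs are reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import decode, encode, random_codes, revcomp_codes, validate_dna
from .mapping import pg_to_mb
from .reference import AnnotatedUnit, assemble_reference_unit

NATIVE = "native"
FOREIGN_RIBOTYPES = ("panicum", "paspalum", "setaria", "euclasta")

#: Cloned-insert lengths (bp) of the ribotype plasmid standards used for
#: absolute quantification; per-assay defaults for copies-per-ng arithmetic.
DEFAULT_INSERT_LENGTHS = {
    NATIVE: 644,
    "panicum": 538,
    "paspalum": 537,
    "setaria": 539,
    "euclasta": 536,
}

#: Constant placeholder base quality written to simulated FASTQ (Phred 35);
#: the estimators do not use qualities.
PLACEHOLDER_QUALITY = 35


# ---------------------------------------------------------------------------
# ribotype templates


@dataclasses.dataclass(frozen=True)
class RibotypeTemplate:
    """An ITS1-5.8S-ITS2 ribotype sequence plus standards metadata.

    ``insert_length_L`` is the length of the cloned plasmid fragment used
    as the quantification standard for this ribotype; ``its_boundaries``
    (optional) are the ITS1-end / 5.8S-end positions within the sequence.
    """

    label: str
    its_sequence: str
    insert_length_L: int
    its_boundaries: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        validate_dna(self.its_sequence, name=f"{self.label} ITS")
        if self.insert_length_L <= 0:
            raise ValueError("insert_length_L must be positive")


def mutate_ribotype(base: str, divergence: float, seed: int) -> str:
    """Substitute a Bernoulli(divergence) fraction of sites to a different base.

    Deterministic for a fixed seed; the realized substitution fraction is
    binomially distributed around *divergence*.
    """
    validate_dna(base, name="base sequence")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    codes = encode(base).copy()
    mask = rng.random(codes.size) < divergence
    n_mut = int(mask.sum())
    if n_mut:
        codes[mask] = (codes[mask] + rng.integers(1, 4, n_mut).astype(np.uint8)) % 4
    return decode(codes)


def demo_ribotype_panel(
    seed: int = 0,
    *,
    its1_length: int = 220,
    r58_length: int = 160,
    its2_length: int = 220,
    native_foreign_divergence: float = 0.20,
    foreign_foreign_divergence: float = 0.10,
    insert_lengths: Mapping[str, int] = DEFAULT_INSERT_LENGTHS,
) -> dict[str, RibotypeTemplate]:
    """Build a native + four-foreign ribotype panel with known divergence.

    The 5.8S gene is held identical across ribotypes (it is the conserved
    anchor a universal assay targets); ITS1 and ITS2 diverge.  Foreign
    ribotypes descend from a common ancestor so that expected pairwise
    divergence is ~``native_foreign_divergence`` to the native ribotype and
    ~``foreign_foreign_divergence`` among themselves.
    """
    rng = np.random.default_rng(seed)
    native_its = decode(random_codes(its1_length + r58_length + its2_length, 0.5, rng))
    b1, b2 = its1_length, its1_length + r58_length
    r58 = native_its[b1:b2]

    # two-round mutation: solve per-round rates so expected pairwise
    # divergences match the requested values (back-mutation corrected)
    ff = foreign_foreign_divergence
    d2 = (2 - math.sqrt(4 - (16 / 3) * ff)) / (8 / 3)
    d1 = (native_foreign_divergence - d2) / (1 - (4 / 3) * d2)

    def spacers(seq: str) -> tuple[str, str]:
        return seq[:b1], seq[b2:]

    anc1, anc2 = (
        mutate_ribotype(part, d1, int(rng.integers(2**31)))
        for part in spacers(native_its)
    )
    panel = {
        NATIVE: RibotypeTemplate(NATIVE, native_its, insert_lengths[NATIVE], (b1, b2))
    }
    for label in FOREIGN_RIBOTYPES:
        f1 = mutate_ribotype(anc1, d2, int(rng.integers(2**31)))
        f2 = mutate_ribotype(anc2, d2, int(rng.integers(2**31)))
        panel[label] = RibotypeTemplate(label, f1 + r58 + f2, insert_lengths[label], (b1, b2))
    return panel


# ---------------------------------------------------------------------------
# genomes


@dataclasses.dataclass(frozen=True)
class GenomeSpec:
    """Ground-truth specification of a simulated diploid genome.

    Copy numbers are per 2C; ``unit_components`` gives the lengths of the
    universal 18S and 26S genes flanking each ribotype's ITS.
    """

    two_c_size_pg: float
    native_copy_number: int
    foreign_copy_numbers: Mapping[str, int] = dataclasses.field(default_factory=dict)
    unit_components: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"18S": 1800, "26S": 3400}
    )
    background_gc: float = 0.44
    seed: int = 0

    def __post_init__(self) -> None:
        if self.two_c_size_pg <= 0:
            raise ValueError("two_c_size_pg must be positive")
        if self.native_copy_number < 0 or any(v < 0 for v in self.foreign_copy_numbers.values()):
            raise ValueError("copy numbers must be >= 0")
        if set(self.unit_components) != {"18S", "26S"}:
            raise ValueError("unit_components must give lengths for '18S' and '26S'")

    @property
    def two_c_bp(self) -> int:
        return int(round(pg_to_mb(self.two_c_size_pg) * 1e6))


@dataclasses.dataclass
class SimulatedGenome:
    """A realized diploid genome with exact rDNA unit coordinates.

    ``truth`` has one row per realized repeat unit with columns
    (ribotype, contig, start, end), 0-based half-open.
    """

    spec: GenomeSpec
    contigs: dict[str, np.ndarray]
    truth: pd.DataFrame
    genes: dict[str, str]
    templates: dict[str, RibotypeTemplate]

    @property
    def total_length(self) -> int:
        return sum(c.size for c in self.contigs.values())

    def contig_sequences(self) -> dict[str, str]:
        return {name: decode(codes) for name, codes in self.contigs.items()}

    def unit_length(self, ribotype: str = NATIVE) -> int:
        tpl = self.templates[ribotype]
        return self.spec.unit_components["18S"] + len(tpl.its_sequence) + self.spec.unit_components["26S"]

    def native_reference(self) -> AnnotatedUnit:
        """The annotated native repeat unit, as the mapping reference."""
        tpl = self.templates[NATIVE]
        if tpl.its_boundaries is None:
            raise ValueError("native template lacks its_boundaries")
        return assemble_reference_unit(
            self.genes["18S"], tpl.its_sequence, self.genes["26S"], NATIVE,
            its_boundaries=tpl.its_boundaries,
        )

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.contig_sequences().items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def build_synthetic_genome(
    spec: GenomeSpec, templates: Iterable[RibotypeTemplate] | Mapping[str, RibotypeTemplate]
) -> SimulatedGenome:
    """Realize a diploid genome from a spec and a set of ribotype templates.

    The native units form one contiguous tandem array per haplotype; foreign
    units are dispersed insertions of 1-2 units per site outside the native
    array.  Total length equals the 2C size exactly; realized unit counts
    equal the spec exactly.
    """
    if isinstance(templates, Mapping):
        tdict = dict(templates)
    else:
        tdict = {t.label: t for t in templates}
    needed = {NATIVE, *spec.foreign_copy_numbers}
    missing = needed - set(tdict)
    if missing:
        raise ValueError(f"templates missing for ribotypes: {sorted(missing)}")

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    genes = {
        "18S": decode(random_codes(spec.unit_components["18S"], 0.5, rng)),
        "26S": decode(random_codes(spec.unit_components["26S"], 0.5, rng)),
    }
    unit_codes = {
        label: encode(genes["18S"] + tdict[label].its_sequence + genes["26S"])
        for label in sorted(needed)
    }

    two_c = spec.two_c_bp
    hap_lengths = [two_c // 2, two_c - two_c // 2]

    def split(count: int) -> tuple[int, int]:
        return count - count // 2, count // 2

    native_split = split(spec.native_copy_number)
    foreign_split = {r: split(c) for r, c in spec.foreign_copy_numbers.items()}

    contigs: dict[str, np.ndarray] = {}
    truth_rows: list[dict] = []
    for h, hap_len in enumerate(hap_lengths):
        name = f"hap{h + 1}"
        # segments to insert: the native array plus dispersed foreign sites
        segments: list[tuple[str, int]] = []  # (ribotype, n_units)
        if native_split[h]:
            segments.append((NATIVE, native_split[h]))
        for r in sorted(spec.foreign_copy_numbers):
            remaining = foreign_split[r][h]
            while remaining:
                site = int(min(remaining, rng.integers(1, 3)))
                segments.append((r, site))
                remaining -= site
        rdna_bp = sum(unit_codes[r].size * n for r, n in segments)
        bg_len = hap_len - rdna_bp
        if bg_len < 0:
            raise ValueError(
                f"infeasible spec: {rdna_bp} bp of rDNA exceeds haplotype length {hap_len}"
            )
        background = random_codes(bg_len, spec.background_gc, rng)
        if segments:
            points = np.sort(rng.choice(bg_len + 1, size=len(segments), replace=False))
            order = rng.permutation(len(segments))
        else:
            points = np.empty(0, dtype=int)
            order = np.empty(0, dtype=int)
        pieces: list[np.ndarray] = []
        cursor = 0  # position in background coordinates
        offset = 0  # inserted bp so far
        for point, seg_idx in zip(points, order):
            ribotype, n_units = segments[seg_idx]
            u = unit_codes[ribotype].size
            pieces.append(background[cursor:point])
            seg_start = point + offset
            pieces.append(np.tile(unit_codes[ribotype], n_units))
            for j in range(n_units):
                truth_rows.append(
                    {
                        "ribotype": ribotype,
                        "contig": name,
                        "start": seg_start + j * u,
                        "end": seg_start + (j + 1) * u,
                    }
                )
            cursor = point
            offset += n_units * u
        pieces.append(background[cursor:])
        contigs[name] = np.concatenate(pieces) if pieces else background

    truth = pd.DataFrame(truth_rows, columns=["ribotype", "contig", "start", "end"])
    truth = truth.sort_values(["contig", "start"], ignore_index=True)
    return SimulatedGenome(spec=spec, contigs=contigs, truth=truth, genes=genes, templates=tdict)


# ---------------------------------------------------------------------------
# reads


@dataclasses.dataclass
class ReadSet:
    """A set of equal-length simulated (or loaded) short reads.

    Reads are stored as a (n_reads, read_length) uint8 code matrix.  For
    simulated reads, the sampling origin (contig index, start, strand) is
    retained so truth-based checks are possible.
    """

    codes: np.ndarray
    contig_names: list[str] | None = None
    origin_contig: np.ndarray | None = None
    origin_start: np.ndarray | None = None
    origin_strand: np.ndarray | None = None

    def __len__(self) -> int:
        return self.codes.shape[0]

    @property
    def read_length(self) -> int:
        return self.codes.shape[1]

    def sequences(self) -> list[str]:
        return [decode(row) for row in self.codes]

    def subset(self, index: np.ndarray) -> "ReadSet":
        return ReadSet(
            codes=self.codes[index],
            contig_names=self.contig_names,
            origin_contig=None if self.origin_contig is None else self.origin_contig[index],
            origin_start=None if self.origin_start is None else self.origin_start[index],
            origin_strand=None if self.origin_strand is None else self.origin_strand[index],
        )

    def to_fastq(self, path: str | Path) -> None:
        qual = [PLACEHOLDER_QUALITY] * self.read_length
        records = (
            SeqRecord(
                Seq(decode(row)),
                id=f"r{i}",
                description="",
                letter_annotations={"phred_quality": qual},
            )
            for i, row in enumerate(self.codes)
        )
        SeqIO.write(records, str(path), "fastq")

    @classmethod
    def from_fastq(cls, path: str | Path) -> "ReadSet":
        seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]
        if not seqs:
            raise ValueError(f"no reads in {path}")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("ReadSet requires equal-length reads; got lengths " f"{sorted(lengths)}")
        return cls(codes=np.vstack([encode(s) for s in seqs]))


def simulate_reads(
    genome: SimulatedGenome,
    coverage: float,
    read_length: int,
    error_rate: float,
    seed: int,
) -> ReadSet:
    """Uniform single-end reads at *coverage*-fold of the 1C genome size.

    Read count = round(coverage x 1C_bp / read_length); start positions are
    uniform over the genome; strands are random; substitution errors are
    i.i.d. at *error_rate*.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if read_length < 30:
        raise ValueError("read_length must be >= 30")
    names = list(genome.contigs)
    lengths = np.array([genome.contigs[n].size for n in names])
    if read_length > lengths.min():
        raise ValueError("read_length exceeds a contig length")
    one_c_bp = genome.total_length / 2
    n_reads = int(round(coverage * one_c_bp / read_length))

    rng = np.random.default_rng(seed)
    weights = (lengths - read_length + 1).astype(float)
    counts = rng.multinomial(n_reads, weights / weights.sum())

    blocks, contig_idx, starts = [], [], []
    for ci, (name, count) in enumerate(zip(names, counts)):
        if count == 0:
            continue
        s = rng.integers(0, lengths[ci] - read_length + 1, size=count)
        block = genome.contigs[name][s[:, None] + np.arange(read_length)]
        blocks.append(block)
        contig_idx.append(np.full(count, ci))
        starts.append(s)
    codes = np.vstack(blocks) if blocks else np.empty((0, read_length), dtype=np.uint8)
    contig_idx = np.concatenate(contig_idx) if contig_idx else np.empty(0, dtype=int)
    starts = np.concatenate(starts) if starts else np.empty(0, dtype=int)

    strand = rng.random(n_reads) < 0.5
    if strand.any():
        codes[strand] = revcomp_codes(codes[strand])
    if error_rate > 0:
        mask = rng.random(codes.shape) < error_rate
        n_err = int(mask.sum())
        if n_err:
            codes[mask] = (codes[mask] + rng.integers(1, 4, n_err).astype(np.uint8)) % 4

    return ReadSet(
        codes=codes,
        contig_names=names,
        origin_contig=contig_idx,
        origin_start=starts,
        origin_strand=strand,
    )


# ---------------------------------------------------------------------------
# qPCR plates


def _cq_model(copies: np.ndarray | float, efficiency_e: float, cq_intercept: float):
    return cq_intercept - np.log10(copies) / np.log10(1.0 + efficiency_e)


@dataclasses.dataclass
class QpcrPlateSim:
    """A simulated qPCR plate: wells of (true copies, replicate Cq values)."""

    assay: str
    wells: list[tuple[float, tuple[float, ...]]]
    efficiency_e: float
    cq_intercept: float
    noise_sd: float
    seed: int | None = None

    def __post_init__(self) -> None:
        for copies, cqs in self.wells:
            if len(cqs) < 1 or not all(np.isfinite(cqs)):
                raise ValueError("each well needs >= 1 finite Cq replicate")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"assay": self.assay, "well": w, "true_copies": copies, "replicate": r + 1, "cq": cq}
            for w, (copies, cqs) in enumerate(self.wells)
            for r, cq in enumerate(cqs)
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def simulate_dilution_series(
    assay: str,
    *,
    start_copies: float = 1e6,
    dilution_factor: float = 10.0,
    n_points: int = 7,
    efficiency_e: float = 1.0,
    cq_intercept: float = 38.0,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int | None = None,
) -> QpcrPlateSim:
    """Simulate a 10-fold standard dilution series (default 10^6 -> 1 copies)."""
    if start_copies < 1:
        raise ValueError("start_copies must be >= 1")
    if not 0 < efficiency_e <= 1.5:
        raise ValueError("efficiency_e must be in (0, 1.5]")
    rng = np.random.default_rng(seed)
    wells = []
    for i in range(n_points):
        copies = start_copies / dilution_factor**i
        cq0 = _cq_model(copies, efficiency_e, cq_intercept)
        cqs = cq0 + rng.normal(0.0, noise_sd, size=replicates) if noise_sd > 0 else np.full(replicates, cq0)
        wells.append((copies, tuple(float(c) for c in cqs)))
    return QpcrPlateSim(assay, wells, efficiency_e, cq_intercept, noise_sd, seed)


def simulate_sample_cq(
    true_copies: float,
    *,
    efficiency_e: float = 1.0,
    cq_intercept: float = 38.0,
    noise_sd: float = 0.0,
    replicates: int = 2,
    seed: int | None = None,
) -> list[float]:
    """Replicate Cq values for one unknown (default two technical replicates)."""
    if true_copies <= 0:
        raise ValueError("true_copies must be positive")
    if not 0 < efficiency_e <= 1.5:
        raise ValueError("efficiency_e must be in (0, 1.5]")
    rng = np.random.default_rng(seed)
    cq0 = _cq_model(true_copies, efficiency_e, cq_intercept)
    if noise_sd > 0:
        return [float(cq0 + rng.normal(0.0, noise_sd)) for _ in range(replicates)]
    return [float(cq0)] * replicates
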