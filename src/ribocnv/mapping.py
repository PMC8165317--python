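"""Copy-number estimation from whole-genome short reads.

The estimator converts the fraction of reads assigned to a complete rDNA
repeat-unit reference into genome proportion, rDNA genome space and copy
number per 2C:

    P = m / n                      (mapped fraction)
    S = P x 2C                     (genome space, Mb)
    CN = S / U                     (copies per 2C, U = unit length)

Read assignment is a k-mer-seeded ungapped local matcher: a read maps iff
it shares an exact k-mer with the reference (either strand) whose implied
ungapped overlap is at least ``min_match_length`` bases at identity at
least ``min_identity``.  Every read is counted at most once.  The matcher
evaluates seeds at every read offset, so its mapped/unmapped decision
coincides with a brute-force scan over all exact k-mer co-occurrences.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import encode, kmer_codes, kmer_codes_matrix, revcomp_codes
from .reference import AnnotatedUnit

#: 1 pg of DNA corresponds to 978 Mb (dsDNA mean molecular weight).
MB_PER_PG = 978.0


def pg_to_mb(two_c_pg: float) -> float:
    """Convert a 2C DNA amount in picograms to megabases (1 pg = 978 Mb)."""
    if two_c_pg <= 0:
        raise ValueError("two_c_pg must be positive")
    return two_c_pg * MB_PER_PG


def _round_half_up(x: float, ndigits: int = 0) -> float:
    factor = 10.0**ndigits
    return math.floor(x * factor + 0.5) / factor


def round_to_nearest_10(x: float) -> int:
    """Round to the nearest multiple of 10, halves away from zero."""
    return int(math.floor(x / 10.0 + 0.5)) * 10


# ---------------------------------------------------------------------------
# read assignment


@dataclasses.dataclass(frozen=True)
class MappingParams:
    """Matcher settings: seed k-mer length, identity and match-length floors."""

    k: int = 20
    min_identity: float = 0.90
    min_match_length: int = 50

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ValueError("k must be >= 4")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_match_length < self.k:
            raise ValueError("min_match_length must be >= k")


@dataclasses.dataclass
class MappingResult:
    """Read-assignment counts and per-base depth over a reference unit."""

    reference: str
    n_total_reads: int
    m_mapped_reads: int
    per_base_depth: np.ndarray

    def __post_init__(self) -> None:
        if not 0 <= self.m_mapped_reads <= self.n_total_reads:
            raise ValueError("need 0 <= m <= n")


class _UnitIndex:
    """Exact k-mer position index over a reference unit."""

    def __init__(self, unit_codes: np.ndarray, k: int):
        self.codes = np.asarray(unit_codes, dtype=np.uint8)
        self.k = k
        self.length = self.codes.size
        codes = kmer_codes(self.codes, k)
        self.positions: dict[int, list[int]] = {}
        for pos, code in enumerate(codes):
            self.positions.setdefault(int(code), []).append(pos)
        self.sorted_codes = np.sort(codes)


def _evaluate_offset(
    read: np.ndarray, index: _UnitIndex, offset: int, params: MappingParams
) -> tuple[int, int] | None:
    """Check the ungapped overlap implied by aligning read pos i to ref pos i+offset."""
    a = max(0, -offset)
    b = min(read.size, index.length - offset)
    ov = b - a
    if ov < params.min_match_length:
        return None
    mismatches = int(np.count_nonzero(read[a:b] != index.codes[a + offset : b + offset]))
    if 1.0 - mismatches / ov < params.min_identity:
        return None
    return a + offset, b + offset


def _assign_single(
    read: np.ndarray, index: _UnitIndex, params: MappingParams
) -> tuple[int, int] | None:
    """Map one read; returns the matched reference interval or None."""
    for oriented in (read, revcomp_codes(read)):
        codes = kmer_codes(oriented, params.k)
        for i, code in enumerate(codes):
            hits = index.positions.get(int(code))
            if not hits:
                continue
            for p in hits:
                interval = _evaluate_offset(oriented, index, p - i, params)
                if interval is not None:
                    return interval
    return None


def assign_reads(
    reads, unit: AnnotatedUnit, params: MappingParams | None = None
) -> MappingResult:
    """Assign reads to a repeat-unit reference; each read counted at most once.

    *reads* may be a ReadSet (uniform-length code matrix; vectorized seed
    screening) or a sequence of ACGT strings (per-read path).
    """
    params = params or MappingParams()
    index = _UnitIndex(encode(unit.sequence), params.k)
    depth = np.zeros(index.length, dtype=np.int64)

    if hasattr(reads, "codes"):  # ReadSet
        codes = reads.codes
        n = codes.shape[0]
        if n == 0:
            raise ValueError("empty read set")
        if params.k > codes.shape[1]:
            raise ValueError("seed length k exceeds read length")
        fwd = kmer_codes_matrix(codes, params.k)
        rc = kmer_codes_matrix(revcomp_codes(codes), params.k)
        candidate = np.zeros(n, dtype=bool)
        for mat in (fwd, rc):
            idx = np.searchsorted(index.sorted_codes, mat)
            idx[idx == index.sorted_codes.size] = 0
            candidate |= (index.sorted_codes[idx] == mat).any(axis=1)
        m = 0
        for row in np.flatnonzero(candidate):
            interval = _assign_single(codes[row], index, params)
            if interval is not None:
                m += 1
                depth[interval[0] : interval[1]] += 1
        return MappingResult(unit.species, n, m, depth)

    read_list: Sequence[str] = list(reads)
    if not read_list:
        raise ValueError("empty read set")
    m = 0
    for seq in read_list:
        read = encode(seq)
        if params.k > read.size:
            raise ValueError("seed length k exceeds read length")
        interval = _assign_single(read, index, params)
        if interval is not None:
            m += 1
            depth[interval[0] : interval[1]] += 1
    return MappingResult(unit.species, len(read_list), m, depth)


# ---------------------------------------------------------------------------
# subsampling and the count -> copy-number chain


def subsample_to_coverage(
    reads,
    two_c_pg: float,
    read_length: int | None = None,
    target_coverage: float = 1.0,
    seed: int | None = None,
):
    """Subsample reads to ~``target_coverage`` x of the 1C genome size.

    Requests round(coverage x 1C_bp / read_length) reads drawn uniformly
    without replacement; clamps to the available reads with a warning.
    """
    if target_coverage <= 0:
        raise ValueError("target_coverage must be positive")
    n_available = len(reads)
    if n_available == 0:
        raise ValueError("empty read set")
    if read_length is None:
        if hasattr(reads, "read_length"):
            read_length = reads.read_length
        else:
            raise ValueError("read_length required for non-ReadSet input")
    one_c_bp = pg_to_mb(two_c_pg) / 2.0 * 1e6
    n_target = int(round(target_coverage * one_c_bp / read_length))
    if n_target >= n_available:
        if n_target > n_available:
            warnings.warn(
                f"requested {n_target} reads but only {n_available} available; using all",
                stacklevel=2,
            )
        return reads
    rng = np.random.default_rng(seed)
    index = np.sort(rng.choice(n_available, size=n_target, replace=False))
    if hasattr(reads, "subset"):
        return reads.subset(index)
    return [reads[i] for i in index]


def genome_proportion(m_mapped: int, n_total: int) -> float:
    """Mapped-read fraction as a percentage (unrounded; report at 2 d.p.)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= m_mapped <= n_total:
        raise ValueError("need 0 <= m <= n")
    return 100.0 * m_mapped / n_total


def genome_space(mapped_fraction: float, two_c_mb: float) -> float:
    """rDNA genome space in Mb: mapped fraction x 2C size (Mb)."""
    if mapped_fraction < 0 or two_c_mb <= 0:
        raise ValueError("inputs must be non-negative / positive")
    return mapped_fraction * two_c_mb


def copy_number_from_mapping(genome_space_kb: float, unit_length_bp: int) -> int:
    """Copies per 2C = genome space (Kb) x 1000 / U, rounded to nearest 10."""
    if unit_length_bp <= 0:
        raise ValueError("unit length must be positive")
    return round_to_nearest_10(genome_space_kb * 1000.0 / unit_length_bp)


@dataclasses.dataclass
class CnEstimate:
    """Genome proportion, genome space and rounded copy number per 2C.

    Unrounded values are carried; table-style rounding (proportion 2 d.p.,
    space 3 d.p. Mb / integer Kb, CN to nearest 10) applies at reporting.
    """

    genome_proportion_pct: float
    genome_space_mb: float
    genome_space_kb: int
    copy_number: int

    @property
    def proportion_pct_2dp(self) -> float:
        return _round_half_up(self.genome_proportion_pct, 2)

    @property
    def space_mb_3dp(self) -> float:
        return _round_half_up(self.genome_space_mb, 3)


def estimate_copy_number(
    m_mapped: int, n_total: int, two_c_mb: float, unit_length_bp: int
) -> CnEstimate:
    """Full count -> proportion -> space -> copy-number chain."""
    pct = genome_proportion(m_mapped, n_total)
    space_mb = genome_space(pct / 100.0, two_c_mb)
    space_kb = int(_round_half_up(space_mb * 1000.0))
    cn = copy_number_from_mapping(space_kb, unit_length_bp)
    return CnEstimate(pct, space_mb, space_kb, cn)


# ---------------------------------------------------------------------------
# coverage diagnostics


def coverage_profile(
    result: MappingResult, unit: AnnotatedUnit, bias_factor: float = 1.5
) -> tuple[pd.DataFrame, bool]:
    """Mean depth per unit component plus a coverage-bias flag.

    The flag is raised when any component's mean depth deviates from the
    unit-wide mean by more than ``bias_factor`` (ratio above it or below
    its reciprocal).  With zero mapped reads the flag is suppressed.
    """
    depth = result.per_base_depth
    rows = []
    for name, (start, end) in unit.components.items():
        rows.append({"component": name, "mean_depth": float(depth[start:end].mean())})
    profile = pd.DataFrame(rows)
    unit_mean = float(depth.mean())
    if result.m_mapped_reads == 0 or unit_mean == 0:
        if result.m_mapped_reads == 0:
            warnings.warn("zero mapped reads; coverage bias flag suppressed", stacklevel=2)
        return profile, False
    ratio = profile["mean_depth"] / unit_mean
    flag = bool(((ratio > bias_factor) | (ratio < 1.0 / bias_factor)).any())
    return profile, flag


# ---------------------------------------------------------------------------
# model interface


class ReadMappingModel:
    """Read-mapping copy-number estimator for one sample.

    Parameters
    ----------
    reads : ReadSet or sequence of str
        Input reads (already simulated or loaded from FASTQ).
    unit : AnnotatedUnit
        Complete rDNA repeat-unit reference.
    two_c_pg : float
        Sample 2C genome size in picograms.
    params : MappingParams, optional
        Matcher settings.

    ``fit`` optionally subsamples to a target 1C coverage, assigns reads,
    and returns :class:`ReadMappingResults`.
    """

    def __init__(self, reads, unit: AnnotatedUnit, two_c_pg: float, params: MappingParams | None = None):
        self.reads = reads
        self.unit = unit
        self.two_c_pg = two_c_pg
        self.two_c_mb = pg_to_mb(two_c_pg)
        self.params = params or MappingParams()

    def fit(self, target_coverage: float | None = None, seed: int | None = None) -> "ReadMappingResults":
        reads = self.reads
        if target_coverage is not None:
            reads = subsample_to_coverage(reads, self.two_c_pg, target_coverage=target_coverage, seed=seed)
        mapping = assign_reads(reads, self.unit, self.params)
        estimate = estimate_copy_number(
            mapping.m_mapped_reads, mapping.n_total_reads, self.two_c_mb, self.unit.unit_length
        )
        return ReadMappingResults(self, mapping, estimate)


@dataclasses.dataclass
class ReadMappingResults:
    """Results of a read-mapping copy-number fit."""

    model: ReadMappingModel
    mapping: MappingResult
    estimate: CnEstimate

    @property
    def copy_number(self) -> int:
        return self.estimate.copy_number

    def coverage_profile(self, bias_factor: float = 1.5) -> tuple[pd.DataFrame, bool]:
        return coverage_profile(self.mapping, self.model.unit, bias_factor)

    def to_row(self, sample: str) -> dict:
        """One survey-table row (sample, sizes, counts, proportion, space, CN)."""
        est = self.estimate
        return {
            "sample": sample,
            "genome_size_mb": self.model.two_c_mb,
            "n_reads": self.mapping.n_total_reads,
            "m_mapped": self.mapping.m_mapped_reads,
            "proportion_pct": est.proportion_pct_2dp,
            "genome_space_mb": est.space_mb_3dp,
            "genome_space_kb": est.genome_space_kb,
            "copy_number": est.copy_number,
        }

    def summary(self) -> str:
        est = self.estimate
        lines = [
            "Read-mapping copy-number estimate",
            "=" * 40,
            f"reference unit:      {self.model.unit.species} ({self.model.unit.unit_length} bp)",
            f"2C genome size:      {self.model.two_c_mb:.2f} Mb",
            f"reads mapped:        {self.mapping.m_mapped_reads} / {self.mapping.n_total_reads}",
            f"genome proportion:   {est.proportion_pct_2dp:.2f} %",
            f"genome space:        {est.space_mb_3dp:.3f} Mb ({est.genome_space_kb} Kb)",
            f"copy number per 2C:  {est.copy_number} (rounded to nearest 10)",
        ]
        return "\n".join(lines)
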