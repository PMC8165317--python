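"""Packaged survey datasets used as worked examples.

Two published tables from a survey of nrDNA copy number in diploid barley
(*Hordeum*) species ship with the package as plain TSV:

* ``hordeum_qpcr_cohort`` — per-taxon qPCR estimates: clade/subclade and
  geography metadata, 2C genome size (pg), FISH locus-pair counts, and
  mean (s.d.) copies per 2C of the native ribotype and of four foreign
  (panicoid-derived) ribotypes.  "n.d." marks a ribotype not detected —
  a missing observation, never a zero.
* ``hordeum_read_mapping`` — per-sample read-mapping estimates: 2C size
  (Mb), subsampled read counts, reads mapped to the complete repeat-unit
  reference, genome proportion/space and rounded copy number.

These are the inputs the worked examples and the acceptance computations
re-run; they are data, not test expectations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_NA = ["n.d.", ""]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath("data", name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", na_values=_NA, keep_default_na=False, comment="#")


def load_qpcr_cohort() -> pd.DataFrame:
    """The qPCR cohort table (one row per taxon; copy numbers per 2C)."""
    return _read("hordeum_qpcr_cohort.tsv")


def load_read_mapping_survey() -> pd.DataFrame:
    """The read-mapping survey table (one row per sequenced sample)."""
    return _read("hordeum_read_mapping.tsv")
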