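"""Assembly and annotation of complete rDNA repeat-unit references.

The mapping track counts reads against one complete transcription unit
(18S-ITS1-5.8S-ITS2-26S).  Using the whole unit rather than the ITS alone
avoids the coverage bias between genes and spacers.  A reference is built
by flanking a species-specific ITS region with universal 18S and 26S genes;
component boundaries are supplied explicitly by the user.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import validate_dna

COMPONENT_ORDER = ("18S", "ITS1", "5.8S", "ITS2", "26S")

#: Default component lengths (bp).  These reproduce the ~5.8 kb unit length
#: implied by dividing rDNA genome space by rounded copy number in the
#: Hordeum read-mapping survey; override per species where known.
DEFAULT_COMPONENT_LENGTHS = {"18S": 1800, "ITS1": 220, "5.8S": 160, "ITS2": 220, "26S": 3400}


@dataclasses.dataclass(frozen=True)
class AnnotatedUnit:
    """A complete rDNA repeat unit with component annotation.

    Parameters
    ----------
    species : str
        Label of the species (or synthetic ribotype) the ITS came from.
    sequence : str
        Full unit sequence, 18S + ITS1 + 5.8S + ITS2 + 26S.
    components : dict[str, tuple[int, int]]
        0-based half-open (start, end) per component, in COMPONENT_ORDER,
        tiling [0, U) exactly.
    """

    species: str
    sequence: str
    components: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        validate_dna(self.sequence, name="unit sequence")
        if tuple(self.components) != COMPONENT_ORDER:
            raise ValueError(f"components must be exactly {COMPONENT_ORDER} in order")
        cursor = 0
        for name, (start, end) in self.components.items():
            if start != cursor or end <= start:
                raise ValueError(
                    f"component {name} interval ({start}, {end}) breaks the tiling of [0, U)"
                )
            cursor = end
        if cursor != len(self.sequence):
            raise ValueError("component intervals do not tile the full sequence")

    @property
    def unit_length(self) -> int:
        """Unit length U in bp (equals the sequence length)."""
        return len(self.sequence)

    def component_sequence(self, name: str) -> str:
        start, end = self.components[name]
        return self.sequence[start:end]


def assemble_reference_unit(
    gene_18s: str,
    its_region: str,
    gene_26s: str,
    species: str,
    *,
    its_boundaries: tuple[int, int],
) -> AnnotatedUnit:
    """Concatenate 18S + ITS + 26S into an annotated repeat unit.

    ``its_boundaries = (b1, b2)`` are 0-based positions within *its_region*
    where ITS1 ends and the 5.8S gene ends, i.e. ITS1 = its[:b1],
    5.8S = its[b1:b2], ITS2 = its[b2:].
    """
    validate_dna(gene_18s, name="18S gene")
    validate_dna(its_region, name="ITS region")
    validate_dna(gene_26s, name="26S gene")
    b1, b2 = its_boundaries
    if not (0 < b1 < b2 < len(its_region)):
        raise ValueError(
            f"ITS boundaries {its_boundaries} invalid for ITS region of length {len(its_region)}"
        )
    g18, its, g26 = len(gene_18s), len(its_region), len(gene_26s)
    components = {
        "18S": (0, g18),
        "ITS1": (g18, g18 + b1),
        "5.8S": (g18 + b1, g18 + b2),
        "ITS2": (g18 + b2, g18 + its),
        "26S": (g18 + its, g18 + its + g26),
    }
    return AnnotatedUnit(species=species, sequence=gene_18s + its_region + gene_26s, components=components)


def unit_length(unit: AnnotatedUnit) -> int:
    """Total unit length U in bp."""
    return unit.unit_length


def write_unit(unit: AnnotatedUnit, fasta_path: str | Path, annotation_path: str | Path) -> None:
    """Write a unit to FASTA plus a component-annotation TSV."""
    record = SeqRecord(Seq(unit.sequence), id=unit.species, description="complete rDNA repeat unit")
    SeqIO.write([record], str(fasta_path), "fasta")
    rows = [
        {"component": name, "start": start, "end": end}
        for name, (start, end) in unit.components.items()
    ]
    pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)


def read_unit(fasta_path: str | Path, annotation_path: str | Path) -> AnnotatedUnit:
    """Read a unit back from FASTA + annotation TSV (inverse of write_unit)."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record in {fasta_path}")
    annot = pd.read_csv(annotation_path, sep="\t", comment="#")
    components = {
        str(row.component): (int(row.start), int(row.end)) for row in annot.itertuples()
    }
    ordered = {name: components[name] for name in COMPONENT_ORDER}
    return AnnotatedUnit(species=records[0].id, sequence=str(records[0].seq).upper(), components=ordered)
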