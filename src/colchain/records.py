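"""Containers for collagen (I) α-chain sequences and the concatenated alignment.

Collagen type I is built from up to three distinct α-chains.  In this package
their helical domains have the fixed aligned lengths

    α1: 1058   α2: 1041   α3: 1062

so a fully concatenated alignment is exactly 3161 columns wide, with the
chains laid out in the order α1, α2, α3.  A taxon whose genome lacks the α3
chain (common outside teleosts and in a few teleost lineages) is padded with
gap characters across the α3 partition.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Characters allowed in a chain sequence: amino acids, gap, unknown.
ALPHABET = frozenset(AMINO_ACIDS) | {"-", "X"}

#: Fixed helical-domain lengths per chain (aligned columns).
CHAIN_LENGTHS: dict[str, int] = {"alpha1": 1058, "alpha2": 1041, "alpha3": 1062}

#: Chain layout order in the concatenated alignment.
CHAIN_ORDER: tuple[str, ...] = ("alpha1", "alpha2", "alpha3")

#: Total concatenated width: 1058 + 1041 + 1062.
TOTAL_COLUMNS = sum(CHAIN_LENGTHS.values())


class Region(str, enum.Enum):
    """Which part of the molecule a sequence covers."""

    HELICAL = "helical"
    PROCOLLAGEN = "procollagen"


class ValidationError(ValueError):
    """A record or alignment violates a structural invariant."""


class ConflictError(ValueError):
    """Two records claim the same (taxon, chain, isoform) slot."""


class DimensionError(ValueError):
    """A sequence or matrix has the wrong length/shape."""


@dataclass
class ChainRecord:
    """One α-chain sequence for one taxon.

    Parameters
    ----------
    taxon
        Species identifier.
    chain
        One of ``alpha1``, ``alpha2``, ``alpha3`` or ``unknown``.
    sequence
        Amino-acid string over the 20-letter alphabet plus ``-`` and ``X``.
    isoform
        Optional isoform tag (tetraploid fishes carry diverged A/B gene
        copies of each chain).
    region
        ``helical`` (triple-helical domain only) or ``procollagen`` (full
        precursor including signal peptide, propeptides and telopeptides).
    source_id
        Free-text provenance / accession string.
    relaxed_length
        When False (default), a helical record of a known chain must have
        the canonical ungapped length for that chain.  Set True for chain
        fragments fed to the classifier (e.g. single tryptic peptides).
    """

    taxon: str
    chain: str
    sequence: str
    isoform: str | None = None
    region: Region = Region.HELICAL
    source_id: str = ""
    relaxed_length: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.region, str):
            self.region = Region(self.region)
        if self.chain not in {"alpha1", "alpha2", "alpha3", "unknown"}:
            raise ValidationError(f"unknown chain label {self.chain!r}")
        if not self.sequence:
            raise ValidationError(f"empty sequence for taxon {self.taxon!r}")
        for i, ch in enumerate(self.sequence):
            if ch not in ALPHABET:
                raise ValidationError(
                    f"illegal character {ch!r} at position {i + 1} in record "
                    f"{self.taxon!r} ({self.chain})"
                )
        if (
            not self.relaxed_length
            and self.region is Region.HELICAL
            and self.chain in CHAIN_LENGTHS
        ):
            expected = CHAIN_LENGTHS[self.chain]
            if self.ungapped_length != expected:
                raise DimensionError(
                    f"{self.chain} helical record for {self.taxon!r} has "
                    f"ungapped length {self.ungapped_length}, expected {expected} "
                    "(pass relaxed_length=True for fragments)"
                )

    @property
    def ungapped_length(self) -> int:
        return len(self.sequence) - self.sequence.count("-")

    @property
    def ungapped(self) -> str:
        """Sequence with gap characters removed."""
        return self.sequence.replace("-", "")


@dataclass
class ConcatenatedAlignment:
    """Taxa × 3161 concatenated collagen (I) alignment.

    ``partitions`` maps each chain to its 1-based closed column interval;
    the partitions tile ``[1, 3161]`` in the order α1, α2, α3.
    """

    taxa: list[str]
    matrix: list[str]
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValidationError("alignment has no taxa")
        if len(self.taxa) != len(set(self.taxa)):
            raise ValidationError("duplicate taxon labels in alignment")
        if len(self.matrix) != len(self.taxa):
            raise DimensionError("row count does not match taxon count")
        if not self.partitions:
            self.partitions = default_partitions()
        width = max(hi for _, hi in self.partitions.values())
        self._check_partitions(width)
        for taxon, row in zip(self.taxa, self.matrix):
            if len(row) != width:
                raise DimensionError(
                    f"row for {taxon!r} has {len(row)} columns, expected {width}"
                )
            bad = set(row) - ALPHABET
            if bad:
                raise ValidationError(f"illegal characters {bad!r} in row {taxon!r}")

    def _check_partitions(self, width: int) -> None:
        expected_start = 1
        for chain in CHAIN_ORDER:
            if chain not in self.partitions:
                raise ValidationError(f"missing partition for {chain}")
            lo, hi = self.partitions[chain]
            if lo != expected_start or hi < lo:
                raise ValidationError(
                    f"partition {chain} = ({lo}, {hi}) does not tile the alignment"
                )
            expected_start = hi + 1
        if expected_start - 1 != width:
            raise ValidationError(
                f"partitions cover {expected_start - 1} columns, matrix has {width}"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.matrix[0])

    def partition_slice(self, chain: str) -> slice:
        """0-based python slice for one chain's columns."""
        lo, hi = self.partitions[chain]
        return slice(lo - 1, hi)

    def chain_block(self, chain: str) -> list[str]:
        """Rows restricted to one chain's partition."""
        sl = self.partition_slice(chain)
        return [row[sl] for row in self.matrix]

    def row(self, taxon: str) -> str:
        return self.matrix[self.taxa.index(taxon)]


def default_partitions() -> dict[str, tuple[int, int]]:
    """The canonical α1/α2/α3 column intervals (1-based, closed)."""
    parts: dict[str, tuple[int, int]] = {}
    start = 1
    for chain in CHAIN_ORDER:
        end = start + CHAIN_LENGTHS[chain] - 1
        parts[chain] = (start, end)
        start = end + 1
    return parts
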