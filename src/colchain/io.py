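"""Reading, concatenating and writing collagen α-chain sequence data.

FASTA headers follow a pipe-delimited grammar::

    >taxon|chain|isoform|region|source_id

Only ``taxon`` is mandatory; missing fields fall back to per-call defaults.
``chain`` is one of ``alpha1/alpha2/alpha3/unknown`` (``a1/a2/a3`` accepted),
``region`` is ``helical`` or ``procollagen``.  Alignments are written as
FASTA, NEXUS (with a ``charset`` block carrying the partition map) or relaxed
PHYLIP; FASTA and PHYLIP carry the partition map in a TSV sidecar
(``<path>.partitions.tsv``). All partition coordinates are 1-based closed
intervals.
"""

from __future__ import annotations

import logging
import os
from collections import defaultdict
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    CHAIN_LENGTHS,
    CHAIN_ORDER,
    ChainRecord,
    ConcatenatedAlignment,
    ConflictError,
    DimensionError,
    Region,
    ValidationError,
    default_partitions,
)

logger = logging.getLogger(__name__)

_CHAIN_ALIASES = {
    "alpha1": "alpha1", "a1": "alpha1", "col1a1": "alpha1", "col1a1a": "alpha1",
    "alpha2": "alpha2", "a2": "alpha2", "col1a2": "alpha2",
    "alpha3": "alpha3", "a3": "alpha3", "col1a1b": "alpha3",
    "unknown": "unknown",
}


class FastaParseError(ValueError):
    """Malformed FASTA input."""


def _parse_header(header: str, defaults: dict) -> dict:
    fields = [f.strip() for f in header.split("|")]
    out = dict(defaults)
    out["taxon"] = fields[0]
    if len(fields) > 1 and fields[1]:
        key = fields[1].lower()
        if key not in _CHAIN_ALIASES:
            raise FastaParseError(f"unrecognised chain token {fields[1]!r} in header {header!r}")
        out["chain"] = _CHAIN_ALIASES[key]
    if len(fields) > 2 and fields[2]:
        out["isoform"] = fields[2]
    if len(fields) > 3 and fields[3]:
        out["region"] = Region(fields[3].lower())
    if len(fields) > 4 and fields[4]:
        out["source_id"] = fields[4]
    return out


def read_chain_fasta(
    path: str | os.PathLike,
    chain: str = "unknown",
    region: str | Region = Region.HELICAL,
    isoform: str | None = None,
    relaxed_length: bool = False,
) -> list[ChainRecord]:
    """Read α-chain records from a FASTA file.

    ``chain``/``region``/``isoform`` supply defaults for header fields the
    file does not encode.  Raises :class:`FastaParseError` on malformed FASTA
    and :class:`~colchain.records.ValidationError` on illegal characters
    (the error names the offending record and position).
    """
    path = Path(path)
    defaults = {
        "chain": chain,
        "region": Region(region),
        "isoform": isoform,
        "source_id": "",
    }
    records: list[ChainRecord] = []
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise FastaParseError(f"{path}: line 1 does not start with '>'")
    for entry in SeqIO.parse(str(path), "fasta"):
        meta = _parse_header(entry.description, defaults)
        records.append(
            ChainRecord(
                taxon=meta["taxon"],
                chain=meta["chain"],
                sequence=str(entry.seq).upper(),
                isoform=meta["isoform"],
                region=meta["region"],
                source_id=meta["source_id"],
                relaxed_length=relaxed_length,
            )
        )
    if not records:
        raise FastaParseError(f"{path}: no FASTA entries found")
    return records


def select_isoforms(
    records: list[ChainRecord],
    policy: str = "A",
    overrides: dict[str, str] | None = None,
) -> list[ChainRecord]:
    """Pick one isoform per (taxon, chain).

    Tetraploid fishes carry two diverged gene copies (isoforms A/B) of each
    chain; only one can enter the alignment.  ``policy`` is the default tag
    to prefer, ``overrides`` maps taxon -> preferred tag.  Records without an
    isoform tag always pass through.
    """
    overrides = overrides or {}
    grouped: dict[tuple[str, str], list[ChainRecord]] = defaultdict(list)
    for rec in records:
        grouped[(rec.taxon, rec.chain)].append(rec)
    chosen: list[ChainRecord] = []
    for (taxon, _), group in grouped.items():
        if len(group) == 1:
            chosen.append(group[0])
            continue
        want = overrides.get(taxon, policy)
        matches = [r for r in group if (r.isoform or "") == want]
        pick = matches[0] if matches else sorted(group, key=lambda r: r.isoform or "")[0]
        if not matches:
            logger.warning(
                "taxon %s has no isoform %r for chain %s; using %r",
                taxon, want, pick.chain, pick.isoform,
            )
        chosen.append(pick)
    return chosen


def concatenate_chains(
    records: list[ChainRecord],
    taxa: list[str] | None = None,
    lengths: dict[str, int] | None = None,
) -> ConcatenatedAlignment:
    """Concatenate per-chain records into the 3161-column alignment.

    Column layout is α1 (1–1058), α2 (1059–2099), α3 (2100–3161).  A taxon
    missing its α3 chain is dash-filled across the α3 partition (absence is
    treated as biological).  Taxa missing α1 or α2 are excluded with a
    warning — both chains are required for inclusion.  Records must already
    be reduced to one per (taxon, chain); see :func:`select_isoforms`.

    ``lengths`` overrides the canonical partition widths (used for scaled
    simulated datasets); the canonical 1058/1041/1062 layout is the default.
    """
    widths = dict(CHAIN_LENGTHS) if lengths is None else dict(lengths)
    by_taxon: dict[str, dict[str, ChainRecord]] = defaultdict(dict)
    for rec in records:
        if rec.region is not Region.HELICAL:
            raise ValidationError(
                f"record {rec.taxon!r}/{rec.chain} is not a helical-domain sequence"
            )
        if rec.chain not in widths:
            raise ValidationError(
                f"record {rec.taxon!r} has unclassified chain; classify before concatenating"
            )
        if rec.chain in by_taxon[rec.taxon]:
            raise ConflictError(
                f"duplicate record for ({rec.taxon!r}, {rec.chain}); "
                "select one isoform per chain first"
            )
        if len(rec.sequence) != widths[rec.chain]:
            raise DimensionError(
                f"{rec.chain} record for {rec.taxon!r} has {len(rec.sequence)} "
                f"columns, partition width is {widths[rec.chain]}"
            )
        by_taxon[rec.taxon][rec.chain] = rec

    if taxa is None:
        taxa = sorted(by_taxon)
    included: list[str] = []
    rows: list[str] = []
    for taxon in taxa:
        chains = by_taxon.get(taxon, {})
        if "alpha1" not in chains or "alpha2" not in chains:
            logger.warning(
                "excluding taxon %s: α1 and α2 chains are both required "
                "(have: %s)", taxon, sorted(chains) or "none",
            )
            continue
        parts = []
        for chain in CHAIN_ORDER:
            if chain in chains:
                parts.append(chains[chain].sequence)
            else:
                parts.append("-" * widths[chain])
        included.append(taxon)
        rows.append("".join(parts))
    if not included:
        raise ValidationError("no taxon satisfies the α1+α2 inclusion rule")
    parts_map: dict[str, tuple[int, int]] = {}
    start = 1
    for chain in CHAIN_ORDER:
        parts_map[chain] = (start, start + widths[chain] - 1)
        start += widths[chain]
    return ConcatenatedAlignment(taxa=included, matrix=rows, partitions=parts_map)


# ---------------------------------------------------------------------------
# alignment writers / readers

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".partitions.tsv")


def _write_partition_sidecar(aln: ConcatenatedAlignment, path: Path) -> None:
    with open(_sidecar_path(path), "w") as fh:
        fh.write("chain\tstart\tend\n")
        for chain in CHAIN_ORDER:
            lo, hi = aln.partitions[chain]
            fh.write(f"{chain}\t{lo}\t{hi}\n")


def _read_partition_sidecar(path: Path) -> dict[str, tuple[int, int]] | None:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        return None
    parts: dict[str, tuple[int, int]] = {}
    with open(sidecar) as fh:
        next(fh)
        for line in fh:
            chain, lo, hi = line.split()
            parts[chain] = (int(lo), int(hi))
    return parts


def write_alignment(
    aln: ConcatenatedAlignment, path: str | os.PathLike, format: str = "fasta"
) -> None:
    """Write the alignment as ``fasta``, ``nexus`` or ``phylip`` (relaxed).

    NEXUS output embeds the partition map as a ``charset`` block; the other
    formats get a ``<path>.partitions.tsv`` sidecar.
    """
    path = Path(path)
    if format == "fasta":
        recs = [
            SeqRecord(Seq(row), id=taxon, description="")
            for taxon, row in zip(aln.taxa, aln.matrix)
        ]
        SeqIO.write(recs, str(path), "fasta")
        _write_partition_sidecar(aln, path)
    elif format == "phylip":
        with open(path, "w") as fh:
            fh.write(f" {aln.n_taxa} {aln.n_columns}\n")
            for taxon, row in zip(aln.taxa, aln.matrix):
                fh.write(f"{taxon}  {row}\n")
        _write_partition_sidecar(aln, path)
    elif format == "nexus":
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nbegin data;\n")
            fh.write(f"  dimensions ntax={aln.n_taxa} nchar={aln.n_columns};\n")
            fh.write("  format datatype=protein missing=X gap=-;\n  matrix\n")
            for taxon, row in zip(aln.taxa, aln.matrix):
                fh.write(f"    {taxon}  {row}\n")
            fh.write("  ;\nend;\n\nbegin sets;\n")
            for chain in CHAIN_ORDER:
                lo, hi = aln.partitions[chain]
                fh.write(f"  charset {chain} = {lo}-{hi};\n")
            fh.write("end;\n")
    else:
        raise ValueError(f"unsupported alignment format {format!r}")


def read_alignment(path: str | os.PathLike, format: str = "fasta") -> ConcatenatedAlignment:
    """Read an alignment written by :func:`write_alignment`."""
    path = Path(path)
    taxa: list[str] = []
    rows: list[str] = []
    partitions: dict[str, tuple[int, int]] | None = None
    if format == "fasta":
        for entry in SeqIO.parse(str(path), "fasta"):
            taxa.append(entry.id)
            rows.append(str(entry.seq).upper())
        partitions = _read_partition_sidecar(path)
    elif format == "phylip":
        with open(path) as fh:
            header = fh.readline().split()
            ntax = int(header[0])
            for line in fh:
                if not line.strip():
                    continue
                name, seq = line.split(None, 1)
                taxa.append(name)
                rows.append(seq.strip().upper())
        if len(taxa) != ntax:
            raise FastaParseError(f"{path}: header claims {ntax} taxa, found {len(taxa)}")
        partitions = _read_partition_sidecar(path)
    elif format == "nexus":
        partitions = {}
        in_matrix = False
        with open(path) as fh:
            for line in fh:
                stripped = line.strip()
                low = stripped.lower()
                if low == "matrix":
                    in_matrix = True
                    continue
                if in_matrix:
                    if stripped == ";":
                        in_matrix = False
                        continue
                    if stripped:
                        name, seq = stripped.split(None, 1)
                        taxa.append(name)
                        rows.append(seq.upper())
                elif low.startswith("charset"):
                    body = stripped.rstrip(";")
                    _, rest = body.split(None, 1)
                    name, interval = rest.split("=")
                    lo, hi = interval.strip().split("-")
                    partitions[name.strip()] = (int(lo), int(hi))
    else:
        raise ValueError(f"unsupported alignment format {format!r}")
    return ConcatenatedAlignment(
        taxa=taxa, matrix=rows, partitions=partitions or default_partitions()
    )
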