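"""α1-vs-α3 chain discrimination and in-silico tryptic digestion.

Two lines of evidence separate 'true' α1 (I) chains from the frequently
mislabelled α3 (I) chains:

1. **T32/33 rule** — the 17-residue region at helical positions 334–350.
   In α1 chains its ninth residue is lysine (K), so trypsin splits the
   region into two peptides; in α3 chains the lysine is replaced by
   glutamine (Q) and the region survives digestion as a single peptide.
2. **Position-1264 rule** — in full procollagen sequences the residue at
   position 1264 is cysteine (C) in α1 and serine (S) in α3.

Both rules are applied where the input allows; disagreement is reported as
a conflict rather than silently resolved, and residues outside {K, Q} or
{C, S} yield an *indeterminate* call (unseen taxa may violate the rules).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from . import references as refs
from .records import AMINO_ACIDS, ChainRecord, DimensionError, Region, ValidationError


class NoHomologyError(ValueError):
    """Query could not be aligned to the reference above the score floor."""


class RegionAbsentError(ValueError):
    """Query does not span the diagnostic region."""


@dataclass
class TrypticPeptide:
    """One tryptic fragment, with 1-based inclusive parent coordinates."""

    sequence: str
    start: int
    end: int


@dataclass
class DiscriminatorResult:
    """Outcome of the α1/α3 discriminators for one record."""

    taxon: str
    call: str = "indeterminate"  # alpha1 | alpha3 | indeterminate | conflict
    t33_residue: str | None = None
    pos1264_residue: str | None = None
    window: str | None = None
    evidence_notes: list[str] = field(default_factory=list)


def tryptic_digest(
    sequence: str, suppress_before_proline: bool = True
) -> list[TrypticPeptide]:
    """Cut a sequence where trypsin would: C-terminal to every K or R.

    With ``suppress_before_proline`` (default, standard trypsin
    specificity) a K/R immediately followed by proline does not cleave.
    The peptides tile the input exactly.
    """
    if not sequence:
        raise ValidationError("cannot digest an empty sequence")
    if "-" in sequence:
        raise ValidationError("cannot digest a gapped sequence; ungap first")
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValidationError(f"non-standard residues in digest input: {sorted(bad)}")
    peptides: list[TrypticPeptide] = []
    start = 0
    for i, ch in enumerate(sequence):
        if ch in "KR" and i + 1 < len(sequence):
            if suppress_before_proline and sequence[i + 1] == "P":
                continue
            peptides.append(TrypticPeptide(sequence[start : i + 1], start + 1, i + 1))
            start = i + 1
    if start < len(sequence):
        peptides.append(TrypticPeptide(sequence[start:], start + 1, len(sequence)))
    return peptides


def _make_aligner() -> Align.PairwiseAligner:
    # overlap-style global alignment: free end gaps so helical-domain
    # queries embed into procollagen references and vice versa
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()

#: Minimum alignment score per aligned reference column for homology.
SCORE_FLOOR_PER_COLUMN = 1.0


def _map_reference_positions(reference: str, query: str) -> dict[int, int | None]:
    """Align query to reference; map 0-based ref index -> query index (or None).

    Raises :class:`NoHomologyError` when the best alignment scores below the
    floor (untunable garbage input).
    """
    alignment = _ALIGNER.align(reference, query.replace("-", ""))[0]
    if alignment.score < SCORE_FLOOR_PER_COLUMN * min(len(reference), len(query)):
        raise NoHomologyError(
            f"alignment score {alignment.score:.1f} below homology floor"
        )
    mapping: dict[int, int | None] = {i: None for i in range(len(reference))}
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for offset in range(t1 - t0):
            mapping[int(t0) + offset] = int(q0) + offset
    return mapping


def locate_t33_window(record: ChainRecord) -> tuple[str, tuple[int, int], bool]:
    """Extract the query residues homologous to α1 helical positions 334–350.

    Aligns the (ungapped) query to the bundled synthetic α1 helical
    reference and transfers the window coordinates.  Returns
    ``(window, (query_start, query_end), is_short)`` with 1-based query
    coordinates; ``is_short`` flags indels inside the window.
    """
    reference = refs.alpha1_helical_reference()
    query = record.ungapped
    mapping = _map_reference_positions(reference, query)
    hits = [
        mapping[i]
        for i in range(refs.T33_WINDOW_START - 1, refs.T33_WINDOW_END)
        if mapping[i] is not None
    ]
    if not hits:
        raise RegionAbsentError(f"T32/33 region absent from {record.taxon!r}")
    window = "".join(query[i] for i in hits)
    expected = refs.T33_WINDOW_END - refs.T33_WINDOW_START + 1
    is_short = len(window) != expected or (hits[-1] - hits[0] + 1 != expected)
    return window, (hits[0] + 1, hits[-1] + 1), is_short


def classify_t33(window: str, taxon: str = "") -> DiscriminatorResult:
    """Call α1/α3 from a 17-residue T32/33 window.

    K at the ninth position ⇒ α1 (the region digests into two tryptic
    peptides); Q ⇒ α3 (one peptide); anything else ⇒ indeterminate.
    """
    expected = refs.T33_WINDOW_END - refs.T33_WINDOW_START + 1
    if len(window) != expected:
        raise DimensionError(
            f"T32/33 window must have {expected} residues, got {len(window)}"
        )
    residue = window[8]
    result = DiscriminatorResult(taxon=taxon, t33_residue=residue, window=window)
    n_peptides = len(tryptic_digest(window))
    result.evidence_notes.append(f"window digests into {n_peptides} tryptic peptide(s)")
    if residue == "K":
        result.call = "alpha1"
    elif residue == "Q":
        result.call = "alpha3"
    else:
        result.call = "indeterminate"
        result.evidence_notes.append(f"ninth window residue {residue!r} is neither K nor Q")
    return result


def classify_procollagen_1264(record: ChainRecord) -> DiscriminatorResult:
    """Call α1/α3 from the residue homologous to procollagen position 1264.

    C ⇒ α1, S ⇒ α3, anything else ⇒ indeterminate.  Helical-domain-only
    input cannot span the position and raises :class:`RegionAbsentError`.
    """
    if record.region is not Region.PROCOLLAGEN:
        raise RegionAbsentError(
            "position 1264 lies outside the helical domain; full procollagen required"
        )
    reference = refs.alpha1_procollagen_reference()
    query = record.ungapped
    mapping = _map_reference_positions(reference, query)
    qi = mapping[refs.PROCOLLAGEN_DIAGNOSTIC_POS - 1]
    if qi is None:
        raise RegionAbsentError(
            f"query {record.taxon!r} does not span procollagen position "
            f"{refs.PROCOLLAGEN_DIAGNOSTIC_POS}"
        )
    residue = query[qi]
    result = DiscriminatorResult(taxon=record.taxon, pos1264_residue=residue)
    if residue == refs.ALPHA1_1264:
        result.call = "alpha1"
    elif residue == refs.ALPHA3_1264:
        result.call = "alpha3"
    else:
        result.call = "indeterminate"
        result.evidence_notes.append(
            f"position-1264 residue {residue!r} is neither C nor S"
        )
    return result


def classify_chain(record: ChainRecord) -> DiscriminatorResult:
    """Combine the T32/33 and position-1264 rules into one call.

    The T32/33 rule is always attempted; the 1264 rule additionally for
    procollagen input.  Agreement (or a single informative rule) gives the
    call; contradiction gives ``conflict``; no informative evidence gives
    ``indeterminate``.
    """
    result = DiscriminatorResult(taxon=record.taxon)
    try:
        window, coords, is_short = locate_t33_window(record)
        result.window = window
        if is_short:
            result.evidence_notes.append(
                f"window at query {coords[0]}–{coords[1]} contains indels; T32/33 rule skipped"
            )
            t33_call = None
        else:
            sub = classify_t33(window, taxon=record.taxon)
            result.t33_residue = sub.t33_residue
            result.evidence_notes.extend(sub.evidence_notes)
            t33_call = sub.call if sub.call in ("alpha1", "alpha3") else None
    except (NoHomologyError, RegionAbsentError) as exc:
        result.evidence_notes.append(f"T32/33 rule unavailable: {exc}")
        t33_call = None

    pos_call = None
    if record.region is Region.PROCOLLAGEN:
        try:
            sub = classify_procollagen_1264(record)
            result.pos1264_residue = sub.pos1264_residue
            result.evidence_notes.extend(sub.evidence_notes)
            pos_call = sub.call if sub.call in ("alpha1", "alpha3") else None
        except (NoHomologyError, RegionAbsentError) as exc:
            result.evidence_notes.append(f"position-1264 rule unavailable: {exc}")

    calls = {c for c in (t33_call, pos_call) if c is not None}
    if len(calls) == 2:
        result.call = "conflict"
    elif len(calls) == 1:
        result.call = calls.pop()
    else:
        result.call = "indeterminate"
    return result
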