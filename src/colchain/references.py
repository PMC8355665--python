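"""Bundled reference sequences for window localisation and chain calls.

These references are synthetic stand-ins built deterministically in code, not
database entries: collagen-like helical domains with glycine at every third
position and conserved lysine/arginine tryptic boundaries, carrying the two
empirically diagnostic features at their published coordinates —

* the T32/33 window (helical positions 334–350), which in α1 chains contains
  lysine at its ninth position (``GGPGVVGPKGATGEPGR`` in zebrafish) and in α3
  chains glutamine (``GANGPMGAQGASGESGR``), and
* the procollagen position-1264 residue, cysteine in α1 and serine in α3.

The flanking sequence is generated, so these references support coordinate
transfer by alignment but are not literal zebrafish accessions.
"""

from __future__ import annotations

from functools import lru_cache

from .records import CHAIN_LENGTHS

#: Diagnostic T32/33 windows at helical positions 334–350 (1-based).
T33_WINDOW_START = 334
T33_WINDOW_END = 350
ALPHA1_T33_WINDOW = "GGPGVVGPKGATGEPGR"
ALPHA3_T33_WINDOW = "GANGPMGAQGASGESGR"

#: Diagnostic procollagen coordinate (1-based) and residues.
PROCOLLAGEN_DIAGNOSTIC_POS = 1264
ALPHA1_1264 = "C"
ALPHA3_1264 = "S"

#: Procollagen layout of the synthetic reference: N-terminal leader
#: (signal peptide + N-propeptide stand-in), helical domain, C-propeptide.
PRO_N_LEADER = 161
PRO_C_TAIL = 246

# Xaa/Yaa fillers chosen to avoid the residues that carry signal elsewhere
# (no K/R except at boundaries, no C/S at generated Yaa, no G off-frame).
_XAA = "PAELVDNTQM"
_YAA = "PTAEQVNDLH"
_TAIL = "DNEQHLVTYFAPMIW"


def _helical_scaffold(length: int) -> list[str]:
    """Gly-Xaa-Yaa repeat with a K or R closing every sixth triplet."""
    seq: list[str] = []
    for p in range(1, length + 1):
        frame = p % 3
        triplet = (p - 1) // 3
        if frame == 1:
            seq.append("G")
        elif frame == 2:
            seq.append(_XAA[triplet % len(_XAA)])
        else:
            if triplet % 6 == 5:
                seq.append("K" if triplet % 12 == 5 else "R")
            else:
                seq.append(_YAA[triplet % len(_YAA)])
    # trypsin boundary must not precede proline
    for i in range(length - 1):
        if seq[i] in "KR" and seq[i + 1] == "P":
            seq[i + 1] = "A"
    return seq


def _with_window(seq: list[str], window: str) -> list[str]:
    out = list(seq)
    out[T33_WINDOW_START - 1 : T33_WINDOW_END] = list(window)
    return out


@lru_cache(maxsize=None)
def alpha1_helical_reference() -> str:
    """Synthetic α1 helical-domain reference (1058 aa, α1 T32/33 window)."""
    return "".join(_with_window(_helical_scaffold(CHAIN_LENGTHS["alpha1"]), ALPHA1_T33_WINDOW))


@lru_cache(maxsize=None)
def alpha3_helical_reference() -> str:
    """Synthetic α3 helical-domain reference (1062 aa, α3 T32/33 window)."""
    return "".join(_with_window(_helical_scaffold(CHAIN_LENGTHS["alpha3"]), ALPHA3_T33_WINDOW))


def _tail(length: int, phase: int) -> str:
    return "".join(_TAIL[(phase + i * 7) % len(_TAIL)] for i in range(length))


def _procollagen(helical: str, residue_1264: str) -> str:
    seq = list(_tail(PRO_N_LEADER, 3) + helical + _tail(PRO_C_TAIL, 5))
    seq[PROCOLLAGEN_DIAGNOSTIC_POS - 1] = residue_1264
    return "".join(seq)


@lru_cache(maxsize=None)
def alpha1_procollagen_reference() -> str:
    """Synthetic α1 full-procollagen reference; Cys at position 1264."""
    return _procollagen(alpha1_helical_reference(), ALPHA1_1264)


@lru_cache(maxsize=None)
def alpha3_procollagen_reference() -> str:
    """Synthetic α3 full-procollagen reference; Ser at position 1264."""
    return _procollagen(alpha3_helical_reference(), ALPHA3_1264)
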