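"""The Dayhoff empirical amino-acid substitution model.

Fixed published constants: the PAM exchangeability counts and stationary
frequencies of the Dayhoff model, in the conventional amino-acid order
``ARNDCQEGHILKMFPSTWYV``.  The instantaneous rate matrix is built as
``Q[i, j] = s[i, j] * pi[j]`` with the diagonal set so rows sum to zero,
then rescaled so the expected number of substitutions per site per unit
branch length is one at stationarity.  The model is time-reversible
(detailed balance: ``pi[i] Q[i, j] = pi[j] Q[j, i]``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

#: Amino-acid order of the model matrices.
MODEL_ORDER = "ARNDCQEGHILKMFPSTWYV"

# Lower triangle of the symmetric exchangeability matrix, column-major:
# first the 19 rates of every residue against A, then 18 against R, ...
_EXCHANGEABILITIES = [
    # vs A
    27, 98, 120, 36, 89, 198, 240, 23, 65, 41, 26, 72, 18, 250, 409, 371, 0, 24, 208,
    # vs R
    32, 0, 23, 246, 1, 9, 240, 64, 15, 464, 90, 14, 103, 154, 26, 201, 8, 24,
    # vs N
    905, 0, 103, 148, 139, 535, 77, 34, 318, 1, 14, 42, 495, 229, 23, 95, 15,
    # vs D
    0, 134, 1153, 125, 86, 24, 0, 71, 0, 0, 13, 95, 66, 0, 0, 18,
    # vs C
    0, 0, 11, 28, 44, 0, 0, 0, 0, 19, 161, 16, 0, 96, 49,
    # vs Q
    716, 28, 606, 18, 73, 153, 114, 0, 153, 56, 53, 0, 0, 35,
    # vs E
    81, 43, 61, 11, 83, 30, 0, 51, 79, 34, 0, 22, 37,
    # vs G
    10, 0, 7, 27, 17, 15, 34, 234, 30, 0, 0, 54,
    # vs H
    7, 44, 26, 0, 48, 94, 35, 22, 27, 127, 44,
    # vs I
    257, 46, 336, 196, 12, 24, 192, 0, 37, 889,
    # vs L
    18, 527, 157, 32, 17, 33, 46, 28, 175,
    # vs K
    243, 0, 33, 96, 136, 0, 13, 10,
    # vs M
    92, 17, 62, 104, 0, 0, 258,
    # vs F
    11, 46, 13, 76, 698, 12,
    # vs P
    245, 78, 0, 0, 48,
    # vs S
    550, 75, 34, 30,
    # vs T
    0, 42, 157,
    # vs W
    61, 0,
    # vs Y
    28,
]

_FREQUENCIES = [
    0.087127, 0.040904, 0.040432, 0.046872, 0.033474, 0.038255, 0.049530,
    0.088612, 0.033619, 0.036886, 0.085357, 0.080482, 0.014753, 0.039772,
    0.050680, 0.069577, 0.058542, 0.010494, 0.029916, 0.064718,
]


def _symmetric_exchangeabilities() -> np.ndarray:
    S = np.zeros((20, 20))
    it = iter(_EXCHANGEABILITIES)
    for col in range(19):
        for row in range(col + 1, 20):
            S[row, col] = S[col, row] = next(it)
    return S


@dataclass
class SubstitutionModel:
    """Time-reversible amino-acid substitution model.

    ``rate_matrix`` is scaled to one expected substitution per site per
    unit branch length at stationarity, so branch lengths passed to
    :meth:`transition_probabilities` are in expected substitutions per site.
    """

    name: str
    frequencies: np.ndarray
    exchangeabilities: np.ndarray
    rate_matrix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pi = np.asarray(self.frequencies, dtype=float)
        pi = pi / pi.sum()
        self.frequencies = pi
        S = np.asarray(self.exchangeabilities, dtype=float)
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        self.rate_matrix = Q / mu

    def transition_probabilities(self, branch_length: float) -> np.ndarray:
        """P(t) = exp(Q t) for a branch of the given expected length."""
        if branch_length < 0:
            raise ValueError("branch length must be non-negative")
        if branch_length == 0:
            return np.eye(20)
        return expm(self.rate_matrix * branch_length)

    def index(self, residue: str) -> int:
        return MODEL_ORDER.index(residue)


def dayhoff_model() -> SubstitutionModel:
    """The Dayhoff (PAM) model with its published constants."""
    return SubstitutionModel(
        name="Dayhoff",
        frequencies=np.array(_FREQUENCIES),
        exchangeabilities=_symmetric_exchangeabilities(),
    )
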