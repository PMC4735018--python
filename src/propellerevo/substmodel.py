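"""Amino-acid substitution models for ancestral inference and sequence simulation.

Implements time-reversible 20-state Markov models of protein evolution built
from published exchangeability tables and stationary frequencies.  The model
exposes transition-probability matrices P(t) = exp(Qt), the expected pairwise
sequence identity at a given evolutionary distance, and its numerical inverse
(a maximum-likelihood distance from an observed identity), which together
support distance-based tree building and divergence-time simulation.

Only the JTT model (Jones, Taylor & Thornton 1992) is registered by default;
the registry accepts additional models built from any exchangeability table.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import brentq

#: Canonical amino-acid ordering used by all model matrices (PAML order).
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Alphabetically sorted amino acids, used for deterministic tie-breaking.
AMINO_ACIDS_ALPHA = "".join(sorted(AMINO_ACIDS))

# JTT exchangeability counts (lower triangle, column-major over the PAML
# amino-acid order above) and stationary frequencies, as published.
_JTT_EXCH_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64,
    126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232,
    8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46,
    31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26,
    597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18,
    5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47,
    16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40,
    245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47,
    103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]

_JTT_FREQS = [
    0.07674792325, 0.05169094831, 0.04264495736, 0.05154394846, 0.01980298020,
    0.04075195925, 0.06182993817, 0.07315192685, 0.02294397706, 0.05376094624,
    0.09190390810, 0.05867594132, 0.02382597617, 0.04012595987, 0.05090094910,
    0.06876493124, 0.05856494144, 0.01426098574, 0.03210196790, 0.06600493400,
]


class ModelConfigError(ValueError):
    """Raised for an unknown substitution-model identifier."""


def _lower_to_symmetric(values: list[float]) -> np.ndarray:
    s = np.zeros((20, 20))
    tri = np.tril_indices(20, k=-1)
    # column-major lower triangle: transpose the row-major upper fill
    su = np.zeros((20, 20))
    su[np.triu_indices(20, k=1)] = values
    s = su + su.T
    del tri
    return s


class SubstitutionModel:
    """A reversible amino-acid substitution model normalised to one expected
    substitution per site per unit time.

    Parameters
    ----------
    name:
        Identifier of the model (e.g. ``"jtt"``).
    exchangeabilities:
        Symmetric 20x20 matrix of exchangeability coefficients (diagonal
        ignored), in the :data:`AMINO_ACIDS` ordering.
    frequencies:
        Stationary amino-acid frequencies, summing to one.
    """

    def __init__(self, name: str, exchangeabilities: np.ndarray,
                 frequencies: np.ndarray):
        self.name = name
        pi = np.asarray(frequencies, dtype=float)
        pi = pi / pi.sum()
        s = np.asarray(exchangeabilities, dtype=float)
        q = s * pi[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # normalise: expected rate -sum(pi_i * q_ii) == 1
        rate = -np.sum(pi * np.diag(q))
        q /= rate
        self.frequencies = pi
        self.rate_matrix = q
        # symmetrised eigendecomposition for fast, stable expm
        d = np.sqrt(pi)
        b = (q * d[:, np.newaxis]) / d[np.newaxis, :]
        b = 0.5 * (b + b.T)
        eigval, eigvec = eigh(b)
        self._eigval = eigval
        self._left = eigvec / d[:, np.newaxis]          # D^-1 V, rows scaled
        self._right = eigvec.T * d[np.newaxis, :]       # V^T D

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one, entries clipped at zero."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        p = (self._left * np.exp(self._eigval * t)) @ self._right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def expected_identity(self, d: float) -> float:
        """Expected fraction of identical sites between two sequences whose
        total path length through their common ancestor is ``d``."""
        p = self.transition_matrix(d)
        return float(np.sum(self.frequencies * np.diag(p)))

    def ml_distance(self, identity: float, max_distance: float = 12.0) -> float:
        """Invert :meth:`expected_identity`: the total distance at which the
        expected identity equals the observed one.  Saturated identities (at
        or below the random floor) are capped at ``max_distance``."""
        identity = float(identity)
        if identity >= 1.0:
            return 0.0
        floor = self.expected_identity(max_distance)
        if identity <= floor:
            return max_distance
        return brentq(lambda d: self.expected_identity(d) - identity,
                      1e-9, max_distance)

    def stationary_sample(self, n: int, rng: np.random.Generator) -> str:
        """Draw an i.i.d. sequence of length ``n`` from the stationary
        distribution."""
        idx = rng.choice(20, size=n, p=self.frequencies)
        return "".join(AMINO_ACIDS[i] for i in idx)

    def evolve(self, sequence: str, t: float, rng: np.random.Generator) -> str:
        """Evolve ``sequence`` for distance ``t`` (substitutions/site)."""
        p = self.transition_matrix(t)
        out = []
        cum = np.cumsum(p, axis=1)
        u = rng.random(len(sequence))
        for k, a in enumerate(sequence):
            row = cum[AA_INDEX[a]]
            out.append(AMINO_ACIDS[int(np.searchsorted(row, u[k]))])
        return "".join(out)


_REGISTRY: dict[str, SubstitutionModel] = {}


def get_model(name: str) -> SubstitutionModel:
    """Look up a registered substitution model by identifier."""
    key = name.lower()
    if key not in _REGISTRY:
        raise ModelConfigError(
            f"unknown substitution model {name!r}; available: "
            f"{sorted(_REGISTRY)}")
    return _REGISTRY[key]


def register_model(model: SubstitutionModel) -> None:
    _REGISTRY[model.name.lower()] = model


register_model(SubstitutionModel(
    "jtt", _lower_to_symmetric(_JTT_EXCH_LOWER), np.array(_JTT_FREQS)))
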