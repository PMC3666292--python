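"""Feature extraction: conformation parameters, physicochemical lookups,
and sliding-window encoding.

The feature vector for residue *i* concatenates the normalized PSSM rows of
the WS residues centred at *i* (WS odd, 7..19) with six scalars describing
the central residue only: its three conformation parameters (propensity for
H, E and C), net charge, hydropathy and side-chain mass, each scaled into
[0, 1].  The dimension is therefore 20*WS + 6 (e.g. 266 at WS = 13).

Conformation parameters are the class-conditional propensities
S_ij = a_ij / a_i, where a_i counts occurrences of amino acid *i* in a
labelled data set and a_ij those occurrences observed in structure class *j*
(H, E or C).  They are estimated from the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .pssm import CANONICAL_ORDER, PssmProfile
from .sequences import (
    AMINO_ACIDS,
    Alphabet,
    ProteinChain,
    StructureString,
    THREE_STATES,
)

WINDOW_SIZES = (7, 9, 11, 13, 15, 17, 19)

# Net charge at physiological pH: R, H, K positive; D, E negative.
NET_CHARGE: dict[str, int] = {
    "A": 0, "R": +1, "N": 0, "D": -1, "C": 0,
    "E": -1, "Q": 0, "G": 0, "H": +1, "I": 0,
    "L": 0, "K": +1, "M": 0, "F": 0, "P": 0,
    "S": 0, "T": 0, "W": 0, "Y": 0, "V": 0,
}

# Kyte-Doolittle hydropathy: positive = hydrophobic.
HYDROPATHY: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "E": -3.5, "Q": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Side-chain (R-group) mass in Da; glycine's side chain is a lone hydrogen.
SIDE_CHAIN_MASS: dict[str, float] = {
    "A": 15.0347, "R": 100.1431, "N": 58.0597, "D": 59.0445, "C": 47.0947,
    "E": 73.0713, "Q": 72.0865, "G": 1.0079, "H": 81.0969, "I": 57.1151,
    "L": 57.1151, "K": 72.1297, "M": 75.1483, "F": 91.1323, "P": 41.0725,
    "S": 31.0341, "T": 45.0609, "W": 130.1689, "Y": 107.1317, "V": 43.0883,
}

# fixed scaling ranges (table min/max, not data-dependent)
_HYDRO_RANGE = (-4.5, 4.5)
_MASS_RANGE = (1.0079, 130.1689)


@dataclass(frozen=True)
class PhysicoTables:
    net_charge: dict[str, int] = field(default_factory=lambda: dict(NET_CHARGE))
    hydropathy: dict[str, float] = field(default_factory=lambda: dict(HYDROPATHY))
    side_chain_mass: dict[str, float] = field(
        default_factory=lambda: dict(SIDE_CHAIN_MASS)
    )

    def __post_init__(self) -> None:
        for table in (self.net_charge, self.hydropathy, self.side_chain_mass):
            missing = set(AMINO_ACIDS) - set(table)
            if missing:
                raise ValueError(f"physicochemical table missing residues {missing}")


DEFAULT_PHYSICO = PhysicoTables()


def lookup_physico(
    residue: str, tables: PhysicoTables = DEFAULT_PHYSICO, strict: bool = False
) -> tuple[float, float, float]:
    """Return (net charge, hydropathy, side-chain mass) for a residue.

    Non-standard residues yield (0, 0, 0) under the default lenient policy.
    """
    if residue in tables.net_charge:
        return (
            float(tables.net_charge[residue]),
            tables.hydropathy[residue],
            tables.side_chain_mass[residue],
        )
    if strict:
        raise KeyError(f"unknown residue {residue!r}")
    return (0.0, 0.0, 0.0)


class ConformationTable:
    """Propensities S_ij = a_ij / a_i of each amino acid for H, E, C.

    Rows follow :data:`sspipe.pssm.CANONICAL_ORDER`; rows for amino acids
    never observed (a_i = 0) are flagged and set to the uniform (1/3, 1/3,
    1/3).
    """

    def __init__(self, counts: np.ndarray):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (20, 3):
            raise ValueError(f"counts must be 20 x 3, got {counts.shape}")
        self.counts = counts
        totals = counts.sum(axis=1)
        self.totals = totals
        self.flagged_uniform = totals == 0
        S = np.full((20, 3), 1.0 / 3.0)
        nz = totals > 0
        S[nz] = counts[nz] / totals[nz, None]
        self.S = S

    def row(self, residue: str) -> np.ndarray:
        """(S_iH, S_iE, S_iC) for a residue; uniform for non-standard codes."""
        idx = CANONICAL_ORDER.find(residue)
        if idx < 0:
            return np.full(3, 1.0 / 3.0)
        return self.S[idx]

    @classmethod
    def from_values(cls, values: dict[str, tuple[float, float, float]],
                    scale: int = 10_000) -> "ConformationTable":
        """Build a table from published propensities via integer pseudo-counts."""
        counts = np.zeros((20, 3), dtype=np.int64)
        for res, props in values.items():
            counts[CANONICAL_ORDER.index(res)] = np.rint(
                np.asarray(props) * scale
            ).astype(np.int64)
        return cls(counts)


def compute_conformation_parameters(
    pairs: list[tuple[ProteinChain, StructureString]],
) -> ConformationTable:
    """Pool residue/structure counts over chains and form S_ij = a_ij / a_i."""
    if not pairs:
        raise ValueError("no (chain, structure) pairs supplied")
    counts = np.zeros((20, 3), dtype=np.int64)
    for chain, ss in pairs:
        if ss.alphabet is not Alphabet.THREE:
            raise ValueError(f"chain {chain.id!r}: structure must be 3-state")
        if len(ss) != len(chain):
            raise ValueError(
                f"chain {chain.id!r}: sequence length {len(chain)} != "
                f"structure length {len(ss)}"
            )
        for res, state in zip(chain.sequence, ss.states):
            i = CANONICAL_ORDER.find(res)
            if i >= 0:
                counts[i, THREE_STATES.index(state)] += 1
    return ConformationTable(counts)


#: whole-benchmark conformation parameters as conventionally tabulated for
#: the CB513 set (rows (H, E, C)); shipped for comparison with tables
#: recomputed from training data.
PUBLISHED_CONFORMATION: dict[str, tuple[float, float, float]] = {
    "A": (0.49, 0.16, 0.35), "R": (0.42, 0.19, 0.39), "N": (0.27, 0.13, 0.60),
    "D": (0.31, 0.11, 0.58), "C": (0.26, 0.29, 0.45), "E": (0.49, 0.15, 0.36),
    "Q": (0.46, 0.16, 0.38), "G": (0.16, 0.14, 0.70), "H": (0.30, 0.22, 0.48),
    "I": (0.35, 0.37, 0.28), "L": (0.45, 0.24, 0.31), "K": (0.40, 0.17, 0.43),
    "M": (0.44, 0.23, 0.33), "F": (0.35, 0.30, 0.35), "P": (0.18, 0.09, 0.74),
    "S": (0.28, 0.19, 0.54), "T": (0.25, 0.27, 0.48), "W": (0.37, 0.29, 0.35),
    "Y": (0.34, 0.30, 0.36), "V": (0.30, 0.41, 0.29),
}


def published_conformation_table() -> ConformationTable:
    return ConformationTable.from_values(PUBLISHED_CONFORMATION)


def feature_dimension(window_size: int) -> int:
    """Encoded vector length: 20 per window position plus 6 central scalars."""
    _check_ws(window_size)
    return 20 * window_size + 6


def _check_ws(ws: int) -> None:
    if ws % 2 == 0 or not 7 <= ws <= 19:
        raise ValueError(f"window size must be odd and in [7, 19], got {ws}")


def _central_scalars(
    residue: str, ct: ConformationTable, pt: PhysicoTables
) -> np.ndarray:
    sH, sE, sC = ct.row(residue)
    if residue in pt.net_charge:
        charge = (pt.net_charge[residue] + 1) / 2.0  # {-1,0,+1} -> {0,0.5,1}
        lo, hi = _HYDRO_RANGE
        hydro = (pt.hydropathy[residue] - lo) / (hi - lo)
        lo, hi = _MASS_RANGE
        mass = (pt.side_chain_mass[residue] - lo) / (hi - lo)
    else:
        charge = hydro = mass = 0.0
    return np.array([sH, sE, sC, charge, hydro, mass])


def encode_windows(
    chain: ProteinChain,
    profile: PssmProfile,
    ct: ConformationTable,
    pt: PhysicoTables = DEFAULT_PHYSICO,
    window_size: int = 13,
    pad_value: float = 0.0,
) -> np.ndarray:
    """Encode every residue of a chain as a 20*WS + 6 feature vector.

    ``profile`` must be normalized to [0, 1].  Window positions falling
    outside the chain contribute constant ``pad_value`` blocks (0 = "no
    information" under min-max normalization; 0.5 is the half-value
    alternative).
    """
    _check_ws(window_size)
    if not profile.normalized:
        raise ValueError("profile must be normalized before encoding")
    L = len(chain)
    if len(profile) != L:
        raise ValueError(
            f"chain {chain.id!r}: profile has {len(profile)} rows for "
            f"{L} residues"
        )
    half = (window_size - 1) // 2
    padded = np.full((L + 2 * half, 20), pad_value, dtype=float)
    padded[half : half + L] = profile.matrix
    D = feature_dimension(window_size)
    X = np.empty((L, D))
    for i in range(L):
        X[i, : 20 * window_size] = padded[i : i + window_size].ravel()
        X[i, 20 * window_size :] = _central_scalars(chain.sequence[i], ct, pt)
    return X


class WindowEncoder(BaseEstimator):
    """Transformer turning (chain, profile) pairs into feature matrices.

    ``fit`` estimates the conformation table from labelled training chains
    (training set only — test labels never enter the encoding); ``transform``
    window-encodes chains against their normalized PSSM profiles.

    Parameters
    ----------
    window_size : odd int in [7, 19], default 13
        Sliding-window width WS; feature dimension is 20*WS + 6.
    pad_value : float, default 0.0
        PSSM value used for window positions beyond the chain ends.
    """

    def __init__(self, window_size: int = 13, pad_value: float = 0.0):
        self.window_size = window_size
        self.pad_value = pad_value

    def fit(
        self, pairs: list[tuple[ProteinChain, StructureString]], y=None
    ) -> "WindowEncoder":
        _check_ws(self.window_size)
        self.conformation_table_ = compute_conformation_parameters(pairs)
        self.physico_tables_ = DEFAULT_PHYSICO
        self.n_features_out_ = feature_dimension(self.window_size)
        return self

    def transform(
        self, chains: list[ProteinChain], profiles: dict[str, PssmProfile]
    ) -> np.ndarray:
        if not hasattr(self, "conformation_table_"):
            raise RuntimeError("WindowEncoder is not fitted")
        blocks = []
        for chain in chains:
            if chain.id not in profiles:
                raise KeyError(f"no PSSM profile for chain {chain.id!r}")
            blocks.append(
                encode_windows(
                    chain,
                    profiles[chain.id],
                    self.conformation_table_,
                    self.physico_tables_,
                    self.window_size,
                    self.pad_value,
                )
            )
        return np.vstack(blocks)
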