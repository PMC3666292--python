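"""Position-specific scoring matrix (PSSM) profiles.

A PSSM is an L x 20 matrix of per-position log-odds scores produced by an
iterative homology search (PSI-BLAST); it captures which residues are
tolerated at each position of the query and is the main evolutionary input
feature for secondary-structure prediction.  This module parses the PSI-BLAST
ASCII matrix layout (header lines, then one row per residue with the position
index, the query residue letter and 20 integer log-odds columns), writes the
same layout for fixtures, rescales scores to [0, 1], and synthesizes
profile stand-ins for testing without running PSI-BLAST.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .sequences import AMINO_ACIDS, ProteinChain

#: column order used by PSI-BLAST ASCII output
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"
#: internal canonical column order (alphabetical one-letter codes)
CANONICAL_ORDER = AMINO_ACIDS


@dataclass(frozen=True)
class PssmProfile:
    """L x 20 profile aligned to a chain; columns in :data:`CANONICAL_ORDER`."""

    chain_id: str
    matrix: np.ndarray
    residues: str  # residue letters from the file rows, for cross-checking
    normalized: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[1] != 20:
            raise ValueError(f"PSSM matrix must be L x 20, got {m.shape}")
        if m.shape[0] != len(self.residues):
            raise ValueError("PSSM row count != residue string length")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PssmProfile):
            return NotImplemented
        return (
            self.chain_id == other.chain_id
            and self.residues == other.residues
            and self.normalized == other.normalized
            and np.array_equal(self.matrix, other.matrix)
        )


class NormalizationMethod(enum.Enum):
    MINMAX = "minmax"
    LOGISTIC = "logistic"


@dataclass(frozen=True)
class NormalizationSpec:
    """How raw log-odds scores are mapped into [0, 1].

    MINMAX uses fixed bounds with clipping, x -> clip((x - lo)/(hi - lo), 0, 1),
    so the train and test transforms are identical without dataset statistics;
    LOGISTIC uses the sigmoid 1/(1 + exp(-x)), the other convention common in
    PSSM-based predictors.
    """

    method: NormalizationMethod = NormalizationMethod.MINMAX
    lo: float = -10.0
    hi: float = 10.0

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError("NormalizationSpec requires lo < hi")

    def apply(self, values: np.ndarray) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        if self.method is NormalizationMethod.MINMAX:
            return np.clip((x - self.lo) / (self.hi - self.lo), 0.0, 1.0)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-x))


DEFAULT_NORMALIZATION = NormalizationSpec()

# permutation taking a PSI-BLAST-ordered row to canonical order
_TO_CANONICAL = np.array([PSIBLAST_ORDER.index(a) for a in CANONICAL_ORDER])


def parse_pssm(path: str | Path, chain: ProteinChain | None = None) -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM file.

    Header lines are skipped up to the column-header line; each data row must
    carry a position index, a residue letter and at least 20 integer log-odds
    values (further columns — the percentage block, information content — are
    ignored).  If ``chain`` is given, row residue letters are checked against
    its sequence.
    """
    path = Path(path)
    rows: list[list[int]] = []
    residues: list[str] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            parts = raw.split()
            if not header_seen:
                # the column-header line lists the 20 residue letters (twice
                # in full PSI-BLAST output); detect it and start parsing after
                if len(parts) >= 20 and all(len(p) == 1 for p in parts[:20]):
                    header_seen = True
                continue
            if not parts:
                continue
            if not parts[0].isdigit():
                break  # footer (statistics block)
            if len(parts) < 22:
                raise ValueError(
                    f"{path}:{lineno}: expected 20 log-odds values, "
                    f"found {max(len(parts) - 2, 0)}"
                )
            try:
                scores = [int(v) for v in parts[2:22]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer log-odds value") from exc
            residues.append(parts[1])
            rows.append(scores)
    if not rows:
        raise ValueError(f"{path}: no PSSM rows found")
    matrix = np.array(rows, dtype=int)[:, _TO_CANONICAL]
    residue_str = "".join(residues)
    if chain is not None:
        if len(residue_str) != len(chain):
            raise ValueError(
                f"{path}: {len(residue_str)} PSSM rows for chain "
                f"{chain.id!r} of length {len(chain)}"
            )
        for i, (a, b) in enumerate(zip(residue_str, chain.sequence)):
            if a != b:
                raise ValueError(
                    f"{path}: residue mismatch at position {i + 1}: "
                    f"PSSM has {a!r}, chain {chain.id!r} has {b!r}"
                )
    return PssmProfile(path.stem if chain is None else chain.id, matrix, residue_str)


def write_pssm(profile: PssmProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII layout (log-odds block only)."""
    if profile.normalized:
        raise ValueError("refusing to write a normalized profile as raw PSSM")
    perm = np.array([CANONICAL_ORDER.index(a) for a in PSIBLAST_ORDER])
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("      " + "  ".join(PSIBLAST_ORDER) + "\n")
        for i, (res, row) in enumerate(zip(profile.residues, profile.matrix), 1):
            vals = " ".join(f"{int(v):3d}" for v in np.asarray(row)[perm])
            fh.write(f"{i:5d} {res} {vals}\n")


def normalize_profile(
    profile: PssmProfile, spec: NormalizationSpec = DEFAULT_NORMALIZATION
) -> PssmProfile:
    """Rescale every profile entry into [0, 1] per the normalization spec."""
    return replace(profile, matrix=spec.apply(profile.matrix), normalized=True)


def synthesize_pssm(
    chain: ProteinChain, signal: float = 0.8, rng_seed: int = 0
) -> PssmProfile:
    """Generate a synthetic integer log-odds profile for a chain.

    Background scores are iid discretized Gaussians (mean -2, sd 2, clipped to
    [-10, 10], roughly the spread of real log-odds columns).  With probability
    ``signal`` a row is "conserved": the true residue's column is raised
    strictly above the row's background maximum.  At ``signal=1`` the true
    residue is therefore the argmax of every row; at ``signal=0`` rows carry
    no information about the residue.  Deterministic for a fixed seed.
    """
    if not 0.0 <= signal <= 1.0:
        raise ValueError("signal must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    L = len(chain)
    matrix = np.clip(np.rint(rng.normal(-2.0, 2.0, size=(L, 20))), -10, 10).astype(int)
    conserved = rng.random(L) < signal
    boosts = rng.integers(1, 4, size=L)
    for i, res in enumerate(chain.sequence):
        if conserved[i] and res in CANONICAL_ORDER:
            j = CANONICAL_ORDER.index(res)
            matrix[i, j] = matrix[i].max() + boosts[i]
    return PssmProfile(chain.id, matrix, chain.sequence)
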