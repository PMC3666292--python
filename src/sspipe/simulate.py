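"""Synthetic chains, structures and PSSM stand-ins for end-to-end testing.

The generator emulates the three statistical properties the prediction
pipeline relies on, without any database download:

* segmental structure — states come in maximal runs with the physical
  minimum lengths (helix >= 3, sheet >= 2, coil >= 1); run lengths are
  geometric with that floor;
* class-conditional residue composition — residues are emitted from
  per-class distributions obtained by Bayes-inverting published
  helix/sheet/coil propensities under a uniform residue prior, sharpened by
  a concentration exponent that sets problem difficulty;
* evolution-like profiles — PSSM stand-ins whose true-residue column is
  elevated with probability ``pssm_signal`` (see
  :func:`sspipe.pssm.synthesize_pssm`).

What it does NOT emulate: homology between chains, position-specific
conservation patterns, amphipathic periodicity, or real run-length tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import ConformationTable, published_conformation_table
from .pssm import CANONICAL_ORDER, PssmProfile, synthesize_pssm
from .sequences import ProteinChain, StructureString, THREE_STATES

#: hard minimum run lengths per class
MIN_RUN = {"H": 3, "E": 2, "C": 1}

#: geometric continuation parameters; mean run = floor + (1-p)/p ... shaped so
#: helices average ~6 residues, strands ~3.5, coil ~4
RUN_GEOM_P = {"H": 0.3, "E": 0.4, "C": 0.3}

#: first-segment class probabilities (approximate helix/sheet/coil balance)
START_PROBS = {"H": 0.35, "E": 0.20, "C": 0.45}

#: class-transition probabilities between consecutive segments (no self loop)
TRANSITIONS = {
    "H": {"E": 0.15, "C": 0.85},
    "E": {"H": 0.15, "C": 0.85},
    "C": {"H": 0.55, "E": 0.45},
}


def emission_from_propensities(
    table: ConformationTable | None = None, concentration: float = 1.0
) -> np.ndarray:
    """3 x 20 residue-emission probabilities, one row per class (H, E, C).

    Bayes inversion under a uniform residue prior: P(res | class) is the
    class column of the propensity table renormalized over residues, raised
    to ``concentration`` and renormalized again (>1 sharpens class
    signatures, <1 flattens them).
    """
    if table is None:
        table = published_conformation_table()
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    cols = table.S.T  # 3 x 20, P(class | res) up to the prior
    probs = cols / cols.sum(axis=1, keepdims=True)
    probs = probs**concentration
    return probs / probs.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one simulated data set."""

    n_chains: int = 200
    length_range: tuple[int, int] = (30, 80)
    emission: np.ndarray | None = None  # 3 x 20; default from propensities
    emission_concentration: float = 2.5
    pssm_signal: float = 0.8
    seed: int = 0
    run_geom_p: dict[str, float] = field(default_factory=lambda: dict(RUN_GEOM_P))

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo > hi or lo < max(MIN_RUN.values()):
            raise ValueError(
                f"infeasible length range {self.length_range}: minimum chain "
                f"length must be >= {max(MIN_RUN.values())} (shortest helix)"
            )
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0.0 <= self.pssm_signal <= 1.0:
            raise ValueError("pssm_signal must be in [0, 1]")

    def emission_matrix(self) -> np.ndarray:
        if self.emission is not None:
            e = np.asarray(self.emission, dtype=float)
            if e.shape != (3, 20):
                raise ValueError("emission must be 3 x 20")
            if not np.allclose(e.sum(axis=1), 1.0):
                raise ValueError("emission rows must sum to 1")
            return e
        return emission_from_propensities(concentration=self.emission_concentration)


def _sample_structure(L: int, rng: np.random.Generator,
                      geom_p: dict[str, float]) -> str:
    """Segmental 3-state string of length L honouring the minimum runs."""
    states: list[str] = []
    runs: list[tuple[str, int]] = []
    cls = rng.choice(list(START_PROBS), p=list(START_PROBS.values()))
    while len(states) < L:
        run = MIN_RUN[cls] + rng.geometric(geom_p[cls]) - 1
        remaining = L - len(states)
        if run > remaining:
            if remaining >= MIN_RUN[cls]:
                run = remaining
            elif runs:
                # too little room for a legal new segment: extend the last one
                states.extend(runs[-1][0] * remaining)
                break
            else:
                cls = "C"  # a whole short chain can always be coil
                run = remaining
        states.extend(cls * run)
        runs.append((cls, run))
        nxt = TRANSITIONS[cls]
        cls = rng.choice(list(nxt), p=list(nxt.values()))
    return "".join(states[:L])


def simulate(
    spec: SimSpec,
) -> list[tuple[ProteinChain, StructureString, PssmProfile]]:
    """Draw chains, true 3-state structures and matching PSSM stand-ins.

    Deterministic for a fixed ``spec.seed``; every structure string obeys
    the hard minimum run lengths by construction.
    """
    rng = np.random.default_rng(spec.seed)
    emission = spec.emission_matrix()
    residues = np.array(list(CANONICAL_ORDER))
    out = []
    for k in range(spec.n_chains):
        L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        ss = _sample_structure(L, rng, spec.run_geom_p)
        seq = "".join(
            residues[rng.choice(20, p=emission[THREE_STATES.index(s)])]
            for s in ss
        )
        chain = ProteinChain(f"sim{k:04d}", seq)
        profile_seed = int(rng.integers(0, 2**31 - 1))
        profile = synthesize_pssm(chain, spec.pssm_signal, profile_seed)
        out.append((chain, StructureString(ss), profile))
    return out


def corrupt_prediction(
    truth: StructureString | str, error_rate: float, seed: int = 0
) -> StructureString:
    """Flip each position to a uniformly chosen *other* class with the given
    probability; a deterministic stand-in for an imperfect predictor."""
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    states = truth.states if isinstance(truth, StructureString) else truth
    rng = np.random.default_rng(seed)
    flips = rng.random(len(states)) < error_rate
    picks = rng.integers(0, 2, size=len(states))
    out = []
    for i, ch in enumerate(states):
        if flips[i]:
            others = [s for s in THREE_STATES if s != ch]
            out.append(others[picks[i]])
        else:
            out.append(ch)
    return StructureString("".join(out))
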