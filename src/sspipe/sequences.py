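"""Protein chains, secondary-structure strings, and 8-state -> 3-state reduction.

Secondary structure assigned from 3D coordinates (DSSP convention) uses eight
states: H (alpha-helix), G (3-10 helix), I (pi-helix), E (beta-strand),
B (isolated beta-bridge), T (turn), S (bend) and ``-`` (rest).  Prediction is
conventionally scored on the three-state alphabet {H, E, C} (helix, sheet,
coil); five reduction conventions are in common use and are all provided here.
Reduction scheme 1 (H,G,I -> H; E -> E; rest -> C) is the default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residue codes that appear in real FASTA but are not one of the 20 standard
#: amino acids; handled by a configurable policy (see :class:`UnknownPolicy`)
NONSTANDARD = "BZXUO"

EIGHT_STATES = "HGIEBTS-"
THREE_STATES = "HEC"
#: accepted in 8-state input although DSSP itself never emits it: partially
#: reduced strings (e.g. CB513-style distributions) write coil as 'C'; it
#: passes through every reduction unchanged
EIGHT_STATE_SYNONYMS = "C"


class Alphabet(enum.Enum):
    EIGHT = "EIGHT"
    THREE = "THREE"


class UnknownPolicy(enum.Enum):
    """What to do with non-standard residue codes (B, Z, X, U, O).

    ``UNKNOWN`` (default) keeps them and gives them all-zero physicochemical
    features and uniform conformation parameters downstream; ``STRICT``
    raises; ``SKIP_CHAIN`` drops the whole chain at parse time.
    """

    UNKNOWN = "unknown"
    STRICT = "strict"
    SKIP_CHAIN = "skip_chain"


@dataclass(frozen=True)
class ProteinChain:
    """A named amino-acid sequence over the 20 one-letter codes."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"chain {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class StructureString:
    """Per-residue secondary-structure labels for one chain."""

    states: str
    alphabet: Alphabet = Alphabet.THREE

    def __post_init__(self) -> None:
        valid = (
            EIGHT_STATES + EIGHT_STATE_SYNONYMS
            if self.alphabet is Alphabet.EIGHT
            else THREE_STATES
        )
        for pos, ch in enumerate(self.states):
            if ch not in valid:
                raise ValueError(
                    f"invalid state {ch!r} at position {pos} for "
                    f"{self.alphabet.value} alphabet"
                )

    def __len__(self) -> int:
        return len(self.states)


# The five published 8->3 reduction conventions.  Each maps a subset of
# {H,G,I,E,B} explicitly; every unlisted state goes to C ("the rest to C").
_SCHEME_CORE: dict[int, dict[str, str]] = {
    1: {"H": "H", "G": "H", "I": "H", "E": "E"},
    2: {"H": "H", "G": "H", "E": "E", "B": "E"},
    3: {"H": "H", "G": "H", "E": "E"},
    4: {"H": "H", "E": "E", "B": "E"},
    5: {"H": "H", "E": "E"},
}


@dataclass(frozen=True)
class ReductionScheme:
    """Total mapping from the 8-state to the 3-state alphabet."""

    scheme_index: int
    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scheme_index not in _SCHEME_CORE:
            raise ValueError(f"unknown reduction scheme {self.scheme_index}")
        if not self.mapping:
            core = _SCHEME_CORE[self.scheme_index]
            full = {s: core.get(s, "C") for s in EIGHT_STATES}
            # DSSP sometimes emits a blank for "rest"; treat it as '-'
            full[" "] = full["-"]
            full["C"] = "C"  # already-reduced coil passes through
            object.__setattr__(self, "mapping", full)


DEFAULT_SCHEME = ReductionScheme(1)


def reduce_structure(
    ss: StructureString, scheme: ReductionScheme = DEFAULT_SCHEME
) -> StructureString:
    """Reduce an 8-state structure string to 3 states {H, E, C}.

    Length is preserved; each character is mapped independently by the
    scheme's total function.
    """
    if ss.alphabet is not Alphabet.EIGHT:
        raise ValueError("reduce_structure expects an 8-state structure string")
    out = []
    for pos, ch in enumerate(ss.states):
        try:
            out.append(scheme.mapping[ch])
        except KeyError:
            raise ValueError(f"invalid 8-state character {ch!r} at position {pos}")
    return StructureString("".join(out), Alphabet.THREE)


def read_fasta(
    path: str | Path, policy: UnknownPolicy = UnknownPolicy.UNKNOWN
) -> list[ProteinChain]:
    """Read a multi-record FASTA file into :class:`ProteinChain` objects.

    Sequences are uppercased; record order is preserved.  An empty file is an
    error, as is a record whose sequence contains characters outside the
    20-letter alphabet plus the tolerated non-standard codes.
    """
    chains: list[ProteinChain] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("*", "")
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r}: empty sequence")
        bad = [c for c in seq if c not in AMINO_ACIDS and c not in NONSTANDARD]
        if bad:
            raise ValueError(
                f"FASTA record {rec.id!r}: invalid residue code(s) {sorted(set(bad))}"
            )
        if any(c in NONSTANDARD for c in seq):
            if policy is UnknownPolicy.STRICT:
                raise ValueError(
                    f"FASTA record {rec.id!r}: non-standard residues under strict policy"
                )
            if policy is UnknownPolicy.SKIP_CHAIN:
                continue
        chains.append(ProteinChain(rec.id, seq))
    if not chains:
        raise ValueError(f"{path}: no FASTA records found")
    return chains


def write_fasta(chains: Iterable[ProteinChain], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="") for c in chains
    ]
    SeqIO.write(records, str(path), "fasta")


def read_structures(
    path: str | Path, alphabet: Alphabet = Alphabet.THREE
) -> dict[str, StructureString]:
    """Read structure strings from plain text, one ``<id> <string>`` per line.

    Blank lines and ``#`` comments are ignored.
    """
    out: dict[str, StructureString] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected '<id> <states>'")
            cid, states = parts
            out[cid] = StructureString(states.strip(), alphabet)
    if not out:
        raise ValueError(f"{path}: no structure strings found")
    return out


def write_structures(
    structures: dict[str, StructureString], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for cid, ss in structures.items():
            fh.write(f"{cid} {ss.states}\n")


def pair_chains_structures(
    chains: Sequence[ProteinChain], structures: dict[str, StructureString]
) -> list[tuple[ProteinChain, StructureString]]:
    """Align chains with their structure strings by id, validating lengths."""
    pairs = []
    for chain in chains:
        if chain.id not in structures:
            raise KeyError(f"no structure string for chain {chain.id!r}")
        ss = structures[chain.id]
        if len(ss) != len(chain):
            raise ValueError(
                f"chain {chain.id!r}: sequence length {len(chain)} != "
                f"structure length {len(ss)}"
            )
        pairs.append((chain, ss))
    return pairs
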