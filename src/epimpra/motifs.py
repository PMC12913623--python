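"""Transcription-factor motif definitions and a simple log-odds scanner.

A :class:`MotifDef` couples an IUPAC consensus with a position weight
matrix (PWM).  When no PWM is supplied one is derived from the consensus:
the bases permitted by each IUPAC code share almost all of the probability
mass, so a log-odds scan against a uniform background behaves like a
(nearly) exact consensus match.  This is deliberately conservative — the
scanner's job in this package is to veto randomized sequences that happen
to recreate a known binding site, not to emulate a full motif-discovery
p-value machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Probability assigned to each base *not* permitted by the consensus code.
CONSENSUS_EPSILON = 1e-3


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def pwm_from_consensus(consensus: str, epsilon: float = CONSENSUS_EPSILON) -> np.ndarray:
    """Build an (L, 4) probability matrix from an IUPAC consensus string.

    Bases allowed by the code split ``1 - epsilon * n_disallowed`` equally;
    disallowed bases each receive ``epsilon``.
    """
    consensus = consensus.upper()
    pwm = np.empty((len(consensus), 4))
    for i, code in enumerate(consensus):
        try:
            allowed = IUPAC_CODES[code]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {code!r} in consensus {consensus!r}")
        n_dis = 4 - len(allowed)
        p_allowed = (1.0 - epsilon * n_dis) / len(allowed)
        for b in BASES:
            pwm[i, _BASE_INDEX[b]] = p_allowed if b in allowed else epsilon
    return pwm


@dataclass(frozen=True)
class MotifDef:
    """A named TF binding motif: IUPAC consensus plus PWM.

    Parameters
    ----------
    name : str
        Short identifier (e.g. the TF symbol).
    consensus : str
        IUPAC nucleotide string; its length defines the motif length.
    pwm : numpy.ndarray, optional
        (length, 4) matrix of per-column base probabilities (A, C, G, T).
        Derived from the consensus when omitted.
    """

    name: str
    consensus: str
    pwm: np.ndarray | None = None

    def __post_init__(self) -> None:
        consensus = self.consensus.upper()
        object.__setattr__(self, "consensus", consensus)
        if not consensus:
            raise ValueError(f"motif {self.name!r}: empty consensus")
        for code in consensus:
            if code not in IUPAC_CODES:
                raise ValueError(f"motif {self.name!r}: invalid IUPAC code {code!r}")
        if self.pwm is None:
            object.__setattr__(self, "pwm", pwm_from_consensus(consensus))
        else:
            pwm = np.asarray(self.pwm, dtype=float)
            if pwm.shape != (len(consensus), 4):
                raise ValueError(
                    f"motif {self.name!r}: pwm shape {pwm.shape} does not match "
                    f"consensus length {len(consensus)}"
                )
            sums = pwm.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"motif {self.name!r}: pwm columns must each sum to 1")
            object.__setattr__(self, "pwm", pwm)

    @property
    def length(self) -> int:
        return len(self.consensus)

    def consensus_sequence(self) -> str:
        """Most probable base per PWM column (alphabetical tie-break)."""
        return "".join(BASES[int(np.argmax(col))] for col in self.pwm)

    def log_odds(self, background: float = 0.25) -> np.ndarray:
        """(length, 4) log2-odds matrix against a uniform background."""
        return np.log2(self.pwm / background)

    def max_score(self, background: float = 0.25) -> float:
        return float(self.log_odds(background).max(axis=1).sum())


class MotifHit(NamedTuple):
    """One scanner hit; ``start`` is 1-based on the forward strand."""

    motif_name: str
    start: int
    strand: str
    score: float


def _encode(sequence: str) -> np.ndarray:
    return np.array([_BASE_INDEX[b] for b in sequence], dtype=np.intp)


def _scan_one_strand(encoded: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Scores of every window of ``len(lom)`` along the encoded sequence."""
    L = lom.shape[0]
    n = encoded.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for offset in range(L):
        scores += lom[offset, encoded[offset : offset + n]]
    return scores


def scan_motifs(
    sequence: str,
    motif_set: Iterable[MotifDef],
    score_frac: float = 0.8,
    score_threshold: float | None = None,
    background: float = 0.25,
) -> list[MotifHit]:
    """Scan both strands of ``sequence`` for PWM log-odds matches.

    A window is a hit when its log2-odds score is at least
    ``score_threshold`` (absolute units) or, by default, ``score_frac``
    times the motif's maximum attainable score.  Minus-strand hits are
    reported at their forward-strand 1-based start.  Hits are ordered by
    (start, motif_name, strand).
    """
    sequence = sequence.upper()
    motifs = list(motif_set)
    if not motifs or not sequence:
        return []
    if any(b not in BASES for b in sequence):
        raise ValueError("scan_motifs expects an unambiguous A/C/G/T sequence")
    encoded = _encode(sequence)
    hits: list[MotifHit] = []
    for motif in motifs:
        if motif.length > len(sequence):
            continue
        lom = motif.log_odds(background)
        threshold = (
            score_threshold if score_threshold is not None else score_frac * motif.max_score(background)
        )
        fwd = _scan_one_strand(encoded, lom)
        for i in np.nonzero(fwd >= threshold)[0]:
            hits.append(MotifHit(motif.name, int(i) + 1, "+", float(fwd[i])))
        # minus strand: score the reverse-complemented PWM on the forward
        # sequence so coordinates stay in forward-strand space.
        lom_rc = lom[::-1, ::-1]
        rev = _scan_one_strand(encoded, lom_rc)
        for i in np.nonzero(rev >= threshold)[0]:
            hits.append(MotifHit(motif.name, int(i) + 1, "-", float(rev[i])))
    hits.sort(key=lambda h: (h.start, h.motif_name, h.strand))
    return hits


def default_motif_set() -> list[MotifDef]:
    """The nine liver-expressed TF motifs used by the synthetic-enhancer design.

    Consensus strings are short core motifs (<= 12 bp, so that four slots fit
    on a 100-bp template); they are package defaults and fully replaceable.
    """
    return [
        MotifDef("CEBPA", "ATTGCGCAAT"),
        MotifDef("CTCF", "TGGCCACCAGGG"),
        MotifDef("FOXA1", "TGTTTACTTT"),
        MotifDef("HNF1A", "GTTAATGATTAA"),
        MotifDef("NR2F2", "TGACCTTTGACC"),
        MotifDef("ONECUT1", "TTTATTGATT"),
        MotifDef("PPARA", "AGGTCAAAGGTC"),
        MotifDef("REST", "TTCAGCACCACG"),
        MotifDef("XBP1", "GCCACGTCAT"),
    ]


def motifs_from_table(rows: Sequence[tuple[str, str]]) -> list[MotifDef]:
    """Build motifs from (name, consensus) pairs (e.g. a parsed TSV)."""
    return [MotifDef(name, consensus) for name, consensus in rows]
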