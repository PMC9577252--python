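"""Fickett TESTCODE statistic for protein-coding potential.

The statistic combines, for each base, a codon-position asymmetry parameter
(max over the three codon positions of the base count divided by min + 1)
and the overall base composition, each converted to a coding probability via
the published lookup tables and combined with fixed weights. Values above
~0.95 indicate coding-like sequence, below ~0.74 non-coding-like.
"""

from __future__ import annotations

_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def _lookup(value: float, cutoffs: list[float], probs: list[float]) -> float:
    for cutoff, prob in zip(cutoffs, probs):
        if value >= cutoff:
            return prob
    return probs[-1]


def fickett_testcode(sequence: str) -> float:
    """TESTCODE score of a nucleotide sequence (ambiguous bases ignored)."""
    seq = sequence.upper()
    total = sum(seq.count(b) for b in "ACGT")
    if total == 0:
        return 0.0
    score = 0.0
    for base in "ACGT":
        pos_counts = [seq[i::3].count(base) for i in range(3)]
        position_param = max(pos_counts) / (min(pos_counts) + 1.0)
        content_param = seq.count(base) / total
        score += (
            _lookup(position_param, _POSITION_PARA, _POSITION_PROB[base])
            * _POSITION_WEIGHT[base]
        )
        score += (
            _lookup(content_param, _CONTENT_PARA, _CONTENT_PROB[base])
            * _CONTENT_WEIGHT[base]
        )
    return score
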