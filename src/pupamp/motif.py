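"""Position-weight-matrix promoter scanning with exact DP p-values.

A position frequency matrix (PFM) of nucleotide counts becomes a log-odds
position weight matrix (PWM, in bits) against a background distribution with
a pseudocount.  The null distribution of the score of a random
background-distributed L-mer is computed exactly — up to score
discretization — by dynamic programming, giving each window score a p-value
``P(score >= s)``.  A scan reports every window on either strand whose
p-value beats the threshold (the published filter is p < 1e-4).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from pupamp.io import NUCLEOTIDES, PfmRecord

UNIFORM_BACKGROUND = np.full(4, 0.25)
_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G in A,C,G,T order


@dataclasses.dataclass(frozen=True)
class PWM:
    """Log-odds matrix (bits) with its background and pseudocount."""

    log_odds: np.ndarray  # 4 x L
    background: np.ndarray  # length-4 probabilities
    pseudocount: float

    def __post_init__(self) -> None:
        lo = np.asarray(self.log_odds, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if lo.ndim != 2 or lo.shape[0] != 4:
            raise ValueError("log_odds must be a 4 x L matrix")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
            raise ValueError("background must be 4 positive probabilities summing to 1")
        # -inf marks a zero-probability base (pseudocount 0); +inf/nan are bugs
        if np.isnan(lo).any() or np.isposinf(lo).any():
            raise ValueError("log-odds contain nan or +inf entries")
        object.__setattr__(self, "log_odds", lo)
        object.__setattr__(self, "background", bg)

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())


@dataclasses.dataclass(frozen=True)
class MotifHit:
    start: int  # 0-based offset on the forward strand
    strand: str  # "+" or "-"
    score: float  # bits
    p_value: float
    matched: str  # forward-strand slice, for audit


def pfm_to_pwm(
    pfm: PfmRecord,
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
) -> PWM:
    """Log-odds PWM from a count matrix.

    Each cell becomes ``log2[ (count + pseudocount * bg_b) /
    (column_total + pseudocount) / bg_b ]`` — the pseudocount is distributed
    over bases proportionally to the background.
    """
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (4,) or (bg <= 0).any() or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 positive probabilities summing to 1")
    counts = pfm.counts
    totals = counts.sum(axis=0)
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and (counts == 0).any():
        # zero cells would give -inf; the PWM constructor rejects them
        pass
    with np.errstate(divide="ignore"):
        prob = (counts + pseudocount * bg[:, None]) / (totals + pseudocount)[None, :]
        log_odds = np.log2(prob / bg[:, None])
    return PWM(log_odds=log_odds, background=bg, pseudocount=float(pseudocount))


@dataclasses.dataclass(frozen=True)
class ScorePvalueTable:
    """Discretized null distribution of PWM scores on background sequence.

    ``tail[q]`` is the probability that a random background L-mer attains a
    discretized score of at least ``q`` grid units above the minimum
    attainable score; ``delta`` is the grid width in bits.
    """

    quantized: np.ndarray  # 4 x L integer matrix, columns shifted to min 0
    offset: float  # sum of per-column minimum scores (bits)
    delta: float  # bits per grid unit
    tail: np.ndarray  # P(Q >= q) for q = 0..Qmax

    def quantize(self, score: float) -> int:
        q = int(round((score - self.offset) / self.delta)) if self.delta > 0 else 0
        return int(np.clip(q, 0, len(self.tail) - 1))

    def pvalue(self, score: float) -> float:
        return float(self.tail[self.quantize(score)])

    def word_pvalue(self, indices: np.ndarray) -> float:
        """p-value of an L-mer given as base indices, via the integer grid
        (exactly consistent with the DP)."""
        q = int(self.quantized[indices, np.arange(self.quantized.shape[1])].sum())
        return float(self.tail[q])


def score_pvalue_table(pwm: PWM, granularity: int = 1000) -> ScorePvalueTable:
    """Exact null score distribution by dynamic programming.

    Scores are discretized onto ``granularity`` bins spanning the attainable
    range; the distribution of the discretized score of an i.i.d.
    background L-mer is accumulated column by column, then converted to tail
    probabilities ``P(score >= s)``.
    """
    if granularity < 100:
        raise ValueError("granularity must be >= 100 bins")
    lo = pwm.log_odds
    if not np.isfinite(lo).all():
        raise ValueError(
            "PWM has -inf cells; use a positive pseudocount before computing p-values"
        )
    col_min = lo.min(axis=0)
    col_max = lo.max(axis=0)
    span = float((col_max - col_min).sum())
    delta = span / granularity if span > 0 else 1.0

    quantized = np.rint((lo - col_min[None, :]) / delta).astype(int)
    qmax = int(quantized.max(axis=0).sum())

    dist = np.zeros(qmax + 1)
    dist[0] = 1.0
    for j in range(pwm.length):
        new = np.zeros_like(dist)
        for b in range(4):
            q = quantized[b, j]
            new[q:] += pwm.background[b] * dist[: len(dist) - q if q else None]
        dist = new
    tail = dist[::-1].cumsum()[::-1]
    tail = np.minimum(tail, 1.0)
    return ScorePvalueTable(
        quantized=quantized, offset=float(col_min.sum()), delta=delta, tail=tail
    )


def _encode(seq: str) -> np.ndarray:
    """Base indices; anything outside A,C,G,T (e.g. N) becomes -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=int)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def scan_sequence(
    seq: SeqRecord | str,
    pwm: PWM,
    p_threshold: float = 1e-4,
    table: ScorePvalueTable | None = None,
) -> list[MotifHit]:
    """All motif hits on both strands with p-value below the threshold.

    The reverse strand is scored against the reverse complement of each
    window; hit coordinates are 0-based, half-open on the forward strand.
    Windows containing any non-ACGT character are skipped.
    """
    if isinstance(seq, SeqRecord):
        s = str(seq.seq)
    else:
        s = str(seq)
    L = pwm.length
    if len(s) < L:
        raise ValueError(f"sequence length {len(s)} is shorter than the motif ({L})")
    if table is None:
        table = score_pvalue_table(pwm)
    enc = _encode(s)
    cols = np.arange(L)
    hits: list[MotifHit] = []
    for start in range(len(s) - L + 1):
        window = enc[start : start + L]
        if (window < 0).any():
            continue
        for strand in ("+", "-"):
            if strand == "+":
                idx = window
            else:
                idx = _COMPLEMENT_INDEX[window[::-1]]
            score = float(pwm.log_odds[idx, cols].sum())
            q = int(table.quantized[idx, cols].sum())
            p = float(table.tail[q])
            if p < p_threshold:
                hits.append(
                    MotifHit(
                        start=start,
                        strand=strand,
                        score=score,
                        p_value=p,
                        matched=s[start : start + L].upper(),
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits
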