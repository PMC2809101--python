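"""Promoter transcription-factor binding-site enrichment.

JASPAR count matrices are log2-transformed into position-specific scoring
matrices with Laplace smoothing (pseudocount added per cell, uniform 25%
background), promoters are scanned on both strands at a relative-score
threshold, and the percentage of promoters with at least one hit is
compared between regulation sets with the two-proportion z-test.  A
column-shuffled matrix serves as the negative control: it preserves the
information content of the motif but destroys its positional structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffsets import RegulationSets
from .formats import CountMatrix, SequenceRecord
from .seedscan import two_proportion_test
from .wordscan import _N_CODE, encode

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.8
DEFAULT_BACKGROUND = 0.25
DEFAULT_PSEUDOCOUNT = 1.0

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N


@dataclass(frozen=True)
class PSSM:
    """Log2-ratio weight matrix with its achievable score range."""

    motif_id: str
    name: str
    weights: np.ndarray  # 4 x L, float
    s_min: float
    s_max: float

    @property
    def length(self) -> int:
        return int(self.weights.shape[1])

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.weights.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int  # 0-based on the input sequence's frame
    strand: str  # "+" or "-"
    abs_score: float
    rel_score: float


def build_pssm(
    matrix: CountMatrix,
    background: float = DEFAULT_BACKGROUND,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PSSM:
    """Log2 position weight matrix from a count matrix.

    Per column j with total n_j:
    ``w(b, j) = log2(((count(b, j) + pseudocount) / (n_j + 4 pseudocount)) / background)``.
    A uniform count column yields zero weights at the default 25%
    background.
    """
    if not 0.0 < background < 1.0:
        raise ValueError("background frequency must be in (0, 1)")
    counts = matrix.counts.astype(float)
    totals = counts.sum(axis=0, keepdims=True)
    freq = (counts + pseudocount) / (totals + 4.0 * pseudocount)
    weights = np.log2(freq / background)
    s_min = float(weights.min(axis=0).sum())
    s_max = float(weights.max(axis=0).sum())
    return PSSM(matrix.motif_id, matrix.name, weights, s_min, s_max)


def _window_scores(x: np.ndarray, pssm: PSSM) -> np.ndarray:
    """Score every window of a coded sequence; windows with N get -inf.

    ``x`` may be 1-D (one sequence) or 2-D (stacked equal-length
    sequences).
    """
    L = pssm.length
    n_win = x.shape[-1] - L + 1
    scores = np.zeros(x.shape[:-1] + (n_win,), dtype=float)
    has_n = np.zeros_like(scores, dtype=bool)
    for j in range(L):
        col = x[..., j : j + n_win]
        is_n = col == _N_CODE
        has_n |= is_n
        scores += pssm.weights[:, j][np.where(is_n, 0, col)]
    scores[has_n] = -np.inf
    return scores


def scan(
    record: SequenceRecord,
    pssm: PSSM,
    threshold: float = DEFAULT_THRESHOLD,
    strands: str = "both",
) -> list[MotifHit]:
    """All windows whose relative score reaches ``threshold``.

    The relative score is (score - s_min)/(s_max - s_min), so the
    consensus scores 1 and the anti-consensus 0 regardless of matrix
    length.  Minus-strand hits are reported in the input sequence's
    coordinate frame.  Windows containing N are skipped.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if strands not in ("plus", "both"):
        raise ValueError("strands must be 'plus' or 'both'")
    x = encode(record.sequence)
    L = pssm.length
    if len(x) < L:
        return []
    span = pssm.s_max - pssm.s_min
    hits: list[MotifHit] = []

    def emit(scores: np.ndarray, strand: str) -> None:
        rel = (scores - pssm.s_min) / span if span > 0 else np.where(np.isfinite(scores), 1.0, -1.0)
        for i in np.nonzero(rel >= threshold)[0]:
            start = int(i) if strand == "+" else len(x) - L - int(i)
            hits.append(MotifHit(record.seq_id, start, strand, float(scores[i]), float(rel[i])))

    emit(_window_scores(x, pssm), "+")
    if strands == "both":
        emit(_window_scores(_COMPLEMENT[x][::-1], pssm), "-")
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def hits_to_bed(hits: list[MotifHit], pssm: PSSM) -> pd.DataFrame:
    rows = [
        (h.seq_id, h.start, h.start + pssm.length, pssm.motif_id, round(h.rel_score, 6), h.strand)
        for h in hits
    ]
    return pd.DataFrame(
        rows, columns=["seq_id", "start", "end", "motif_id", "rel_score", "strand"]
    )


def _has_hit(x: np.ndarray, pssm: PSSM, threshold: float, strands: str) -> bool:
    if len(x) < pssm.length:
        return False
    span = pssm.s_max - pssm.s_min
    cutoff = pssm.s_min + threshold * span
    if _window_scores(x, pssm).max(initial=-np.inf) >= cutoff:
        return True
    if strands == "both":
        return bool(_window_scores(_COMPLEMENT[x][::-1], pssm).max(initial=-np.inf) >= cutoff)
    return False


def promoter_enrichment(
    sets: RegulationSets,
    promoters: list[SequenceRecord],
    pssms: list[PSSM],
    threshold: float = DEFAULT_THRESHOLD,
    strands: str = "both",
) -> pd.DataFrame:
    """Percentage of promoters with >= 1 motif hit, per regulation set.

    Returns one row per motif with percent_down / percent_up /
    percent_nochange and two-sided two-proportion p-values for down vs.
    no-change and up vs. no-change.  Set genes without a promoter sequence
    are dropped (and counted in the log).
    """
    coded = {rec.seq_id: encode(rec.sequence) for rec in promoters}
    groups: dict[str, list[np.ndarray]] = {}
    for label, members in (("down", sets.down), ("up", sets.up), ("no_change", sets.no_change)):
        present = [coded[g] for g in sorted(members) if g in coded]
        n_missing = len(members) - len(present)
        if n_missing:
            logger.info("promoter_enrichment: %d %s gene(s) without promoter; dropped", n_missing, label)
        if not present:
            raise ValueError(f"{label} set has no promoter sequences")
        groups[label] = present

    rows = []
    for pssm in pssms:
        counts = {
            label: sum(_has_hit(x, pssm, threshold, strands) for x in seqs)
            for label, seqs in groups.items()
        }
        sizes = {label: len(seqs) for label, seqs in groups.items()}
        rows.append(
            {
                "motif_id": pssm.motif_id,
                "name": pssm.name,
                "percent_down": 100.0 * counts["down"] / sizes["down"],
                "percent_up": 100.0 * counts["up"] / sizes["up"],
                "percent_nochange": 100.0 * counts["no_change"] / sizes["no_change"],
                "p_dn_vs_nc": two_proportion_test(
                    counts["down"], sizes["down"], counts["no_change"], sizes["no_change"]
                ),
                "p_up_vs_nc": two_proportion_test(
                    counts["up"], sizes["up"], counts["no_change"], sizes["no_change"]
                ),
            }
        )
    return pd.DataFrame(rows)


def shuffle_matrix(matrix: CountMatrix, seed: int | np.random.Generator = 0) -> CountMatrix:
    """Permute the columns of a count matrix (never the identity).

    Column contents are intact, so base composition and per-column
    information content are preserved while positional structure is
    destroyed.
    """
    if matrix.length < 2:
        raise ValueError("need >= 2 columns to shuffle")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(matrix.length)
    while (perm == np.arange(matrix.length)).all():
        perm = rng.permutation(matrix.length)
    return CountMatrix(
        motif_id=f"{matrix.motif_id}_shuffled",
        name=f"{matrix.name} (column-shuffled)",
        counts=matrix.counts[:, perm],
    )
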