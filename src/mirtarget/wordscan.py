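"""Unbiased word analysis over a logFC-ranked list of 3'UTR sequences.

Every k-mer is scored per sequence for overrepresentation against a
mononucleotide-shuffle null: with N(m) the number of shuffles in which the
word occurred at least as often as the m observed occurrences, the score is

    score = -log10((N(m) + 1) / (B + 1))

so a word no more frequent than chance scores ~0 and a word never reached
by B shuffles scores log10(B + 1).  The +1 is a crude correction for
sampling uncertainty that also avoids log(0).  For each word the scores
are mean-centred and cumulatively summed down the ranked list (most
down-regulated sequence first); the maximum of this running sum is the
word's enrichment statistic, standardised into a z-score against ranked-
list permutations, with a pooled permutation-null FDR per word.

The per-sequence null depends only on sequence length and mononucleotide
composition, so down-regulation enrichment of a word appears as an early
peak of the running sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import SequenceRecord
from .seedscan import SeedSiteLexicon

logger = logging.getLogger(__name__)

DEFAULT_B = 5000  # mononucleotide shuffles per sequence
_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_N_CODE = 4
K_RANGE = (4, 8)  # resource guard on word length


@dataclass(frozen=True)
class NullTail:
    """Shuffle-null tail for one word in one sequence."""

    word: str
    m_obs: int
    tail: int  # N(m_obs): shuffles with >= m_obs occurrences
    B: int


@dataclass
class WordScoreMatrix:
    """Per-(sequence, word) overrepresentation scores, rows in ranked order.

    ``scores`` is dense (n_sequences x 4^k, float32); words absent from a
    sequence score exactly 0.
    """

    ranked_seq_ids: list[str]
    k: int
    B: int
    rng_seed: int
    scores: np.ndarray

    @property
    def n_words(self) -> int:
        return 4**self.k


@dataclass(frozen=True)
class RunningSumProfile:
    """Cumulative sum of mean-centred scores for one word; S[-1] == 0."""

    word: str
    S: np.ndarray
    statistic: float


@dataclass
class WordEnrichmentTable:
    """Ranked word z-scores and permutation FDRs (one row per k-mer)."""

    table: pd.DataFrame  # columns: rank, word, statistic, z_score, fdr, annotation
    k: int
    B: int
    P: int
    rng_seed: int


def encode(sequence: str) -> np.ndarray:
    """Map a DNA string to codes A=0, C=1, G=2, T=3, N=4 (uint8)."""
    out = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    table = np.full(256, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        table[ord(base)] = code
    table[ord("N")] = _N_CODE
    codes = table[out]
    if (codes == 255).any():
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    return codes


def decode_word(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def encode_word(word: str) -> int:
    code = 0
    for ch in word:
        code = (code << 2) | _CODE[ch]
    return code


def mononucleotide_shuffle(sequence: str, seed: int | np.random.Generator) -> str:
    """Uniform random permutation of the sequence's characters.

    Preserves mononucleotide composition exactly; ``N`` characters are
    permuted along with the rest.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    return rng.permutation(arr).tobytes().decode("ascii")


def _window_codes(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k-mer codes for every window of a coded sequence (or a stack of them).

    Returns (codes, valid) where ``valid`` flags windows free of N.  Works
    on 1-D arrays (one sequence) and 2-D arrays (rows are sequences of
    equal length).
    """
    n_win = x.shape[-1] - k + 1
    codes = np.zeros(x.shape[:-1] + (n_win,), dtype=np.int32)
    invalid = np.zeros_like(codes, dtype=bool)
    for j in range(k):
        col = x[..., j : j + n_win].astype(np.int32)
        is_n = col == _N_CODE
        invalid |= is_n
        codes = codes * 4 + np.where(is_n, 0, col)
    return codes, ~invalid


def count_words(sequence: str, k: int) -> dict[str, int]:
    """Occurrence counts (overlapping, N-windows excluded) of every k-mer
    present in the sequence."""
    x = encode(sequence)
    if len(x) < k:
        return {}
    codes, valid = _window_codes(x, k)
    uniq, counts = np.unique(codes[valid], return_counts=True)
    return {decode_word(int(c), k): int(m) for c, m in zip(uniq, counts)}


def _sequence_tails(
    x: np.ndarray, k: int, B: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed word codes, counts and shuffle-null tails for one sequence.

    One batch of B mononucleotide permutations is scanned with a sliding
    window; only words observed in the original sequence are materialised.
    Returns (obs_codes sorted, m_obs, N(m_obs)).
    """
    empty = (np.empty(0, np.int32), np.empty(0, np.int64), np.empty(0, np.int64))
    if len(x) < k:
        return empty
    codes, valid = _window_codes(x, k)
    obs_codes, m_obs = np.unique(codes[valid], return_counts=True)
    if obs_codes.size == 0:
        return empty

    tiled = np.tile(x, (B, 1))
    rng.permuted(tiled, axis=1, out=tiled)
    shuf_codes, shuf_valid = _window_codes(tiled, k)

    idx = np.searchsorted(obs_codes, shuf_codes)
    idx[idx == obs_codes.size] = 0  # out-of-range probes can never match
    match = (obs_codes[idx] == shuf_codes) & shuf_valid
    flat = np.nonzero(match.ravel())[0]
    pair = (flat // shuf_codes.shape[1]) * obs_codes.size + idx.ravel()[flat]
    counts = np.bincount(pair, minlength=B * obs_codes.size).reshape(B, obs_codes.size)
    tails = (counts >= m_obs[None, :]).sum(axis=0)
    return obs_codes, m_obs.astype(np.int64), tails.astype(np.int64)


def null_tails(
    sequence: str, k: int, B: int = DEFAULT_B, seed: int | np.random.Generator = 0
) -> dict[str, NullTail]:
    """Shuffle-null tails N(m_obs) for every word observed in ``sequence``.

    Words absent from the sequence are not materialised (their score is 0
    by convention).  Returns an empty dict when the sequence is shorter
    than k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs_codes, m_obs, tails = _sequence_tails(encode(sequence), k, B, rng)
    return {
        decode_word(int(c), k): NullTail(decode_word(int(c), k), int(m), int(t), B)
        for c, m, t in zip(obs_codes, m_obs, tails)
    }


def overrep_score(tail: NullTail) -> float:
    """-log10((N(m)+1)/(B+1)); 0 when the word is no rarer than chance."""
    return float(-np.log10((tail.tail + 1) / (tail.B + 1)))


def build_score_matrix(
    ranked_records: list[SequenceRecord],
    k: int,
    B: int,
    seed: int | np.random.SeedSequence,
) -> WordScoreMatrix:
    """Score every k-mer in every sequence against its own shuffle null.

    ``ranked_records`` must already be ordered by ascending logFC (most
    down-regulated first); the row order is frozen into the matrix.  Each
    sequence consumes an independent child RNG stream derived from
    ``seed``, so scores do not depend on sequence order or labels.
    """
    if not K_RANGE[0] <= k <= K_RANGE[1]:
        raise ValueError(f"k={k} outside supported range {K_RANGE}")
    n = len(ranked_records)
    scores = np.zeros((n, 4**k), dtype=np.float32)
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = root.spawn(n)
    for i, (rec, stream) in enumerate(zip(ranked_records, streams)):
        rng = np.random.default_rng(stream)
        obs_codes, _, tails = _sequence_tails(encode(rec.sequence), k, B, rng)
        if obs_codes.size:
            scores[i, obs_codes] = -np.log10((tails + 1) / (B + 1))
    return WordScoreMatrix(
        ranked_seq_ids=[r.seq_id for r in ranked_records],
        k=k,
        B=B,
        rng_seed=int(root.entropy) if root.entropy is not None else 0,
        scores=scores,
    )


def running_sum(scores: np.ndarray, word: str = "") -> RunningSumProfile:
    """Cumulative sum of mean-centred scores; the statistic is its maximum.

    The final cumulative value is 0 by construction (up to float
    summation error), and adding any constant to the scores leaves the
    profile unchanged.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size < 2:
        raise ValueError("need a 1-D score vector with >= 2 entries")
    S = np.cumsum(scores - scores.mean())
    # S[-1] is 0 up to float error, so the max is non-negative by construction
    return RunningSumProfile(word=word, S=S, statistic=max(float(S.max()), 0.0))


def _matrix_statistics(scores: np.ndarray) -> np.ndarray:
    """Max running sum per word (column) for a mean-centred score matrix."""
    centered = scores - scores.mean(axis=0, keepdims=True)
    return np.maximum.reduce(np.cumsum(centered, axis=0))


def running_sum_profile(matrix: WordScoreMatrix, word: str) -> RunningSumProfile:
    """Running-sum profile of one word down the ranked list (for plotting)."""
    col = matrix.scores[:, encode_word(word)].astype(float)
    return running_sum(col, word=word)


def _longest_common_substring(a: str, b: str) -> int:
    best = 0
    for i in range(len(a)):
        for j in range(i + best + 1, len(a) + 1):
            if a[i:j] in b:
                best = j - i
            else:
                break
    return best


def annotate_word(word: str, lexicon: SeedSiteLexicon, min_overlap: int = 5) -> str:
    """Seed-site annotation: complete match names the miRNA and site class;
    a shared substring of >= ``min_overlap`` nt with the 8mer word marks a
    partial match."""
    for category, seed_word in lexicon.words.items():
        if word == seed_word:
            return f"{lexicon.mirna_id} {category}"
    if _longest_common_substring(word, lexicon.word8) >= min_overlap:
        return f"{lexicon.mirna_id} partial"
    return ""


def word_analysis(
    ranked_records: list[SequenceRecord],
    k: int = 7,
    B: int = DEFAULT_B,
    P: int = 100,
    seed: int = 0,
    lexicon: SeedSiteLexicon | None = None,
) -> WordEnrichmentTable:
    """Rank all 4^k words by ranked-list enrichment z-score.

    Procedure: build the score matrix over the ranked sequences; compute
    each word's max-running-sum statistic; recompute it under P random
    permutations of the ranked order; standardise the observed statistic
    against its own word's permutation mean and sd (z = 0 when sd = 0);
    estimate a per-word FDR as the fraction of pooled permutation z-values
    at or above the word's z divided by the fraction of observed z-values
    at or above it, clipped to [0, 1].  The resolution floor of the FDR is
    1/(P * 4^k).
    """
    if P < 2:
        raise ValueError("need P >= 2 ranked-list permutations")
    if len(ranked_records) < 2:
        raise ValueError("need >= 2 ranked sequences")
    root = np.random.SeedSequence(seed)
    shuffle_stream, perm_stream = root.spawn(2)
    matrix = build_score_matrix(ranked_records, k=k, B=B, seed=shuffle_stream)
    matrix.rng_seed = seed

    n, W = matrix.scores.shape
    observed = _matrix_statistics(matrix.scores)

    rng = np.random.default_rng(perm_stream)
    perm_stats = np.empty((P, W), dtype=np.float32)
    centered = matrix.scores - matrix.scores.mean(axis=0, keepdims=True)
    for p in range(P):
        order = rng.permutation(n)
        perm_stats[p] = np.maximum.reduce(np.cumsum(centered[order], axis=0))

    mu = perm_stats.mean(axis=0)
    sd = perm_stats.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (observed - mu) / sd, 0.0)
        perm_z = np.where(sd[None, :] > 0, (perm_stats - mu[None, :]) / sd[None, :], 0.0)

    # pooled permutation-null FDR, monotone non-increasing in z
    pooled = np.sort(perm_z.ravel())
    obs_sorted = np.sort(z)
    n_pool = pooled.size
    frac_perm = (n_pool - np.searchsorted(pooled, z, side="left")) / n_pool
    frac_obs = (W - np.searchsorted(obs_sorted, z, side="left")) / W
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(frac_obs > 0, frac_perm / frac_obs, 1.0)
    fdr = np.clip(fdr, 0.0, 1.0)

    order = np.argsort(-z, kind="stable")
    # enforce monotonicity in z (q-value convention): each word's FDR is the
    # smallest raw ratio at or below its own significance level
    fdr_ordered = np.minimum.accumulate(fdr[order][::-1])[::-1]
    words = [decode_word(int(c), k) for c in order]
    table = pd.DataFrame(
        {
            "rank": np.arange(1, W + 1),
            "word": words,
            "statistic": observed[order],
            "z_score": z[order],
            "fdr": fdr_ordered,
            "annotation": [annotate_word(w, lexicon) if lexicon else "" for w in words],
        }
    )
    return WordEnrichmentTable(table=table, k=k, B=B, P=P, rng_seed=seed)
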