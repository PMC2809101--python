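"""Hierarchical miRNA seed-site counting and set-level enrichment tests.

A mature miRNA defines four canonical target words on the mRNA sense
strand: the 6mer (reverse complement of miRNA positions 2-7), the 7mer-m8
(reverse complement of positions 2-8), the 7mer-1A (6mer followed by an A
opposite miRNA position 1), and the 8mer (7mer-m8 followed by that A).
Counting is hierarchical (TargetScan-style): every raw occurrence of the
6mer core is assigned to exactly one class by its flanking bases, so longer
sites are never double-counted as shorter ones.

Enrichment between regulation sets is assessed with a two-sided pooled
two-proportion z-test on three metrics: the percentage of genes with at
least one site, sites per kb of scanned positions, and raw counts after
down-sampling all sets to the smallest set's size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .diffsets import RegulationSets
from .formats import SequenceRecord

logger = logging.getLogger(__name__)

#: Site categories in hierarchy order (strongest first).
CATEGORIES = ("8mer", "7mer_m8", "7mer_1a", "6mer")
#: The pooled category reported alongside the four exclusive ones; the 6mer
#: class is excluded from the pool.
POOLED = "pooled_7_8mer"
POOLED_MEMBERS = ("8mer", "7mer_m8", "7mer_1a")

_RNA = frozenset("ACGU")


@dataclass(frozen=True)
class SeedSiteLexicon:
    """The four seed-match DNA words derived from one mature miRNA."""

    mirna_id: str
    mature: str  # RNA, 5'->3'
    word6: str
    word7m8: str
    word7a1: str
    word8: str

    @property
    def words(self) -> dict[str, str]:
        return {
            "8mer": self.word8,
            "7mer_m8": self.word7m8,
            "7mer_1a": self.word7a1,
            "6mer": self.word6,
        }


@dataclass(frozen=True)
class SiteCounts:
    """Exclusive site counts and 0-based start offsets for one sequence.

    Starts refer to the full site word (so 8mer/7mer-m8 sites start one
    base 5' of their 6mer core).  The class counts always sum to the raw
    substring-occurrence count of the 6mer core.
    """

    seq_id: str
    n8: int
    n7m8: int
    n7a1: int
    n6: int
    positions: dict[str, tuple[int, ...]]
    length: int

    @property
    def total(self) -> int:
        return self.n8 + self.n7m8 + self.n7a1 + self.n6

    def count(self, category: str) -> int:
        if category == POOLED:
            return self.n8 + self.n7m8 + self.n7a1
        return {"8mer": self.n8, "7mer_m8": self.n7m8, "7mer_1a": self.n7a1, "6mer": self.n6}[
            category
        ]


def derive_seed_words(mirna_id: str, mature: str) -> SeedSiteLexicon:
    """Derive the 6mer/7mer-m8/7mer-1A/8mer target words from a mature miRNA.

    ``mature`` is the RNA sequence 5'->3'.  The 6mer is the DNA reverse
    complement of positions 2-7, the 7mer-m8 of positions 2-8; the 1A
    variants append an ``A`` (matched regardless of pairing with miRNA
    position 1).
    """
    mature = mature.strip().upper().replace("T", "U")
    if len(mature) < 8:
        raise ValueError(f"mature miRNA must be >= 8 nt (got {len(mature)})")
    bad = set(mature) - _RNA
    if bad:
        raise ValueError(f"mature miRNA has non-RNA characters: {sorted(bad)}")
    dna = mature.replace("U", "T")
    word6 = str(Seq(dna[1:7]).reverse_complement())
    word7m8 = str(Seq(dna[1:8]).reverse_complement())
    return SeedSiteLexicon(
        mirna_id=mirna_id,
        mature=mature,
        word6=word6,
        word7m8=word7m8,
        word7a1=word6 + "A",
        word8=word7m8 + "A",
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (overlapping) start offsets of ``needle`` in ``haystack``."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def count_sites(record: SequenceRecord, lexicon: SeedSiteLexicon) -> SiteCounts:
    """Classify every raw 6mer-core occurrence into one exclusive category.

    A core occurrence whose preceding base completes the 7mer-m8 word and
    whose following base is ``A`` is an 8mer; only the former, a 7mer-m8;
    only the latter, a 7mer-1A; neither, a plain 6mer.  Sequence ends and
    ``N`` flanks count as non-matching flanks; a window containing ``N``
    never matches because matching is exact.
    """
    seq = record.sequence
    m8_flank = lexicon.word7m8[0]  # base 5' of the core that upgrades to a 7mer-m8
    positions: dict[str, list[int]] = {c: [] for c in CATEGORIES}
    for core_start in _find_all(seq, lexicon.word6):
        before = seq[core_start - 1] if core_start > 0 else ""
        after_idx = core_start + len(lexicon.word6)
        after = seq[after_idx] if after_idx < len(seq) else ""
        has_m8 = before == m8_flank
        has_a1 = after == "A"
        if has_m8 and has_a1:
            positions["8mer"].append(core_start - 1)
        elif has_m8:
            positions["7mer_m8"].append(core_start - 1)
        elif has_a1:
            positions["7mer_1a"].append(core_start)
        else:
            positions["6mer"].append(core_start)
    return SiteCounts(
        seq_id=record.seq_id,
        n8=len(positions["8mer"]),
        n7m8=len(positions["7mer_m8"]),
        n7a1=len(positions["7mer_1a"]),
        n6=len(positions["6mer"]),
        positions={c: tuple(v) for c, v in positions.items()},
        length=len(seq),
    )


def sites_to_bed(counts: SiteCounts, lexicon: SeedSiteLexicon) -> pd.DataFrame:
    """Export site positions as 0-based half-open intervals."""
    word_len = {"8mer": 8, "7mer_m8": 7, "7mer_1a": 7, "6mer": 6}
    rows = [
        (counts.seq_id, start, start + word_len[cat], cat)
        for cat in CATEGORIES
        for start in counts.positions[cat]
    ]
    return pd.DataFrame(rows, columns=["seq_id", "start", "end", "category"])


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided pooled two-proportion z-test (no continuity correction).

    Returns 1.0 when the pooled proportion is degenerate (0 or 1).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("trial count must be >= 1")
        if not 0 <= k <= n:
            raise ValueError(f"successes {k} outside [0, {n}]")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (k1 / n1 - k2 / n2) / se
    return float(2.0 * stats.norm.sf(abs(z)))


_WORD_LEN = {"8mer": 8, "7mer_m8": 7, "7mer_1a": 7, "6mer": 6, POOLED: 7}

METRICS = ("percent_of_genes", "per_kb", "downscaled_counts")


def _collect_counts(
    gene_ids: frozenset[str],
    site_index: dict[str, SiteCounts],
    label: str,
) -> list[SiteCounts]:
    found = [site_index[g] for g in sorted(gene_ids) if g in site_index]
    n_missing = len(gene_ids) - len(found)
    if n_missing:
        logger.info("enrich: %d gene(s) in %s set without a sequence; dropped", n_missing, label)
    return found


def enrich(
    sets: RegulationSets,
    sequences: list[SequenceRecord],
    lexicon: SeedSiteLexicon,
    metric: str = "percent_of_genes",
    seed: int = 0,
) -> pd.DataFrame:
    """Seed-site enrichment of the down set against the up and no-change sets.

    Returns one row per site category (the four exclusive classes plus the
    pooled 7mer-m8 + 7mer-1A + 8mer class) with per-set values on the chosen
    metric and two-sided two-proportion p-values for down vs. up and down
    vs. no-change.

    Metrics:

    ``percent_of_genes``
        percentage of genes in a set with >=1 site of the category; the
        test uses genes-with-site out of genes-in-set.
    ``per_kb``
        category site count per kb of scanned positions (sum of
        len - k + 1 over a set's sequences); tested as proportions over
        positions.
    ``downscaled_counts``
        sets are first subsampled without replacement to the smallest
        set's size using ``seed``; raw counts are then compared as
        proportions over scanned positions.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    site_index = {rec.seq_id: count_sites(rec, lexicon) for rec in sequences}
    groups = {
        "up": _collect_counts(sets.up, site_index, "up"),
        "down": _collect_counts(sets.down, site_index, "down"),
        "no_change": _collect_counts(sets.no_change, site_index, "no_change"),
    }
    for label, members in groups.items():
        if not members:
            raise ValueError(f"{label} set is empty after dropping genes without sequences")

    if metric == "downscaled_counts":
        rng = np.random.default_rng(seed)
        smallest = min(len(v) for v in groups.values())
        groups = {
            label: [members[i] for i in sorted(rng.choice(len(members), smallest, replace=False))]
            for label, members in groups.items()
        }

    categories = list(CATEGORIES) + [POOLED]
    rows = []
    for cat in categories:
        k = _WORD_LEN[cat]
        stat: dict[str, tuple[int, int, float]] = {}
        for label, members in groups.items():
            if metric == "percent_of_genes":
                successes = sum(1 for sc in members if sc.count(cat) > 0)
                trials = len(members)
                value = 100.0 * successes / trials
            else:
                successes = sum(sc.count(cat) for sc in members)
                trials = sum(max(sc.length - k + 1, 0) for sc in members)
                value = 1000.0 * successes / trials if trials else 0.0
            stat[label] = (successes, trials, value)
        p_dn_up = two_proportion_test(stat["down"][0], stat["down"][1], stat["up"][0], stat["up"][1])
        p_dn_nc = two_proportion_test(
            stat["down"][0], stat["down"][1], stat["no_change"][0], stat["no_change"][1]
        )
        rows.append(
            {
                "category": cat,
                "metric": metric,
                "up": stat["up"][2],
                "down": stat["down"][2],
                "no_change": stat["no_change"][2],
                "n_up": stat["up"][1],
                "n_down": stat["down"][1],
                "n_no_change": stat["no_change"][1],
                "p_dn_vs_up": p_dn_up,
                "p_dn_vs_nc": p_dn_nc,
            }
        )
    return pd.DataFrame(rows)


def region_sweep(
    sets: RegulationSets,
    sequences_by_region: dict[str, list[SequenceRecord]],
    lexicon: SeedSiteLexicon,
) -> pd.DataFrame:
    """Percent-of-genes enrichment per region (3'UTR, CDS, 5'UTR, cDNA).

    When no explicit cDNA records are given but other regions are, a cDNA
    record per gene is built by concatenating 5'UTR + CDS + 3'UTR (skipping
    absent parts), mirroring a whole-transcript scan.
    """
    if not sequences_by_region:
        raise ValueError("need at least one region")
    sequences_by_region = dict(sequences_by_region)
    if "cdna" not in sequences_by_region:
        parts: dict[str, list[str]] = {}
        for region in ("utr5", "cds", "utr3"):
            for rec in sequences_by_region.get(region, []):
                parts.setdefault(rec.seq_id, []).append(rec.sequence)
        if parts:
            sequences_by_region["cdna"] = [
                SequenceRecord(gid, "cdna", "".join(chunks)) for gid, chunks in parts.items()
            ]
    frames = []
    for region, records in sequences_by_region.items():
        if not records:
            continue
        result = enrich(sets, records, lexicon, metric="percent_of_genes")
        result.insert(0, "region", region)
        frames.append(result)
    return pd.concat(frames, ignore_index=True)
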