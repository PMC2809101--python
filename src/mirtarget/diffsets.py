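"""Expression-side processing: probeset collapsing, variance filtering,
differential statistics, and FDR-threshold regulation sets.

The input is a matrix of normalised log2 intensities (probesets or genes by
samples) with a treated/control label per sample.  Probesets are collapsed
to genes by discarding promiscuous probesets (mapping to more than two
genes) and, per gene, keeping the probeset with the largest inter-quartile
range across all samples.  Genes with low across-array variance are
removed, a per-gene Welch t-test with Benjamini-Hochberg correction gives
the differential table, and FDR thresholds partition genes into up, down
and no-change sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Genes below this FDR are called up- or down-regulated by logFC sign.
FDR_REGULATED = 0.25
#: Genes above this FDR form the no-change (background) set.
FDR_NOCHANGE = 0.8
#: Default across-array variance cutoff for non-specific filtering.
VARIANCE_CUTOFF = 0.25

CONDITIONS = ("treated", "control")


@dataclass
class ExpressionMatrix:
    """Normalised log-intensities, rows keyed by probeset or gene id."""

    values: pd.DataFrame  # rows: probesets/genes, columns: samples
    condition: dict[str, str]  # sample id -> "treated" | "control"

    def __post_init__(self) -> None:
        unknown = set(self.condition.values()) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition label(s): {sorted(unknown)}")
        missing = set(self.values.columns) - set(self.condition)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)[:5]}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition[s] == condition]


@dataclass(frozen=True)
class RegulationSets:
    """Disjoint up/down/no-change gene-id sets with their defining thresholds.

    Genes whose FDR falls in [fdr_regulated, fdr_nochange] are deliberately
    unassigned and retained in :attr:`unassigned`.
    """

    up: frozenset[str]
    down: frozenset[str]
    no_change: frozenset[str]
    unassigned: frozenset[str] = frozenset()
    fdr_regulated: float = FDR_REGULATED
    fdr_nochange: float = FDR_NOCHANGE
    provenance: str = ""

    def __post_init__(self) -> None:
        for a, b in (
            (self.up, self.down),
            (self.up, self.no_change),
            (self.down, self.no_change),
        ):
            if a & b:
                raise ValueError("regulation sets must be pairwise disjoint")

    def to_frame(self, table: pd.DataFrame | None = None) -> pd.DataFrame:
        """Serialise as a (gene_id, set, logFC) table."""
        rows = []
        logfc = {}
        if table is not None:
            logfc = dict(zip(table["gene_id"], table["logFC"]))
        for label, members in (
            ("up", self.up),
            ("down", self.down),
            ("no_change", self.no_change),
            ("unassigned", self.unassigned),
        ):
            for gid in sorted(members):
                rows.append((gid, label, logfc.get(gid, np.nan)))
        return pd.DataFrame(rows, columns=["gene_id", "set", "logFC"])


def collapse_probesets(
    matrix: ExpressionMatrix, probe_gene_map: dict[str, set[str]]
) -> ExpressionMatrix:
    """Collapse a probeset-keyed matrix to a gene-keyed one.

    Probesets mapping to more than two genes are discarded; a probeset
    mapping to two genes contributes to both.  When several probesets serve
    one gene, the one with the largest inter-quartile range of intensity
    across all samples wins (ties broken by probeset id, deterministically).
    """
    missing = [p for p in matrix.values.index if p not in probe_gene_map]
    if missing:
        raise KeyError(f"probeset(s) absent from probe-gene map: {missing[:10]}")

    vals = matrix.values
    iqr = vals.quantile(0.75, axis=1) - vals.quantile(0.25, axis=1)

    n_promiscuous = 0
    best: dict[str, str] = {}  # gene -> winning probeset
    for probeset in vals.index:
        genes = probe_gene_map[probeset]
        if len(genes) > 2:
            n_promiscuous += 1
            continue
        for gene in genes:
            prev = best.get(gene)
            if (
                prev is None
                or iqr[probeset] > iqr[prev]
                or (iqr[probeset] == iqr[prev] and probeset < prev)
            ):
                best[gene] = probeset
    logger.info(
        "collapse_probesets: dropped %d promiscuous probesets; %d genes retained",
        n_promiscuous,
        len(best),
    )
    genes = sorted(best)
    collapsed = vals.loc[[best[g] for g in genes]].copy()
    collapsed.index = pd.Index(genes, name="gene_id")
    return ExpressionMatrix(collapsed, matrix.condition)


def variance_filter(
    matrix: ExpressionMatrix, cutoff: float = VARIANCE_CUTOFF
) -> ExpressionMatrix:
    """Remove genes whose across-sample variance (n-1 denominator) is below
    ``cutoff``.  A variance exactly equal to the cutoff is kept."""
    var = matrix.values.var(axis=1, ddof=1)
    keep = var >= cutoff
    logger.info(
        "variance_filter: removed %d of %d genes (cutoff %.3g); %d left",
        int((~keep).sum()),
        len(keep),
        cutoff,
        int(keep.sum()),
    )
    return ExpressionMatrix(matrix.values.loc[keep].copy(), matrix.condition)


def differential_stats(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene logFC (treated - control), Welch t p-value, and BH FDR.

    Returns a DataFrame with columns gene_id, logFC, p, fdr ordered as the
    input matrix.  Identical groups give logFC 0 and p = 1.
    """
    treated = matrix.samples("treated")
    control = matrix.samples("control")
    if len(treated) < 2 or len(control) < 2:
        raise ValueError(
            f"need >=2 samples per condition (got {len(treated)} treated, "
            f"{len(control)} control)"
        )
    a = matrix.values[treated].to_numpy(dtype=float)
    b = matrix.values[control].to_numpy(dtype=float)
    logfc = a.mean(axis=1) - b.mean(axis=1)
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)  # zero-variance ties -> no evidence
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "gene_id": matrix.values.index.astype(str),
            "logFC": logfc,
            "p": p,
            "fdr": fdr,
        }
    ).reset_index(drop=True)


def assign_sets(
    table: pd.DataFrame,
    fdr_regulated: float = FDR_REGULATED,
    fdr_nochange: float = FDR_NOCHANGE,
) -> RegulationSets:
    """Partition a differential table into up/down/no-change sets.

    ``fdr < fdr_regulated`` with positive logFC -> up, with negative
    logFC -> down; ``fdr > fdr_nochange`` -> no-change; everything else
    (including significant genes with logFC exactly 0) is unassigned.
    """
    if len(table) == 0:
        raise ValueError("empty differential table")
    gid = table["gene_id"].astype(str)
    fdr = table["fdr"].to_numpy(dtype=float)
    logfc = table["logFC"].to_numpy(dtype=float)
    up = frozenset(gid[(fdr < fdr_regulated) & (logfc > 0)])
    down = frozenset(gid[(fdr < fdr_regulated) & (logfc < 0)])
    nc = frozenset(gid[fdr > fdr_nochange])
    unassigned = frozenset(gid) - up - down - nc
    logger.info(
        "assign_sets: up=%d down=%d no_change=%d unassigned=%d",
        len(up),
        len(down),
        len(nc),
        len(unassigned),
    )
    return RegulationSets(
        up,
        down,
        nc,
        unassigned,
        fdr_regulated,
        fdr_nochange,
        provenance=f"fdr<{fdr_regulated} (up/down by logFC sign), fdr>{fdr_nochange} (no change)",
    )


def functional_set(table: pd.DataFrame, cutoff: float = float(np.log2(1.1))) -> set[str]:
    """Genes with |logFC| strictly above ``cutoff``, for external annotation.

    The default reads the threshold as a fold change of 1.1 (cutoff
    log2(1.1) in log2 units); pass ``cutoff=1.1`` for the literal
    log2-units reading.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    mask = table["logFC"].abs().to_numpy() > cutoff
    return set(table.loc[mask, "gene_id"].astype(str))
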