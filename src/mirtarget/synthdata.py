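"""Synthetic miRNA-overexpression experiments with known ground truth.

The generator emulates the statistical structure of a transfection
microarray study: a gene universe with random region sequences (3'UTR,
CDS, 5'UTR, promoter), a fraction of genes designated miRNA targets that
carry planted seed sites and a correspondingly down-shifted log2 fold
change, replicate-level Gaussian noise from which p-values and FDRs are
computed, a global additive logFC displacement (a technical artefact the
analysis must tolerate), and a transcription-factor regulon whose members
carry a planted promoter motif and a coordinated expression shift.

Ground truth (planted site counts and positions, target and regulon
membership, total expected shift) is emitted per gene so recovery can be
tested end to end.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffsets, seedscan
from .diffsets import ExpressionMatrix
from .formats import CountMatrix, SequenceRecord, write_fasta
from .seedscan import SeedSiteLexicon

logger = logging.getLogger(__name__)

#: Hierarchy-ordered default per-site logFC shifts (8mer strongest).
DEFAULT_EFFECTS = {"8mer": -0.6, "7mer_m8": -0.4, "7mer_1a": -0.3, "6mer": -0.1}
#: Probability that a target gene receives one planted site of each class.
DEFAULT_SITE_PROBS = {"8mer": 0.3, "7mer_m8": 0.6, "7mer_1a": 0.4, "6mer": 0.4}


@dataclass
class RegulonConfig:
    """A TF regulon: members get the motif planted and a coherent shift."""

    motif: CountMatrix | None = None
    member_fraction: float = 0.1
    plant_prob_members: float = 0.7
    plant_prob_background: float = 0.5
    regulon_shift: float = -0.3


@dataclass
class SimulationConfig:
    """Parameters of one synthetic experiment (all rates per gene)."""

    n_genes: int = 2000
    seed: int = 0
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    utr3_len_median: float = 1000.0
    utr3_len_sigma: float = 0.6
    cds_len_median: float = 1300.0
    cds_len_sigma: float = 0.5
    utr5_len_median: float = 150.0
    utr5_len_sigma: float = 0.5
    promoter_len: int = 2000
    target_fraction: float = 0.15
    site_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SITE_PROBS))
    effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    noise_sd: float = 0.25
    global_shift: float = 0.226
    n_treated: int = 4
    n_control: int = 4
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    regulon: RegulonConfig | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not math.isclose(sum(self.composition), 1.0, abs_tol=1e-9):
            raise ValueError("composition must sum to 1")
        for name in ("target_fraction",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for probs in (self.site_probs,):
            if any(not 0.0 <= p <= 1.0 for p in probs.values()):
                raise ValueError("site probabilities must be in [0, 1]")
        if self.n_treated < 2 or self.n_control < 2:
            raise ValueError("need >= 2 replicates per condition")

    def to_dict(self) -> dict:
        out = {
            k: v
            for k, v in self.__dict__.items()
            if k != "regulon"
        }
        out["composition"] = list(self.composition)
        if self.regulon is not None:
            out["regulon"] = {
                "motif_id": self.regulon.motif.motif_id if self.regulon.motif else None,
                "member_fraction": self.regulon.member_fraction,
                "plant_prob_members": self.regulon.plant_prob_members,
                "plant_prob_background": self.regulon.plant_prob_background,
                "regulon_shift": self.regulon.regulon_shift,
            }
        return out


@dataclass
class SyntheticExperiment:
    """Generated sequences, expression matrix, differential table, truth."""

    sequences: dict[str, list[SequenceRecord]]
    expression: ExpressionMatrix
    diff: pd.DataFrame
    truth: pd.DataFrame  # gene_id, is_target, n_<category>..., regulon_member, true_shift
    config: SimulationConfig
    lexicon: SeedSiteLexicon


def _random_sequences(
    rng: np.random.Generator,
    n: int,
    median: float,
    sigma: float,
    composition: tuple[float, ...],
    min_len: int = 30,
) -> list[str]:
    lengths = np.maximum(
        rng.lognormal(mean=np.log(median), sigma=sigma, size=n).astype(int), min_len
    )
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [
        rng.choice(bases, size=length, p=composition).tobytes().decode("ascii")
        for length in lengths
    ]


def _classify(sequence: str, lexicon: SeedSiteLexicon) -> dict[str, int]:
    """Hierarchical site counts of a raw string (thin count_sites wrapper)."""
    counts = seedscan.count_sites(SequenceRecord("tmp", "utr3", sequence), lexicon)
    return {cat: counts.count(cat) for cat in seedscan.CATEGORIES}


def plant_word(
    sequence: str,
    word: str,
    position: int | str = "random",
    seed: int | np.random.Generator = 0,
    lexicon: SeedSiteLexicon | None = None,
    max_tries: int = 100,
) -> str:
    """Overwrite a stretch of ``sequence`` with ``word``.

    With ``position="random"`` and a lexicon, a placement is accepted only
    if the hierarchical site classification of the result differs from the
    original by exactly the planted word's own contribution: +1 in the
    word's category when ``word`` is one of the lexicon's seed words, no
    change at all otherwise.  Placements that accidentally create,
    destroy, or re-class sites are resampled (at most ``max_tries``
    attempts, then an error).
    """
    if len(word) > len(sequence):
        raise ValueError(f"word ({len(word)} nt) longer than sequence ({len(sequence)} nt)")
    if position != "random":
        pos = int(position)
        if pos < 0 or pos + len(word) > len(sequence):
            raise ValueError("position out of bounds")
        return sequence[:pos] + word + sequence[pos + len(word) :]

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    expected: dict[str, int] | None = None
    if lexicon is not None:
        expected = _classify(sequence, lexicon)
        for cat, seed_word in lexicon.words.items():
            if word == seed_word:
                expected[cat] += 1
                break
    for _ in range(max_tries):
        pos = int(rng.integers(0, len(sequence) - len(word) + 1))
        candidate = sequence[:pos] + word + sequence[pos + len(word) :]
        if expected is None or _classify(candidate, lexicon) == expected:
            return candidate
    raise RuntimeError(f"could not place word without side effects in {max_tries} tries")


def simulate_experiment(
    config: SimulationConfig, lexicon: SeedSiteLexicon
) -> SyntheticExperiment:
    """Generate a fully-labelled synthetic experiment.

    Deterministic given ``config.seed``; the differential table is
    computed from the simulated replicate matrix with the package's own
    Welch-t + BH statistics, so planted effects pass through the same
    analysis path as real data.
    """
    min_utr3 = 30
    if max(len(w) for w in lexicon.words.values()) > min_utr3:
        raise ValueError("seed words longer than the minimum UTR length")
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]

    utr3 = _random_sequences(
        rng, config.n_genes, config.utr3_len_median, config.utr3_len_sigma, config.composition
    )
    cds = _random_sequences(
        rng, config.n_genes, config.cds_len_median, config.cds_len_sigma, config.composition
    )
    utr5 = _random_sequences(
        rng, config.n_genes, config.utr5_len_median, config.utr5_len_sigma, config.composition
    )
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    promoters = [
        rng.choice(bases, size=config.promoter_len, p=config.composition).tobytes().decode("ascii")
        for _ in range(config.n_genes)
    ]

    n_targets = int(config.target_fraction * config.n_genes)
    target_idx = set(rng.choice(config.n_genes, size=n_targets, replace=False).tolist())

    # chance sites are counted before planting; the rejection sampling in
    # plant_word then guarantees final counts = chance + planted per class
    planted = {cat: np.zeros(config.n_genes, dtype=int) for cat in seedscan.CATEGORIES}
    chance = {cat: np.zeros(config.n_genes, dtype=int) for cat in seedscan.CATEGORIES}
    for i in range(config.n_genes):
        pre = _classify(utr3[i], lexicon)
        for cat in seedscan.CATEGORIES:
            chance[cat][i] = pre[cat]
    true_shift = np.zeros(config.n_genes)
    for i in sorted(target_idx):
        for cat in seedscan.CATEGORIES:
            if rng.random() < config.site_probs.get(cat, 0.0):
                word = lexicon.words[cat]
                try:
                    utr3[i] = plant_word(utr3[i], word, "random", rng, lexicon=lexicon)
                except RuntimeError:
                    logger.warning("could not plant %s site in gene %s; skipped", cat, gene_ids[i])
                    continue
                planted[cat][i] += 1
                true_shift[i] += config.effects.get(cat, 0.0)

    regulon_member = np.zeros(config.n_genes, dtype=bool)
    if config.regulon is not None and config.regulon.motif is not None:
        reg = config.regulon
        n_members = int(reg.member_fraction * config.n_genes)
        members = rng.choice(config.n_genes, size=n_members, replace=False)
        regulon_member[members] = True
        true_shift[regulon_member] += reg.regulon_shift
        from .tfbs import build_pssm  # local import to avoid a cycle

        consensus = build_pssm(reg.motif).consensus
        for i in range(config.n_genes):
            prob = reg.plant_prob_members if regulon_member[i] else reg.plant_prob_background
            if rng.random() < prob:
                promoters[i] = plant_word(promoters[i], consensus, "random", rng)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    control = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, config.n_control)
    )
    treated = (
        baseline[:, None]
        + true_shift[:, None]
        + config.global_shift
        + rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_treated))
    )
    sample_ids = [f"treated_{j+1}" for j in range(config.n_treated)] + [
        f"control_{j+1}" for j in range(config.n_control)
    ]
    values = pd.DataFrame(
        np.hstack([treated, control]), index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids
    )
    condition = {s: ("treated" if s.startswith("treated") else "control") for s in sample_ids}
    expression = ExpressionMatrix(values, condition)
    diff = diffsets.differential_stats(expression)

    sequences = {
        "utr3": [SequenceRecord(g, "utr3", s) for g, s in zip(gene_ids, utr3)],
        "cds": [SequenceRecord(g, "cds", s) for g, s in zip(gene_ids, cds)],
        "utr5": [SequenceRecord(g, "utr5", s) for g, s in zip(gene_ids, utr5)],
        "promoter": [SequenceRecord(g, "promoter", s) for g, s in zip(gene_ids, promoters)],
    }
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_target": [i in target_idx for i in range(config.n_genes)],
            **{f"n_planted_{cat}": planted[cat] for cat in seedscan.CATEGORIES},
            **{f"n_sites_{cat}": planted[cat] + chance[cat] for cat in seedscan.CATEGORIES},
            "regulon_member": regulon_member,
            "true_shift": true_shift,
        }
    )
    return SyntheticExperiment(sequences, expression, diff, truth, config, lexicon)


def export_experiment(exp: SyntheticExperiment, out_dir: str | Path) -> None:
    """Write FASTA per region, diff and truth TSVs, and a YAML provenance
    record; everything re-ingestible by the formats module."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for region, records in exp.sequences.items():
        write_fasta(records, out / f"{region}.fasta")
    exp.diff.to_csv(out / "diff.tsv", sep="\t", index=False)
    exp.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    provenance = {
        "config": exp.config.to_dict(),
        "mirna_id": exp.lexicon.mirna_id,
        "mature": exp.lexicon.mature,
    }
    with open(out / "simulation.yaml", "w", encoding="utf-8") as handle:
        yaml.safe_dump(provenance, handle, sort_keys=True)
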