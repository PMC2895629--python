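"""Synthetic expression data with planted, recoverable structure.

The generator emulates the statistical shape of a scaled single-channel
expression-array experiment over five pollen stages (UNM, BCP, TCP, MPG, GPG)
and three sporophytic control tissues (callus, root, leaf), three replicates
each:

* per-gene baseline abundance drawn log-normal (right-skewed, positive);
* planted gene classes — per-stage enriched, per-stage downregulated,
  pollen-preferential, constitutive, absent — with configurable fold effects;
* five temporal templates (c0–c4: rising to germination, peaking at maturity
  and germination, peaking at maturity then falling, peaking mid-development,
  highest in microspores) that shape pollen-preferential genes;
* multiplicative log-normal replicate noise with a configurable coefficient
  of variation;
* detection calls from a fixed intensity floor (a quantile of the
  absent-class distribution);
* a cluster-conditional functional-category distribution, so cluster/category
  association tests have planted signal.

Everything is deterministic given the seed.  Homolog tables (12-column BLAST
tabular) and promoter FASTA sets with a planted word are generated by
:func:`simulate_homologs` and :func:`simulate_promoters`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expr_model import (
    ALL_TISSUES,
    POLLEN_STAGES,
    SPOROPHYTIC_TISSUES,
    ExpressionDataset,
    ProbeAnnotation,
    SampleDesign,
)

PATTERN_NAMES: tuple[str, ...] = ("c0", "c1", "c2", "c3", "c4")

#: Temporal templates over (UNM, BCP, TCP, MPG, GPG), scaled to [0, 1].
#: c0 rises steadily to germinated pollen; c1 is low early and peaks jointly
#: at mature and germinated pollen; c2 rises to mature pollen then falls on
#: germination; c3 peaks at the bicellular/tricellular stages; c4 is highest
#: in microspores and falls away.
PATTERN_TEMPLATES: dict[str, np.ndarray] = {
    "c0": np.array([0.10, 0.25, 0.45, 0.70, 1.00]),
    "c1": np.array([0.05, 0.05, 0.30, 1.00, 1.00]),
    "c2": np.array([0.05, 0.30, 0.70, 1.00, 0.30]),
    "c3": np.array([0.30, 1.00, 1.00, 0.15, 0.05]),
    "c4": np.array([1.00, 0.45, 0.15, 0.05, 0.05]),
}

#: The six functional groups whose expression patterns the screens focus on.
CORE_GROUPS: tuple[str, ...] = (
    "transcription factor",
    "phytohormone",
    "cell cycle",
    "kinase",
    "defense/stress response",
    "UPS",
)

#: Remaining named groups of the 13-group catalogue, plus the three
#: bookkeeping labels excluded from functional summaries.
OTHER_GROUPS: tuple[str, ...] = (
    "metabolism",
    "transcription/RNA process",
    "transport",
    "signalling",
    "cell wall",
    "cytoskeleton",
    "vesicle trafficking",
    "unclassified",
)
EXCLUDED_GROUPS: tuple[str, ...] = ("unknown", "transposable-element")


@dataclass
class SimulationConfig:
    """Study conditions for :func:`simulate_dataset`.

    Proportions are per class; per-stage proportions apply to *each* of the
    five stages.  The remainder after all classes is flat "background".
    Folds are multiplicative effects on the log-normal baseline; ``cv`` is the
    natural-scale coefficient of variation of replicate noise.
    """

    seed: int
    n_genes: int = 5000
    stage_enriched_prop: float = 0.02
    stage_down_prop: float = 0.01
    preferential_prop: float = 0.20
    constitutive_prop: float = 0.15
    absent_prop: float = 0.10
    enrichment_fold: float = 8.0
    downregulation_fold: float = 8.0
    preferential_fold: float = 8.0
    cv: float = 0.10
    baseline_meanlog: float = math.log(500.0)
    baseline_sdlog: float = 1.0
    absent_meanlog: float = math.log(20.0)
    absent_sdlog: float = 0.5
    call_floor_quantile: float = 0.99
    category_association: float = 0.8
    n_replicates: int = 3
    pattern_mix: tuple[float, ...] = field(default=(0.2, 0.2, 0.2, 0.2, 0.2))

    def __post_init__(self) -> None:
        total = (
            5 * self.stage_enriched_prop
            + 5 * self.stage_down_prop
            + self.preferential_prop
            + self.constitutive_prop
            + self.absent_prop
        )
        props = (
            self.stage_enriched_prop,
            self.stage_down_prop,
            self.preferential_prop,
            self.constitutive_prop,
            self.absent_prop,
        )
        if any(p < 0 for p in props):
            raise ValueError("class proportions must be non-negative")
        if total > 1 + 1e-12:
            raise ValueError(f"class proportions sum to {total:.3f} > 1")
        for fold in (self.enrichment_fold, self.downregulation_fold, self.preferential_fold):
            if fold <= 1:
                raise ValueError("fold effects must exceed 1")
        if not 0 <= self.cv:
            raise ValueError("cv must be non-negative")

    @property
    def call_floor(self) -> float:
        """Intensity above which a replicate is called present (P)."""
        from scipy import stats

        return float(
            stats.lognorm.ppf(
                self.call_floor_quantile, s=self.absent_sdlog,
                scale=math.exp(self.absent_meanlog),
            )
        )


@dataclass
class TruthLabels:
    """Planted class of every synthetic gene.

    ``table`` is indexed by gene id with columns ``cls`` (background,
    constitutive, absent, pollen-preferential, enriched:<stage>,
    downregulated:<stage>), ``stage``, ``pattern`` and ``functional_group``.
    """

    table: pd.DataFrame

    def of_class(self, cls: str) -> pd.Index:
        return self.table.index[self.table["cls"] == cls]

    def enriched_at(self, stage: str) -> pd.Index:
        return self.of_class(f"enriched:{stage}")

    def downregulated_at(self, stage: str) -> pd.Index:
        return self.of_class(f"downregulated:{stage}")

    @property
    def background(self) -> pd.Index:
        return self.of_class("background")


def _noise_sigma(cv: float) -> float:
    # log-normal sigma giving natural-scale CV = cv, unit mean
    return math.sqrt(math.log(1.0 + cv * cv))


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, ProbeAnnotation, TruthLabels]:
    """Generate a dataset with planted classes, calls, annotation and truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"P{i:06d}" for i in range(n)]

    class_names = (
        [f"enriched:{s}" for s in POLLEN_STAGES]
        + [f"downregulated:{s}" for s in POLLEN_STAGES]
        + ["pollen-preferential", "constitutive", "absent", "background"]
    )
    probs = np.array(
        [config.stage_enriched_prop] * 5
        + [config.stage_down_prop] * 5
        + [config.preferential_prop, config.constitutive_prop, config.absent_prop]
    )
    probs = np.append(probs, max(0.0, 1.0 - probs.sum()))
    probs /= probs.sum()
    cls = rng.choice(len(class_names), size=n, p=probs)
    cls_labels = np.array(class_names, dtype=object)[cls]

    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, size=n)
    floor = config.call_floor
    absent_mask = cls_labels == "absent"
    # capped below the call floor so absent genes stay absent under noise
    baseline[absent_mask] = np.minimum(
        rng.lognormal(config.absent_meanlog, config.absent_sdlog,
                      size=int(absent_mask.sum())),
        0.8 * floor,
    )
    # constitutive genes must clear the call floor in every replicate
    const_mask = cls_labels == "constitutive"
    baseline[const_mask] = np.maximum(baseline[const_mask], 10.0 * floor)

    stage_idx = {s: i for i, s in enumerate(POLLEN_STAGES)}
    n_tissues = len(ALL_TISSUES)
    means = np.tile(baseline[:, None], (1, n_tissues))

    patterns = np.full(n, "none", dtype=object)
    stages = np.full(n, "none", dtype=object)
    pref_mask = cls_labels == "pollen-preferential"
    n_pref = int(pref_mask.sum())
    if n_pref:
        mix = np.asarray(config.pattern_mix, dtype=float)
        mix = mix / mix.sum()
        chosen = rng.choice(len(PATTERN_NAMES), size=n_pref, p=mix)
        patterns[pref_mask] = np.array(PATTERN_NAMES, dtype=object)[chosen]
        tmpl = np.stack([PATTERN_TEMPLATES[PATTERN_NAMES[c]] for c in chosen])
        pollen_mult = 1.0 + (config.preferential_fold - 1.0) * tmpl
        means[pref_mask, :5] = baseline[pref_mask, None] * pollen_mult

    for s, si in stage_idx.items():
        m = cls_labels == f"enriched:{s}"
        means[m, si] = baseline[m] * config.enrichment_fold
        stages[m] = s
        m = cls_labels == f"downregulated:{s}"
        means[m, si] = baseline[m] / config.downregulation_fold
        stages[m] = s

    sigma = _noise_sigma(config.cv)
    n_rep = config.n_replicates
    noise = rng.lognormal(-0.5 * sigma * sigma, sigma, size=(n, n_tissues, n_rep))
    values = means[:, :, None] * noise

    design = SampleDesign.default(n_replicates=n_rep)
    columns = design.sample_ids
    flat = values.reshape(n, n_tissues * n_rep)
    intensity = pd.DataFrame(flat, index=pd.Index(genes, name="probe_id"), columns=columns)
    calls = pd.DataFrame(
        np.where(flat > floor, "P", "A"), index=intensity.index, columns=columns
    )
    dataset = ExpressionDataset(intensity=intensity, calls=calls, design=design)

    groups = _assign_groups(rng, cls_labels, patterns, config.category_association)
    loci = _assign_loci(rng, n)
    annotation = ProbeAnnotation(
        table=pd.DataFrame(
            {"locus": loci, "functional_group": groups},
            index=intensity.index,
        )
    )
    truth = TruthLabels(
        table=pd.DataFrame(
            {"cls": cls_labels, "stage": stages, "pattern": patterns,
             "functional_group": groups},
            index=intensity.index,
        )
    )
    return dataset, annotation, truth


def _assign_groups(
    rng: np.random.Generator,
    cls_labels: np.ndarray,
    patterns: np.ndarray,
    association: float,
) -> np.ndarray:
    """Functional groups; pattern genes draw cluster-conditionally.

    A pattern-carrying gene receives its pattern's paired core group with
    probability ``association + (1 - association)/6`` and any core group
    uniformly otherwise; the χ²-based cluster-number selection therefore has
    planted signal of tunable strength.
    """
    n = len(cls_labels)
    catalogue = np.array(
        CORE_GROUPS + OTHER_GROUPS + EXCLUDED_GROUPS, dtype=object
    )
    base_p = np.concatenate([
        np.full(len(CORE_GROUPS), 0.6 / len(CORE_GROUPS)),
        np.full(len(OTHER_GROUPS), 0.33 / len(OTHER_GROUPS)),
        np.full(len(EXCLUDED_GROUPS), 0.07 / len(EXCLUDED_GROUPS)),
    ])
    base_p /= base_p.sum()
    groups = catalogue[rng.choice(len(catalogue), size=n, p=base_p)]

    has_pattern = patterns != "none"
    idx = np.flatnonzero(has_pattern)
    if idx.size:
        pat_num = np.array(
            [PATTERN_NAMES.index(p) for p in patterns[idx]]
        )
        n_core = len(CORE_GROUPS)
        linked = np.array(CORE_GROUPS, dtype=object)[pat_num % n_core]
        take_linked = rng.random(idx.size) < association
        uniform = np.array(CORE_GROUPS, dtype=object)[
            rng.integers(0, n_core, size=idx.size)
        ]
        groups[idx] = np.where(take_linked, linked, uniform)
    return groups


def _assign_loci(rng: np.random.Generator, n: int, share_rate: float = 0.1) -> np.ndarray:
    """Locus ids with ~share_rate of probes sharing the previous probe's locus."""
    loci = np.empty(n, dtype=object)
    counter = 0
    share = rng.random(n) < share_rate
    for i in range(n):
        if i > 0 and share[i]:
            loci[i] = loci[i - 1]
        else:
            loci[i] = f"LOC_Os{counter:06d}"
            counter += 1
    return loci


BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def simulate_homologs(
    truth: TruthLabels,
    conservation_rate: float,
    expressed_rate: float,
    seed: int,
    decoy_rate: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cross-species homolog search and second-species status.

    Each gene independently has a conserved counterpart with probability
    ``conservation_rate``; conserved hits get E-values below the conventional
    1e-5 cutoff.  A ``decoy_rate`` fraction of the remaining genes emit a weak
    hit (E-value ≥ 1e-5) so cutoff filtering is exercised.  Conserved subjects
    are flagged pollen-expressed with probability ``expressed_rate``; a subset
    of those are additionally pollen-preferential or stage-enriched.

    Returns ``(hits, status)`` where ``hits`` is a 12-column BLAST tabular
    DataFrame and ``status`` is indexed by subject id with boolean columns
    ``pollen_expressed``, ``pollen_preferential``, ``stage_enriched``.
    """
    for name, rate in (("conservation_rate", conservation_rate),
                       ("expressed_rate", expressed_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    genes = truth.table.index.to_numpy()
    conserved = rng.random(len(genes)) < conservation_rate

    rows: list[list[object]] = []
    subjects: list[str] = []
    counter = 0
    for gi, gene in enumerate(genes):
        if conserved[gi]:
            subject = f"AT1G{counter:05d}"
            counter += 1
            subjects.append(subject)
            evalue = 10.0 ** (-rng.uniform(6.0, 60.0))
            bits = rng.uniform(100.0, 600.0)
            rows.append(_hit_row(rng, gene, subject, evalue, bits))
            if rng.random() < 0.3:  # secondary weaker hit: best-hit must ignore it
                rows.append(_hit_row(
                    rng, gene, f"AT1G{counter:05d}",
                    10.0 ** (-rng.uniform(6.0, 20.0)), bits - rng.uniform(10.0, 60.0),
                ))
                counter += 1
        elif rng.random() < decoy_rate:
            rows.append(_hit_row(
                rng, gene, f"ATDECOY{gi:05d}",
                10.0 ** (-rng.uniform(0.0, 4.9)), rng.uniform(20.0, 50.0),
            ))
    hits = pd.DataFrame(rows, columns=BLAST_COLUMNS)

    subj = pd.Index(subjects, name="subject").unique()
    expressed = rng.random(len(subj)) < expressed_rate
    preferential = expressed & (rng.random(len(subj)) < 0.25)
    enriched = preferential & (rng.random(len(subj)) < 0.3)
    status = pd.DataFrame(
        {"pollen_expressed": expressed, "pollen_preferential": preferential,
         "stage_enriched": enriched},
        index=subj,
    )
    return hits, status


def _hit_row(
    rng: np.random.Generator, query: str, subject: str, evalue: float, bits: float
) -> list[object]:
    length = int(rng.integers(80, 500))
    qstart = int(rng.integers(1, 100))
    sstart = int(rng.integers(1, 100))
    return [
        query, subject, round(float(rng.uniform(40.0, 99.0)), 2), length,
        int(rng.integers(0, 30)), int(rng.integers(0, 5)),
        qstart, qstart + length - 1, sstart, sstart + length - 1,
        evalue, round(bits, 1),
    ]


def simulate_promoters(
    gene_sets: Mapping[str, Sequence[str]],
    planted_word: str,
    plant_rate: float | Mapping[str, float],
    length: int = 2000,
    seed: int = 0,
) -> dict[str, dict[str, str]]:
    """Random ACGT promoters with a word planted into chosen sets.

    ``plant_rate`` may be a single rate applied to every set or a mapping
    set-name → rate (missing names get 0).  The word is written over the
    background sequence at a random position in the chosen fraction of each
    set's promoters.  Deterministic given the seed.
    """
    word = planted_word.upper()
    if not 3 <= len(word) <= 8:
        raise ValueError("planted word length must be 3-8")
    if set(word) - set("ACGT"):
        raise ValueError(f"planted word has non-ACGT letters: {word}")
    if len(word) > length:
        raise ValueError("word longer than promoter")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))

    def rate_of(name: str) -> float:
        if isinstance(plant_rate, Mapping):
            return float(plant_rate.get(name, 0.0))
        return float(plant_rate)

    out: dict[str, dict[str, str]] = {}
    for name, gene_list in gene_sets.items():
        rate = rate_of(name)
        seqs: dict[str, str] = {}
        for gene in gene_list:
            letters = alphabet[rng.integers(0, 4, size=length)]
            if rng.random() < rate:
                pos = int(rng.integers(0, length - len(word) + 1))
                letters[pos:pos + len(word)] = list(word)
            seqs[str(gene)] = "".join(letters)
        out[name] = seqs
    return out
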