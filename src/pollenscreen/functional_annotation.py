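"""Functional-group distributions and term over-representation.

Two summaries: signed per-stage functional-group percentages for the
enriched/downregulated screens (positive for stage-enriched, negative for
stage-downregulated; unknown and transposable-element probes are excluded
before the percentages are formed), and a generic hypergeometric
over-representation test with Benjamini–Hochberg correction for gene → term
maps such as GO annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expr_model import ProbeAnnotation

#: Annotation groups excluded from functional summaries before percentages.
DEFAULT_EXCLUDED = ("unknown", "transposable-element")


@dataclass
class GroupDistribution:
    """Signed stage × functional-group counts and within-stage percentages."""

    counts: pd.DataFrame       # stage × group, signed counts
    percentages: pd.DataFrame  # stage × group, signed, rows sum to ±100


@dataclass
class EnrichmentRecord:
    term: str
    set_count: int        # k: genes in set annotated with term
    set_size: int         # n
    background_count: int  # K
    background_size: int   # N
    p_value: float
    adjusted_p: float


def group_distribution(
    enriched: Mapping[str, Iterable[str]],
    downregulated: Mapping[str, Iterable[str]],
    annotation: ProbeAnnotation,
    excluded_groups: tuple[str, ...] = DEFAULT_EXCLUDED,
) -> GroupDistribution:
    """Per-stage functional-group distribution of the two screens.

    Enriched counts/percentages are positive, downregulated negative;
    percentages are within each (stage, direction) over classifiable genes.
    """
    groups = annotation.functional_groups()
    keep = groups[~groups.isin(excluded_groups)]
    all_groups = sorted(keep.unique())

    def one(stage: str, gene_set: Iterable[str], sign: int) -> tuple[pd.Series, pd.Series]:
        members = [g for g in gene_set if g in keep.index]
        counts = keep.loc[members].value_counts().reindex(all_groups, fill_value=0)
        total = counts.sum()
        pct = 100.0 * counts / total if total else counts.astype(float)
        return sign * counts, sign * pct

    count_rows, pct_rows = {}, {}
    for stage, genes in enriched.items():
        c, p = one(stage, genes, +1)
        count_rows[f"{stage}:enriched"], pct_rows[f"{stage}:enriched"] = c, p
    for stage, genes in downregulated.items():
        c, p = one(stage, genes, -1)
        count_rows[f"{stage}:downregulated"], pct_rows[f"{stage}:downregulated"] = c, p
    return GroupDistribution(
        counts=pd.DataFrame(count_rows).T,
        percentages=pd.DataFrame(pct_rows).T,
    )


def term_enrichment(
    gene_set: Iterable[str],
    background_set: Iterable[str],
    gene_terms: Mapping[str, Iterable[str]],
    adjust_method: str = "fdr_bh",
) -> list[EnrichmentRecord]:
    """Hypergeometric upper-tail over-representation per term, BH-adjusted.

    With N background genes, K of them carrying a term, and a set of n genes
    of which k carry it, the p-value is P(X ≥ k) for X hypergeometric.
    Records are sorted by adjusted p then term id.
    """
    genes = set(gene_set)
    background = set(background_set)
    if not genes <= background:
        extra = sorted(genes - background)[:5]
        raise ValueError(f"gene set not contained in background, e.g. {extra}")
    n, N = len(genes), len(background)

    term_bg: dict[str, int] = {}
    term_set: dict[str, int] = {}
    for gene in background:
        for term in gene_terms.get(gene, ()):  # genes may lack annotations
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in genes:
                term_set[term] = term_set.get(term, 0) + 1

    terms = sorted(term_bg)
    pvals = [
        float(stats.hypergeom.sf(term_set.get(t, 0) - 1, N, term_bg[t], n))
        for t in terms
    ]
    if pvals:
        _, adjusted, _, _ = multipletests(pvals, method=adjust_method)
    else:
        adjusted = []
    records = [
        EnrichmentRecord(
            term=t, set_count=term_set.get(t, 0), set_size=n,
            background_count=term_bg[t], background_size=N,
            p_value=p, adjusted_p=float(a),
        )
        for t, p, a in zip(terms, pvals, adjusted)
    ]
    records.sort(key=lambda r: (r.adjusted_p, r.p_value, r.term))
    return records


def parent_chain(term: str, term_parents: Mapping[str, str]) -> list[str]:
    """Walk a child → parent table up to a root (cycle-safe)."""
    chain: list[str] = []
    seen = {term}
    current = term
    while current in term_parents:
        current = term_parents[current]
        if current in seen:
            break
        chain.append(current)
        seen.add(current)
    return chain
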