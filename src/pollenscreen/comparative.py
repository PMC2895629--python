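"""Cross-species conservation of pollen gene sets.

Consumes 12-column BLAST tabular hits (``-outfmt 6``), filters them at an
E-value cutoff (default 1e-5, strict inequality), keeps one best subject per
query (highest bit-score, ties broken by lowest E-value then subject id), and
summarises how a gene set maps onto a second species: how many genes have a
conserved counterpart, how many distinct counterpart genes that is, and what
fraction of those are pollen-expressed / pollen-preferential / stage-enriched
there.  A separate helper compares per-family transcription-factor counts
between the two species' pollen.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()

_NUMERIC = {
    "pident": float, "length": int, "mismatch": int, "gapopen": int,
    "qstart": int, "qend": int, "sstart": int, "send": int,
    "evalue": float, "bitscore": float,
}


@dataclass
class ConservationSummary:
    """Nested conservation counts with 1-decimal percentages."""

    n_input: int
    n_with_homolog: int
    n_subject_genes: int
    n_subject_pollen_expressed: int
    n_subject_pollen_preferential: int
    n_subject_stage_enriched: int
    n_subject_unknown_status: int = 0

    @property
    def pct_with_homolog(self) -> float:
        return percentage(self.n_with_homolog, self.n_input)

    @property
    def pct_subject_pollen_expressed(self) -> float:
        return percentage(self.n_subject_pollen_expressed, self.n_subject_genes)


def percentage(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Printed-style percentage: 100·k/n rounded to ``decimals``."""
    if denominator == 0:
        return 0.0
    return round(100.0 * numerator / denominator, decimals)


def read_blast_tabular(path: str | Path) -> pd.DataFrame:
    """Parse a 12-column BLAST tabular file, rejecting malformed lines."""
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                row = {
                    name: _NUMERIC.get(name, str)(value)
                    for name, value in zip(BLAST_COLUMNS, fields)
                }
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            rows.append(row)
    return pd.DataFrame(rows, columns=BLAST_COLUMNS)


def write_blast_tabular(hits: pd.DataFrame, path: str | Path) -> None:
    hits[BLAST_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def best_hits(hits: pd.DataFrame, evalue_cutoff: float = 1e-5) -> dict[str, str]:
    """One best subject per query among hits with E-value < cutoff.

    Best = highest bit-score; ties broken by lowest E-value, then
    lexicographically smallest subject id.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be positive")
    kept = hits[hits["evalue"] < evalue_cutoff]
    if kept.empty:
        return {}
    ranked = kept.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    top = ranked.drop_duplicates("qseqid", keep="first")
    return dict(zip(top["qseqid"], top["sseqid"]))


def conservation_summary(
    gene_set: Iterable[str],
    homolog_map: Mapping[str, str],
    status_table: pd.DataFrame,
) -> ConservationSummary:
    """Summarise conservation and second-species expression of a gene set.

    ``status_table`` is indexed by subject id with boolean columns
    ``pollen_expressed``, ``pollen_preferential``, ``stage_enriched``.
    Expression percentages are over *distinct* subject genes.  Subjects
    missing from the table are counted as unknown status.
    """
    genes = set(gene_set)
    mapped = {g: homolog_map[g] for g in genes if g in homolog_map}
    subjects = sorted(set(mapped.values()))
    known = [s for s in subjects if s in status_table.index]
    unknown = len(subjects) - len(known)
    if unknown:
        import warnings

        warnings.warn(f"{unknown} mapped subjects lack an expression status")
    sub = status_table.loc[known] if known else status_table.iloc[0:0]
    return ConservationSummary(
        n_input=len(genes),
        n_with_homolog=len(mapped),
        n_subject_genes=len(subjects),
        n_subject_pollen_expressed=int(sub["pollen_expressed"].sum()),
        n_subject_pollen_preferential=int(sub["pollen_preferential"].sum()),
        n_subject_stage_enriched=int(sub["stage_enriched"].sum()),
        n_subject_unknown_status=unknown,
    )


def tf_family_comparison(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
) -> pd.DataFrame:
    """Merge per-family TF counts of two species and classify families.

    Each input is indexed by family with columns ``genome`` (genes on the
    array, the percentage denominator) and ``pollen`` (pollen-expressed).
    The output carries per-species integer percentages (pollen/genome·100,
    rounded) and a ``status`` column: ``shared``, ``A-specific``,
    ``B-specific`` (pollen expression in only one species) or ``neither``.
    """
    for name, tab in (("A", table_a), ("B", table_b)):
        missing = {"genome", "pollen"} - set(tab.columns)
        if missing:
            raise ValueError(f"table {name} missing columns {sorted(missing)}")
        bad = tab.index[tab["pollen"] > tab["genome"]]
        if len(bad):
            raise ValueError(
                f"table {name}: pollen count exceeds genome count for {list(bad)}"
            )
    families = table_a.index.union(table_b.index)
    out = pd.DataFrame(index=families)
    for suffix, tab in (("A", table_a), ("B", table_b)):
        genome = tab["genome"].reindex(families, fill_value=0).astype(int)
        pollen = tab["pollen"].reindex(families, fill_value=0).astype(int)
        pct = pd.Series(0, index=families, dtype=int)
        nz = genome > 0
        pct[nz] = (100.0 * pollen[nz] / genome[nz]).round().astype(int)
        out[f"genome_{suffix}"] = genome
        out[f"pollen_{suffix}"] = pollen
        out[f"pct_{suffix}"] = pct
    in_a = out["pollen_A"] > 0
    in_b = out["pollen_B"] > 0
    out["status"] = "neither"
    out.loc[in_a & in_b, "status"] = "shared"
    out.loc[in_a & ~in_b, "status"] = "A-specific"
    out.loc[~in_a & in_b, "status"] = "B-specific"
    return out
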