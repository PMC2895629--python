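"""Core data model and I/O for pollen expression screens.

The experimental design profiled here is eight tissues, each with three
biological replicates: five pollen developmental stages — uninucleate
microspore (UNM), bicellular pollen (BCP), immature tricellular pollen (TCP),
mature pollen grain (MPG) and germinated pollen grain (GPG) — plus three
sporophytic control tissues (callus, root, leaf).  Intensities come from a
single-channel expression array; each measurement additionally carries a
detection call: P (present), A (absent) or M (missing/marginal).

This module holds the containers (:class:`SampleDesign`,
:class:`ExpressionDataset`, :class:`ProbeAnnotation`), the tab-delimited
readers, per-array trimmed-mean scaling, the presence rule used to call a gene
"expressed in a tissue", and the probe-set → locus (unigene) collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

POLLEN_STAGES: tuple[str, ...] = ("UNM", "BCP", "TCP", "MPG", "GPG")
SPOROPHYTIC_TISSUES: tuple[str, ...] = ("callus", "root", "leaf")
ALL_TISSUES: tuple[str, ...] = POLLEN_STAGES + SPOROPHYTIC_TISSUES

VALID_CALLS = frozenset("PAM")


class DatasetError(ValueError):
    """Raised when an expression dataset fails a structural validation."""


@dataclass(frozen=True)
class SampleDesign:
    """Assignment of array samples to tissues, replicates and roles.

    Parameters
    ----------
    samples
        Ordered ``(sample_id, tissue, replicate)`` triples.  Sample order is
        canonical: matrices are reordered to match it on read.
    roles
        ``tissue -> role`` with role ``"pollen-stage"`` or ``"sporophytic"``.
    """

    samples: tuple[tuple[str, str, int], ...]
    roles: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s for s, _, _ in self.samples]
        if len(set(ids)) != len(ids):
            raise DatasetError("duplicate sample ids in design")
        roles = dict(self.roles)
        if not roles:
            roles = {
                t: ("pollen-stage" if t in POLLEN_STAGES else "sporophytic")
                for t in self.tissues
            }
            object.__setattr__(self, "roles", roles)
        for tissue in self.tissues:
            if tissue not in roles:
                raise DatasetError(f"tissue {tissue!r} has no role in design")
        bad = set(roles.values()) - {"pollen-stage", "sporophytic"}
        if bad:
            raise DatasetError(f"unknown tissue roles: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _, _ in self.samples]

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, t, _ in self.samples:
            seen.setdefault(t)
        return list(seen)

    @property
    def pollen_stages(self) -> list[str]:
        return [t for t in self.tissues if self.roles[t] == "pollen-stage"]

    @property
    def sporophytic(self) -> list[str]:
        return [t for t in self.tissues if self.roles[t] == "sporophytic"]

    def samples_of(self, tissue: str) -> list[str]:
        out = [s for s, t, _ in self.samples if t == tissue]
        if not out:
            raise DatasetError(f"tissue {tissue!r} not in design")
        return out

    @classmethod
    def default(cls, n_replicates: int = 3) -> "SampleDesign":
        """The canonical 8-tissue x ``n_replicates`` design."""
        samples = tuple(
            (f"{t}_{r + 1}", t, r + 1)
            for t in ALL_TISSUES
            for r in range(n_replicates)
        )
        return cls(samples=samples)


@dataclass
class ExpressionDataset:
    """Intensity matrix, detection calls and design, kept congruent.

    ``intensity`` and ``calls`` are gene x sample DataFrames sharing index and
    columns; columns follow the design's sample order.
    """

    intensity: pd.DataFrame
    calls: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        inten, calls = self.intensity, self.calls
        if inten.shape != calls.shape:
            raise DatasetError(
                f"intensity shape {inten.shape} != calls shape {calls.shape}"
            )
        if list(inten.columns) != self.design.sample_ids:
            missing = set(self.design.sample_ids) - set(inten.columns)
            if missing:
                raise DatasetError(f"samples missing from matrix: {sorted(missing)}")
            self.intensity = inten = inten[self.design.sample_ids]
        if list(calls.columns) != self.design.sample_ids:
            missing = set(self.design.sample_ids) - set(calls.columns)
            if missing:
                raise DatasetError(f"samples missing from calls: {sorted(missing)}")
            self.calls = calls = calls[self.design.sample_ids]
        if not inten.index.equals(calls.index):
            raise DatasetError("gene ids differ between intensity and calls")
        if inten.index.has_duplicates:
            dups = inten.index[inten.index.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate gene ids: {dups[:5]}")
        values = inten.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DatasetError("non-numeric intensity values")
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            g, s = map(int, np.argwhere(bad)[0])
            raise DatasetError(
                f"invalid intensity {values[g, s]!r} at gene "
                f"{inten.index[g]!r}, sample {inten.columns[s]!r}"
            )
        call_values = set(np.unique(calls.to_numpy().astype(str)))
        if not call_values <= VALID_CALLS:
            raise DatasetError(
                f"invalid detection calls: {sorted(call_values - VALID_CALLS)}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.intensity.index

    @property
    def n_genes(self) -> int:
        return len(self.intensity)

    def tissue_medians(self, tissues: Sequence[str] | None = None) -> pd.DataFrame:
        """Per-gene median of replicate intensities, one column per tissue."""
        tissues = list(tissues) if tissues is not None else self.design.tissues
        cols = {t: self.intensity[self.design.samples_of(t)].median(axis=1) for t in tissues}
        return pd.DataFrame(cols)


@dataclass
class ProbeAnnotation:
    """Probe set -> locus (unigene), functional group, GO terms, TF family.

    Every probe maps to exactly one functional group; several probes may share
    one locus.  ``table`` is indexed by probe id with columns ``locus``,
    ``functional_group`` and optional ``go_terms`` (semicolon-joined) and
    ``tf_family``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"locus", "functional_group"}
        missing = required - set(self.table.columns)
        if missing:
            raise DatasetError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise DatasetError("duplicate probe ids in annotation")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def locus_of(self, probe: str) -> str:
        return self.table.at[probe, "locus"]

    def functional_groups(self) -> pd.Series:
        return self.table["functional_group"]


def _read_table(path: str | Path) -> pd.DataFrame:
    # first column is the id column regardless of its header name; tolerate CRLF
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str).rename_axis("probe_id")


def read_expression_dataset(
    matrix_path: str | Path,
    calls_path: str | Path,
    design_path: str | Path,
) -> ExpressionDataset:
    """Read intensity matrix, detection calls and sample design from TSV files.

    The design file has columns ``sample``, ``tissue``, ``replicate`` and
    optional ``role``; sample order in the design file is canonical.
    """
    design_df = pd.read_csv(design_path, sep="\t", dtype=str)
    required = {"sample", "tissue", "replicate"}
    if not required <= set(design_df.columns):
        raise DatasetError(
            f"design file needs columns {sorted(required)}, got {list(design_df.columns)}"
        )
    samples = tuple(
        (row["sample"], row["tissue"], int(row["replicate"]))
        for _, row in design_df.iterrows()
    )
    roles: dict[str, str] = {}
    if "role" in design_df.columns:
        roles = dict(zip(design_df["tissue"], design_df["role"]))
    design = SampleDesign(samples=samples, roles=roles)

    raw = _read_table(matrix_path)
    unknown = set(design.sample_ids) - set(raw.columns)
    if unknown:
        raise DatasetError(f"design samples absent from matrix: {sorted(unknown)}")
    try:
        intensity = raw[design.sample_ids].astype(float)
    except ValueError as exc:
        raise DatasetError(f"non-numeric intensity value: {exc}") from exc
    calls = _read_table(calls_path)
    missing = set(design.sample_ids) - set(calls.columns)
    if missing:
        raise DatasetError(f"calls file missing samples: {sorted(missing)}")
    calls = calls[design.sample_ids]
    return ExpressionDataset(intensity=intensity, calls=calls, design=design)


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    return ProbeAnnotation(table=_read_table(path))


def scale_arrays(
    dataset: ExpressionDataset,
    target_intensity: float = 500.0,
    trim: float = 0.02,
) -> ExpressionDataset:
    """Scale each array so its two-sided trimmed mean equals ``target_intensity``.

    Emulates the global scaling step of single-array normalisation: every
    sample column is multiplied by ``target / trimmed_mean(column)``, so
    within-column ratios are preserved and the operation is idempotent.

    Parameters
    ----------
    target_intensity
        Post-scaling trimmed mean of every array; default 500.
    trim
        Fraction trimmed from *each* tail before averaging; default 2%.
    """
    if target_intensity <= 0:
        raise ValueError("target_intensity must be positive")
    scaled = dataset.intensity.copy()
    for col in scaled.columns:
        tm = stats.trim_mean(scaled[col].to_numpy(), trim)
        if tm <= 0:
            raise DatasetError(f"array {col!r} has non-positive trimmed mean")
        scaled[col] *= target_intensity / tm
    return ExpressionDataset(intensity=scaled, calls=dataset.calls.copy(), design=dataset.design)


def tissue_expressed(
    dataset: ExpressionDataset,
    min_present_reps: int = 2,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x tissue expressed table under the P-call replicate rule.

    A gene counts as expressed in a tissue when at least ``min_present_reps``
    of that tissue's replicates carry a P (present) call; M and A both count
    as not-present.  Returns the boolean table and per-tissue expressed-gene
    counts (its column sums).
    """
    n_reps = min(
        len(dataset.design.samples_of(t)) for t in dataset.design.tissues
    )
    if min_present_reps > n_reps:
        raise ValueError(
            f"min_present_reps={min_present_reps} exceeds replicate count {n_reps}"
        )
    is_p = dataset.calls == "P"
    cols = {
        t: is_p[dataset.design.samples_of(t)].sum(axis=1) >= min_present_reps
        for t in dataset.design.tissues
    }
    table = pd.DataFrame(cols)
    return table, table.sum(axis=0)


def collapse_to_unigenes(
    gene_set: Iterable[str],
    annotation: ProbeAnnotation,
) -> set[str]:
    """Collapse a probe-set collection to its distinct loci (unigenes)."""
    genes = list(gene_set)
    known = annotation.table.index
    missing = [g for g in genes if g not in known]
    if missing:
        raise DatasetError(f"genes without locus mapping: {sorted(missing)[:10]}")
    loci = annotation.table.loc[genes, "locus"]
    if loci.isna().any():
        offenders = loci[loci.isna()].index.tolist()
        raise DatasetError(f"genes without locus mapping: {offenders[:10]}")
    return set(loci)
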