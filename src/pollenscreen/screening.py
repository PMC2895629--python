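"""Stage-exclusion Z-score and ratio screens for pollen transcripts.

For a focal pollen stage the statistic works on per-tissue replicate medians.
With :math:`X_i` the median of the focal stage's replicates and the reference
set the medians of every *other* tissue (the focal stage is excluded),

.. math:: Z = (X_i - \\mu) / \\mathrm{SD}

where :math:`\\mu` and SD are the mean and sample standard deviation of the
reference medians, and the relative ratio is the focal median divided by the
largest reference median.  Two reference sets are used:

* the *stage* screen compares one pollen stage against the seven remaining
  tissues (four other pollen stages + callus, root, leaf);
* the *pollen-preferential* screen compares a pollen stage against the three
  sporophytic tissues only.

Screens combine a ratio cutoff with a Z cutoff: stage-enriched
(ratio ≥ 2, Z ≥ 3.75), stage-downregulated (ratio ≤ 0.5, Z ≤ −1.7245) and
pollen-preferential (ratio ≥ 2, Z ≥ 3.19) by default.  With the
max-of-others denominator the per-stage enriched sets are pairwise disjoint:
a gene with ratio ≥ 2 at one stage has ratio ≤ 1/2 everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .expr_model import ExpressionDataset


@dataclass(frozen=True)
class ScreenConfig:
    """Cutoffs for the three screens and numerical guards.

    ``ratio_denominator`` selects the comparison statistic: ``"max"`` (most
    stringent; the default, and what makes per-stage enriched sets disjoint)
    or ``"mean"``.  ``stage_reference`` selects the reference tissues of the
    stage screen: ``"all-others"`` (default) or ``"sporophytic"``.
    ``sd_floor_scale`` is multiplied by the global mean intensity to give the
    floor applied to SD and ratio denominators.  ``log2`` applies a log2(x+1)
    transform before computing medians.
    """

    enriched_ratio: float = 2.0
    enriched_z: float = 3.75
    down_ratio: float = 0.5
    down_z: float = -1.7245
    preferential_ratio: float = 2.0
    preferential_z: float = 3.19
    sd_floor_scale: float = 1e-8
    ratio_denominator: str = "max"
    stage_reference: str = "all-others"
    log2: bool = False

    def __post_init__(self) -> None:
        if self.ratio_denominator not in ("max", "mean"):
            raise ValueError("ratio_denominator must be 'max' or 'mean'")
        if self.stage_reference not in ("all-others", "sporophytic"):
            raise ValueError("stage_reference must be 'all-others' or 'sporophytic'")
        if self.sd_floor_scale <= 0:
            raise ValueError("sd_floor_scale must be positive")


@dataclass
class ScreenResult:
    """Outcome of the four screens plus the full per-stage statistic tables.

    ``enriched`` / ``downregulated`` map stage → gene-id set;
    ``preferential_flags`` is a gene × stage boolean table whose row-wise OR
    is the ``preferential`` set; ``zscore_tables`` holds per-stage DataFrames
    with columns X_i, mu, sd, z, ratio, sd_floored.
    """

    enriched: dict[str, set[str]]
    downregulated: dict[str, set[str]]
    preferential: set[str]
    preferential_flags: pd.DataFrame
    constitutive: set[str]
    zscore_tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out = {f"enriched_{s}": len(g) for s, g in self.enriched.items()}
        out.update({f"downregulated_{s}": len(g) for s, g in self.downregulated.items()})
        out["enriched_total"] = sum(len(g) for g in self.enriched.values())
        out["preferential"] = len(self.preferential)
        out["constitutive"] = len(self.constitutive)
        return out


def _medians(dataset: ExpressionDataset, log2: bool) -> pd.DataFrame:
    med = dataset.tissue_medians()
    if log2:
        med = np.log2(med + 1.0)
    return med


def _sd_floor(dataset: ExpressionDataset, config: ScreenConfig) -> float:
    return config.sd_floor_scale * float(dataset.intensity.to_numpy().mean())


def _zscore_from_medians(
    medians: pd.DataFrame,
    focal: str,
    reference: list[str],
    eps: float,
    ratio_denominator: str,
) -> pd.DataFrame:
    if len(reference) < 2:
        raise ValueError(f"need >=2 reference tissues, got {reference}")
    x = medians[focal]
    ref = medians[reference]
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    sd_floored = sd < eps
    z = (x - mu) / sd.clip(lower=eps)
    denom = ref.max(axis=1) if ratio_denominator == "max" else mu
    ratio = x / denom.clip(lower=eps)
    return pd.DataFrame(
        {"X_i": x, "mu": mu, "sd": sd, "z": z, "ratio": ratio,
         "sd_floored": sd_floored}
    )


def stage_zscore(
    dataset: ExpressionDataset,
    focal_stage: str,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Stage-exclusion Z and ratio for one pollen stage vs all other tissues.

    Returns a per-gene DataFrame with columns ``X_i`` (median of focal
    replicates), ``mu``, ``sd`` (mean / sample SD of the reference tissue
    medians), ``z``, ``ratio`` and ``sd_floored``.
    """
    config = config or ScreenConfig()
    design = dataset.design
    if focal_stage not in design.pollen_stages:
        raise ValueError(f"{focal_stage!r} is not a pollen stage")
    if config.stage_reference == "all-others":
        reference = [t for t in design.tissues if t != focal_stage]
    else:
        reference = list(design.sporophytic)
    med = _medians(dataset, config.log2)
    return _zscore_from_medians(
        med, focal_stage, reference, _sd_floor(dataset, config),
        config.ratio_denominator,
    )


def stage_ratio(
    dataset: ExpressionDataset,
    focal_stage: str,
    config: ScreenConfig | None = None,
) -> pd.Series:
    """Relative ratio of one stage against the other tissues (see module doc)."""
    return stage_zscore(dataset, focal_stage, config)["ratio"]


def pollen_zscore(
    dataset: ExpressionDataset,
    focal_stage: str,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Z and ratio of one pollen stage against the sporophytic tissues only."""
    config = config or ScreenConfig()
    design = dataset.design
    if focal_stage not in design.pollen_stages:
        raise ValueError(f"{focal_stage!r} is not a pollen stage")
    med = _medians(dataset, config.log2)
    return _zscore_from_medians(
        med, focal_stage, list(design.sporophytic),
        _sd_floor(dataset, config), config.ratio_denominator,
    )


def pollen_ratio(
    dataset: ExpressionDataset,
    focal_stage: str,
    config: ScreenConfig | None = None,
) -> pd.Series:
    return pollen_zscore(dataset, focal_stage, config)["ratio"]


def screen_stage_enriched(
    dataset: ExpressionDataset,
    config: ScreenConfig | None = None,
) -> dict[str, set[str]]:
    """Per-stage sets of stage-enriched genes (ratio and Z above cutoffs)."""
    config = config or ScreenConfig()
    out: dict[str, set[str]] = {}
    for stage in dataset.design.pollen_stages:
        tab = stage_zscore(dataset, stage, config)
        sel = (tab["ratio"] >= config.enriched_ratio) & (tab["z"] >= config.enriched_z)
        out[stage] = set(tab.index[sel])
    return out


def screen_stage_downregulated(
    dataset: ExpressionDataset,
    config: ScreenConfig | None = None,
) -> dict[str, set[str]]:
    """Per-stage sets of stage-downregulated genes (ratio and Z below cutoffs)."""
    config = config or ScreenConfig()
    out: dict[str, set[str]] = {}
    for stage in dataset.design.pollen_stages:
        tab = stage_zscore(dataset, stage, config)
        sel = (tab["ratio"] <= config.down_ratio) & (tab["z"] <= config.down_z)
        out[stage] = set(tab.index[sel])
    return out


def screen_pollen_preferential(
    dataset: ExpressionDataset,
    config: ScreenConfig | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Pollen-preferential genes: elevated in ≥1 stage vs sporophytic tissues.

    Returns the union set and a gene × stage boolean table of per-stage
    qualification flags.
    """
    config = config or ScreenConfig()
    flags = {}
    for stage in dataset.design.pollen_stages:
        tab = pollen_zscore(dataset, stage, config)
        flags[stage] = (tab["ratio"] >= config.preferential_ratio) & (
            tab["z"] >= config.preferential_z
        )
    flag_table = pd.DataFrame(flags)
    union = set(flag_table.index[flag_table.any(axis=1)])
    return union, flag_table


def screen_constitutive(
    dataset: ExpressionDataset,
    min_present_reps: int = 2,
) -> set[str]:
    """Genes expressed (presence rule) in every pollen stage and every
    sporophytic tissue."""
    from .expr_model import tissue_expressed

    table, _ = tissue_expressed(dataset, min_present_reps=min_present_reps)
    return set(table.index[table.all(axis=1)])


def run_screens(
    dataset: ExpressionDataset,
    config: ScreenConfig | None = None,
    min_present_reps: int = 2,
) -> ScreenResult:
    """Run all four screens and collect the per-stage statistic tables."""
    config = config or ScreenConfig()
    preferential, flags = screen_pollen_preferential(dataset, config)
    tables = {s: stage_zscore(dataset, s, config) for s in dataset.design.pollen_stages}
    return ScreenResult(
        enriched=screen_stage_enriched(dataset, config),
        downregulated=screen_stage_downregulated(dataset, config),
        preferential=preferential,
        preferential_flags=flags,
        constitutive=screen_constitutive(dataset, min_present_reps),
        zscore_tables=tables,
    )


def profile_correlation(dataset: ExpressionDataset) -> pd.DataFrame:
    """Pearson correlation between per-tissue median profiles.

    Symmetric with unit diagonal; a zero-variance profile yields NaN against
    every other tissue.
    """
    if dataset.n_genes < 3:
        raise ValueError("profile correlation needs >=3 genes")
    med = dataset.tissue_medians()
    corr = med.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    zero_var = med.std(axis=0) == 0
    for t in med.columns[zero_var]:
        corr.loc[t, :] = np.nan
        corr.loc[:, t] = np.nan
        corr.loc[t, t] = 1.0
    return corr
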