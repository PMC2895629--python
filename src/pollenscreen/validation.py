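"""qRT-PCR quantification (ΔΔCt) and profile-confirmation statistics.

Relative expression follows the classic ΔΔCt convention with amplification
efficiency fixed at 2: ΔCt = Ct(target) − Ct(reference), replicate-averaged;
ΔΔCt = ΔCt(sample) − ΔCt(calibrator); relative expression = 2^(−ΔΔCt), so the
calibrator sample is 1 by construction.  Array profiles are confirmed against
qPCR profiles by Pearson correlation compared with the exact two-tailed
critical value r* = t*/√(t*² + n − 2); a profile is confirmed at a level only
for a *positive* correlation exceeding r*.  At n = 8 samples this gives
r* = 0.707 (α = 0.05) and 0.834 (α = 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QpcrTable:
    """Long-format qPCR table: gene, sample, replicate, ct_target, ct_reference."""

    data: pd.DataFrame

    REQUIRED = ("gene", "sample", "replicate", "ct_target", "ct_reference")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
        for col in ("ct_target", "ct_reference"):
            vals = self.data[col].astype(float)
            if not np.isfinite(vals).all() or (vals <= 0).any():
                raise ValueError(f"{col} must be positive and finite")


def ddct_quantify(qpcr: QpcrTable, calibrator_sample: str) -> pd.DataFrame:
    """Per-gene, per-sample relative expression by the ΔΔCt method.

    Replicate Ct values are averaged arithmetically before differencing.
    Returns a gene × sample DataFrame of 2^(−ΔΔCt); the calibrator column is
    identically 1.
    """
    df = qpcr.data.copy()
    df["dct"] = df["ct_target"].astype(float) - df["ct_reference"].astype(float)
    mean_dct = df.groupby(["gene", "sample"])["dct"].mean().unstack("sample")
    if calibrator_sample not in mean_dct.columns:
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent")
    missing = mean_dct.index[mean_dct[calibrator_sample].isna()]
    if len(missing):
        raise ValueError(
            f"calibrator {calibrator_sample!r} missing for genes {list(missing)[:5]}"
        )
    nan_cells = mean_dct.isna()
    if nan_cells.any().any():
        gene = mean_dct.index[nan_cells.any(axis=1)][0]
        sample = mean_dct.columns[nan_cells.loc[gene]][0]
        raise ValueError(f"missing Ct for gene {gene!r}, sample {sample!r}")
    ddct = mean_dct.sub(mean_dct[calibrator_sample], axis=0)
    return 2.0 ** (-ddct)


def critical_r(n: int, alpha: float) -> float:
    """Two-tailed critical Pearson correlation at sample size ``n``.

    r* = t*/√(t*² + n − 2) with t* the (1 − α/2) quantile of Student's t on
    n − 2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    t_star = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t_star / np.sqrt(t_star**2 + n - 2))


def confirm_profiles(
    array_profile: np.ndarray | pd.Series,
    qpcr_profile: np.ndarray | pd.Series,
    alpha_levels: tuple[float, ...] = (0.05, 0.01),
) -> tuple[float, float | None]:
    """Pearson r between two ordered profiles and the best confirmation tier.

    The tier is the smallest α whose critical r the *positive* correlation
    exceeds; None when no tier is passed.  A zero-variance profile returns
    (nan, None): not assessable.
    """
    x = np.asarray(array_profile, dtype=float)
    y = np.asarray(qpcr_profile, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need profiles of length >= 3")
    if x.std() == 0 or y.std() == 0:
        return float("nan"), None
    r = float(np.corrcoef(x, y)[0, 1])
    tier: float | None = None
    for alpha in sorted(alpha_levels, reverse=True):
        if r > critical_r(n, alpha):
            tier = alpha
    return r, tier


def confirmation_report(
    array_profiles: pd.DataFrame,
    qpcr_profiles: pd.DataFrame,
    alpha_levels: tuple[float, ...] = (0.05, 0.01),
) -> pd.DataFrame:
    """Confirm every shared gene; rows: gene, r, tier (NaN when none)."""
    genes = array_profiles.index.intersection(qpcr_profiles.index)
    rows = []
    for gene in genes:
        r, tier = confirm_profiles(
            array_profiles.loc[gene], qpcr_profiles.loc[gene], alpha_levels
        )
        rows.append({"gene": gene, "r": r, "tier": np.nan if tier is None else tier})
    return pd.DataFrame(rows).set_index("gene")
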