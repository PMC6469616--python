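"""Nonparametric covariate screening for per-cell respiration.

Kendall's tau-b rank correlation (tie-corrected, two-sided) between
R_sb and candidate drivers -- temperature, dissolved nutrient pools
(TDP, TDN, DOC), their molar ratios C:P and C:N, and the growth rate --
computed per subset (e.g. month x depth layer) with Bonferroni
adjustment over the test family.  The family defaults to the factors
within one subset; a global family (factors x subsets) is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, InputError, UndefinedTauError

__all__ = ["CorrelationResult", "kendall_tau_b", "screen", "DERIVED_RATIOS"]

# ratio factors derived from the dissolved pools on demand
DERIVED_RATIOS = {"cp": ("doc", "tdp"), "cn": ("doc", "tdn")}


@dataclass(frozen=True)
class CorrelationResult:
    """One factor x subset correlation against R_sb."""

    factor: str
    subset: str
    tau_b: float
    p_raw: float
    p_adjusted: float
    n: int
    significant: bool


def kendall_tau_b(x, y) -> tuple[float, float]:
    """Tie-corrected Kendall's tau-b with a two-sided p value.

    Uses exact enumeration for small untied samples and the normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise InputError("Kendall's tau requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedTauError("tau undefined when one variable is entirely tied")
    res = sps.kendalltau(x, y, variant="b", method="auto", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def screen(
    table: pd.DataFrame,
    factors: list[str],
    response: str = "r_sb",
    group_cols: list[str] | None = None,
    alpha: float = 0.05,
    family: str = "per_subset",
) -> pd.DataFrame:
    """Correlation screen of ``response`` against ``factors`` per subset.

    ``family`` sets the Bonferroni multiplier: ``"per_subset"`` adjusts
    over the factors within one subset (the default, a logged choice),
    ``"global"`` over all factor x subset tests.
    """
    if family not in ("per_subset", "global"):
        raise ConfigurationError(f"unknown Bonferroni family {family!r}")
    work = table.copy()
    for ratio, (num, den) in DERIVED_RATIOS.items():
        if ratio in factors and ratio not in work.columns:
            if num not in work.columns or den not in work.columns:
                raise ConfigurationError(f"cannot derive {ratio}: need {num} and {den}")
            work[ratio] = work[num] / work[den]
    missing = ({response} | set(factors)) - set(work.columns)
    if missing:
        raise ConfigurationError(f"table lacks columns: {sorted(missing)}")

    if group_cols:
        groups = [("|".join(map(str, key if isinstance(key, tuple) else (key,))), sub)
                  for key, sub in work.groupby(group_cols, sort=True)]
    else:
        groups = [("combined", work)]

    m_global = len(factors) * len(groups)
    rows = []
    for subset_name, sub in groups:
        m = len(factors) if family == "per_subset" else m_global
        for factor in factors:
            pair = sub[[response, factor]].dropna()
            tau, p = kendall_tau_b(pair[factor].to_numpy(), pair[response].to_numpy())
            p_adj = min(1.0, m * p)
            rows.append(
                CorrelationResult(
                    factor=factor, subset=subset_name, tau_b=tau,
                    p_raw=p, p_adjusted=p_adj, n=len(pair),
                    significant=p_adj < alpha,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
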