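"""Differential expression via the correlated two-sample t statistic.

For each gene with paired induced / uninduced replicate vectors of length
``n`` the statistic is

    t = (X1bar - X2bar) / sqrt((s1^2 + s2^2 - 2*gamma*s1*s2) / n),   df = n - 1

where ``s1^2``, ``s2^2`` are sample variances (n-1 denominator) and ``gamma``
is the sample Pearson correlation between the two replicate vectors.  The
identity ``s_d^2 = s1^2 + s2^2 - 2*gamma*s1*s2`` for the differences
``d = x1 - x2`` makes this exactly the classical paired t-test, so the
statistic is exact under paired Gaussian noise whatever the within-pair
correlation.

P-values are two-sided under the central t distribution; multiple testing is
addressed with Benjamini-Hochberg FDR (reported alongside; the default DEG
call thresholds the raw P-value strictly below ``deg_alpha``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientReplicatesError, PairingError
from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_DEG_ALPHA = 0.05

RESULT_COLUMNS = (
    "gene_id",
    "mean_induced",
    "mean_uninduced",
    "var_induced",
    "var_uninduced",
    "gamma",
    "n",
    "t_stat",
    "df",
    "p_value",
    "fdr",
    "is_deg",
    "degenerate",
)


class TComponents(NamedTuple):
    """Per-gene summary statistics feeding the correlated t."""

    mean_induced: float
    mean_uninduced: float
    var_induced: float
    var_uninduced: float
    gamma: float
    n: int
    degenerate: bool


@dataclass
class GeneTestResult:
    gene_id: str
    mean_induced: float
    mean_uninduced: float
    var_induced: float
    var_uninduced: float
    gamma: float
    n: int
    t_stat: float
    df: int
    p_value: float
    fdr: float
    is_deg: bool
    degenerate: bool = False


def _components(x1: np.ndarray, x2: np.ndarray) -> TComponents:
    n = x1.size
    m1, m2 = float(x1.mean()), float(x2.mean())
    v1 = float(x1.var(ddof=1))
    v2 = float(x2.var(ddof=1))
    if v1 > 0.0 and v2 > 0.0:
        gamma = float(np.corrcoef(x1, x2)[0, 1])
        gamma = min(1.0, max(-1.0, gamma))
    else:
        # correlation undefined when either vector is constant
        logger.debug("gamma undefined (zero variance); using gamma = 0")
        gamma = 0.0
    return TComponents(m1, m2, v1, v2, gamma, n, False)


def correlated_t(
    x_induced: Sequence[float], x_uninduced: Sequence[float]
) -> tuple[float, int, TComponents]:
    """Correlated two-sample t statistic on replicate-paired vectors.

    Returns ``(t, df, components)`` with ``df = n - 1``.  A zero denominator
    with equal means yields ``t = 0``; a zero denominator with unequal means
    is flagged degenerate (the caller assigns ``p = 0``) and a warning is
    emitted rather than returning an unqualified infinity.
    """
    x1 = np.asarray(x_induced, dtype=float)
    x2 = np.asarray(x_uninduced, dtype=float)
    if x1.ndim != 1 or x2.ndim != 1 or x1.size != x2.size:
        raise PairingError(
            f"replicate vectors must be 1-D and equal length, got "
            f"{x1.shape} and {x2.shape}"
        )
    if x1.size < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 replicates per group, got {x1.size}"
        )
    comp = _components(x1, x2)
    var_diff = comp.var_induced + comp.var_uninduced - 2.0 * comp.gamma * np.sqrt(
        comp.var_induced * comp.var_uninduced
    )
    var_diff = max(var_diff, 0.0)  # clip tiny negative rounding
    df = comp.n - 1
    delta = comp.mean_induced - comp.mean_uninduced
    if var_diff == 0.0:
        if delta == 0.0:
            return 0.0, df, comp
        warnings.warn(
            "zero variance of differences with unequal means; "
            "degenerate t (p set to 0)",
            RuntimeWarning,
            stacklevel=2,
        )
        comp = comp._replace(degenerate=True)
        return float(np.sign(delta)) * float("inf"), df, comp
    t = delta / np.sqrt(var_diff / comp.n)
    return float(t), df, comp


def t_pvalue(t_stat: float, df: int) -> float:
    """Two-sided P-value ``2 * P(T_df >= |t|)`` under the central t."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if np.isinf(t_stat):
        return 0.0
    return float(min(1.0, 2.0 * stats.t.sf(abs(t_stat), df)))


def adjust_fdr(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in input order."""
    if method != "bh":
        raise ValueError(f"unknown FDR method {method!r}")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_gene_tests(
    em: ExpressionMatrix,
    induced_samples: Sequence[str],
    uninduced_samples: Sequence[str],
    deg_alpha: float = DEFAULT_DEG_ALPHA,
    threshold_on: str = "p",
) -> pd.DataFrame:
    """Run the correlated t over every gene of one induced/uninduced contrast.

    ``induced_samples`` and ``uninduced_samples`` must be replicate-paired in
    order (replicate 1 with replicate 1, ...).  Returns a DataFrame with one
    row per gene in input order, columns :data:`RESULT_COLUMNS`.
    """
    if len(induced_samples) != len(uninduced_samples):
        raise PairingError(
            f"{len(induced_samples)} induced vs {len(uninduced_samples)} "
            "uninduced samples cannot be paired"
        )
    n = len(induced_samples)
    if n < 2:
        raise InsufficientReplicatesError(f"need >= 2 replicates, got {n}")
    x1 = em.values[list(induced_samples)].to_numpy(dtype=float)
    x2 = em.values[list(uninduced_samples)].to_numpy(dtype=float)

    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    cov = ((x1 - m1[:, None]) * (x2 - m2[:, None])).sum(axis=1) / (n - 1)
    both_pos = (v1 > 0) & (v2 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(both_pos, cov / np.sqrt(v1 * v2), 0.0)
    gamma = np.clip(gamma, -1.0, 1.0)

    var_diff = np.maximum(v1 + v2 - 2.0 * gamma * np.sqrt(v1 * v2), 0.0)
    delta = m1 - m2
    df = n - 1
    zero_var = var_diff == 0.0
    degenerate = zero_var & (delta != 0.0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero difference variance "
            "and unequal means; p set to 0 and flagged degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        t = delta / np.sqrt(var_diff / n)
    t = np.where(zero_var & (delta == 0.0), 0.0, t)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.sign(delta) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 0.0, np.minimum(p, 1.0))
    fdr = adjust_fdr(p)

    out = pd.DataFrame(
        {
            "gene_id": em.gene_ids,
            "mean_induced": m1,
            "mean_uninduced": m2,
            "var_induced": v1,
            "var_uninduced": v2,
            "gamma": gamma,
            "n": n,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "fdr": fdr,
            "degenerate": degenerate,
        }
    )
    crit = out["p_value"] if threshold_on == "p" else out["fdr"]
    out["is_deg"] = crit < deg_alpha
    return out[list(RESULT_COLUMNS)]


def call_degs(
    results: pd.DataFrame | Iterable[GeneTestResult],
    deg_alpha: float = DEFAULT_DEG_ALPHA,
    threshold_on: str = "p",
) -> set[str]:
    """Genes whose raw P (or FDR) is strictly below ``deg_alpha``."""
    if threshold_on not in ("p", "fdr"):
        raise ValueError(f"threshold_on must be 'p' or 'fdr', got {threshold_on!r}")
    if isinstance(results, pd.DataFrame):
        col = "p_value" if threshold_on == "p" else "fdr"
        return set(results.loc[results[col] < deg_alpha, "gene_id"])
    out: set[str] = set()
    for r in results:
        value = r.p_value if threshold_on == "p" else r.fdr
        if value < deg_alpha:
            out.add(r.gene_id)
    return out
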