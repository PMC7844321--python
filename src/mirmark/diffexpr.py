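"""Two-group differential expression with empirical-Bayes variance moderation.

Expression is assumed log2-scale and normalized.  For each feature g the
two-group fit gives the log fold change (difference of group means), the
pooled within-group variance s2_g on d_g = n_a + n_b - 2 degrees of freedom,
and the standard-error scale v_g = 1/n_a + 1/n_b.  Empirical-Bayes
moderation shrinks the per-feature variances toward a prior (d0, s0^2)
estimated from the whole matrix:

    s~2_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)
    t~_g  = log_fc_g / sqrt(s~2_g * v_g),   on d0 + d_g df.

The prior is fit by the method of moments on z_g = log s2_g, whose mean and
variance under the scaled-F model are expressed through digamma/trigamma
functions; d0 comes from Newton inversion of the trigamma function.  When
the observed spread of log-variances is no larger than expected from chi^2
sampling alone, d0 is unbounded: all variances collapse to s0^2 and the
moderated t is referred to the normal limit.

Raw p-values are two-sided; multiplicity is controlled per contrast by
Benjamini-Hochberg, and features with adjusted p < 0.05 are called DE.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GROUPS = ("normal", "pPCa", "mPCa")

DE_TABLE_COLUMNS = [
    "log_fc", "s2", "df_resid", "t_mod", "df_total",
    "p_raw", "p_adj", "direction", "is_de",
]


class InsufficientReplicationError(ValueError):
    """A contrast side has fewer than two samples."""


class PriorEstimationError(ValueError):
    """Too few positive-variance features to estimate the eBayes prior."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Feature x sample expression values plus per-sample group labels.

    ``values``: DataFrame, rows = feature ids, columns = sample ids (log2
    normalized intensities).  ``groups``: Series mapping sample id to one of
    ``normal``, ``pPCa``, ``mPCa``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)[:5]}")
        self.groups = self.groups.loc[self.values.columns]
        unknown = set(self.groups.unique()) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        if self.values.isna().any().any():
            raise ValueError("missing expression values")

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def write_tsv(self, values_path, groups_path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="feature")
        self.groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample")

    @classmethod
    def read_tsv(cls, values_path, groups_path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        ann = pd.read_csv(groups_path, sep="\t", index_col=0)
        return cls(values=values, groups=ann.iloc[:, 0])


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison; group_b minus group_a defines the fold change."""

    name: str
    group_a: tuple
    group_b: tuple

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValueError("contrast sides overlap")
        if not self.group_a or not self.group_b:
            raise ValueError("empty contrast side")


#: normal vs PCa — pPCa and mPCa pooled as the cancer class
OCCURRENCE = Contrast("occurrence", ("normal",), ("pPCa", "mPCa"))
#: localized vs metastatic
PROGRESSION = Contrast("progression", ("pPCa",), ("mPCa",))


def occurrence_contrast(pool_metastatic: bool = True) -> Contrast:
    """The normal-vs-cancer contrast; optionally restrict cancer to pPCa."""
    if pool_metastatic:
        return OCCURRENCE
    return Contrast("occurrence", ("normal",), ("pPCa",))


@dataclass(frozen=True)
class EBayesPrior:
    """Fitted prior: d0 (may be ``math.inf``) and s0^2, with the shrunken
    per-feature variances."""

    d0: float
    s0_sq: float
    df_resid: pd.Series
    s_tilde_sq: pd.Series


# ---------------------------------------------------------------------------
# two-group fit
# ---------------------------------------------------------------------------

def fit_two_group(matrix: ExpressionMatrix, contrast: Contrast) -> pd.DataFrame:
    """Per-feature log_fc, pooled variance s2, residual df and SE scale v.

    log_fc = mean(group_b) - mean(group_a); s2 is the pooled within-group
    variance on d_g = n_a + n_b - 2 df; v = 1/n_a + 1/n_b.
    """
    in_a = matrix.groups.isin(contrast.group_a).to_numpy()
    in_b = matrix.groups.isin(contrast.group_b).to_numpy()
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    if n_a < 2 or n_b < 2:
        raise InsufficientReplicationError(
            f"contrast {contrast.name!r}: group sizes {n_a} vs {n_b}; need >= 2 each"
        )
    x = matrix.values.to_numpy(dtype=float)
    a, b = x[:, in_a], x[:, in_b]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ss_a = ((a - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((b - mean_b[:, None]) ** 2).sum(axis=1)
    df_resid = n_a + n_b - 2
    s2 = (ss_a + ss_b) / df_resid
    return pd.DataFrame(
        {
            "log_fc": mean_b - mean_a,
            "s2": s2,
            "df_resid": float(df_resid),
            "v": 1.0 / n_a + 1.0 / n_b,
        },
        index=matrix.values.index,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < tol:
            break
    return float(x)


def fit_f_dist_prior(s2: np.ndarray, df_resid: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior to sample variances.

    Matches the mean and variance of z = log(s2) under s2 ~ s0^2 F(d_g, d0):

        E[z]   = log(s0^2) + digamma(d_g/2) - log(d_g/2)
                 - digamma(d0/2) + log(d0/2)
        Var[z] = trigamma(d_g/2) + trigamma(d0/2)

    Returns ``(d0, s0_sq)``; d0 = inf when the empirical spread of log
    variances does not exceed the chi^2 sampling component.
    """
    s2 = np.asarray(s2, dtype=float)
    df_resid = np.asarray(df_resid, dtype=float)
    ok = s2 > 0
    if ok.sum() < 10:
        raise PriorEstimationError(
            f"need >= 10 features with positive variance, got {int(ok.sum())}"
        )
    s2, df_resid = s2[ok], df_resid[ok]
    z = np.log(s2)
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    e_mean = e.mean()
    n = e.size
    e_var = ((e - e_mean) ** 2).sum() / (n - 1)
    excess = e_var - np.mean(special.polygamma(1, df_resid / 2.0))
    if excess <= 0:
        # no excess spread beyond chi^2 sampling: common variance, estimated
        # by the arithmetic mean of the sample variances
        return math.inf, float(np.mean(s2))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return d0, s0_sq


def ebayes_moderate(fit: pd.DataFrame, d0: float | None = None) -> tuple[EBayesPrior, pd.DataFrame]:
    """Moderated t statistics and raw p-values from a two-group fit.

    ``fit`` is the output of :func:`fit_two_group`.  ``d0`` overrides the
    estimated prior degrees of freedom (d0=0 recovers the ordinary pooled t;
    ``math.inf`` forces the normal limit); s0^2 is always estimated.

    Returns the fitted :class:`EBayesPrior` and a table with columns
    ``log_fc, s2, df_resid, t_mod, df_total, p_raw``.
    """
    s2 = fit["s2"].to_numpy(dtype=float)
    df_resid = fit["df_resid"].to_numpy(dtype=float)
    est_d0, s0_sq = fit_f_dist_prior(s2, df_resid)
    if d0 is None:
        d0 = est_d0

    if math.isinf(d0):
        s_tilde = np.full_like(s2, s0_sq)
        df_total = np.full_like(s2, math.inf)
    elif d0 == 0:
        s_tilde = s2.copy()
        df_total = df_resid.copy()
    else:
        s_tilde = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    log_fc = fit["log_fc"].to_numpy(dtype=float)
    v = fit["v"].to_numpy(dtype=float)
    se = np.sqrt(s_tilde * v)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log_fc / np.where(se > 0, se, 1.0), 0.0)
    if math.isinf(d0):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    # zero shrunken variance (only possible when d0 = 0 and s2 = 0): ordering
    # preserved by sending nonzero effects to p = 0
    degenerate = se == 0
    if degenerate.any():
        logger.warning("%d zero-variance feature(s) with d0=0", int(degenerate.sum()))
        p_raw = np.where(degenerate, np.where(log_fc != 0, 0.0, 1.0), p_raw)
        t_mod = np.where(degenerate, np.where(log_fc != 0, np.inf, 0.0) * np.sign(log_fc), t_mod)

    prior = EBayesPrior(
        d0=float(d0),
        s0_sq=float(s0_sq),
        df_resid=fit["df_resid"].copy(),
        s_tilde_sq=pd.Series(s_tilde, index=fit.index, name="s_tilde_sq"),
    )
    out = fit[["log_fc", "s2", "df_resid"]].copy()
    out["t_mod"] = t_mod
    out["df_total"] = df_total
    out["p_raw"] = np.clip(p_raw, 0.0, 1.0)
    return prior, out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    matrix: ExpressionMatrix,
    contrast: Contrast,
    alpha: float = 0.05,
    d0: float | None = None,
) -> pd.DataFrame:
    """Full DE table for one contrast: fit, moderate, adjust, flag.

    Columns: ``log_fc, s2, df_resid, t_mod, df_total, p_raw, p_adj,
    direction, is_de`` indexed by feature id.
    """
    fit = fit_two_group(matrix, contrast)
    _, tab = ebayes_moderate(fit, d0=d0)
    tab["p_adj"] = bh_adjust(tab["p_raw"].to_numpy())
    tab["direction"] = np.where(tab["log_fc"] >= 0, "Up", "Down")
    tab["is_de"] = (tab["p_adj"] < alpha) if alpha < 1 else True
    return tab


def collapse_probes(table: pd.DataFrame, probe_map: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probe-level DE table to genes.

    For each gene the probe with the smallest raw p is kept verbatim (ties:
    larger \\|log_fc\\|, then lexicographic probe id).  Probes missing from the
    map are dropped with a logged count.
    """
    if not probe_map:
        raise ValueError("empty probe map")
    mapped = table.index.isin(probe_map.keys())
    n_drop = int((~mapped).sum())
    if n_drop:
        logger.info("%d unmapped probe(s) dropped in collapse", n_drop)
    sub = table.loc[mapped].copy()
    sub["_gene"] = [probe_map[p] for p in sub.index]
    sub["_abs_fc"] = sub["log_fc"].abs()
    sub["_probe"] = sub.index
    sub = sub.sort_values(
        ["_gene", "p_raw", "_abs_fc", "_probe"],
        ascending=[True, True, False, True],
    )
    best = sub.drop_duplicates("_gene", keep="first").set_index("_gene")
    best.index.name = "feature"
    return best.drop(columns=["_abs_fc", "_probe"])


def select_de(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Features with adjusted p strictly below ``alpha``, mapped to Up/Down.

    ``alpha=1`` disables the filter (every feature selected), since adjusted
    p-values capped at exactly 1 would otherwise be excluded by the strict
    inequality.
    """
    hit = table["p_adj"] < alpha if alpha < 1 else pd.Series(True, index=table.index)
    return dict(zip(table.index[hit], table.loc[hit, "direction"]))


def write_de_table(table: pd.DataFrame, path) -> None:
    cols = [c for c in DE_TABLE_COLUMNS if c in table.columns]
    table[cols].to_csv(path, sep="\t", index_label="feature", float_format="%.6g")
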