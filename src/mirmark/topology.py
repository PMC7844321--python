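"""Regulator topology features and biomarker prioritization.

Each miRNA in a condition-specific network is scored by three features:

* **NTG** (number of targeted genes) — its out-degree, the classical hub
  property;
* **NSR** (number of single-line regulations) — how many of its targets have
  in-degree exactly 1 in that network, i.e. are regulated by this miRNA
  alone.  Single-line points are vulnerable: perturbing the sole regulator
  perturbs the target with no redundancy, so a high NSR marks a miRNA whose
  dysregulation can destabilize the system;
* **NSR/NTG** — the fraction of a miRNA's targets it controls exclusively.

A miRNA is *prioritized* in a network when all three of its features are
significantly high relative to the other miRNAs (one-sided Wilcoxon
signed-rank, p < 0.05).  Candidate biomarkers are the miRNAs prioritized in
both condition networks (occurrence and progression), and the shared
miRNA-mRNA regulations are the edges of those miRNAs present in both
networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import BipartiteNetwork

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ("ntg", "nsr", "ratio")


class DegenerateInputError(ValueError):
    """All differences are zero: the signed-rank test is undefined."""


class InsufficientNetworkError(ValueError):
    """Too few miRNAs in the condition network to rank against."""


def compute_ntg(network: BipartiteNetwork, mirna: str) -> int:
    """Number of targeted genes: the miRNA's out-degree."""
    return len(network.targets_of(mirna))


def compute_nsr(network: BipartiteNetwork, mirna: str) -> int:
    """Number of single-line regulations: targets whose only regulator is this miRNA."""
    return sum(
        1 for g in network.targets_of(mirna) if len(network.regulators_of(g)) == 1
    )


def compute_ratio(ntg: int, nsr: int) -> float:
    """NSR/NTG to 4 decimals; 0.0 for an isolated miRNA (NTG = 0)."""
    if not 0 <= nsr:
        raise ValueError(f"negative NSR: {nsr}")
    if nsr > ntg:
        raise ValueError(f"NSR ({nsr}) exceeds NTG ({ntg})")
    if ntg == 0:
        return 0.0
    return round(nsr / ntg, 4)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def _exact_signed_rank_pvalues(w: float, n: int) -> tuple[float, float]:
    """P(W <= w) and P(W >= w) under the exact null for untied ranks 1..n.

    Dynamic programme over the 2**n equiprobable sign assignments; W is the
    sum of positively signed ranks, an integer in [0, n(n+1)/2].
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    total = 2.0 ** n
    wi = int(round(w))
    p_less = counts[: wi + 1].sum() / total
    p_greater = counts[wi:].sum() / total
    return p_less, p_greater


def wilcoxon_signed_rank(
    differences, alternative: str = "two-sided"
) -> tuple[float, float]:
    """One-sample Wilcoxon signed-rank test on a vector of differences.

    Zero differences are dropped (Wilcoxon convention); ranks of \\|d\\| use
    midranks for ties.  The statistic W is the sum of positive-signed ranks.
    The p-value is exact (full sign-pattern enumeration) when n <= 25 and no
    absolute values are tied, otherwise a normal approximation with tie and
    continuity correction is used.

    Returns ``(W, p)``.  ``alternative`` is ``"two-sided"``, ``"greater"``
    (median difference > 0) or ``"less"``.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateInputError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n

    if n <= 25 and not has_ties:
        p_less, p_greater = _exact_signed_rank_pvalues(w, n)
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_less, p_greater))
        return w, p

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise DegenerateInputError("zero variance after tie correction")
    sd = np.sqrt(var)
    if alternative == "greater":
        p = float(stats.norm.sf((w - mean - 0.5) / sd))
    elif alternative == "less":
        p = float(stats.norm.cdf((w - mean + 0.5) / sd))
    else:
        # continuity correction shrinks |W - mean| by 0.5
        z = (w - mean - np.sign(w - mean) * 0.5) / sd
        p = float(2.0 * stats.norm.sf(abs(z)))
    return w, min(1.0, p)


# ---------------------------------------------------------------------------
# Feature tables and prioritization
# ---------------------------------------------------------------------------

def mirna_feature_table(network: BipartiteNetwork, condition: str = "") -> pd.DataFrame:
    """Per-miRNA NTG, NSR and NSR/NTG for one condition network.

    Returns a DataFrame indexed by miRNA id with columns ``condition, ntg,
    nsr, ratio`` (rows sorted by id).
    """
    rows = []
    for m in sorted(network.mirna_nodes):
        ntg = compute_ntg(network, m)
        nsr = compute_nsr(network, m)
        rows.append((m, condition, ntg, nsr, compute_ratio(ntg, nsr)))
    df = pd.DataFrame(rows, columns=["mirna", "condition", "ntg", "nsr", "ratio"])
    return df.set_index("mirna")


def _loo_pvalue(values: np.ndarray, i: int) -> float:
    """Leave-one-out signed-rank p that miRNA i's value is high.

    Tests the differences {x_j - x_i : j != i} against a median of zero,
    one-sided "less": small p means the focal value exceeds the network's
    typical value.  All-zero differences (everyone identical) give p = 1.
    """
    diffs = np.delete(values, i) - values[i]
    if not np.any(diffs != 0):
        return 1.0
    _, p = wilcoxon_signed_rank(diffs, alternative="less")
    return p


def _percentile_pvalue(values: np.ndarray, i: int) -> float:
    """Empirical upper-tail percentile of value i among the others."""
    others = np.delete(values, i)
    return (np.sum(others >= values[i]) + 1) / (others.size + 1)


def prioritize(
    features: pd.DataFrame,
    alpha: float = 0.05,
    variant: str = "loo-signed-rank",
) -> pd.DataFrame:
    """Flag miRNAs whose NTG, NSR and NSR/NTG are all significantly high.

    ``features`` is the output of :func:`mirna_feature_table`.  For each
    miRNA and each feature a one-sided test against the remaining miRNAs is
    run (``variant="loo-signed-rank"``: leave-one-out Wilcoxon signed-rank;
    ``variant="percentile"``: empirical percentile rule).  A miRNA is
    prioritized iff all three p-values are below ``alpha`` (no correction
    across miRNAs at this stage; multiplicity is handled only in the DE
    stage).

    Returns a copy with columns ``p_ntg, p_nsr, p_ratio, prioritized``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if len(features) < 10:
        raise InsufficientNetworkError(
            f"need >= 10 miRNAs to prioritize, got {len(features)}"
        )
    if variant == "loo-signed-rank":
        pfun = _loo_pvalue
    elif variant == "percentile":
        pfun = _percentile_pvalue
    else:
        raise ValueError(f"unknown prioritization variant: {variant!r}")

    out = features.copy()
    for col in FEATURE_COLUMNS:
        values = features[col].to_numpy(dtype=float)
        out[f"p_{col}"] = [pfun(values, i) for i in range(values.size)]
    out["prioritized"] = (
        (out["p_ntg"] < alpha) & (out["p_nsr"] < alpha) & (out["p_ratio"] < alpha)
    )
    return out


def prioritized_set(features: pd.DataFrame) -> set:
    """The miRNA ids flagged by :func:`prioritize`."""
    return set(features.index[features["prioritized"]])


def intersect_conditions(occurrence_set, progression_set) -> list:
    """miRNAs prioritized in both condition networks, sorted for determinism."""
    return sorted(set(occurrence_set) & set(progression_set))


@dataclass(frozen=True)
class BiomarkerResult:
    """Cross-condition biomarker nomination.

    ``shared_regulations`` holds the miRNA->mRNA edges incident to shared
    miRNAs; under the default ``"intersection"`` mode an edge must be present
    in both condition networks, under ``"union"`` in at least one.
    """

    occurrence_prioritized: tuple
    progression_prioritized: tuple
    shared_mirnas: tuple
    shared_regulations: tuple
    mode: str = "intersection"

    @property
    def n_target_mrnas(self) -> int:
        return len({g for _, g in self.shared_regulations})

    def to_dict(self) -> dict:
        return {
            "occurrence_prioritized": list(self.occurrence_prioritized),
            "progression_prioritized": list(self.progression_prioritized),
            "shared_mirnas": list(self.shared_mirnas),
            "n_shared_regulations": len(self.shared_regulations),
            "n_target_mrnas": self.n_target_mrnas,
            "shared_regulations": [list(e) for e in self.shared_regulations],
            "mode": self.mode,
        }


def shared_regulations(
    occ_net: BipartiteNetwork,
    prog_net: BipartiteNetwork,
    shared_mirnas,
    mode: str = "intersection",
) -> list:
    """Edges of the shared miRNAs, sorted.

    ``mode="intersection"`` (default) requires an edge in both networks;
    ``mode="union"`` collects biomarker-incident edges from either.
    """
    shared = set(shared_mirnas)
    if not shared:
        raise ValueError("shared miRNA set is empty")
    if mode == "intersection":
        pool = occ_net.edges & prog_net.edges
    elif mode == "union":
        pool = occ_net.edges | prog_net.edges
    else:
        raise ValueError(f"unknown shared-regulation mode: {mode!r}")
    return sorted((m, g) for m, g in pool if m in shared)


def nominate_biomarkers(
    occ_features: pd.DataFrame,
    prog_features: pd.DataFrame,
    occ_net: BipartiteNetwork,
    prog_net: BipartiteNetwork,
    mode: str = "intersection",
) -> BiomarkerResult:
    """Intersect per-condition prioritized sets and extract shared regulations."""
    occ_set = prioritized_set(occ_features)
    prog_set = prioritized_set(prog_features)
    shared = intersect_conditions(occ_set, prog_set)
    edges = shared_regulations(occ_net, prog_net, shared, mode=mode) if shared else []
    return BiomarkerResult(
        occurrence_prioritized=tuple(sorted(occ_set)),
        progression_prioritized=tuple(sorted(prog_set)),
        shared_mirnas=tuple(shared),
        shared_regulations=tuple(edges),
        mode=mode,
    )
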