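"""Synthetic expression matrices and reference networks with planted truth.

The generator emulates the statistical setting of a three-group prostate
microarray study (normal, localized primary tumour ``pPCa``, metastatic
tumour ``mPCa``) together with a global miRNA->mRNA reference map, so the
whole pipeline is testable without any external download.

Planted structure
-----------------
* A subset of features is differentially expressed per contrast: occurrence
  (normal vs pooled PCa) and/or progression (pPCa vs mPCa), with a +-
  ``effect_size`` mean shift on the log2 scale and Gaussian within-group
  noise.
* ``n_planted_biomarkers`` miRNAs are DE in *both* contrasts and each
  receives ``singleline_boost`` exclusive targets in the reference network —
  mRNAs regulated by that miRNA alone, themselves DE in both contrasts so
  exclusivity survives condition-network extraction.  These miRNAs are what
  the pipeline should recover as shared biomarkers.
* All remaining miRNA-mRNA pairs get independent background edges with
  probability ``edge_density`` (exclusive-target mRNAs excluded from the
  background draw, which is what guarantees in-degree 1).

Occurrence effects shift both tumour groups equally relative to normal.
Progression effects shift mPCa relative to pPCa, with the two tumour-group
shifts weighted so the pooled tumour mean stays at the occurrence level:
a progression-only feature is exactly null for the pooled occurrence
contrast, keeping the two ground-truth DE sets well-defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .network import BipartiteNetwork


class ConfigurationError(ValueError):
    """Inconsistent synthetic-data configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults follow the emulated study: miRNA arm 28/99/14 and mRNA arm
    29/131/19 samples (normal/pPCa/mPCa); 150 miRNAs x 1200 mRNAs; a quarter
    of features DE per contrast; 9 planted biomarker miRNAs, each with 15
    exclusive targets; log2 effect size 2.0 over unit noise; background edge
    density 0.02.
    """

    n_normal_mirna: int = 28
    n_ppca_mirna: int = 99
    n_mpca_mirna: int = 14
    n_normal_mrna: int = 29
    n_ppca_mrna: int = 131
    n_mpca_mrna: int = 19
    n_mirna: int = 150
    n_mrna: int = 1200
    n_planted_biomarkers: int = 9
    de_fraction: float = 0.25
    effect_size: float = 2.0
    noise_sd: float = 1.0
    edge_density: float = 0.02
    singleline_boost: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_normal_mirna, self.n_ppca_mirna, self.n_mpca_mirna,
            self.n_normal_mrna, self.n_ppca_mrna, self.n_mpca_mrna,
            self.n_mirna, self.n_mrna,
        )
        if any(c < 1 for c in counts):
            raise ConfigurationError("all sample/feature counts must be >= 1")
        if not 0 < self.de_fraction < 1:
            raise ConfigurationError("de_fraction must be in (0, 1)")
        if not 0 <= self.edge_density < 1:
            raise ConfigurationError("edge_density must be in [0, 1)")
        if self.singleline_boost < 0:
            raise ConfigurationError("singleline_boost must be >= 0")
        if self.n_planted_biomarkers < 0:
            raise ConfigurationError("n_planted_biomarkers must be >= 0")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ConfigurationError("effect_size and noise_sd must be >= 0")

    @property
    def mirna_ids(self) -> list:
        return [f"mir-{i:04d}" for i in range(self.n_mirna)]

    @property
    def mrna_ids(self) -> list:
        return [f"gene-{i:04d}" for i in range(self.n_mrna)]


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure: per-contrast DE sets (with signed directions),
    biomarker miRNAs and their exclusive-target map."""

    planted_de_mirnas_occurrence: frozenset
    planted_de_mirnas_progression: frozenset
    planted_de_mrnas_occurrence: frozenset
    planted_de_mrnas_progression: frozenset
    planted_biomarkers: frozenset
    planted_exclusive_targets: dict
    # feature id -> +1/-1 sign of the planted shift, per feature class/contrast
    mirna_sign_occurrence: dict = field(default_factory=dict)
    mirna_sign_progression: dict = field(default_factory=dict)
    mrna_sign_occurrence: dict = field(default_factory=dict)
    mrna_sign_progression: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.planted_biomarkers <= self.planted_de_mirnas_occurrence:
            raise ConfigurationError("biomarkers must be DE in the occurrence contrast")
        if not self.planted_biomarkers <= self.planted_de_mirnas_progression:
            raise ConfigurationError("biomarkers must be DE in the progression contrast")
        seen: set = set()
        for targets in self.planted_exclusive_targets.values():
            if seen & set(targets):
                raise ConfigurationError("exclusive-target sets overlap")
            seen |= set(targets)

    def to_json(self, path) -> None:
        payload = {
            "planted_de_mirnas_occurrence": sorted(self.planted_de_mirnas_occurrence),
            "planted_de_mirnas_progression": sorted(self.planted_de_mirnas_progression),
            "planted_de_mrnas_occurrence": sorted(self.planted_de_mrnas_occurrence),
            "planted_de_mrnas_progression": sorted(self.planted_de_mrnas_progression),
            "planted_biomarkers": sorted(self.planted_biomarkers),
            "planted_exclusive_targets": {
                m: sorted(t) for m, t in sorted(self.planted_exclusive_targets.items())
            },
            "mirna_sign_occurrence": dict(sorted(self.mirna_sign_occurrence.items())),
            "mirna_sign_progression": dict(sorted(self.mirna_sign_progression.items())),
            "mrna_sign_occurrence": dict(sorted(self.mrna_sign_occurrence.items())),
            "mrna_sign_progression": dict(sorted(self.mrna_sign_progression.items())),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            planted_de_mirnas_occurrence=frozenset(d["planted_de_mirnas_occurrence"]),
            planted_de_mirnas_progression=frozenset(d["planted_de_mirnas_progression"]),
            planted_de_mrnas_occurrence=frozenset(d["planted_de_mrnas_occurrence"]),
            planted_de_mrnas_progression=frozenset(d["planted_de_mrnas_progression"]),
            planted_biomarkers=frozenset(d["planted_biomarkers"]),
            planted_exclusive_targets={
                m: frozenset(t) for m, t in d["planted_exclusive_targets"].items()
            },
            mirna_sign_occurrence={k: int(v) for k, v in d["mirna_sign_occurrence"].items()},
            mirna_sign_progression={k: int(v) for k, v in d["mirna_sign_progression"].items()},
            mrna_sign_occurrence={k: int(v) for k, v in d["mrna_sign_occurrence"].items()},
            mrna_sign_progression={k: int(v) for k, v in d["mrna_sign_progression"].items()},
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _pick_de_sets(
    rng: np.random.Generator, ids: list, n_de: int, forced: list
) -> tuple[set, set]:
    """Two per-contrast DE sets of size n_de each, both containing ``forced``."""
    if n_de < len(forced):
        raise ConfigurationError(
            f"de_fraction too small: {n_de} DE slots for {len(forced)} forced features"
        )
    free = [i for i in ids if i not in set(forced)]
    occ = set(forced) | set(map(str, rng.choice(free, size=n_de - len(forced), replace=False)))
    prog = set(forced) | set(map(str, rng.choice(free, size=n_de - len(forced), replace=False)))
    return occ, prog


def generate_reference_network(
    config: SyntheticConfig,
) -> tuple[BipartiteNetwork, GroundTruth]:
    """Reference map plus the planted ground truth.

    Background edges are independent Bernoulli(``edge_density``) over all
    miRNA-mRNA pairs except those involving a reserved exclusive-target mRNA;
    each planted biomarker then gets its ``singleline_boost`` exclusive
    targets, so their reference in-degree is exactly 1.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    mirnas, mrnas = config.mirna_ids, config.mrna_ids

    biomarkers = sorted(map(str, rng.choice(mirnas, size=config.n_planted_biomarkers, replace=False))) \
        if config.n_planted_biomarkers else []
    n_exclusive = config.n_planted_biomarkers * config.singleline_boost

    n_de_mirna = round(config.de_fraction * config.n_mirna)
    n_de_mrna = round(config.de_fraction * config.n_mrna)
    if n_exclusive > n_de_mrna:
        raise ConfigurationError(
            f"{n_exclusive} exclusive targets exceed the per-contrast DE-mRNA pool ({n_de_mrna})"
        )

    # exclusive targets: disjoint blocks, forced DE in both mRNA contrasts
    exclusive_pool = sorted(
        map(str, rng.choice(mrnas, size=n_exclusive, replace=False))
    ) if n_exclusive else []
    exclusive_map = {
        m: frozenset(
            exclusive_pool[i * config.singleline_boost:(i + 1) * config.singleline_boost]
        )
        for i, m in enumerate(biomarkers)
    }

    occ_mir, prog_mir = _pick_de_sets(rng, mirnas, n_de_mirna, biomarkers)
    occ_mrna, prog_mrna = _pick_de_sets(rng, mrnas, n_de_mrna, exclusive_pool)

    # background edges, excluding reserved exclusive-target columns
    reserved = set(exclusive_pool)
    open_mrnas = [g for g in mrnas if g not in reserved]
    edges: set = set()
    if config.edge_density > 0 and open_mrnas:
        mask = rng.random((config.n_mirna, len(open_mrnas))) < config.edge_density
        mi, gi = np.nonzero(mask)
        edges = {(mirnas[i], open_mrnas[j]) for i, j in zip(mi, gi)}
    for m, targets in exclusive_map.items():
        edges.update((m, g) for g in targets)

    network = BipartiteNetwork.from_edges(
        edges, mirna_nodes=mirnas, mrna_nodes=mrnas
    )

    def signs(ids_in: set) -> dict:
        ordered = sorted(ids_in)
        s = rng.choice([-1, 1], size=len(ordered))
        return {i: int(v) for i, v in zip(ordered, s)}

    truth = GroundTruth(
        planted_de_mirnas_occurrence=frozenset(occ_mir),
        planted_de_mirnas_progression=frozenset(prog_mir),
        planted_de_mrnas_occurrence=frozenset(occ_mrna),
        planted_de_mrnas_progression=frozenset(prog_mrna),
        planted_biomarkers=frozenset(biomarkers),
        planted_exclusive_targets=exclusive_map,
        mirna_sign_occurrence=signs(occ_mir),
        mirna_sign_progression=signs(prog_mir),
        mrna_sign_occurrence=signs(occ_mrna),
        mrna_sign_progression=signs(prog_mrna),
    )
    return network, truth


def _build_matrix(
    rng: np.random.Generator,
    feature_ids: list,
    prefix: str,
    n_normal: int,
    n_ppca: int,
    n_mpca: int,
    occ_set: frozenset,
    prog_set: frozenset,
    occ_sign: dict,
    prog_sign: dict,
    effect: float,
    noise_sd: float,
) -> ExpressionMatrix:
    n_tumour = n_ppca + n_mpca
    samples = [f"{prefix}-s{i:03d}" for i in range(n_normal + n_tumour)]
    groups = pd.Series(
        ["normal"] * n_normal + ["pPCa"] * n_ppca + ["mPCa"] * n_mpca,
        index=samples, name="group",
    )
    # group-mean matrix: baseline 0 on the log2 scale
    mu = np.zeros((len(feature_ids), 3))  # columns: normal, pPCa, mPCa
    w_p = n_mpca / n_tumour  # progression tilt weights keep the pooled tumour mean fixed
    for i, f in enumerate(feature_ids):
        if f in occ_set:
            shift = occ_sign[f] * effect
            mu[i, 1] += shift
            mu[i, 2] += shift
        if f in prog_set:
            tilt = prog_sign[f] * effect
            mu[i, 1] -= tilt * w_p
            mu[i, 2] += tilt * (1.0 - w_p)
    per_sample_mu = np.concatenate(
        [
            np.repeat(mu[:, [0]], n_normal, axis=1),
            np.repeat(mu[:, [1]], n_ppca, axis=1),
            np.repeat(mu[:, [2]], n_mpca, axis=1),
        ],
        axis=1,
    )
    values = per_sample_mu + rng.normal(0.0, noise_sd, size=per_sample_mu.shape)
    df = pd.DataFrame(values, index=feature_ids, columns=samples)
    return ExpressionMatrix(values=df, groups=groups)


def generate_expression(
    config: SyntheticConfig, truth: GroundTruth
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """miRNA and mRNA expression matrices consistent with the planted truth."""
    known = set(config.mirna_ids) | set(config.mrna_ids)
    planted = (
        truth.planted_de_mirnas_occurrence | truth.planted_de_mirnas_progression
        | truth.planted_de_mrnas_occurrence | truth.planted_de_mrnas_progression
    )
    if not planted <= known:
        raise ConfigurationError("truth refers to feature ids absent from the config")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    mirna = _build_matrix(
        rng, config.mirna_ids, "mir",
        config.n_normal_mirna, config.n_ppca_mirna, config.n_mpca_mirna,
        truth.planted_de_mirnas_occurrence, truth.planted_de_mirnas_progression,
        truth.mirna_sign_occurrence, truth.mirna_sign_progression,
        config.effect_size, config.noise_sd,
    )
    mrna = _build_matrix(
        rng, config.mrna_ids, "rna",
        config.n_normal_mrna, config.n_ppca_mrna, config.n_mpca_mrna,
        truth.planted_de_mrnas_occurrence, truth.planted_de_mrnas_progression,
        truth.mrna_sign_occurrence, truth.mrna_sign_progression,
        config.effect_size, config.noise_sd,
    )
    return mirna, mrna


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, BipartiteNetwork, GroundTruth]:
    """Convenience: reference network, truth and both expression matrices."""
    network, truth = generate_reference_network(config)
    mirna, mrna = generate_expression(config, truth)
    return mirna, mrna, network, truth


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)
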