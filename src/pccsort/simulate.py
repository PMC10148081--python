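"""Synthetic particle generator emulating symmetry-expanded classification output.

Produces, for each simulated particle, a true six-site occupancy pattern
drawn from a binding model, then six symmetry-expanded records — one per
site — carrying an ``alpha_present`` / ``alpha_missing`` class label that is
correct up to an optional per-site misclassification probability.  Only the
classification *output* is simulated; no images, projections or noise maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .symmetry import N_SITES, OccupancyConfig

__all__ = [
    "ALPHA_PRESENT",
    "ALPHA_MISSING",
    "BindingModel",
    "ErrorModel",
    "GroundTruth",
    "ExpandedRecord",
    "sample_true_occupancy",
    "apply_classification_error",
    "truth_formula_counts",
]

ALPHA_PRESENT = "alpha_present"
ALPHA_MISSING = "alpha_missing"


@dataclass(frozen=True)
class BindingModel:
    """Stationary occupancy model for the six sites.

    Exactly one of two modes:

    * ``independent_site`` — every site occupied independently with
      probability ``p`` (free-ligand concentration assumed constant, so a
      single per-site propensity suffices).
    * ``explicit_distribution`` — the occupancy count n is drawn from
      ``weights`` (7 values over n = 0..6), then a configuration is drawn
      uniformly among the C(6, n) patterns with that count.
    """

    mode: str
    p: float | None = None
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode == "independent_site":
            if self.p is None or self.weights is not None:
                raise ValueError("independent_site mode requires p and no weights")
            if not 0.0 <= self.p <= 1.0:
                raise ValueError(f"p must be in [0, 1], got {self.p}")
        elif self.mode == "explicit_distribution":
            if self.weights is None or self.p is not None:
                raise ValueError("explicit_distribution mode requires weights and no p")
            w = tuple(float(x) for x in self.weights)
            if len(w) != N_SITES + 1:
                raise ValueError(f"expected 7 weights, got {len(w)}")
            if any(x < 0 for x in w):
                raise ValueError("weights must be nonnegative")
            if not math.isclose(sum(w), 1.0, rel_tol=0, abs_tol=1e-9):
                raise ValueError(f"weights must sum to 1, got {sum(w)}")
            object.__setattr__(self, "weights", w)
        else:
            raise ValueError(f"unknown binding model mode {self.mode!r}")

    @classmethod
    def independent(cls, p: float) -> "BindingModel":
        return cls(mode="independent_site", p=p)

    @classmethod
    def explicit(cls, weights: Sequence[float]) -> "BindingModel":
        return cls(mode="explicit_distribution", weights=tuple(weights))


@dataclass(frozen=True)
class ErrorModel:
    """Per-site, per-copy misclassification probabilities.

    ``eps_fn`` — occupied site labelled alpha_missing (false negative);
    ``eps_fp`` — unoccupied site labelled alpha_present (false positive).
    Defaults are zero: the noiseless case reproduces an error-free
    focused classification.
    """

    eps_fn: float = 0.0
    eps_fp: float = 0.0

    def __post_init__(self) -> None:
        for name, v in (("eps_fn", self.eps_fn), ("eps_fp", self.eps_fp)):
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")


@dataclass(frozen=True)
class GroundTruth:
    particle_id: int
    true_config: OccupancyConfig


@dataclass(frozen=True)
class ExpandedRecord:
    """One symmetry-expanded copy of a particle.

    ``copy_index`` k interrogates site flat_index = k: the focused mask
    sees exactly one fixed site per expanded copy.
    """

    particle_id: int
    copy_index: int
    class_label: str

    def __post_init__(self) -> None:
        if not 0 <= self.copy_index < N_SITES:
            raise ValueError(f"copy_index must be in 0..5, got {self.copy_index}")
        if self.class_label not in (ALPHA_PRESENT, ALPHA_MISSING):
            raise ValueError(f"unknown class label {self.class_label!r}")


def sample_true_occupancy(
    model: BindingModel, n_particles: int, seed: int
) -> list[GroundTruth]:
    """Draw true occupancy patterns for ``n_particles`` particles.

    Deterministic for a given (model, n_particles, seed).
    """
    if n_particles < 1:
        raise ValueError(f"n_particles must be >= 1, got {n_particles}")
    rng = np.random.default_rng(seed)
    if model.mode == "independent_site":
        occ = rng.random((n_particles, N_SITES)) < model.p
    else:
        n_per_particle = rng.choice(N_SITES + 1, size=n_particles, p=model.weights)
        occ = np.zeros((n_particles, N_SITES), dtype=bool)
        for i, n in enumerate(n_per_particle):
            # uniform over the C(6, n) patterns with occupancy count n
            sites = rng.permutation(N_SITES)[:n]
            occ[i, sites] = True
    return [
        GroundTruth(particle_id=i, true_config=OccupancyConfig(tuple(occ[i])))
        for i in range(n_particles)
    ]


def apply_classification_error(
    truth: Sequence[GroundTruth], err: ErrorModel, seed: int
) -> list[ExpandedRecord]:
    """Expand each particle into six labelled records with optional label noise.

    Occupied sites flip to alpha_missing with probability ``eps_fn``,
    unoccupied sites flip to alpha_present with probability ``eps_fp``,
    independently per record.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    occ = np.array([gt.true_config.bits for gt in truth], dtype=bool)
    u = rng.random(occ.shape)
    # observed "alpha present" label after the two one-sided flips
    observed = np.where(occ, u >= err.eps_fn, u < err.eps_fp)
    records: list[ExpandedRecord] = []
    for row, gt in enumerate(truth):
        for site in range(N_SITES):
            records.append(
                ExpandedRecord(
                    particle_id=gt.particle_id,
                    copy_index=site,
                    class_label=ALPHA_PRESENT if observed[row, site] else ALPHA_MISSING,
                )
            )
    return records


def truth_formula_counts(truth: Sequence[GroundTruth]) -> np.ndarray:
    """Ground-truth histogram of occupancy counts n = 0..6 (oracle for sorting)."""
    counts = np.zeros(N_SITES + 1, dtype=np.int64)
    for gt in truth:
        counts[gt.true_config.n_alpha] += 1
    return counts
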