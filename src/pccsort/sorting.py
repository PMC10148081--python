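"""The sorting method: from expanded-copy class labels to a formula distribution.

Each particle has six symmetry-expanded copies, one per binding site.  The
number of copies in the alpha_missing class equals the number of unoccupied
sites, so ``formula_n = 6 - k_missing`` assigns the particle its oligomeric
formula.  Tallying over particles yields the formula frequency distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import binom

from .simulate import ALPHA_MISSING, ALPHA_PRESENT, ErrorModel, ExpandedRecord
from .symmetry import N_SITES

__all__ = [
    "MalformedParticleError",
    "ParticleAssignment",
    "FormulaDistribution",
    "count_missing_per_particle",
    "formula_distribution",
    "mixing_matrix",
    "correct_misclassification",
]

logger = logging.getLogger(__name__)

# condition number above which the misclassification mixing matrix is
# treated as numerically singular
CONDITION_LIMIT = 1e8


class MalformedParticleError(ValueError):
    """A particle's record set violates the 6-records/6-distinct-copies contract."""


@dataclass(frozen=True)
class ParticleAssignment:
    particle_id: int
    k_missing: int
    formula_n: int

    def __post_init__(self) -> None:
        if self.formula_n + self.k_missing != N_SITES:
            raise ValueError("formula_n + k_missing must equal 6")


@dataclass(frozen=True)
class FormulaDistribution:
    """Counts N_n of particles assigned formula alpha_n beta_6, n = 0..6.

    Counts are integral after sorting but may be real-valued after
    misclassification correction (the correction is an estimator).
    """

    counts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != N_SITES + 1:
            raise ValueError(f"expected 7 counts, got {len(self.counts)}")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", tuple(float(c) for c in self.counts))

    @property
    def total(self) -> float:
        return sum(self.counts)

    @property
    def fractions(self) -> tuple[float, ...]:
        t = self.total
        if t == 0:
            raise ValueError("empty distribution has no fractions")
        return tuple(c / t for c in self.counts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


def count_missing_per_particle(
    records: Sequence[ExpandedRecord], skip_malformed: bool = False
) -> list[ParticleAssignment]:
    """Count alpha_missing labels among each particle's six expanded copies.

    Every particle must contribute exactly six records with distinct copy
    indices 0..5; violations raise :class:`MalformedParticleError` (or are
    dropped with a warning when ``skip_malformed`` is set — silent data
    loss would bias the downstream equilibrium statistics, so the drop is
    always logged).
    """
    by_particle: dict[int, list[ExpandedRecord]] = {}
    for rec in records:
        if rec.class_label not in (ALPHA_PRESENT, ALPHA_MISSING):
            raise MalformedParticleError(
                f"particle {rec.particle_id}: unknown class label {rec.class_label!r}"
            )
        by_particle.setdefault(rec.particle_id, []).append(rec)

    assignments: list[ParticleAssignment] = []
    n_skipped = 0
    for pid in sorted(by_particle):
        recs = by_particle[pid]
        problem = None
        if len(recs) != N_SITES:
            problem = f"has {len(recs)} records, expected {N_SITES}"
        elif {r.copy_index for r in recs} != set(range(N_SITES)):
            problem = "duplicate or missing copy_index values"
        if problem is not None:
            if skip_malformed:
                n_skipped += 1
                continue
            raise MalformedParticleError(f"particle {pid}: {problem}")
        k_missing = sum(r.class_label == ALPHA_MISSING for r in recs)
        assignments.append(
            ParticleAssignment(
                particle_id=pid, k_missing=k_missing, formula_n=N_SITES - k_missing
            )
        )
    if n_skipped:
        msg = f"skipped {n_skipped} malformed particle(s)"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return assignments


def formula_distribution(
    assignments: Sequence[ParticleAssignment],
) -> FormulaDistribution:
    """Histogram of formula assignments over n = 0..6."""
    if not assignments:
        raise ValueError("cannot build a distribution from zero assignments")
    counts = [0] * (N_SITES + 1)
    for a in assignments:
        counts[a.formula_n] += 1
    return FormulaDistribution(counts=tuple(counts))


def mixing_matrix(err: ErrorModel) -> np.ndarray:
    """7x7 matrix M with M[k_obs, n_true] = P(k_obs missing labels | n_true occupied).

    With n occupied sites, the observed missing count is the sum of a
    Binomial(n, eps_fn) (occupied sites mislabelled missing) and a
    Binomial(6 - n, 1 - eps_fp) (unoccupied sites correctly labelled
    missing); M's columns are the convolution of the two.
    """
    m = np.zeros((N_SITES + 1, N_SITES + 1))
    for n_true in range(N_SITES + 1):
        fn_part = binom.pmf(np.arange(n_true + 1), n_true, err.eps_fn)
        fp_part = binom.pmf(
            np.arange(N_SITES - n_true + 1), N_SITES - n_true, 1.0 - err.eps_fp
        )
        m[:, n_true] = np.convolve(fn_part, fp_part)
    return m


def correct_misclassification(
    dist: FormulaDistribution, err: ErrorModel
) -> FormulaDistribution:
    """Deconvolve per-site label noise out of an observed formula distribution.

    Solves M x = observed (observed indexed by k_missing = 6 - formula_n)
    by least squares, clips negative components to zero and rescales to
    preserve the particle total.  Requires an invertible mixing regime
    (eps_fn + eps_fp < 1) and a well-conditioned M.
    """
    if err.eps_fn + err.eps_fp >= 1.0:
        raise ValueError(
            f"mixing not invertible: eps_fn + eps_fp = {err.eps_fn + err.eps_fp} >= 1"
        )
    m = mixing_matrix(err)
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise ValueError(
            f"mixing matrix numerically singular (condition number {cond:.3g} "
            f"exceeds {CONDITION_LIMIT:.0e})"
        )
    observed_by_k = dist.as_array()[::-1]  # index by k_missing = 6 - n
    x, *_ = np.linalg.lstsq(m, observed_by_k, rcond=None)
    x = np.clip(x, 0.0, None)
    total = dist.total
    if x.sum() > 0:
        x *= total / x.sum()
    return FormulaDistribution(counts=tuple(x))
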