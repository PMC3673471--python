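"""Perturbation Response Scanning and the dynamic flexibility index.

Linear response theory gives the displacement of the network under a force
``F`` as ``dR = H^-1 F``.  Scanning unit forces over every residue ``i`` and
recording the displacement magnitude of every residue ``j`` yields the N x N
response matrix ``A``; column means of ``A`` give the total response ``S_j``
of each residue, and normalising ``S`` to unit sum gives the dynamic
flexibility index

    dfi_j = S_j / sum_m S_m.

High dfi marks structurally flexible sites; low dfi marks dynamically robust,
hinge-like sites.  ``%dfi`` is the within-protein percentile rank of dfi,
which makes profiles poolable across proteins.

Two estimators of ``A`` are provided:

``monte_carlo``
    The original recipe — average the displacement magnitude over k random
    unit force directions (default k=10), built as antipodal pairs so the
    force set has an exactly zero angular average (isotropy).
``analytic``
    The deterministic isotropic limit: the root-mean-square displacement
    magnitude of residue j under a uniformly distributed unit force at i is
    sqrt(trace(G_ji G_ji^T) / 3) with G_ji the 3x3 coupling block of H^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .enm import HessianModel
from .errors import ContractError, DegenerateProfileError


@dataclass(frozen=True)
class ForceSet:
    """k unit force directions with exactly zero vector sum.

    Directions are drawn as k/2 uniform random unit vectors plus their
    antipodes, so the "zero angular average" isotropy condition holds exactly
    rather than only in expectation.
    """

    directions: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        object.__setattr__(self, "directions", d)
        if d.ndim != 2 or d.shape[1] != 3:
            raise ContractError("directions must be a k x 3 array")
        norms = np.linalg.norm(d, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ContractError("every force direction must be a unit vector")
        if not np.all(np.abs(d.sum(axis=0)) <= 1e-12):
            raise ContractError("force directions must sum to the zero vector")

    @property
    def k(self) -> int:
        return self.directions.shape[0]


def sample_forces(k: int = 10, seed: int | None = None,
                  rng: np.random.Generator | None = None) -> ForceSet:
    """Draw ``k`` isotropic unit force directions (antipodal pairs).

    ``k`` must be even and >= 2: directions come in +/- pairs so their vector
    sum is exactly zero.  Reproducible under ``seed``.
    """
    if k < 2 or k % 2 != 0:
        raise ContractError(
            f"k={k}: the direction count must be even and >= 2 — directions "
            "are built as antipodal pairs to guarantee a zero angular average"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    half = rng.normal(size=(k // 2, 3))
    half /= np.linalg.norm(half, axis=1, keepdims=True)
    return ForceSet(directions=np.vstack([half, -half]), seed=seed)


@dataclass(frozen=True)
class ResponseMatrix:
    """N x N matrix of displacement magnitudes.

    ``A[i, j]`` is the average displacement magnitude of residue j (Angstrom
    per unit force, at unit spring scale) upon perturbation at residue i.
    The matrix is generally *not* symmetric: perturbation and response play
    different roles.  ``scale`` carries the 1/gamma spring-constant factor so
    that scale-free quantities (dfi) can be computed without it.
    """

    A: np.ndarray
    mode: str
    scale: float = 1.0
    k: int | None = None
    per_direction_S: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ContractError("response matrix must be square")
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ContractError("response entries must be finite and >= 0")

    @property
    def physical(self) -> np.ndarray:
        """Response matrix in physical units (includes the spring scale)."""
        return self.A * self.scale

    @property
    def n_residues(self) -> int:
        return self.A.shape[0]


def _require_inverse(model: HessianModel) -> np.ndarray:
    if model.inverse is None:
        raise ContractError("HessianModel has no inverse; call invert_hessian() first")
    return model.inverse


def response_matrix_mc(model: HessianModel, forces: ForceSet,
                       average: str = "mean") -> ResponseMatrix:
    """Monte-Carlo response matrix from an explicit force set.

    For each perturbed residue i and direction f the displacement of the
    whole chain is read off the three columns of H^-1 belonging to residue i,
    scaled by f; ``A[i, j]`` combines the per-direction magnitudes of residue
    j's displacement with the chosen ``average`` (``"mean"``, the original
    recipe, or ``"rms"``, whose k -> infinity limit is the analytic matrix).
    """
    inv = _require_inverse(model)
    if average not in ("mean", "rms"):
        raise ContractError(f"unknown average {average!r}")
    n = model.n_residues
    f = forces.directions.T                      # 3 x k
    a = np.empty((n, n))
    s_dir = np.zeros((n, forces.k))              # per-direction column sums
    for i in range(n):
        disp = inv[:, 3 * i:3 * i + 3] @ f       # 3N x k
        mags = np.sqrt((disp.reshape(n, 3, -1) ** 2).sum(axis=1))  # N x k
        if average == "mean":
            a[i] = mags.mean(axis=1)
        else:
            a[i] = np.sqrt((mags ** 2).mean(axis=1))
        s_dir += mags
    return ResponseMatrix(A=a, mode="monte_carlo", scale=1.0 / model.gamma,
                          k=forces.k, per_direction_S=s_dir / n)


def response_matrix_analytic(model: HessianModel) -> ResponseMatrix:
    """Exact isotropic-average response matrix.

    ``A[i, j] = sqrt(trace(G_ji G_ji^T) / 3)`` — the RMS displacement
    magnitude of residue j under a uniformly distributed unit force at
    residue i, with G_ji the 3x3 block of H^-1 coupling them.
    """
    inv = _require_inverse(model)
    n = model.n_residues
    g = inv.reshape(n, 3, n, 3)
    # sum of squares of each 3x3 block G_ji = g[j, :, i, :], indexed (i, j)
    sq = np.einsum("jaib,jaib->ij", g, g)
    return ResponseMatrix(A=np.sqrt(sq / 3.0), mode="analytic",
                          scale=1.0 / model.gamma)


def percentile_rank(values: np.ndarray) -> np.ndarray:
    """Percentile rank 100 * rank / N with average ranks for ties.

    The maximum maps to 100 (all-distinct case); the minimum to 100/N.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 1:
        raise ContractError("values must be a non-empty 1-D array")
    if not np.all(np.isfinite(values)):
        raise ContractError("values must be finite")
    ranks = scipy.stats.rankdata(values, method="average")
    return 100.0 * ranks / values.size


@dataclass(frozen=True)
class DfiProfile:
    """Per-residue total response S, flexibility index dfi, and %dfi."""

    S: np.ndarray
    dfi: np.ndarray
    pct_dfi: np.ndarray
    mode: str = "analytic"
    se_dfi: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("S", "dfi", "pct_dfi"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def __len__(self) -> int:
        return len(self.dfi)


def dfi_from_response(resp: ResponseMatrix, include_self: bool = True) -> DfiProfile:
    """Reduce a response matrix to the flexibility profile.

    ``S_j`` is the mean over perturbation sites i of ``A[i, j]``; by default
    the self-perturbation row (i == j) is included in the mean, matching the
    matrix-mean formulation — ``include_self=False`` restricts to i != j,
    which changes dfi by O(1/N).  ``dfi_j = S_j / sum(S)``; ``%dfi`` is the
    tie-averaged percentile rank.
    """
    a = resp.A
    n = resp.n_residues
    if include_self:
        s_unit = a.mean(axis=0)
    else:
        s_unit = (a.sum(axis=0) - np.diag(a)) / (n - 1)
    total = s_unit.sum()
    if total == 0.0:
        raise DegenerateProfileError("response matrix is identically zero")
    dfi = s_unit / total
    se = None
    if resp.per_direction_S is not None and include_self and resp.k and resp.k > 1:
        # spread of the per-direction profiles around the MC mean
        se = resp.per_direction_S.std(axis=1, ddof=1) / np.sqrt(resp.k) / total
    return DfiProfile(S=s_unit * resp.scale, dfi=dfi,
                      pct_dfi=percentile_rank(dfi), mode=resp.mode, se_dfi=se)
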