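"""Elastic-network Hessian construction and pseudo-inversion.

The protein is modelled as a network of C-alpha nodes connected by harmonic
springs.  The pairwise potential is

    V = sum_{i<j} gamma_ij (|r_ij| - |r0_ij|)^2 / 2

whose Hessian at the equilibrium geometry has 3x3 off-diagonal blocks

    H_ij = -gamma_ij (d d^T) / r^2,   d = r0_j - r0_i,  r = |d|,

with diagonal blocks the negated sum of the off-diagonal blocks in their row
(translation invariance).  Two spring-weight rules are supported:

``inverse_square``
    gamma_ij = gamma / r^2 for *all* pairs — distance-weighted interactions
    with no cutoff, so the off-diagonal block is -gamma d d^T / r^4.
``cutoff``
    gamma_ij = gamma for r <= radius, else 0 — the classical uniform-spring
    anisotropic network model, provided for cross-checks.

The global spring constant ``gamma`` only sets the energy scale: the
flexibility index downstream is a ratio in which it cancels identically.  It
is therefore kept symbolic — all eigenwork is done on the gamma=1 matrix and
scale-dependent outputs are rescaled on access — so that rescaling the
springs provably changes no dfi value, not even in the last bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import ContractError, DegenerateGeometryError, SingularModelError
from .structure import CalphaStructure

#: Expected zero modes of a non-degenerate 3-D elastic body
#: (3 translations + 3 rotations).
RIGID_BODY_MODES = 6


class DegenerateGeometryWarning(UserWarning):
    """Null space larger/smaller than the 6 rigid-body modes."""


@dataclass
class HessianModel:
    """3N x 3N stiffness matrix with pseudo-inverse bookkeeping.

    ``hessian`` and ``inverse`` are stored at unit spring scale; the physical
    matrices are ``gamma * hessian`` and ``inverse / gamma`` (see
    :attr:`full_hessian`, :attr:`compliance`).
    """

    hessian: np.ndarray
    weighting: str
    gamma: float = 1.0
    inverse: np.ndarray | None = None
    null_dim: int | None = None
    eigenvalues: np.ndarray | None = None

    @property
    def n_residues(self) -> int:
        return self.hessian.shape[0] // 3

    @property
    def full_hessian(self) -> np.ndarray:
        """Hessian including the global spring constant."""
        return self.gamma * self.hessian

    @property
    def compliance(self) -> np.ndarray:
        """Physical pseudo-inverse (displacement per unit force)."""
        if self.inverse is None:
            raise ContractError("call invert_hessian() first")
        return self.inverse / self.gamma


def _pair_geometry(structure: CalphaStructure):
    coords = structure.coords
    diff = coords[:, None, :] - coords[None, :, :]   # d[i, j] = r_i - r_j
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    n = len(structure)
    off = ~np.eye(n, dtype=bool)
    if np.any(r2[off] == 0.0):
        ii, jj = np.nonzero((r2 == 0.0) & off)
        pairs = sorted({tuple(sorted(p)) for p in zip(ii.tolist(), jj.tolist())})
        raise DegenerateGeometryError(f"coincident residues at index pairs {pairs[:5]}")
    return diff, r2


def build_hessian(
    structure: CalphaStructure,
    weighting: str = "inverse_square",
    cutoff: float | None = None,
    gamma: float = 1.0,
) -> HessianModel:
    """Build the elastic-network Hessian for a C-alpha structure.

    Parameters
    ----------
    structure
        C-alpha trace with N >= 2 residues, all pairwise distances > 0.
    weighting
        ``"inverse_square"`` (default; all pairs, spring constant 1/r^2) or
        ``"cutoff"`` (uniform springs within ``cutoff`` Angstrom).
    cutoff
        Interaction radius in Angstrom, required for ``weighting="cutoff"``.
    gamma
        Global spring-constant scale (energy/A^2); kept symbolic.
    """
    diff, r2 = _pair_geometry(structure)
    n = len(structure)
    if weighting == "inverse_square":
        with np.errstate(divide="ignore"):
            k = 1.0 / r2            # spring constant per pair
    elif weighting == "cutoff":
        if cutoff is None or cutoff <= 0:
            raise ContractError("cutoff weighting requires a positive radius")
        k = (r2 <= cutoff * cutoff).astype(float)
    else:
        raise ContractError(f"unknown weighting {weighting!r}")
    np.fill_diagonal(k, 0.0)

    # off-diagonal 3x3 block: -k_ij * d d^T / r^2
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(r2 > 0, k / r2, 0.0)
    blocks = -w[:, :, None, None] * diff[:, :, :, None] * diff[:, :, None, :]
    # diagonal blocks: negated row sums (exact translation invariance)
    diag = -blocks.sum(axis=1)
    idx = np.arange(n)
    blocks[idx, idx] = diag
    hessian = blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    label = weighting if cutoff is None else f"{weighting}({cutoff:g} A)"
    return HessianModel(hessian=hessian, weighting=label, gamma=float(gamma))


def invert_hessian(model: HessianModel, zero_tol: float = 1e-10) -> HessianModel:
    """Pseudo-invert the Hessian, discarding the rigid-body null space.

    Eigenvalues below ``zero_tol * lambda_max`` are treated as zero modes and
    excluded; their count is recorded as ``null_dim``.  A non-degenerate 3-D
    structure has exactly 6 (3 translations + 3 rotations); any other count
    triggers a :class:`DegenerateGeometryWarning`.
    """
    evals, evecs = scipy.linalg.eigh(model.hessian)
    lam_max = float(evals[-1])
    if lam_max <= 0:
        raise SingularModelError("Hessian has no positive eigenvalues")
    keep = evals > zero_tol * lam_max
    null_dim = int(np.count_nonzero(~keep))
    if not np.any(keep):
        raise SingularModelError("all eigenvalues below the zero-mode threshold")
    if null_dim != RIGID_BODY_MODES:
        warnings.warn(
            f"null space has dimension {null_dim}, expected {RIGID_BODY_MODES} "
            "rigid-body modes; the geometry is degenerate",
            DegenerateGeometryWarning,
            stacklevel=2,
        )
    vk = evecs[:, keep]
    model.inverse = (vk / evals[keep]) @ vk.T
    model.null_dim = null_dim
    model.eigenvalues = evals
    return model


@dataclass
class MobilityProfile:
    """Per-residue effective mobility from the slowest network modes."""

    mobility: np.ndarray
    pct: np.ndarray
    n_modes: int

    def __len__(self) -> int:
        return len(self.mobility)


def gnm_mobility(
    structure: CalphaStructure,
    n_slow_modes: int = 10,
    weighting: str = "inverse_square",
    cutoff: float | None = None,
) -> MobilityProfile:
    """Effective mobility (%EM) from a one-dimensional Gaussian network model.

    Builds the N x N Kirchhoff-style connectivity matrix under the same
    spring-weight rule as the 3-D model, pseudo-inverts it (a connected
    network has exactly one zero mode) and sums the mode contributions
    ``u_k u_k^T / lambda_k`` over the ``n_slow_modes`` smallest nonzero
    modes.  The diagonal of that sum is the mobility; it is returned with its
    percentile rank so it can be compared against %dfi.
    """
    from .prs import percentile_rank

    diff, r2 = _pair_geometry(structure)
    n = len(structure)
    if weighting == "inverse_square":
        with np.errstate(divide="ignore"):
            k = 1.0 / r2
    elif weighting == "cutoff":
        if cutoff is None or cutoff <= 0:
            raise ContractError("cutoff weighting requires a positive radius")
        k = (r2 <= cutoff * cutoff).astype(float)
    else:
        raise ContractError(f"unknown weighting {weighting!r}")
    np.fill_diagonal(k, 0.0)
    kirchhoff = -k
    np.fill_diagonal(kirchhoff, k.sum(axis=1))

    evals, evecs = scipy.linalg.eigh(kirchhoff)
    lam_max = float(evals[-1])
    if lam_max <= 0:
        raise SingularModelError("Kirchhoff matrix has no positive eigenvalues")
    nonzero = np.nonzero(evals > 1e-10 * lam_max)[0]
    available = len(nonzero)
    if n_slow_modes > available:
        warnings.warn(
            f"n_slow_modes={n_slow_modes} exceeds the {available} nonzero "
            f"modes; reduced to {available}",
            UserWarning,
            stacklevel=2,
        )
        n_slow_modes = available
    if n_slow_modes < 1:
        raise ContractError("n_slow_modes must be >= 1")
    # Never split a degenerate multiplet: cutting through a tied eigenvalue
    # pair would make the mode sum depend on an arbitrary eigenvector basis
    # (and break symmetry, e.g. non-uniform mobility on a symmetric ring).
    while (n_slow_modes < available
           and evals[nonzero[n_slow_modes]]
           <= evals[nonzero[n_slow_modes - 1]] * (1 + 1e-8)):
        n_slow_modes += 1
    chosen = nonzero[:n_slow_modes]
    mobility = (evecs[:, chosen] ** 2 / evals[chosen]).sum(axis=1)
    return MobilityProfile(mobility=mobility, pct=percentile_rank(mobility),
                           n_modes=int(n_slow_modes))
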