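"""Modelling facade: a fit-able model object and a results object.

`DynamicFlexibilityModel` bundles the pipeline structure -> Hessian ->
pseudo-inverse -> perturbation response -> flexibility profile behind the
familiar model/results idiom: build the model from a structure (or straight
from a PDB file), call :meth:`~DynamicFlexibilityModel.fit`, and read the
estimates off the returned :class:`DFIResults`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import enm, prs, structure as structure_io
from .errors import ContractError
from .structure import CalphaStructure


class DynamicFlexibilityModel:
    """Elastic-network perturbation-response model of one structure.

    Parameters
    ----------
    structure
        C-alpha trace (N >= 2 residues).
    weighting
        Spring-weight rule: ``"inverse_square"`` (default; all residue pairs
        weighted by the inverse square of their separation, no cutoff) or
        ``"cutoff"`` with an interaction ``cutoff`` radius in Angstrom.
    gamma
        Global spring constant; dfi is invariant to it by construction.

    Examples
    --------
    >>> from dfiscan import DynamicFlexibilityModel
    >>> from dfiscan.fixtures import make_structure
    >>> model = DynamicFlexibilityModel(make_structure("ring", 12))
    >>> res = model.fit()          # analytic (deterministic) estimator
    >>> res.dfi.sum()
    1.0
    """

    def __init__(self, structure: CalphaStructure,
                 weighting: str = "inverse_square",
                 cutoff: float | None = None,
                 gamma: float = 1.0) -> None:
        self.structure = structure
        self.weighting = weighting
        self.cutoff = cutoff
        self.gamma = gamma
        self._hessian_model: enm.HessianModel | None = None

    @classmethod
    def from_pdb(cls, path: str | Path,
                 chains: str | Iterable[str] | None = None,
                 model: int = 0, **kwargs) -> "DynamicFlexibilityModel":
        """Build the model straight from a PDB file (first model by default)."""
        return cls(structure_io.read_structure(path, chains=chains, model=model),
                   **kwargs)

    @property
    def hessian_model(self) -> enm.HessianModel:
        """Lazily built and pseudo-inverted network Hessian."""
        if self._hessian_model is None or self._hessian_model.inverse is None:
            hm = enm.build_hessian(self.structure, weighting=self.weighting,
                                   cutoff=self.cutoff, gamma=self.gamma)
            self._hessian_model = enm.invert_hessian(hm)
        return self._hessian_model

    def fit(self, mode: str = "analytic", k: int = 10,
            seed: int | None = None, include_self: bool = True,
            average: str = "mean") -> "DFIResults":
        """Estimate the per-residue flexibility profile.

        Parameters
        ----------
        mode
            ``"analytic"`` — deterministic isotropic-average response
            (default) — or ``"monte_carlo"`` / ``"mc"`` — average over ``k``
            random unit forces (antipodal pairs; the historical recipe uses
            k=10).
        k, seed
            Direction count and RNG seed for Monte-Carlo mode.
        include_self
            Count the self-perturbation row in the response mean (default).
        average
            Magnitude combination for MC mode: ``"mean"`` or ``"rms"``.
        """
        hm = self.hessian_model
        if mode == "analytic":
            resp = prs.response_matrix_analytic(hm)
        elif mode in ("monte_carlo", "mc"):
            forces = prs.sample_forces(k=k, seed=seed)
            resp = prs.response_matrix_mc(hm, forces, average=average)
        else:
            raise ContractError(f"unknown mode {mode!r}")
        profile = prs.dfi_from_response(resp, include_self=include_self)
        return DFIResults(self, resp, profile,
                          params=dict(mode=mode, k=(k if mode != "analytic" else None),
                                      seed=seed, include_self=include_self,
                                      weighting=hm.weighting, gamma=self.gamma))

    def mobility(self, n_slow_modes: int = 10) -> enm.MobilityProfile:
        """GNM-style effective mobility (%EM) for comparison with %dfi."""
        return enm.gnm_mobility(self.structure, n_slow_modes=n_slow_modes,
                                weighting=self.weighting, cutoff=self.cutoff)


class DFIResults:
    """Fitted flexibility profile with its provenance.

    Attributes
    ----------
    S : ndarray
        Total displacement response per residue (Angstrom per unit force).
    dfi : ndarray
        Normalised flexibility index, sums to 1.
    pct_dfi : ndarray
        Within-protein percentile rank of dfi, in (0, 100].
    se_dfi : ndarray or None
        Monte-Carlo standard error of dfi over force directions (MC mode).
    """

    def __init__(self, model: DynamicFlexibilityModel,
                 response: prs.ResponseMatrix, profile: prs.DfiProfile,
                 params: dict) -> None:
        self.model = model
        self.response = response
        self.profile = profile
        self.params = params

    S = property(lambda self: self.profile.S)
    dfi = property(lambda self: self.profile.dfi)
    pct_dfi = property(lambda self: self.profile.pct_dfi)
    se_dfi = property(lambda self: self.profile.se_dfi)

    @property
    def structure(self) -> CalphaStructure:
        return self.model.structure

    @property
    def nobs(self) -> int:
        return len(self.profile)

    def frame(self) -> pd.DataFrame:
        """Per-residue results as a DataFrame."""
        ids = self.structure.residue_ids
        data = {
            "chain": [r[0] for r in ids],
            "resnum": [r[1] for r in ids],
            "icode": [r[2] for r in ids],
            "resname": [r[3] for r in ids],
            "S": self.S,
            "dfi": self.dfi,
            "pct_dfi": self.pct_dfi,
        }
        if self.se_dfi is not None:
            data["se_dfi"] = self.se_dfi
        return pd.DataFrame(data)

    def header_lines(self, extra: Sequence[str] = ()) -> list[str]:
        """Self-documenting parameter header for output tables."""
        p = self.params
        hm = self.model.hessian_model
        lines = [
            f"n_residues = {self.nobs}",
            f"weighting = {p['weighting']}",
            f"gamma = {p['gamma']:g}",
            f"mode = {p['mode']}",
            f"null_dim = {hm.null_dim}",
            f"include_self = {p['include_self']}",
        ]
        if p["mode"] != "analytic":
            lines += [f"k = {p['k']}", f"seed = {p['seed']}"]
        return lines + list(extra)

    def write_table(self, path: str | Path, header_lines: Sequence[str] | None = None) -> None:
        """Write the residue table (chain, resnum, icode, resname, S, dfi, pct_dfi)."""
        if header_lines is None:
            header_lines = self.header_lines()
        structure_io.write_dfi_table(self.profile, self.structure, path,
                                     header_lines=header_lines)

    def write_bfactor_pdb(self, source_path: str | Path, out_path: str | Path) -> None:
        """Copy the source PDB with %dfi stamped into the B-factor column."""
        structure_io.write_bfactor_pdb(source_path, self.profile,
                                       self.structure, out_path)

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        hm = self.model.hessian_model
        dfi = self.dfi
        order = np.argsort(dfi)
        ids = self.structure.residue_ids
        fmt_res = lambda i: f"{ids[i][3]} {ids[i][0]}{ids[i][1]}{ids[i][2]}"
        lines = [
            "Dynamic Flexibility Index Results",
            "=" * 46,
            f"residues:        {self.nobs}",
            f"weighting:       {self.params['weighting']} (gamma={self.params['gamma']:g})",
            f"estimator:       {self.params['mode']}"
            + ("" if self.params["mode"] == "analytic"
               else f" (k={self.params['k']}, seed={self.params['seed']})"),
            f"zero modes:      {hm.null_dim}",
            f"sum(dfi):        {dfi.sum():.12f}",
            f"dfi range:       [{dfi.min():.3e}, {dfi.max():.3e}]",
            f"most rigid:      {fmt_res(order[0])} (%dfi={self.pct_dfi[order[0]]:.1f})",
            f"most flexible:   {fmt_res(order[-1])} (%dfi={self.pct_dfi[order[-1]]:.1f})",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        """Line plot of %dfi along the sequence (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, self.nobs + 1), self.pct_dfi, lw=1.2)
        ax.set_xlabel("residue index")
        ax.set_ylabel("%dfi")
        return ax

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<DFIResults n={self.nobs} mode={self.params['mode']} "
                f"weighting={self.params['weighting']}>")


def compute_dfi(path: str | Path, mode: str = "analytic", k: int = 10,
                seed: int | None = None,
                chains: str | Iterable[str] | None = None,
                model_index: int = 0, out_table: str | Path | None = None,
                include_self: bool = True) -> DFIResults:
    """End-to-end convenience: PDB file in, flexibility profile out."""
    model = DynamicFlexibilityModel.from_pdb(path, chains=chains, model=model_index)
    res = model.fit(mode=mode, k=k, seed=seed, include_self=include_self)
    if out_table is not None:
        res.write_table(out_table)
    return res
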