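"""PDB input/output for the C-alpha coarse-grained representation.

The elastic-network model uses one node per residue, placed at the C-alpha
atom.  This module reads PDB files into :class:`CalphaStructure`, writes
per-residue flexibility profiles back out as tab-separated tables, and can
stamp percentile flexibility values into the B-factor column of a source PDB
for ribbon colouring.

Residues are identified by the author-assigned key ``(chain id, residue
sequence number, insertion code)``; author numbering is preserved verbatim in
all outputs.  Waters and ligands are never part of the network; HETATM
residues are included only when whitelisted (selenomethionine by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, EmptySelectionError, MappingError

logger = logging.getLogger(__name__)

#: HETATM residue names treated as part of the polymer by default.
DEFAULT_HETERO_WHITELIST = ("MSE",)

#: Residue key: (chain id, author residue number, insertion code).
ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class CalphaStructure:
    """Ordered C-alpha trace of one or more protein chains.

    Parameters
    ----------
    residue_ids
        Sequence of ``(chain, resseq, icode, resname)`` tuples in file order.
    coords
        ``(N, 3)`` array of C-alpha coordinates in Angstrom.
    source_label
        Free-text provenance string (file name, fixture description, ...).
    """

    residue_ids: tuple[tuple[str, int, str, str], ...]
    coords: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "residue_ids", tuple(tuple(r) for r in self.residue_ids))
        n = len(self.residue_ids)
        if n < 2:
            raise ContractError(f"a C-alpha structure needs at least 2 residues, got {n}")
        if coords.shape != (n, 3):
            raise ContractError(
                f"coords shape {coords.shape} does not match {n} residues"
            )
        if not np.all(np.isfinite(coords)):
            raise ContractError("coordinates must be finite")
        keys = [r[:3] for r in self.residue_ids]
        if len(set(keys)) != n:
            seen: set[tuple] = set()
            dup = [k for k in keys if k in seen or seen.add(k)]  # type: ignore[func-returns-value]
            raise ContractError(f"duplicate residue keys: {sorted(set(dup))}")

    def __len__(self) -> int:
        return len(self.residue_ids)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    @property
    def residue_keys(self) -> tuple[ResidueKey, ...]:
        """``(chain, resseq, icode)`` keys, in order."""
        return tuple(r[:3] for r in self.residue_ids)


def _normalise_chains(chains: str | Iterable[str] | None) -> set[str] | None:
    if chains is None:
        return None
    if isinstance(chains, str):
        return set(chains.replace(",", ""))
    return set(chains)


def read_structure(
    path: str | Path,
    chains: str | Iterable[str] | None = None,
    model: int = 0,
    include_hetero: Sequence[str] = DEFAULT_HETERO_WHITELIST,
) -> CalphaStructure:
    """Read the C-alpha trace of a PDB file.

    Parameters
    ----------
    path
        PDB file with at least one ``ATOM`` record named ``CA``.
    chains
        Chain identifiers to keep (string like ``"AB"`` or iterable); default
        all chains.
    model
        Zero-based model index for multi-model (e.g. NMR) files; default the
        first model.
    include_hetero
        HETATM residue names to include as polymer residues (default: MSE,
        selenomethionine).

    Notes
    -----
    For alternate locations the highest-occupancy conformer is used, ties
    broken by file order.  Residues lacking a C-alpha are skipped with a
    logged warning.  Waters and non-whitelisted heteroatoms are ignored.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        pdb = parser.get_structure(path.stem, str(path))

    models = list(pdb.get_models())
    if not models:
        raise EmptySelectionError(f"no models found in {path}")
    if model >= len(models) or model < 0:
        raise EmptySelectionError(
            f"model index {model} out of range: {path} has {len(models)} model(s)"
        )
    chain_set = _normalise_chains(chains)
    hetero_ok = {name.upper() for name in include_hetero}

    residue_ids: list[tuple[str, int, str, str]] = []
    coords: list[np.ndarray] = []
    for chain in models[model]:
        if chain_set is not None and chain.id not in chain_set:
            continue
        for residue in chain:
            hetfield, resseq, icode = residue.id
            resname = residue.get_resname().strip()
            if hetfield == "W":
                continue
            if hetfield.strip() and resname.upper() not in hetero_ok:
                continue
            if "CA" not in residue:
                logger.warning(
                    "residue %s %s%s%s lacks a C-alpha atom; skipped",
                    resname, chain.id, resseq, icode.strip(),
                )
                continue
            # Disordered atoms resolve to the highest-occupancy altloc
            # (Biopython keeps the first-listed conformer on ties).
            atom = residue["CA"]
            residue_ids.append((chain.id, int(resseq), icode.strip(), resname))
            # PDB coordinates carry exactly 3 decimals; rounding undoes the
            # float32 storage of the parser so values match the file text.
            coords.append(np.round(np.asarray(atom.get_coord(), dtype=float), 3))

    if not residue_ids:
        sel = "all chains" if chain_set is None else f"chains {sorted(chain_set)}"
        raise EmptySelectionError(
            f"no C-alpha atoms in {path} for {sel}, model {model}"
        )
    return CalphaStructure(
        residue_ids=tuple(residue_ids),
        coords=np.vstack(coords),
        source_label=str(path),
    )


_PDB_ATOM_FMT = (
    "ATOM  {serial:5d}  CA  {resname:>3s} {chain:1s}{resseq:4d}{icode:1s}"
    "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}\n"
)


def write_calpha_pdb(structure: CalphaStructure, path: str | Path,
                     bfactors: np.ndarray | None = None) -> None:
    """Write a C-alpha-only PDB file (one ATOM record per residue)."""
    if bfactors is None:
        bfactors = np.zeros(len(structure))
    bfactors = np.asarray(bfactors, dtype=float)
    if bfactors.shape != (len(structure),):
        raise ContractError("bfactors length must match structure")
    with open(path, "w") as fh:
        for serial, ((chain, resseq, icode, resname), xyz, b) in enumerate(
            zip(structure.residue_ids, structure.coords, bfactors), start=1
        ):
            fh.write(_PDB_ATOM_FMT.format(
                serial=serial, resname=resname or "GLY", chain=chain or "A",
                resseq=resseq, icode=icode or " ",
                x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0, b=b, element="C",
            ))
        fh.write("TER\nEND\n")


_TABLE_COLUMNS = ["chain", "resnum", "icode", "resname", "S", "dfi", "pct_dfi"]


def write_dfi_table(profile, structure: CalphaStructure, path: str | Path,
                    header_lines: Sequence[str] = ()) -> None:
    """Write the per-residue flexibility profile as a tab-separated table.

    Columns: chain, resnum, icode, resname, S, dfi, pct_dfi.  Optional
    ``header_lines`` are emitted first as ``#``-prefixed comments (used by the
    CLI to echo run parameters).
    """
    if len(profile) != len(structure):
        raise ContractError(
            f"profile length {len(profile)} != structure length {len(structure)}"
        )
    frame = pd.DataFrame(
        {
            "chain": [r[0] for r in structure.residue_ids],
            "resnum": [r[1] for r in structure.residue_ids],
            "icode": [r[2] for r in structure.residue_ids],
            "resname": [r[3] for r in structure.residue_ids],
            "S": profile.S,
            "dfi": profile.dfi,
            "pct_dfi": profile.pct_dfi,
        }
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_dfi_table(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_dfi_table`."""
    return pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                       na_values=[], dtype={"chain": str, "icode": str})


def write_bfactor_pdb(source_path: str | Path, profile,
                      structure: CalphaStructure, out_path: str | Path,
                      field: str = "pct_dfi") -> None:
    """Copy a PDB file with per-residue profile values in the B-factor column.

    Every atom of a profiled residue gets that residue's value (``%dfi`` by
    default), fixed-width with 2 decimals in columns 61-66; atoms of
    unprofiled residues get ``0.00``.  All other bytes of the file are copied
    verbatim, so coordinates survive a round-trip bit-exactly.
    """
    if len(profile) != len(structure):
        raise ContractError(
            f"profile length {len(profile)} != structure length {len(structure)}"
        )
    values = dict(zip(structure.residue_keys, np.asarray(getattr(profile, field), dtype=float)))
    seen: set[ResidueKey] = set()
    out_lines: list[str] = []
    with open(source_path) as fh:
        for line in fh:
            if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
                chain = line[21]
                resseq = int(line[22:26])
                icode = line[26].strip() if len(line) > 26 else ""
                key = (chain, resseq, icode)
                value = values.get(key, 0.0)
                if key in values:
                    seen.add(key)
                line = line.rstrip("\n")
                line = line.ljust(66)
                line = line[:60] + f"{value:6.2f}" + line[66:] + "\n"
            out_lines.append(line)
    missing = sorted(set(values) - seen)
    if missing:
        raise MappingError(
            f"profiled residues not found in {source_path}: {missing}"
        )
    with open(out_path, "w") as fh:
        fh.writelines(out_lines)
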