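"""Synthetic structures and annotation tables with known ground truth.

Every stage of the pipeline is testable without downloading a structure:
this module generates toy C-alpha geometries (straight chains, rings,
random globules, two-lobed dumbbells) and planted annotation tables
(variant positions sampled with known per-category weights, evolutionary
rates drawn from a known linear model in %dfi).  The planted parameters are
recoverable by the analysis module, which closes the package's
self-consistency loop.

Geometry defaults emulate protein scale: 3.8 A between consecutive C-alphas,
globules packed at ~0.006 residues/A^3 (about 165 A^3 per residue, the
density of a folded domain) with a 3.5 A minimum pair separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .analysis import DEFAULT_BIN_EDGES, bin_by_pct_dfi
from .errors import ContractError, PackingError
from .structure import CalphaStructure

#: Consecutive C-alpha spacing in Angstrom.
DEFAULT_SPACING = 3.8
#: Globule packing density, residues per cubic Angstrom (~protein-like).
DEFAULT_DENSITY = 0.006
#: Minimum allowed pair distance inside a globule, Angstrom.
MIN_PAIR_DISTANCE = 3.5
#: Rejection-sampling attempt budget per structure.
MAX_REJECTIONS = 10_000

FIXTURE_KINDS = ("linear_chain", "ring", "globule", "dumbbell")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic structure."""

    kind: str
    n_residues: int
    spacing: float = DEFAULT_SPACING
    seed: int | None = None
    lobe_sizes: tuple[int, int] | None = None
    linker_length: int = 3
    density: float = DEFAULT_DENSITY

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ContractError(f"unknown fixture kind {self.kind!r}")
        if self.n_residues < 2:
            raise ContractError("n_residues must be >= 2")
        if self.spacing <= 0:
            raise ContractError("spacing must be > 0")


def _as_structure(coords: np.ndarray, label: str) -> CalphaStructure:
    n = coords.shape[0]
    ids = tuple(("A", i + 1, "", "ALA") for i in range(n))
    return CalphaStructure(residue_ids=ids, coords=coords, source_label=label)


def _globule_coords(n: int, rng: np.random.Generator,
                    density: float = DEFAULT_DENSITY,
                    min_dist: float = MIN_PAIR_DISTANCE,
                    center: np.ndarray | None = None,
                    avoid: np.ndarray | None = None) -> np.ndarray:
    """Uniform points in a sphere with a hard minimum pair distance.

    ``avoid`` adds extra fixed points the samples must also stay
    ``min_dist`` away from (used when packing dumbbell lobes around an
    already-placed linker).
    """
    radius = (3.0 * n / (4.0 * np.pi * density)) ** (1.0 / 3.0)
    origin = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    fixed = [] if avoid is None else [np.asarray(avoid, dtype=float)]
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        if attempts >= MAX_REJECTIONS:
            raise PackingError(
                f"could not pack {n} residues at min distance {min_dist} A in "
                f"radius {radius:.1f} A after {MAX_REJECTIONS} attempts; "
                "lower the density (larger radius)"
            )
        p = origin + rng.uniform(-radius, radius, size=3)
        attempts += 1
        if (p - origin) @ (p - origin) > radius * radius:
            continue
        blockers = fixed + ([np.asarray(pts)] if pts else [])
        if blockers and np.min(
                np.linalg.norm(np.vstack(blockers) - p, axis=1)) < min_dist:
            continue
        pts.append(p)
    return np.asarray(pts)


def globule_radius(n: int, density: float = DEFAULT_DENSITY) -> float:
    """Sphere radius holding ``n`` residues at the given packing density."""
    return (3.0 * n / (4.0 * np.pi * density)) ** (1.0 / 3.0)


def make_structure(spec: FixtureSpec | str | None = None,
                   n_residues: int | None = None, *,
                   kind: str | None = None, **kwargs) -> CalphaStructure:
    """Generate a synthetic C-alpha structure.

    Accepts either a :class:`FixtureSpec` or the same fields as keyword
    arguments (``make_structure(kind="ring", n_residues=12)``; the two-arg
    positional shorthand ``make_structure("ring", 12)`` also works).

    Kinds
    -----
    ``linear_chain``
        Collinear points at fixed spacing (degenerate: 7 zero modes).
    ``ring``
        N points equally spaced on a circle of circumference N * spacing.
    ``globule``
        Self-avoiding uniform points in a sphere at protein-like density —
        the simplest structure with 6 rigid modes and a heterogeneous
        flexibility profile.
    ``dumbbell``
        Two globular lobes joined by a collinear linker — a hinge fixture;
        residue order is lobe A, linker, lobe B.
    """
    if spec is None:
        spec = FixtureSpec(kind=kind, n_residues=n_residues, **kwargs)
    elif isinstance(spec, str):
        spec = FixtureSpec(kind=spec, n_residues=n_residues, **kwargs)
    rng = np.random.default_rng(spec.seed)
    n, a = spec.n_residues, spec.spacing

    if spec.kind == "linear_chain":
        coords = np.zeros((n, 3))
        coords[:, 0] = a * np.arange(n)
        label = f"linear_chain(n={n})"

    elif spec.kind == "ring":
        # A strictly planar ring of central-force springs is degenerate
        # (every out-of-plane displacement is a zero mode), so the ring is
        # crown-puckered: vertices alternate +/- spacing/4 out of plane,
        # which keeps the structure vertex-transitive (uniform dfi) while
        # giving it the 6 rigid modes of a true 3-D body.  Odd N cannot
        # alternate and falls back to the planar, degenerate ring.
        theta = 2.0 * np.pi * np.arange(n) / n
        if n % 2 == 0:
            h = a / 4.0
            z = h * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
            chord = np.sqrt(a * a - 4.0 * h * h)
        else:
            z = np.zeros(n)
            chord = a
        # radius chosen so adjacent (3-D chord) distances equal the spacing
        radius = chord / (2.0 * np.sin(np.pi / n))
        coords = np.column_stack([radius * np.cos(theta),
                                  radius * np.sin(theta), z])
        label = f"ring(n={n})"

    elif spec.kind == "globule":
        coords = _globule_coords(n, rng, density=spec.density)
        label = f"globule(n={n}, seed={spec.seed})"

    else:  # dumbbell
        if spec.lobe_sizes is not None:
            na, nb = spec.lobe_sizes
            n_link = spec.n_residues - na - nb
        else:
            n_link = spec.linker_length
            na = (n - n_link) // 2
            nb = n - n_link - na
        if min(na, nb) < 4 or n_link < 1:
            raise ContractError(
                f"dumbbell needs lobes >= 4 residues and linker >= 1 "
                f"(got lobes {na},{nb}, linker {n_link})"
            )
        # Lobe centers are separated by the linker span, so the two dense
        # lobes meet at the hinge with the collinear linker embedded at the
        # interface (as in a real two-domain protein, where the hinge is
        # packed between the domains, not dangling in solvent).
        span = (n_link + 1) * a
        center_b = np.array([span, 0.0, 0.0])
        linker = np.column_stack([a * np.arange(1, n_link + 1),
                                  np.zeros(n_link), np.zeros(n_link)])
        lobe_a = _globule_coords(na, rng, density=spec.density,
                                 center=np.zeros(3), avoid=linker)
        lobe_b = _globule_coords(nb, rng, density=spec.density,
                                 center=center_b,
                                 avoid=np.vstack([linker, lobe_a]))
        coords = np.vstack([lobe_a, linker, lobe_b])
        label = f"dumbbell(lobes={na}+{nb}, linker={n_link}, seed={spec.seed})"

    return _as_structure(coords, label)


def dumbbell_linker_indices(n_residues: int,
                            lobe_sizes: tuple[int, int] | None = None,
                            linker_length: int = 3) -> np.ndarray:
    """Indices of the linker residues of a dumbbell built by make_structure."""
    if lobe_sizes is not None:
        na = lobe_sizes[0]
        n_link = n_residues - sum(lobe_sizes)
    else:
        n_link = linker_length
        na = (n_residues - n_link) // 2
    return np.arange(na, na + n_link)


def sample_variant_positions(pct, bin_weights: Sequence[float], m_variants: int,
                             seed: int | None = None,
                             edges=DEFAULT_BIN_EDGES,
                             replace: bool = True) -> np.ndarray:
    """Sample variant positions with probability proportional to bin weight.

    Each profiled position gets the weight of its %dfi category; ``m_variants``
    positions are drawn with those (normalised) probabilities, with
    replacement by default (a position can host several variants).
    """
    pct = np.asarray(pct, dtype=float)
    w = np.asarray(bin_weights, dtype=float)
    if w.ndim != 1 or w.size != len(edges) + 1:
        raise ContractError(f"need {len(edges) + 1} bin weights, got {w.size}")
    if np.any(w < 0) or not np.any(w > 0):
        raise ContractError("bin weights must be >= 0 and not all zero")
    if m_variants < 1:
        raise ContractError("m_variants must be >= 1")
    if not replace and m_variants > pct.size:
        raise ContractError(
            f"cannot draw {m_variants} variants from {pct.size} positions "
            "without replacement"
        )
    probs = w[bin_by_pct_dfi(pct, edges)]
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    return rng.choice(pct.size, size=m_variants, replace=replace, p=probs)


def sample_rates(pct, slope: float = 1.0, sigma: float = 0.0,
                 seed: int | None = None) -> np.ndarray:
    """Per-site evolutionary rates from a linear model in %dfi.

    ``r = slope * (%dfi / 100) + Normal(0, sigma)``, truncated at 0 —
    substitutions per site per billion years increasing with flexibility.
    """
    pct = np.asarray(pct, dtype=float)
    if slope < 0 or sigma < 0:
        raise ContractError("slope and sigma must be >= 0")
    rng = np.random.default_rng(seed)
    rates = slope * pct / 100.0
    if sigma > 0:
        rates = rates + rng.normal(0.0, sigma, size=pct.size)
    return np.maximum(rates, 0.0)


def make_annotations(profile, structure: CalphaStructure,
                     planted_bin_weights: Sequence[float] = (1.0,) * 5,
                     m_variants: int = 100, rate_slope: float = 1.0,
                     rate_sigma: float = 0.0, seed: int | None = None,
                     protein_id: str = "synthetic",
                     edges=DEFAULT_BIN_EDGES,
                     label: str = "disease") -> pd.DataFrame:
    """Planted annotation table joining 1:1 against a flexibility profile.

    Emulates the statistical structure of real annotation data — variants
    enriched in chosen %dfi categories, rates increasing with %dfi — with
    every parameter known.  Returns a table with columns ``protein_id,
    chain, resnum, icode, label, rate`` (one row per residue; the ``label``
    column holds the variant label on sampled positions, empty elsewhere;
    multiplicity recorded in ``n_variants``).
    """
    pct = np.asarray(profile.pct_dfi, dtype=float)
    if len(pct) != len(structure):
        raise ContractError("profile and structure lengths differ")
    rng = np.random.default_rng(seed)
    pos_seed = int(rng.integers(2 ** 31))
    rate_seed = int(rng.integers(2 ** 31))
    positions = sample_variant_positions(pct, planted_bin_weights, m_variants,
                                         seed=pos_seed, edges=edges)
    counts = np.bincount(positions, minlength=len(pct))
    rates = sample_rates(pct, slope=rate_slope, sigma=rate_sigma, seed=rate_seed)
    keys = structure.residue_ids
    return pd.DataFrame({
        "protein_id": protein_id,
        "chain": [k[0] for k in keys],
        "resnum": [k[1] for k in keys],
        "icode": [k[2] for k in keys],
        "label": [label if c > 0 else "" for c in counts],
        "n_variants": counts,
        "rate": rates,
    })


def write_annotations(table: pd.DataFrame, path) -> None:
    """Write an annotation table as tab-separated text."""
    table.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    """Read a tab-separated annotation table."""
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[],
                       dtype={"chain": str, "icode": str, "label": str})
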