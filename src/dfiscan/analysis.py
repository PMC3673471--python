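"""Downstream statistics on %dfi profiles.

Covers the variant-enrichment analysis (observed vs expected variant counts
per %dfi category with a chi-squared goodness-of-fit test), frequency
distributions of %dfi for labelled residue sets (catalytic/binding sites),
sliding-window correlation of %dfi with per-site evolutionary rates, and
conservation-group summaries.  Because %dfi is a within-protein percentile,
profiles from different proteins pool by simple concatenation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ContractError, JoinError

#: Fig-2-style default category boundaries: <20, 20-40, 40-60, 60-80, >=80.
DEFAULT_BIN_EDGES = (20.0, 40.0, 60.0, 80.0)


def _check_pct(pct: np.ndarray) -> np.ndarray:
    pct = np.asarray(pct, dtype=float)
    if pct.ndim != 1 or pct.size == 0:
        raise ContractError("%dfi must be a non-empty 1-D array")
    if not np.all(np.isfinite(pct)) or np.any(pct <= 0) or np.any(pct > 100):
        raise ContractError("%dfi values must lie in (0, 100]")
    return pct


def bin_by_pct_dfi(pct, edges=DEFAULT_BIN_EDGES) -> np.ndarray:
    """Assign each %dfi value to a category index.

    Bins are left-closed/right-open — with the default edges: [0,20), [20,40),
    [40,60), [60,80) — except the last, which is closed at 100 so that the
    categories read "<20, 20<=x<40, ..., >=80".
    """
    pct = _check_pct(pct)
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 1 or np.any(np.diff(edges) <= 0):
        raise ContractError("edges must be strictly increasing")
    if edges[0] <= 0 or edges[-1] >= 100:
        raise ContractError("edges must lie strictly inside (0, 100)")
    return np.searchsorted(edges, pct, side="right")


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed/expected variant counts per %dfi category.

    ``expected[i] = (n[i] / N) * M`` where ``n[i]`` counts profiled positions
    in category i, N the total positions and M the total variants; ``ratio``
    is observed/expected; ``chi2``/``dof``/``p`` summarise the goodness-of-fit
    test of the uniform-placement null (categories with zero expectation are
    excluded from the statistic).
    """

    bin_edges: tuple[float, ...]
    n: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    ratio: np.ndarray
    chi2: float
    dof: int
    p: float

    @property
    def n_variants(self) -> int:
        return int(self.observed.sum())

    def frame(self) -> pd.DataFrame:
        edges = (0.0, *self.bin_edges, 100.0)
        labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-2], edges[1:-1])]
        labels.append(f"[{edges[-2]:g},100]")
        return pd.DataFrame({
            "bin": labels, "n_positions": self.n, "observed": self.observed,
            "expected": self.expected, "ratio": self.ratio,
        })


def enrichment(pct, variant_positions, edges=DEFAULT_BIN_EDGES) -> EnrichmentResult:
    """Variant enrichment by %dfi category.

    Parameters
    ----------
    pct
        %dfi of every profiled position (pooled across proteins).
    variant_positions
        Integer indices into ``pct``, one per variant; a position hosting
        several variants appears several times.
    edges
        Category boundaries (default 20/40/60/80).
    """
    pct = _check_pct(pct)
    bins = bin_by_pct_dfi(pct, edges)
    n_bins = len(edges) + 1
    positions = np.asarray(variant_positions, dtype=int)
    if positions.size < 1:
        raise ContractError("need at least one variant (M >= 1)")
    bad = positions[(positions < 0) | (positions >= pct.size)]
    if bad.size:
        raise JoinError(f"variants at unprofiled positions: {sorted(set(bad.tolist()))}")

    n = np.bincount(bins, minlength=n_bins).astype(float)
    observed = np.bincount(bins[positions], minlength=n_bins).astype(float)
    m = float(positions.size)
    expected = n / pct.size * m
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, observed / expected, np.nan)
    keep = expected > 0
    if not np.all(keep):
        warnings.warn(
            f"{int(np.count_nonzero(~keep))} empty categorie(s) excluded from "
            "the chi-squared statistic", UserWarning, stacklevel=2,
        )
    chi2 = float(((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum())
    dof = int(np.count_nonzero(keep)) - 1
    p = float(scipy.stats.chi2.sf(chi2, dof)) if dof > 0 else float("nan")
    return EnrichmentResult(bin_edges=tuple(float(e) for e in edges), n=n,
                            observed=observed, expected=expected, ratio=ratio,
                            chi2=chi2, dof=dof, p=p)


@dataclass(frozen=True)
class FlexibilityDistribution:
    """Normalised %dfi frequency distribution of a labelled residue set."""

    bin_edges: np.ndarray       # length n_bins + 1, covering (0, 100]
    frequency: np.ndarray       # sums to 1
    values: np.ndarray = field(repr=False)

    def fraction_at_or_below(self, threshold: float) -> float:
        """Fraction of the labelled residues with %dfi <= threshold."""
        return float(np.mean(self.values <= threshold))


def flexibility_distribution(pct, labeled, bin_width: float = 10.0) -> FlexibilityDistribution:
    """Frequency distribution of %dfi over a labelled subset of residues.

    ``labeled`` is a boolean mask or integer index array selecting the
    residues of interest (e.g. catalytic or binding sites).  Bins are
    right-closed intervals of ``bin_width`` percent: (0,w], (w,2w], ...
    """
    pct = _check_pct(pct)
    labeled = np.asarray(labeled)
    values = pct[labeled]
    if values.size == 0:
        raise ContractError("labelled residue set is empty")
    if bin_width <= 0 or bin_width > 100:
        raise ContractError("bin_width must lie in (0, 100]")
    n_bins = int(np.ceil(100.0 / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 100.0)
    idx = np.minimum(np.ceil(values / bin_width).astype(int) - 1, n_bins - 1)
    counts = np.bincount(np.maximum(idx, 0), minlength=n_bins).astype(float)
    return FlexibilityDistribution(bin_edges=edges,
                                   frequency=counts / counts.sum(),
                                   values=values)


@dataclass(frozen=True)
class SlidingCorrelation:
    """Window-mean %dfi vs window-mean rate and their Pearson correlation."""

    window_pct: np.ndarray
    window_rate: np.ndarray
    correlation: float
    window_size: int
    step: int


def default_window(n: int) -> int:
    """Default sliding-window size: max(50, N/20) residues."""
    return max(50, n // 20)


def rate_dfi_sliding(pct, rates, window_size: int | None = None,
                     step: int | None = None) -> SlidingCorrelation:
    """Sliding-window correlation of evolutionary rate with %dfi.

    Residues are sorted by %dfi; windows of ``window_size`` residues advance
    by ``step``; the Pearson correlation of the window-mean rate against the
    window-mean %dfi summarises the trend.  Depends on the %dfi values only
    through their order, so it is invariant to monotone rescaling.
    """
    pct = _check_pct(pct)
    rates = np.asarray(rates, dtype=float)
    if rates.shape != pct.shape:
        raise ContractError("rates must join 1:1 with %dfi values")
    if not np.all(np.isfinite(rates)) or np.any(rates < 0):
        raise ContractError("rates must be finite and >= 0")
    n = pct.size
    if window_size is None:
        window_size = default_window(n)
    if step is None:
        step = max(1, window_size // 2)
    if window_size > n:
        raise ContractError(f"window_size {window_size} exceeds N={n}")
    if window_size < 1 or step < 1:
        raise ContractError("window_size and step must be >= 1")
    order = np.argsort(pct, kind="stable")
    starts = np.arange(0, n - window_size + 1, step)
    if starts.size < 2:
        raise ContractError("need at least 2 windows; reduce window_size or step")
    cum_p = np.concatenate([[0.0], np.cumsum(pct[order])])
    cum_r = np.concatenate([[0.0], np.cumsum(rates[order])])
    wp = (cum_p[starts + window_size] - cum_p[starts]) / window_size
    wr = (cum_r[starts + window_size] - cum_r[starts]) / window_size
    corr = float(scipy.stats.pearsonr(wp, wr).statistic)
    return SlidingCorrelation(window_pct=wp, window_rate=wr, correlation=corr,
                              window_size=int(window_size), step=int(step))


def rate_dfi_permutation(pct, rates, window_size: int | None = None,
                         step: int | None = None, n_permutations: int = 1000,
                         seed: int | None = None):
    """Permutation null for the sliding-window correlation.

    Returns ``(observed, permuted)`` where ``permuted`` holds the statistic
    recomputed under ``n_permutations`` random shufflings of the rates.
    """
    observed = rate_dfi_sliding(pct, rates, window_size, step)
    rng = np.random.default_rng(seed)
    rates = np.asarray(rates, dtype=float)
    permuted = np.empty(n_permutations)
    for b in range(n_permutations):
        permuted[b] = rate_dfi_sliding(pct, rng.permutation(rates),
                                       observed.window_size,
                                       observed.step).correlation
    return observed, permuted


#: Conservation categories by substitution rate (substitutions/site/Byr).
CONSERVATION_GROUPS = ("ultra_conserved", "well_conserved", "less_conserved")


def conservation_groups(pct, rates) -> dict[str, dict[str, float] | None]:
    """Five-number %dfi summaries per conservation category.

    Categories: ultra-conserved (r = 0), well-conserved (0 < r <= 1) and less
    conserved (r > 1), with r in substitutions per site per billion years.
    Empty categories are reported as ``None``.
    """
    pct = _check_pct(pct)
    rates = np.asarray(rates, dtype=float)
    if rates.shape != pct.shape:
        raise ContractError("rates must join 1:1 with %dfi values")
    masks = {
        "ultra_conserved": rates == 0,
        "well_conserved": (rates > 0) & (rates <= 1),
        "less_conserved": rates > 1,
    }
    out: dict[str, dict[str, float] | None] = {}
    for name, mask in masks.items():
        vals = pct[mask]
        if vals.size == 0:
            out[name] = None
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out[name] = {"n": int(vals.size), "min": float(vals.min()),
                     "q1": float(q1), "median": float(med), "q3": float(q3),
                     "max": float(vals.max())}
    return out


def group_difference_test(values_a, values_b):
    """Welch two-sample t-test (unequal variances), two-sided.

    Returns ``(t, p, df)`` with Welch-Satterthwaite degrees of freedom.  When
    both groups are constant with equal means the test is vacuous and returns
    ``(0, 1, nan)`` by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ContractError("both groups need at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, float("nan")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue), float(res.df)
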