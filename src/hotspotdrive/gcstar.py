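"""Equilibrium GC content (GC*) from branch-specific substitution counts.

GC-biased gene conversion drives base composition toward an equilibrium set
by the ratio of the per-base weak-to-strong and strong-to-weak substitution
fluxes on a branch:

    GC* = f_WS / (f_WS + f_SW),   f_WS = #AT->GC / #AT,  f_SW = #GC->AT / #GC

where the base counts #AT and #GC are taken at the branch's ancestral node.
Potential CpG sites are masked first (CpG hypermutability would otherwise
bias the strong-to-weak flux): a site is discarded if it forms a CpG
dinucleotide in at least one of the four aligned species.

Spatial profiles around anchors (e.g. hotspot centers) pool substitution
and opportunity counts across anchors per offset window before applying the
flux-ratio formula — a ratio of pooled counts, not a mean of per-anchor
ratios, because 10-bp windows rarely contain any substitution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .branches import QuartetColumns, branch_mutation_masks, resolve_denisovan
from .io import MISSING, RecombMap

__all__ = [
    "SubstitutionCounts",
    "mask_cpg",
    "gc_star",
    "count_substitutions",
    "gcstar_profile",
    "windowed_gcstar_vs_recomb",
]

_WEAK_CODES = (0, 3)  # A, T
_C, _G = 1, 2


@dataclass
class SubstitutionCounts:
    """Branch substitution and opportunity counts after CpG masking."""

    branch: str
    n_ws: int
    n_sw: int
    n_at: int
    n_gc: int

    def __post_init__(self) -> None:
        if min(self.n_ws, self.n_sw, self.n_at, self.n_gc) < 0:
            raise ValueError("counts must be non-negative")


def mask_cpg(sequences: list[np.ndarray]) -> np.ndarray:
    """True where a site must be discarded as a potential CpG.

    Within each species, a C followed by a G masks both positions; the
    final mask is the union over species.
    """
    if not sequences:
        return np.zeros(0, dtype=bool)
    L = len(sequences[0])
    mask = np.zeros(L, dtype=bool)
    for seq in sequences:
        if len(seq) != L:
            raise ValueError("sequences must share a length")
        cpg = (seq[:-1] == _C) & (seq[1:] == _G)
        mask[:-1] |= cpg
        mask[1:] |= cpg
    return mask


def gc_star(counts: SubstitutionCounts) -> float:
    """Equilibrium GC from per-base substitution fluxes; NaN when both
    fluxes are zero (undefined)."""
    if counts.n_at <= 0 or counts.n_gc <= 0:
        raise ValueError("need positive AT and GC opportunity counts")
    f_ws = counts.n_ws / counts.n_at
    f_sw = counts.n_sw / counts.n_gc
    if f_ws + f_sw == 0.0:
        return np.nan
    return f_ws / (f_ws + f_sw)


def _branch_arrays(
    cols: QuartetColumns, den: np.ndarray
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per branch: (mutation mask, ancestral-node base, derived base)."""
    masks = branch_mutation_masks(cols, den)
    hd = np.where(masks["hominini"], cols.human, cols.ancestral)
    return {
        "chimpanzee": (masks["chimpanzee"], cols.ancestral, cols.chimp),
        "hominini": (masks["hominini"], cols.ancestral, cols.human),
        "human": (masks["human"], hd, cols.human),
        "denisovan": (masks["denisovan"], hd, den),
    }


def _flux_site_masks(mut, anc_node, derived, include):
    """Boolean per-site arrays (ws, sw, at, gc) on included sites."""
    anc_ok = include & (anc_node != MISSING)
    anc_weak = anc_ok & np.isin(anc_node, _WEAK_CODES)
    anc_strong = anc_ok & ~np.isin(anc_node, _WEAK_CODES) & (anc_node != MISSING)
    der_strong = np.isin(derived, (_C, _G)) & (derived != MISSING)
    der_weak = np.isin(derived, _WEAK_CODES)
    ws = anc_weak & mut & der_strong
    sw = anc_strong & mut & der_weak
    return ws, sw, anc_weak, anc_strong


def count_substitutions(
    cols: QuartetColumns,
    branch: str,
    site_mask: np.ndarray | None = None,
    seed: int = 0,
    apply_cpg_mask: bool = True,
) -> SubstitutionCounts:
    """Weak->strong / strong->weak substitution counts and opportunities for
    one branch, with CpG masking and an optional site filter."""
    rng = np.random.default_rng(seed)
    den = resolve_denisovan(cols, rng)
    arrays = _branch_arrays(cols, den)
    if branch not in arrays:
        raise ValueError(f"unknown branch {branch!r}")
    include = np.ones(len(cols), dtype=bool)
    if site_mask is not None:
        include &= site_mask
    if apply_cpg_mask:
        include &= ~mask_cpg([cols.ancestral, cols.human, den, cols.chimp])
    mut, anc_node, derived = arrays[branch]
    ws, sw, at, gc = _flux_site_masks(mut, anc_node, derived, include)
    return SubstitutionCounts(
        branch=branch,
        n_ws=int(ws.sum()),
        n_sw=int(sw.sum()),
        n_at=int(at.sum()),
        n_gc=int(gc.sum()),
    )


def gcstar_profile(
    anchors: np.ndarray,
    cols: QuartetColumns,
    branch: str,
    span: int = 10_000,
    dot_window: int = 10,
    smooth_window: int = 500,
    site_mask: np.ndarray | None = None,
    seed: int = 0,
    apply_cpg_mask: bool = True,
) -> pd.DataFrame:
    """GC* as a function of offset from anchor midpoints.

    Counts are pooled across anchors into ``dot_window``-bp offset bins;
    GC* is the flux ratio of the pooled counts, plus a ``smooth_window``
    rolling-pooled version.  Bins with no informative counts yield NaN.
    """
    anchors = np.asarray(anchors, dtype=int)
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    rng = np.random.default_rng(seed)
    den = resolve_denisovan(cols, rng)
    arrays = _branch_arrays(cols, den)
    mut, anc_node, derived = arrays[branch]
    include = np.ones(len(cols), dtype=bool)
    if site_mask is not None:
        include &= site_mask
    if apply_cpg_mask:
        include &= ~mask_cpg([cols.ancestral, cols.human, den, cols.chimp])
    ws, sw, at, gc = _flux_site_masks(mut, anc_node, derived, include)

    nb = 2 * span // dot_window
    counts = np.zeros((4, nb))
    L = len(cols)
    for a in anchors:
        lo, hi = a - span, a + span
        s, e = max(lo, 0), min(hi, L)
        if s >= e:
            continue
        bins = (np.arange(s, e) - lo) // dot_window
        for i, arr in enumerate((ws, sw, at, gc)):
            counts[i] += np.bincount(bins, weights=arr[s:e], minlength=nb)

    def ratio(c):
        n_ws, n_sw, n_at, n_gc = c
        with np.errstate(invalid="ignore", divide="ignore"):
            f_ws = np.where(n_at > 0, n_ws / n_at, np.nan)
            f_sw = np.where(n_gc > 0, n_sw / n_gc, np.nan)
            tot = f_ws + f_sw
            return np.where(tot > 0, f_ws / tot, np.nan)

    k = max(smooth_window // dot_window, 1)
    kernel = np.ones(k)
    smooth = np.stack(
        [np.convolve(c, kernel, mode="same") for c in counts]
    )
    centers = -span + dot_window * (np.arange(nb) + 0.5)
    return pd.DataFrame(
        {
            "offset": centers,
            "gcstar": ratio(counts),
            "gcstar_smooth": ratio(smooth),
            "n_ws": counts[0],
            "n_sw": counts[1],
            "n_at": counts[2],
            "n_gc": counts[3],
        }
    )


def windowed_gcstar_vs_recomb(
    cols: QuartetColumns,
    rmap: RecombMap,
    branch: str,
    window: int = 1_000_000,
    site_mask: np.ndarray | None = None,
    seed: int = 0,
    apply_cpg_mask: bool = True,
):
    """Per-window GC* against mean crossover rate, with an OLS fit.

    Returns (table, fit) where ``fit`` has slope, intercept, r_squared and
    p_value attributes (statsmodels OLS).  Requires >= 10 windows with
    defined GC* and non-degenerate rate variance.
    """
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    den = resolve_denisovan(cols, rng)
    arrays = _branch_arrays(cols, den)
    mut, anc_node, derived = arrays[branch]
    include = np.ones(len(cols), dtype=bool)
    if site_mask is not None:
        include &= site_mask
    if apply_cpg_mask:
        include &= ~mask_cpg([cols.ancestral, cols.human, den, cols.chimp])
    ws, sw, at, gc = _flux_site_masks(mut, anc_node, derived, include)

    L = len(cols)
    rows = []
    for s in range(0, L - window + 1, window):
        e = s + window
        c = SubstitutionCounts(
            branch,
            int(ws[s:e].sum()),
            int(sw[s:e].sum()),
            int(at[s:e].sum()),
            int(gc[s:e].sum()),
        )
        if c.n_at == 0 or c.n_gc == 0:
            continue
        g = gc_star(c)
        rate = rmap.mean_rate(cols.chrom, s, e)
        if np.isnan(g) or np.isnan(rate):
            continue
        rows.append({"start": s, "end": e, "gcstar": g, "rate": rate})
    table = pd.DataFrame(rows)
    if len(table) < 10:
        raise ValueError(f"only {len(table)} usable windows; need >= 10")
    if np.var(table["rate"]) == 0 or np.var(table["gcstar"]) == 0:
        raise ValueError("degenerate variance; regression undefined")
    X = sm.add_constant(table["rate"].to_numpy())
    res = sm.OLS(table["gcstar"].to_numpy(), X).fit()

    @dataclass
    class RegressionFit:
        slope: float
        intercept: float
        r_squared: float
        p_value: float

    fit = RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
    )
    return table, fit
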