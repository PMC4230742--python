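"""Branch assignment, filter tiers, motif loss rates and DAF extraction.

Each aligned position carries the human-chimp ancestral base, the human
base, the diploid Denisovan genotype and the chimpanzee base.  A mutation
is placed on the chimpanzee branch when the ancestor differs from the
chimpanzee; on the Hominini branch (human-chimp ancestor to human-Denisovan
ancestor) when both the human and the (resolved) Denisovan base share a
state different from the ancestor; on a terminal branch when only that
lineage differs.  Sites where human and Denisovan carry two distinct
derived states are excluded.  Heterozygous Denisovan genotypes are resolved
by a random draw, and loss counts are averaged over repeated resolutions.

Filter tiers F1 ⊂ F2 ⊂ F3 discard unreliable sites (missing Denisovan
genotype / indels; alignment-quality and primate concordance; ancient-DNA
coverage, mappability and paralogy), and a motif is retained under a tier
only if all of its comparison-informative sites pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, RecombMap, overlap_mask
from .motifs import CM, HM, MotifHit

__all__ = [
    "QuartetColumns",
    "QuartetColumn",
    "FILTER_TIERS",
    "apply_filter",
    "motif_filter_mask",
    "branch_mutation_masks",
    "assign_branch",
    "compute_loss_rates",
    "proportion_test",
    "extract_daf",
    "recomb_profile",
]

_PATTERNS = {"HM": HM, "CM": CM}


@dataclass
class QuartetColumns:
    """Vectorized container of aligned quartet columns (uint8 base codes,
    255 = missing) plus per-site annotation tracks."""

    chrom: str
    ancestral: np.ndarray
    human: np.ndarray
    den1: np.ndarray
    den2: np.ndarray
    chimp: np.ndarray
    annotations: pd.DataFrame

    def __len__(self) -> int:
        return len(self.ancestral)

    @classmethod
    def from_simulation(cls, sim) -> "QuartetColumns":
        return cls(
            chrom=sim.chrom,
            ancestral=sim.ancestor,
            human=sim.human,
            den1=sim.den1,
            den2=sim.den2,
            chimp=sim.chimp,
            annotations=sim.annotations,
        )


@dataclass
class QuartetColumn:
    """One aligned position (convenience scalar view)."""

    position: int
    ancestral_base: int
    human_base: int
    denisovan_genotype: tuple[int, int]
    chimp_base: int


# ---------------------------------------------------------------------------
# Filter tiers
# ---------------------------------------------------------------------------


def _f1(cols: QuartetColumns) -> np.ndarray:
    ann = cols.annotations
    ok = (
        (cols.den1 != MISSING)
        & (cols.den2 != MISSING)
        & (cols.ancestral != MISSING)
        & (cols.human != MISSING)
        & (cols.chimp != MISSING)
    )
    return ok & (ann["indel"].to_numpy() == 0) & (ann["den_missing"].to_numpy() == 0)


def _f2(cols: QuartetColumns) -> np.ndarray:
    ann = cols.annotations
    return (
        _f1(cols)
        & (ann["filtered_alignment"].to_numpy() == 1)
        & (ann["concordance"].to_numpy() >= 3)
    )


def _f3(cols: QuartetColumns) -> np.ndarray:
    ann = cols.annotations
    cov = ann["coverage"].to_numpy()
    return (
        _f2(cols)
        & (ann["lowqual"].to_numpy() == 0)
        & (ann["syserr"].to_numpy() == 0)
        & (ann["map20"].to_numpy() == 1)
        & (cov >= 16)
        & (cov <= 46)
        & (ann["paralogs_human"].to_numpy() <= 1)
        & (ann["paralogs_chimp"].to_numpy() <= 1)
    )


FILTER_TIERS = {"F1": _f1, "F2": _f2, "F3": _f3}


def apply_filter(cols: QuartetColumns, tier: str) -> np.ndarray:
    """Per-site pass mask for a filter tier."""
    try:
        return FILTER_TIERS[tier](cols)
    except KeyError:
        raise ValueError(f"unknown filter tier {tier!r}; expected F1/F2/F3")


def motif_filter_mask(site_mask: np.ndarray, hits: list[MotifHit]) -> np.ndarray:
    """A motif is retained iff all comparison-informative sites pass."""
    out = np.empty(len(hits), dtype=bool)
    for i, h in enumerate(hits):
        pos = h.informative_positions(_PATTERNS[h.motif_id])
        out[i] = bool(site_mask[pos].all())
    return out


# ---------------------------------------------------------------------------
# Branch assignment
# ---------------------------------------------------------------------------


def resolve_denisovan(cols: QuartetColumns, rng: np.random.Generator) -> np.ndarray:
    """Pick one allele per site; heterozygous genotypes resolve at random."""
    pick = rng.random(len(cols)) < 0.5
    return np.where(pick, cols.den1, cols.den2)


def branch_mutation_masks(
    cols: QuartetColumns, den: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-branch boolean mutation masks given a resolved Denisovan base.

    Missing data never counts as a mutation.  ``excluded`` marks sites where
    human and Denisovan carry two distinct derived states.
    """
    anc, hum, chp = cols.ancestral, cols.human, cols.chimp
    present_h = (anc != MISSING) & (hum != MISSING) & (den != MISSING)
    hum_ne = (hum != anc) & present_h
    den_ne = (den != anc) & present_h
    excluded = hum_ne & den_ne & (hum != den)
    return {
        "chimpanzee": (chp != anc) & (chp != MISSING) & (anc != MISSING),
        "hominini": hum_ne & den_ne & (hum == den),
        "human": hum_ne & ~den_ne,
        "denisovan": den_ne & ~hum_ne,
        "excluded": excluded,
    }


def assign_branch(column: QuartetColumn, rng: np.random.Generator) -> str:
    """Classify one column to a branch (scalar convenience wrapper).

    Heterozygous Denisovan genotypes are resolved by a random draw, so
    repeated calls on the same heterozygous column may return different
    branches.
    """
    anc, hum, chp = column.ancestral_base, column.human_base, column.chimp_base
    g1, g2 = column.denisovan_genotype
    den = g1 if rng.random() < 0.5 else g2
    if MISSING in (np.uint8(anc), np.uint8(hum), np.uint8(den), np.uint8(chp)):
        raise ValueError("missing base after filtering")
    hum_ne, den_ne = hum != anc, den != anc
    if hum_ne and den_ne and hum != den:
        return "excluded"
    if hum_ne and den_ne:
        return "hominini"
    if hum_ne:
        return "human"
    if den_ne:
        return "denisovan"
    if chp != anc:
        return "chimpanzee"
    return "none"


# ---------------------------------------------------------------------------
# Loss rates
# ---------------------------------------------------------------------------


def compute_loss_rates(
    hits: list[MotifHit],
    cols: QuartetColumns,
    tier: str = "F2",
    strata: dict[str, pd.DataFrame] | None = None,
    repeats: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-branch motif loss rates, averaged over heterozygote resolutions.

    A motif is lost on a branch as soon as one comparison-informative site
    carries a mutation assigned to that branch.  A motif lost on the
    Hominini branch is not counted intact at the human-Denisovan ancestor,
    so it is removed from both the numerator and the denominator of the
    terminal branches.  Motifs containing an excluded site are dropped.
    Strata are 'all' plus within/outside each supplied interval track under
    the any-overlap rule.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    site_mask = apply_filter(cols, tier)
    keep = motif_filter_mask(site_mask, hits)
    kept = [h for h, k in zip(hits, keep) if k]
    if not kept:
        raise ValueError("no motif passes the filter tier")

    info = [np.array(h.informative_positions(_PATTERNS[h.motif_id])) for h in kept]
    n_info = {len(p) for p in info}
    if 0 in n_info:
        raise ValueError("motif with zero informative sites")
    pos_matrix = np.stack(info)  # (n_motifs, 10)
    classes = np.array([h.motif_id for h in kept])
    starts = np.array([h.start for h in kept])
    ends = np.array([h.end for h in kept])

    stratum_masks: dict[str, np.ndarray] = {"all": np.ones(len(kept), dtype=bool)}
    for name, track in (strata or {}).items():
        inside = overlap_mask(starts, ends, track, cols.chrom)
        stratum_masks[f"within_{name}"] = inside
        stratum_masks[f"outside_{name}"] = ~inside

    branches = ("chimpanzee", "hominini", "human", "denisovan")
    acc: dict[tuple, list] = {}
    hom_frac_acc: dict[tuple, list] = {}
    for _ in range(repeats):
        den = resolve_denisovan(cols, rng)
        masks = branch_mutation_masks(cols, den)
        lost = {b: masks[b][pos_matrix].any(axis=1) for b in branches}
        bad = masks["excluded"][pos_matrix].any(axis=1)
        hom_derived = (
            (cols.den1 == cols.den2)
            & (cols.den1 != cols.ancestral)
            & (cols.den1 != MISSING)
        )
        for cls in ("HM", "CM"):
            is_cls = (classes == cls) & ~bad
            for sname, smask in stratum_masks.items():
                sel = is_cls & smask
                n_anc = int(sel.sum())
                hd_intact = sel & ~lost["hominini"]
                n_hd = int(hd_intact.sum())
                for b in branches:
                    if b in ("chimpanzee", "hominini"):
                        denom, num = n_anc, int((lost[b] & sel).sum())
                    else:
                        denom, num = n_hd, int((lost[b] & hd_intact).sum())
                    acc.setdefault((cls, b, sname), []).append((denom, num))
                # Denisovan homozygosity among derived informative sites
                den_sites = masks["denisovan"][pos_matrix] & hd_intact[:, None]
                flat = pos_matrix[den_sites]
                if len(flat):
                    hom_frac_acc.setdefault((cls, sname), []).append(
                        float(hom_derived[flat].mean())
                    )

    rows = []
    for (cls, b, sname), vals in acc.items():
        denoms = np.array([v[0] for v in vals], dtype=float)
        nums = np.array([v[1] for v in vals], dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(denoms > 0, nums / denoms, np.nan)
        if np.all(np.isnan(rates)):
            rates = np.full_like(rates, np.nan)
            stats_ok = False
        else:
            stats_ok = True
        hom = hom_frac_acc.get((cls, sname))
        rows.append(
            {
                "motif_class": cls,
                "branch": b,
                "stratum": sname,
                "N_ancestral": float(np.mean(denoms)),
                "n_lost": float(np.mean(nums)),
                "loss_rate": float(np.nanmean(rates)) if stats_ok else np.nan,
                "loss_rate_sd": float(np.nanstd(rates)) if stats_ok else np.nan,
                "loss_rate_min": float(np.nanmin(rates)) if stats_ok else np.nan,
                "loss_rate_max": float(np.nanmax(rates)) if stats_ok else np.nan,
                "hom_fraction": (
                    float(np.mean(hom)) if (b == "denisovan" and hom) else np.nan
                ),
            }
        )
    order = {b: i for i, b in enumerate(branches)}
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["motif_class", "stratum", "branch"],
        key=lambda s: s.map(order) if s.name == "branch" else s,
        kind="stable",
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Proportion test (continuity-corrected Z)
# ---------------------------------------------------------------------------


def proportion_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided normal-approximate Z-test for two proportions with Yates
    continuity correction and pooled variance."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 1.0
    cc = 0.5 * (1.0 / n1 + 1.0 / n2)
    num = max(abs(p1 - p2) - cc, 0.0)
    sd = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = num / sd
    return float(min(max(2.0 * stats.norm.sf(z), 0.0), 1.0))


# ---------------------------------------------------------------------------
# DAF extraction
# ---------------------------------------------------------------------------


def extract_daf(
    sites: pd.DataFrame,
    af_table: pd.DataFrame,
    reference: np.ndarray,
) -> tuple[pd.DataFrame, int]:
    """Derived-allele frequencies at motif informative sites.

    ``sites`` needs columns (chrom, pos, ancestral_base) with ancestral_base
    a base code (0..3).  A site present in the AF table yields the frequency
    of its derived (non-ancestral) allele; a site absent from the table is a
    fixed change (DAF = 1) when the reference carries a non-ancestral base,
    and yields no value when the reference is intact.  Rows whose table
    alleles do not include the ancestral base are skipped and counted.
    """
    from .io import BASES

    af_idx = {
        (r.chrom, r.pos): (r.ref, r.alt, r.af) for r in af_table.itertuples()
    }
    rows, mismatches = [], 0
    for r in sites.itertuples():
        anc = BASES[r.ancestral_base]
        rec = af_idx.get((r.chrom, r.pos))
        if rec is not None:
            ref, alt, af = rec
            if anc == ref:
                daf = af
            elif anc == alt:
                daf = 1.0 - af
            else:
                mismatches += 1
                continue
            rows.append((r.chrom, r.pos, daf, False))
        else:
            ref_base = int(reference[r.pos])
            if ref_base != r.ancestral_base and ref_base != 255:
                rows.append((r.chrom, r.pos, 1.0, True))
    out = pd.DataFrame(rows, columns=["chrom", "pos", "daf", "fixed"])
    if mismatches:
        import warnings

        warnings.warn(f"extract_daf: skipped {mismatches} allele-mismatch rows")
    return out, mismatches


# ---------------------------------------------------------------------------
# Recombination profiles around anchors
# ---------------------------------------------------------------------------


def recomb_profile(
    anchors: np.ndarray,
    rmap: RecombMap,
    chrom: str,
    half_span: int = 10_000,
    window: int = 2_000,
    step: int = 1_000,
) -> pd.DataFrame:
    """Mean crossover rate in overlapping windows around anchor midpoints.

    Returns one row per offset: bp-weighted mean of cM/Mb across anchors
    whose window is fully covered by the map, with a normal-approximation
    95% CI and the number of contributing anchors.
    """
    anchors = np.asarray(anchors, dtype=float)
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    offsets = np.arange(-half_span, half_span + 1, step)
    positions, _, cum = rmap.chrom_maps[chrom]
    lo_cov, hi_cov = positions[0], positions[-1]

    rows = []
    for off in offsets:
        s = anchors + off - window / 2
        e = anchors + off + window / 2
        covered = (s >= lo_cov) & (e <= hi_cov)
        cms = np.interp(s[covered], positions, cum)
        cme = np.interp(e[covered], positions, cum)
        vals = (cme - cms) / (window / 1e6)
        n = len(vals)
        mean = float(np.mean(vals)) if n else np.nan
        se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "offset": int(off),
                "mean_rate": mean,
                "ci_lo": mean - 1.96 * se,
                "ci_hi": mean + 1.96 * se,
                "n_anchors": n,
            }
        )
    return pd.DataFrame(rows)
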