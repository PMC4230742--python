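"""Synthetic data with known ground truth.

Everything the pipeline consumes can be generated here: quartet alignment
columns (human-chimp ancestor, human, diploid Denisovan, chimpanzee) with
branch-planted substitutions, annotation tracks for the filter tiers,
hotspot/THE1-like interval tracks, gamma-distributed recombination maps,
and derived-allele-frequency spectra drawn from the Poisson-field model.
A forward Wright-Fisher simulator provides an independent oracle for the
diffusion formulas.

Default parameters mirror the study conditions: n = 2184 sampled
chromosomes, 4,440 hotspot (HM) and 4,393 control (CM) motifs, per-branch
substitution rates that reproduce the observed control-motif loss rates
(~5.3% chimpanzee, ~4.5% Hominini, ~0.5% Denisovan, ~0.4% human over 10
informative sites), conversion intensity G = 8.55, and a crossover-rate
gamma law with mean 5.02 cM/Mb and shape 0.28.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as hio
from . import sfs
from .motifs import CM, HM, MotifHit, MotifPattern

__all__ = [
    "SimConfig",
    "BRANCHES",
    "simulate_daf_spectrum",
    "simulate_class_counts",
    "simulate_wright_fisher",
    "WrightFisherResult",
    "simulate_quartet_alignment",
    "QuartetSimulation",
    "expected_gcstar",
]

BRANCHES = ("chimpanzee", "hominini", "human", "denisovan")

_WEAK = np.array([True, False, False, True])  # A, C, G, T


def component_rng(seed: int, name: str) -> np.random.Generator:
    """Independent stream per component, derived from one root seed by
    stable hashing of the component name."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic study."""

    seed: int = 0
    n_chrom: int = 2184
    diploid_size: int = 10_000
    scaled_mutation: float = 32.5  # theta*L per class; ~500 SNPs/class at n=2184
    G_true: float = 8.55
    r_distortions: np.ndarray | None = None
    L_HM: int = 4440
    L_CM: int = 4393
    branch_sub_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "chimpanzee": 0.0055,
            "hominini": 0.0046,
            "denisovan": 0.0005,
            "human": 0.0004,
        }
    )
    hm_excess_rates: Mapping[str, float] = field(
        default_factory=lambda: {"human": 0.0014, "denisovan": 0.0005}
    )
    gbgc_bias: Mapping[str, float] = field(
        default_factory=lambda: {"human": 0.5, "hominini": 0.1}
    )
    het_rate: float = 2e-4
    map_mean: float = 5.02
    map_shape: float = 0.28
    gc_content: float = 0.4
    motif_spacing: int = 1000
    seq_length: int | None = None
    hotspot_fraction: float = 0.28
    hotspot_width: int = 2000
    hotspot_rate: float = 10.0
    the1_fraction: float = 0.033
    the1_width: int = 350
    fixed_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"HM": 0.037, "CM": 0.002}
    )
    chrom: str = "chrSim"

    def __post_init__(self) -> None:
        if self.n_chrom < 2 or self.diploid_size < 2:
            raise ValueError("n_chrom and diploid_size must be >= 2")
        if self.scaled_mutation <= 0:
            raise ValueError("scaled_mutation must be positive")
        if self.G_true < 0:
            raise ValueError("G_true must be non-negative")
        if self.r_distortions is not None:
            r = np.asarray(self.r_distortions, dtype=float)
            if r[0] != 1.0:
                raise ValueError("r_distortions[0] must be 1")
            if np.any(r <= 0):
                raise ValueError("r_distortions must be positive")
            self.r_distortions = r
        for name, rate in {**self.branch_sub_rates, **self.hm_excess_rates}.items():
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"substitution rate for {name} out of [0, 1)")
        for name, b in self.gbgc_bias.items():
            if not 0.0 <= b < 1.0:
                raise ValueError(f"gBGC bias for {name} out of [0, 1)")
        if not 0.0 <= self.het_rate < 1.0:
            raise ValueError("het_rate out of [0, 1)")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content out of (0, 1)")


# ---------------------------------------------------------------------------
# DAF spectra from the Poisson-field model
# ---------------------------------------------------------------------------


def simulate_daf_spectrum(
    config: SimConfig, bins: np.ndarray | None = None, m: int = 5
) -> sfs.DAFSpectrum:
    """Draw one paired DAF spectrum: neutral class at G = 0, test class at
    G = G_true, each bin Poisson with mean r_j * theta * int_bin H."""
    edges = sfs.make_bins(config.n_chrom, m) if bins is None else np.asarray(bins, float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    rng = component_rng(config.seed, "daf_spectrum")
    nb = len(edges) - 1
    r = np.ones(nb) if config.r_distortions is None else np.asarray(config.r_distortions)
    if len(r) != nb:
        raise ValueError("r_distortions must have one entry per bin")
    mean_n = sfs.expected_bin_counts(0.0, edges, r, config.scaled_mutation)
    mean_t = sfs.expected_bin_counts(config.G_true, edges, r, config.scaled_mutation)
    return sfs.DAFSpectrum(
        n_chrom=config.n_chrom,
        edges=edges,
        counts_neutral=rng.poisson(mean_n),
        counts_test=rng.poisson(mean_t),
        L_neutral=config.L_CM,
        L_test=config.L_HM,
        truth={
            "G_true": config.G_true,
            "r": r,
            "scaled_mutation": config.scaled_mutation,
            "mean_neutral": mean_n,
            "mean_test": mean_t,
        },
    )


def simulate_class_counts(
    config: SimConfig, n: int | None = None, n_reps: int = 1
) -> dict:
    """Draw unbinned per-frequency-class counts k_i (i = 1..n-1) from the
    exact discrete model (binomial sampling retained); used as the slow
    oracle for the continuous approximation.  Count arrays have shape
    (n_reps, n-1)."""
    n = config.n_chrom if n is None else n
    rng = component_rng(config.seed, "class_counts")
    mean_n = sfs.discrete_class_means(0.0, n, config.scaled_mutation)
    mean_t = sfs.discrete_class_means(config.G_true, n, config.scaled_mutation)
    return {
        "n": n,
        "counts_neutral": rng.poisson(mean_n, size=(n_reps, n - 1)),
        "counts_test": rng.poisson(mean_t, size=(n_reps, n - 1)),
        "mean_neutral": mean_n,
        "mean_test": mean_t,
    }


# ---------------------------------------------------------------------------
# Wright-Fisher forward simulator (diffusion oracle)
# ---------------------------------------------------------------------------


@dataclass
class WrightFisherResult:
    fixed: np.ndarray
    generations: np.ndarray

    @property
    def n_reps(self) -> int:
        return len(self.fixed)

    def fixation_probability(self) -> tuple[float, float]:
        p = float(np.mean(self.fixed))
        se = float(np.sqrt(max(p * (1 - p), 1e-300) / self.n_reps))
        return p, se

    def mean_fixation_time(self) -> tuple[float, float]:
        t = self.generations[self.fixed]
        if len(t) == 0:
            return np.nan, np.nan
        return float(np.mean(t)), float(np.std(t, ddof=1) / np.sqrt(len(t)))


def simulate_wright_fisher(
    N: int,
    g: float,
    x0: float,
    n_reps: int,
    seed: int = 0,
    max_gen: int = 10_000_000,
) -> WrightFisherResult:
    """Forward Wright-Fisher simulation of a semidominant conversion/
    selection advantage: a heterozygote transmits the favored allele with
    probability (1+g)/2, i.e. deterministic change g*x*(1-x) per
    generation, so 4*N*g corresponds to the package-wide G scaling.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if not 0.0 < x0 < 1.0:
        raise ValueError("x0 must lie strictly inside (0, 1)")
    if g < 0:
        raise ValueError("g must be non-negative")
    rng = component_rng(seed, "wright_fisher")
    two_n = 2 * N
    x = np.full(n_reps, x0)
    gens = np.zeros(n_reps, dtype=np.int64)
    fixed = np.zeros(n_reps, dtype=bool)
    active = np.arange(n_reps)
    gen = 0
    while len(active) and gen < max_gen:
        gen += 1
        xa = x[active]
        xp = np.clip(xa + g * xa * (1.0 - xa), 0.0, 1.0)
        xa = rng.binomial(two_n, xp).astype(float) / two_n
        x[active] = xa
        gens[active] = gen
        done = (xa == 0.0) | (xa == 1.0)
        fixed[active[xa == 1.0]] = True
        active = active[~done]
    if len(active):
        raise RuntimeError(f"{len(active)} replicates unabsorbed after {max_gen} gen")
    return WrightFisherResult(fixed=fixed, generations=gens)


# ---------------------------------------------------------------------------
# Quartet alignment with planted truth
# ---------------------------------------------------------------------------


def _substitute(rng, codes: np.ndarray, idx: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """New bases for ``codes[idx]`` under the symmetric 3-target model with
    per-site strong/weak bias b: strong targets get weight (1+b), weak
    targets (1-b).  Returns the replacement codes."""
    old = codes[idx]
    weights = np.ones((len(idx), 4))
    weights[np.arange(len(idx)), old] = 0.0
    strong = ~_WEAK  # C, G
    weights[:, strong] *= (1.0 + bias)[:, None]
    weights[:, _WEAK] *= (1.0 - bias)[:, None]
    weights /= weights.sum(axis=1, keepdims=True)
    u = rng.random(len(idx))
    return (np.cumsum(weights, axis=1) < u[:, None]).sum(axis=1).astype(np.uint8)


def expected_gcstar(bias: float) -> float:
    """Stationary/equilibrium GC of the substitution-direction model with
    strong/weak bias b (closed form; 0.5 at b = 0)."""
    f_ws = 2.0 * (1.0 + bias) / (3.0 + bias)
    f_sw = 2.0 * (1.0 - bias) / (3.0 - bias)
    return f_ws / (f_ws + f_sw)


@dataclass
class QuartetSimulation:
    """Bundle of synthetic inputs plus the planted truth."""

    config: SimConfig
    ancestor: np.ndarray       # uint8 codes at the human-chimp ancestor
    hd_ancestor: np.ndarray    # human-Denisovan ancestor (hominini applied)
    human: np.ndarray
    den1: np.ndarray
    den2: np.ndarray
    chimp: np.ndarray
    annotations: pd.DataFrame
    motifs: list[MotifHit]
    truth: pd.DataFrame
    hotspots: pd.DataFrame
    the1: pd.DataFrame
    recomb_map: hio.RecombMap
    af_table: pd.DataFrame

    @property
    def chrom(self) -> str:
        return self.config.chrom

    def sequences(self) -> dict[str, str]:
        return {
            "ancestor": hio.decode_seq(self.ancestor),
            "human": hio.decode_seq(self.human),
            "denisovan_1": hio.decode_seq(self.den1),
            "denisovan_2": hio.decode_seq(self.den2),
            "chimpanzee": hio.decode_seq(self.chimp),
        }

    def motif_bed(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [h.chrom for h in self.motifs],
                "start": [h.start for h in self.motifs],
                "end": [h.end for h in self.motifs],
                "name": [h.motif_id for h in self.motifs],
                "score": 0,
                "strand": [h.strand for h in self.motifs],
            }
        )

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seed = self.config.seed
        hio.write_fasta(self.sequences(), outdir / "quartet.fa", seed=seed)
        hio.write_bed(self.motif_bed(), outdir / "motifs.bed", seed=seed)
        hio.write_bed(self.hotspots, outdir / "hotspots.bed", seed=seed)
        hio.write_bed(self.the1, outdir / "the1.bed", seed=seed)
        hio.write_recomb_map(self.recomb_map, outdir / "recomb_map.tsv", seed=seed)
        hio.write_table(self.truth, outdir / "truth_mutations.tsv", seed=seed)
        hio.write_table(self.annotations, outdir / "annotations.tsv", seed=seed)
        af = self.af_table.copy()
        af["pos"] = af["pos"] + 1  # 1-based on disk
        af.columns = ["CHROM", "POS", "REF", "ALT", "AF"]
        hio.write_table(af, outdir / "af_table.tsv", seed=seed)


def _sample_sojourn(rng, G: float, n_chrom: int, size: int) -> np.ndarray:
    """Sample frequencies from H(x, G) restricted to [1/n, 1), by inverse
    CDF on a log-spaced grid."""
    lo = 1.0 / n_chrom
    grid = np.exp(np.linspace(np.log(lo), np.log(1.0 - 1e-9), 4000))
    h = sfs.sojourn_density(grid, G)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (h[1:] + h[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    u = rng.random(size)
    return np.interp(u, cdf, grid)


def simulate_quartet_alignment(config: SimConfig) -> QuartetSimulation:
    """Generate the full quartet with planted substitutions and truth.

    The ancestral sequence is i.i.d. with the configured GC content; HM and
    CM motifs are planted at non-overlapping loci on random strands; each
    branch receives Bernoulli background substitutions at its configured
    rate, HM comparison-informative sites receive extra losses in the
    branches under conversion drive, and substitution direction is
    strong/weak-biased inside hotspot intervals on the branches listed in
    ``gbgc_bias``.  The Denisovan genotype is heterozygous at additional
    sites with probability ``het_rate``.
    """
    cfg = config
    n_motifs = cfg.L_HM + cfg.L_CM
    L = cfg.seq_length or (cfg.motif_spacing * n_motifs + 2000)
    slot = (L - 2000) // n_motifs
    if slot < 40:
        raise ValueError(
            f"motif density too high: {n_motifs} motifs in {L} bp "
            f"({slot} bp per motif; need >= 40)"
        )
    rng_seq = component_rng(cfg.seed, "sequence")
    rng_mut = component_rng(cfg.seed, "mutations")
    rng_map = component_rng(cfg.seed, "recomb_map")
    rng_ann = component_rng(cfg.seed, "annotations")
    rng_af = component_rng(cfg.seed, "allele_freqs")

    gc = cfg.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    anc = rng_seq.choice(4, size=L, p=probs).astype(np.uint8)

    # --- plant motifs ------------------------------------------------------
    from .motifs import revcomp

    starts = 1000 + np.arange(n_motifs) * slot
    starts = starts + rng_seq.integers(0, max(slot - 20, 1), size=n_motifs)
    ids = np.array(["HM"] * cfg.L_HM + ["CM"] * cfg.L_CM)
    rng_seq.shuffle(ids)
    strands = np.where(rng_seq.random(n_motifs) < 0.5, "+", "-")
    pattern_by_id: dict[str, MotifPattern] = {"HM": HM, "CM": CM}

    pos13 = starts[:, None] + np.arange(13)[None, :]
    values = np.empty((n_motifs, 13), dtype=np.uint8)
    n_fill = rng_seq.integers(0, 4, size=(n_motifs, 2)).astype(np.uint8)
    info_matrix = np.empty((n_motifs, 10), dtype=np.int64)
    for mid in ("HM", "CM"):
        pat = pattern_by_id[mid]
        offsets = np.array(sorted(pat.comparison_informative_positions))
        for strand in ("+", "-"):
            sel = (ids == mid) & (strands == strand)
            template = pat.pattern if strand == "+" else revcomp(pat.pattern)
            codes = hio.encode_seq(template)
            n_slots = np.flatnonzero(codes == hio.MISSING)
            values[sel] = codes
            values[np.ix_(np.flatnonzero(sel), n_slots)] = n_fill[sel]
            if strand == "+":
                info_matrix[sel] = starts[sel, None] + offsets[None, :]
            else:
                info_matrix[sel] = starts[sel, None] + np.sort(12 - offsets)[None, :]
    anc[pos13] = values

    hits: list[MotifHit] = [
        MotifHit(
            cfg.chrom,
            int(s),
            int(s) + 13,
            strand,
            mid,
            hio.decode_seq(values[i]),
        )
        for i, (s, mid, strand) in enumerate(zip(starts, ids, strands))
    ]
    info_pos = {h: info_matrix[i] for i, h in enumerate(hits)}

    # --- interval tracks ---------------------------------------------------
    hm_hits = [h for h in hits if h.motif_id == "HM"]
    n_hot = int(round(cfg.hotspot_fraction * len(hm_hits)))
    hot_idx = rng_seq.choice(len(hm_hits), size=n_hot, replace=False)
    hot_rows = []
    for i in sorted(hot_idx):
        mid_pos = (hm_hits[i].start + hm_hits[i].end) // 2
        hot_rows.append(
            (cfg.chrom, max(0, mid_pos - cfg.hotspot_width // 2),
             min(L, mid_pos + cfg.hotspot_width // 2), f"hotspot_{i}", 0, "+")
        )
    hotspots = pd.DataFrame(
        hot_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    n_the1 = int(round(cfg.the1_fraction * len(hm_hits)))
    the1_idx = rng_seq.choice(len(hm_hits), size=n_the1, replace=False)
    the1_rows = []
    for i in sorted(the1_idx):
        mid_pos = (hm_hits[i].start + hm_hits[i].end) // 2
        the1_rows.append(
            (cfg.chrom, max(0, mid_pos - cfg.the1_width // 2),
             min(L, mid_pos + cfg.the1_width // 2), f"THE1_{i}", 0, "+")
        )
    the1 = pd.DataFrame(
        the1_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )

    in_hotspot = np.zeros(L, dtype=bool)
    for _, row in hotspots.iterrows():
        in_hotspot[row["start"] : row["end"]] = True

    # --- branch substitutions ---------------------------------------------
    site_motif = np.full(L, -1, dtype=np.int64)  # informative-site -> hit index
    site_motif[info_matrix] = np.arange(n_motifs)[:, None]
    motif_class = ids
    base_lut = np.array(list(hio.BASES))
    truth_frames: list[pd.DataFrame] = []

    def record(idx: np.ndarray, old: np.ndarray, new: np.ndarray, branch: str):
        j = site_motif[idx]
        truth_frames.append(
            pd.DataFrame(
                {
                    "position": idx,
                    "branch": branch,
                    "from_base": base_lut[old],
                    "to_base": base_lut[new],
                    "motif_class": np.where(j >= 0, motif_class[np.maximum(j, 0)], ""),
                    "motif_index": j,
                }
            )
        )

    hm_info_flat = info_matrix[ids == "HM"].ravel()

    def mutate_branch(base_seq: np.ndarray, branch: str) -> np.ndarray:
        mask = rng_mut.random(L) < cfg.branch_sub_rates.get(branch, 0.0)
        excess = cfg.hm_excess_rates.get(branch, 0.0)
        if excess > 0:
            extra = hm_info_flat[rng_mut.random(len(hm_info_flat)) < excess]
            mask[extra] = True
        idx = np.flatnonzero(mask)
        out = base_seq.copy()
        if len(idx) == 0:
            return out
        bias_site = np.where(in_hotspot[idx], cfg.gbgc_bias.get(branch, 0.0), 0.0)
        new = _substitute(rng_mut, out, idx, bias_site)
        record(idx, out[idx], new, branch)
        out[idx] = new
        return out

    chimp = mutate_branch(anc, "chimpanzee")
    hd = mutate_branch(anc, "hominini")
    human = mutate_branch(hd, "human")
    den = mutate_branch(hd, "denisovan")

    den1 = den.copy()
    den2 = den.copy()
    het_idx = np.flatnonzero(rng_mut.random(L) < cfg.het_rate)
    if len(het_idx):
        new = _substitute(rng_mut, den2, het_idx, np.zeros(len(het_idx)))
        record(het_idx, den2[het_idx], new, "denisovan_het")
        den2[het_idx] = new

    truth = (
        pd.concat(truth_frames, ignore_index=True)
        if truth_frames
        else pd.DataFrame(
            columns=["position", "branch", "from_base", "to_base", "motif_class",
                     "motif_index"]
        )
    )
    truth = truth.sort_values(["position", "branch"], kind="stable").reset_index(
        drop=True
    )

    # --- annotation tracks --------------------------------------------------
    # per-site failure rates tuned so motif retention along F1/F2/F3
    # mirrors the observed filter cascade (~96%/78%/~45% of motifs kept)
    u8 = np.uint8
    annotations = pd.DataFrame(
        {
            "position": np.arange(L, dtype=np.int64),
            "coverage": np.minimum(rng_ann.poisson(31, size=L), 255).astype(u8),
            "map20": (rng_ann.random(L) < 0.97).astype(u8),
            "lowqual": (rng_ann.random(L) < 0.015).astype(u8),
            "syserr": (rng_ann.random(L) < 0.005).astype(u8),
            "paralogs_human": np.where(rng_ann.random(L) < 0.995, 1, 2).astype(u8),
            "paralogs_chimp": np.where(rng_ann.random(L) < 0.995, 1, 2).astype(u8),
            "filtered_alignment": (rng_ann.random(L) < 0.985).astype(u8),
            "concordance": rng_ann.choice(
                np.array([4, 3, 2], dtype=u8), size=L, p=[0.985, 0.009, 0.006]
            ),
            "den_missing": (rng_ann.random(L) < 0.002).astype(u8),
            "indel": (rng_ann.random(L) < 0.002).astype(u8),
        }
    )
    miss = annotations["den_missing"].to_numpy().astype(bool)
    den1 = den1.copy()
    den2 = den2.copy()
    den1[miss] = hio.MISSING
    den2[miss] = hio.MISSING

    # --- recombination map ---------------------------------------------------
    seg = 2000
    seg_starts = np.arange(0, L + seg, seg)
    n_seg = len(seg_starts) - 1
    rates = rng_map.gamma(cfg.map_shape, cfg.map_mean / cfg.map_shape, size=n_seg)
    hot_seg = np.zeros(n_seg, dtype=bool)
    for _, row in hotspots.iterrows():
        hot_seg[row["start"] // seg : row["end"] // seg + 1] = True
    rates[hot_seg] = cfg.hotspot_rate
    rmap = hio.RecombMap.from_arrays(
        cfg.chrom, seg_starts, np.concatenate([rates, [0.0]])
    )

    # --- allele-frequency table for human-branch mutations -------------------
    hum_truth = truth[truth["branch"] == "human"].reset_index(drop=True)
    cls_arr = hum_truth["motif_class"].to_numpy()
    fixed_p = np.array(
        [cfg.fixed_fraction.get(c, cfg.fixed_fraction.get("CM", 0.002))
         for c in cls_arr]
    )
    poly = rng_af.random(len(hum_truth)) >= fixed_p  # fixed sites stay out
    is_hm = cls_arr == "HM"
    af = np.empty(len(hum_truth))
    af[is_hm] = _sample_sojourn(rng_af, cfg.G_true, cfg.n_chrom, int(is_hm.sum()))
    af[~is_hm] = _sample_sojourn(rng_af, 0.0, cfg.n_chrom, int((~is_hm).sum()))
    frames = [
        pd.DataFrame(
            {
                "chrom": cfg.chrom,
                "pos": hum_truth["position"].to_numpy()[poly],
                "ref": hum_truth["from_base"].to_numpy()[poly],
                "alt": hum_truth["to_base"].to_numpy()[poly],
                "af": np.round(af[poly], 6),
            }
        )
    ]
    # segregating variants invisible in the reference: the bulk of the DAF
    # spectrum (expected count per class = theta * int H over [1/n, 1))
    lut = np.array(list(hio.BASES))
    for cls, G_cls in (("HM", cfg.G_true), ("CM", 0.0)):
        sites = info_matrix[ids == cls].ravel()
        lam = cfg.scaled_mutation * float(
            sfs.bin_integrals(G_cls, np.array([1.0 / cfg.n_chrom, 1.0]))[0]
        )
        n_poly = min(rng_af.poisson(lam), len(sites))
        pos = rng_af.choice(sites, size=n_poly, replace=False)
        anc_codes = anc[pos]
        alt_codes = (anc_codes + rng_af.integers(1, 4, size=n_poly)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": cfg.chrom,
                    "pos": pos,
                    "ref": lut[anc_codes],
                    "alt": lut[alt_codes.astype(np.uint8)],
                    "af": np.round(
                        _sample_sojourn(rng_af, G_cls, cfg.n_chrom, n_poly), 6
                    ),
                }
            )
        )
    af_table = (
        pd.concat(frames, ignore_index=True)
        .drop_duplicates(subset=["chrom", "pos"], keep="first")
        .sort_values("pos", kind="stable")
        .reset_index(drop=True)
    )

    return QuartetSimulation(
        config=cfg,
        ancestor=anc,
        hd_ancestor=hd,
        human=human,
        den1=den1,
        den2=den2,
        chimp=chimp,
        annotations=annotations,
        motifs=hits,
        truth=truth,
        hotspots=hotspots,
        the1=the1,
        recomb_map=rmap,
        af_table=af_table,
    )
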