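"""Pipeline driver: simulate -> scan -> classify -> loss rates -> DAF ->
conversion-intensity fit -> GC* -> lifespan, with provenance-stamped
outputs and stage timing."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import branches, gcstar, io as hio, lifespan, motifs, sfs, synth

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("hotspotdrive")


@dataclass
class PipelineConfig:
    outdir: str = "hotspotdrive_out"
    seed: int = 0
    filter_tier: str = "F2"
    m_bins: int = 5
    lossrate_repeats: int = 20
    verbosity: str = "INFO"
    sim: dict = field(default_factory=dict)
    lifespan_params: dict = field(default_factory=dict)
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate", "scan", "lossrates", "daf", "fit", "gcstar", "lifespan",
        ]
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def sim_config(self) -> synth.SimConfig:
        return synth.SimConfig(seed=self.seed, **self.sim)


def _stage(name):
    def deco(fun):
        def wrapper(state, cfg):
            t0 = time.perf_counter()
            fun(state, cfg)
            log.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)

        wrapper.stage_name = name
        return wrapper

    return deco


@_stage("simulate")
def _simulate(state, cfg):
    sim = synth.simulate_quartet_alignment(cfg.sim_config())
    sim.write(Path(cfg.outdir) / "inputs")
    state["sim"] = sim
    state["cols"] = branches.QuartetColumns.from_simulation(sim)
    log.info("  %d bp, %d motifs, %d planted mutations",
             len(sim.ancestor), len(sim.motifs), len(sim.truth))


@_stage("scan")
def _scan(state, cfg):
    sim = state["sim"]
    seq = hio.decode_seq(sim.ancestor)
    hits = []
    for pat in (motifs.HM, motifs.CM):
        hits.extend(motifs.scan_motifs(seq, pat, chrom=sim.chrom))
    hits.sort()
    state["hits"] = hits
    bed = pd.DataFrame(
        [(h.chrom, h.start, h.end, h.motif_id, 0, h.strand) for h in hits],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    hio.write_bed(bed, Path(cfg.outdir) / "scanned_motifs.bed", seed=cfg.seed)
    log.info("  %d motif hits", len(hits))


@_stage("lossrates")
def _lossrates(state, cfg):
    sim = state["sim"]
    table = branches.compute_loss_rates(
        state["hits"],
        state["cols"],
        tier=cfg.filter_tier,
        strata={"hotspots": sim.hotspots, "the1": sim.the1},
        repeats=cfg.lossrate_repeats,
        seed=cfg.seed,
    )
    state["loss_rates"] = table
    hio.write_table(table, Path(cfg.outdir) / "loss_rates.tsv", seed=cfg.seed)


@_stage("daf")
def _daf(state, cfg):
    sim = state["sim"]
    if sim.af_table is None or len(sim.af_table) == 0:
        log.warning("  no allele-frequency table; skipping DAF and fit stages")
        state["skip_fit"] = True
        return
    cols = state["cols"]
    site_mask = branches.apply_filter(cols, cfg.filter_tier)
    # restrict to motifs intact at the human-Denisovan ancestor
    den = branches.resolve_denisovan(cols, np.random.default_rng(cfg.seed))
    hominini = branches.branch_mutation_masks(cols, den)["hominini"]
    daf_lists = {}
    for cls in ("HM", "CM"):
        hits = [h for h in state["hits"] if h.motif_id == cls]
        keep = branches.motif_filter_mask(site_mask, hits)
        rows = []
        for h, k in zip(hits, keep):
            if not k:
                continue
            pat = motifs.PATTERNS[cls]
            pos = h.informative_positions(pat)
            if hominini[pos].any():
                continue
            for p in pos:
                rows.append((sim.chrom, p, int(sim.ancestor[p])))
        sites = pd.DataFrame(rows, columns=["chrom", "pos", "ancestral_base"])
        daf, _ = branches.extract_daf(sites, sim.af_table, sim.human)
        daf_lists[cls] = daf
        hio.write_table(daf, Path(cfg.outdir) / f"daf_{cls}.tsv", seed=cfg.seed)
    state["daf"] = daf_lists


@_stage("fit")
def _fit(state, cfg):
    if state.get("skip_fit"):
        return
    sim = state["sim"]
    daf = state["daf"]
    spec = sfs.spectrum_from_daf(
        daf["CM"]["daf"], daf["HM"]["daf"],
        n_chrom=sim.config.n_chrom, m=cfg.m_bins,
        L_neutral=sim.config.L_CM, L_test=sim.config.L_HM,
    )
    result = sfs.fit(spec, "M1")
    state["fit"] = result
    with open(Path(cfg.outdir) / "dbgc_fit.txt", "w") as fh:
        fh.write(hio.provenance_header(cfg.seed) + "\n" + result.summary() + "\n")
    log.info("  G_hat=%.3g CI=[%.3g, %.3g]", result.G_hat, result.ci_lo, result.ci_hi)


@_stage("gcstar")
def _gcstar(state, cfg):
    sim = state["sim"]
    site_mask = branches.apply_filter(state["cols"], cfg.filter_tier)
    anchors = ((sim.hotspots["start"] + sim.hotspots["end"]) // 2).to_numpy()
    frames = []
    for branch in synth.BRANCHES:
        prof = gcstar.gcstar_profile(
            anchors, state["cols"], branch,
            span=5000, site_mask=site_mask, seed=cfg.seed,
        )
        prof.insert(0, "branch", branch)
        frames.append(prof)
    table = pd.concat(frames, ignore_index=True)
    state["gcstar_profile"] = table
    hio.write_table(table, Path(cfg.outdir) / "gcstar_profile.tsv", seed=cfg.seed)


@_stage("lifespan")
def _lifespan(state, cfg):
    params = lifespan.LifespanParams(**cfg.lifespan_params)
    sim = state["sim"]
    # gamma law of G from the local crossover rates at HM motifs
    mids = np.array(
        [(h.start + h.end) // 2 for h in state["hits"] if h.motif_id == "HM"]
    )
    rates = np.array(
        [sim.recomb_map.mean_rate(sim.chrom, m - 1000, m + 1000) for m in mids]
    )
    rates = rates[~np.isnan(rates)]
    rate_fit = sfs.fit_gamma_to_rates(rates)
    g_hat = state["fit"].G_hat if state.get("fit") else sim.config.G_true
    c = g_hat / rate_fit.mean if rate_fit.mean > 0 else 0.0
    dist = sfs.GDistribution(
        shape=rate_fit.shape, m_x=rate_fit.mean, c=c,
        zero_fraction=rate_fit.zero_fraction,
    )
    rows = [
        {"quantity": "loss_fraction_overall",
         "value": lifespan.expected_loss_fraction(dist, params)},
        {"quantity": "loss_fraction_top8pct",
         "value": lifespan.expected_loss_fraction(dist, params, (0.92, 1.0))},
        {"quantity": "mean_G", "value": dist.mean_G},
        {"quantity": "median_G", "value": dist.median()},
    ]
    table = pd.DataFrame(rows)
    state["lifespan"] = table
    hio.write_table(table, Path(cfg.outdir) / "lifespan.tsv", seed=cfg.seed)


_STAGES = {
    f.stage_name: f
    for f in (_simulate, _scan, _lossrates, _daf, _fit, _gcstar, _lifespan)
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in order; returns the state bundle."""
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), 20),
                        format="%(message)s")
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    state: dict = {}
    for name in config.stages:
        if name not in _STAGES:
            raise ValueError(f"unknown stage {name!r}")
        try:
            _STAGES[name](state, config)
        except Exception:
            log.error("stage %s failed", name)
            raise
    return state
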