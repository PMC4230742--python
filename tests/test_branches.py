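"""Filter tiers, branch assignment, loss rates, DAF and recombination profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hotspotdrive import branches, io as hio
from hotspotdrive.branches import (
    QuartetColumn,
    QuartetColumns,
    apply_filter,
    assign_branch,
    branch_mutation_masks,
    compute_loss_rates,
    extract_daf,
    proportion_test,
    recomb_profile,
)
from hotspotdrive.motifs import MotifHit


def _clean_annotations(n):
    return pd.DataFrame(
        {
            "position": np.arange(n),
            "coverage": np.full(n, 30),
            "map20": np.ones(n, int),
            "lowqual": np.zeros(n, int),
            "syserr": np.zeros(n, int),
            "paralogs_human": np.ones(n, int),
            "paralogs_chimp": np.ones(n, int),
            "filtered_alignment": np.ones(n, int),
            "concordance": np.full(n, 4),
            "den_missing": np.zeros(n, int),
            "indel": np.zeros(n, int),
        }
    )


def _cols(anc, hum, den1, den2, chimp, annotations=None):
    e = hio.encode_seq
    n = len(anc)
    return QuartetColumns(
        chrom="t",
        ancestral=e(anc),
        human=e(hum),
        den1=e(den1),
        den2=e(den2),
        chimp=e(chimp),
        annotations=_clean_annotations(n) if annotations is None else annotations,
    )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def test_missing_denisovan_fails_f1():
    ann = _clean_annotations(1)
    ann.loc[0, "den_missing"] = 1
    cols = _cols("A", "A", "N", "N", "A", ann)
    assert not apply_filter(cols, "F1")[0]


def test_coverage_15_passes_f1_f2_fails_f3():
    ann = _clean_annotations(1)
    ann.loc[0, "coverage"] = 15
    cols = _cols("A", "A", "A", "A", "A", ann)
    assert apply_filter(cols, "F1")[0]
    assert apply_filter(cols, "F2")[0]
    assert not apply_filter(cols, "F3")[0]


def test_coverage_47_fails_f3():
    ann = _clean_annotations(1)
    ann.loc[0, "coverage"] = 47
    cols = _cols("A", "A", "A", "A", "A", ann)
    assert not apply_filter(cols, "F3")[0]


def test_all_clean_columns_pass_every_tier():
    cols = _cols("ACGT", "ACGT", "ACGT", "ACGT", "ACGT")
    for tier in ("F1", "F2", "F3"):
        assert apply_filter(cols, tier).all()


def test_unknown_tier_rejected(clean_cols):
    with pytest.raises(ValueError):
        apply_filter(clean_cols, "F9")


def test_filter_monotone_on_simulated_tracks(het_cols):
    f1 = apply_filter(het_cols, "F1")
    f2 = apply_filter(het_cols, "F2")
    f3 = apply_filter(het_cols, "F3")
    assert np.all(f2 <= f1) and np.all(f3 <= f2)


# ---------------------------------------------------------------------------
# Branch assignment
# ---------------------------------------------------------------------------


def _col(anc, hum, den, chimp):
    e = lambda c: int(hio.encode_seq(c)[0])
    return QuartetColumn(0, e(anc), e(hum), (e(den[0]), e(den[1])), e(chimp))


@pytest.mark.parametrize(
    "anc,hum,den,chimp,expected",
    [
        ("A", "G", "GG", "A", "hominini"),
        ("A", "G", "AA", "A", "human"),
        ("A", "A", "GG", "A", "denisovan"),
        ("A", "C", "GG", "T", "excluded"),
        ("A", "A", "AA", "G", "chimpanzee"),
        ("A", "A", "AA", "A", "none"),
    ],
)
def test_assign_branch_rules(anc, hum, den, chimp, expected, rng):
    assert assign_branch(_col(anc, hum, den, chimp), rng) == expected


def test_heterozygote_resolution_splits_evenly(rng):
    """(anc A, hum G, den A/G): resolving to A gives 'human', to G gives
    'hominini'; over many draws both occur at ~50%."""
    col = _col("A", "G", "AG", "A")
    draws = [assign_branch(col, rng) for _ in range(4000)]
    frac = draws.count("human") / len(draws)
    assert set(draws) == {"human", "hominini"}
    assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(4000)


def test_branch_masks_consistent_with_scalar_rule(clean_cols, rng):
    den = branches.resolve_denisovan(clean_cols, rng)
    masks = branch_mutation_masks(clean_cols, den)
    # disjointness of hominin-side assignments
    assert not np.any(masks["hominini"] & masks["human"])
    assert not np.any(masks["hominini"] & masks["denisovan"])
    assert not np.any(masks["excluded"] & masks["hominini"])


# ---------------------------------------------------------------------------
# Loss rates
# ---------------------------------------------------------------------------


def _toy_hits(n, spacing=20):
    return [
        MotifHit("t", i * spacing, i * spacing + 13, "+", "HM", "")
        for i in range(n)
    ]


def _toy_cols(n_motifs, mutated, branch="human", spacing=20):
    """n_motifs planted HM motifs on an otherwise constant background;
    ``mutated`` motif indices carry one informative-site mutation."""
    L = n_motifs * spacing + 20
    anc = "A" * L
    seqs = {k: list(anc) for k in ("hum", "den", "chimp")}
    for j in mutated:
        pos = j * spacing + 2  # informative offset 2
        if branch == "human":
            seqs["hum"][pos] = "G"
        elif branch == "hominini":
            seqs["hum"][pos] = "G"
            seqs["den"][pos] = "G"
        elif branch == "chimpanzee":
            seqs["chimp"][pos] = "G"
    return _cols(
        anc, "".join(seqs["hum"]), "".join(seqs["den"]), "".join(seqs["den"]),
        "".join(seqs["chimp"]),
    )


def test_loss_rate_simple_count():
    hits = _toy_hits(100)
    cols = _toy_cols(100, mutated=[3, 50])
    table = compute_loss_rates(hits, cols, tier="F1", repeats=1)
    table = table[table.motif_class == "HM"]
    row = table[(table.branch == "human") & (table.stratum == "all")].iloc[0]
    assert row.N_ancestral == 100 and row.n_lost == 2
    assert row.loss_rate == pytest.approx(0.02)


def test_hominini_precedence_over_terminal():
    """A motif mutated in both Hominini and human branches counts once, as
    a Hominini loss, and leaves the terminal denominator."""
    hits = _toy_hits(10)
    cols = _toy_cols(10, mutated=[0], branch="hominini")
    # add a second, human-only mutation inside the same motif (offset 3)
    cols.human[3] = hio.encode_seq("C")[0]
    table = compute_loss_rates(hits, cols, tier="F1", repeats=1)
    table = table[table.motif_class == "HM"]
    g = lambda b: table[(table.branch == b) & (table.stratum == "all")].iloc[0]
    assert g("hominini").n_lost == 1
    assert g("human").n_lost == 0
    assert g("human").N_ancestral == 9


def test_loss_conservation(clean_sim, clean_cols):
    """Losses plus intact motifs account for every ancestral motif."""
    table = compute_loss_rates(clean_sim.motifs, clean_cols, tier="F1", repeats=1)
    sub = table[table.stratum == "all"]
    for cls in ("HM", "CM"):
        s = sub[sub.motif_class == cls].set_index("branch")
        n_anc = s.loc["chimpanzee", "N_ancestral"]
        assert s.loc["hominini", "N_ancestral"] == n_anc
        assert (
            s.loc["human", "N_ancestral"]
            == n_anc - s.loc["hominini", "n_lost"]
        )


def test_loss_rates_match_planted_truth(clean_sim, clean_cols):
    """With no heterozygotes the table equals the generator truth exactly."""
    sim = clean_sim
    table = compute_loss_rates(sim.motifs, clean_cols, tier="F1", repeats=1)
    site_mask = apply_filter(clean_cols, "F1")
    keep = branches.motif_filter_mask(site_mask, sim.motifs)
    info = {
        j: np.array(h.informative_positions(branches._PATTERNS[h.motif_id]))
        for j, h in enumerate(sim.motifs)
    }
    lost = {b: set() for b in ("chimpanzee", "hominini", "human", "denisovan")}
    for r in sim.truth[sim.truth.motif_index >= 0].itertuples():
        if r.branch in lost and r.position in info[r.motif_index]:
            lost[r.branch].add(r.motif_index)
    kept = {j for j, k in enumerate(keep) if k}
    cls = {j: h.motif_id for j, h in enumerate(sim.motifs)}
    for c in ("HM", "CM"):
        sel = {j for j in kept if cls[j] == c}
        hom = lost["hominini"] & sel
        expected = {
            "chimpanzee": len(lost["chimpanzee"] & sel),
            "hominini": len(hom),
            "human": len((lost["human"] & sel) - hom),
            "denisovan": len((lost["denisovan"] & sel) - hom),
        }
        sub = table[(table.motif_class == c) & (table.stratum == "all")]
        for b, n in expected.items():
            assert sub[sub.branch == b].iloc[0].n_lost == n


def test_loss_rates_with_heterozygotes_within_spread(het_sim, het_cols):
    """Averaged rates lie inside the min-max envelope across repeats."""
    table = compute_loss_rates(het_sim.motifs, het_cols, tier="F1", repeats=10)
    sub = table[(table.stratum == "all") & table.loss_rate.notna()]
    assert np.all(sub.loss_rate >= sub.loss_rate_min - 1e-12)
    assert np.all(sub.loss_rate <= sub.loss_rate_max + 1e-12)


def test_strata_any_overlap(clean_sim, clean_cols):
    table = compute_loss_rates(
        clean_sim.motifs,
        clean_cols,
        tier="F1",
        strata={"hotspots": clean_sim.hotspots},
        repeats=1,
    )
    sub = table[table.motif_class == "HM"].set_index(["stratum", "branch"])
    n_all = sub.loc[("all", "chimpanzee"), "N_ancestral"]
    n_in = sub.loc[("within_hotspots", "chimpanzee"), "N_ancestral"]
    n_out = sub.loc[("outside_hotspots", "chimpanzee"), "N_ancestral"]
    assert n_in + n_out == n_all
    assert n_in > 0


# ---------------------------------------------------------------------------
# Proportion test
# ---------------------------------------------------------------------------


def test_proportion_test_equal_rates_p_one():
    assert proportion_test(50, 1000, 50, 1000) == pytest.approx(1.0, abs=1e-9)


def test_proportion_test_observed_contrast():
    """THE1 versus non-THE1 loss-rate contrast (9/134 vs 69/4102)."""
    assert proportion_test(9, 134, 69, 4102) == pytest.approx(8.2e-5, rel=0.05)


def _reference_prop_test(x1, n1, x2, n2):
    p1, p2 = x1 / n1, x2 / n2
    p = (x1 + x2) / (n1 + n2)
    num = max(abs(p1 - p2) - 0.5 * (1 / n1 + 1 / n2), 0.0)
    z = num / np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    return 2 * stats.norm.sf(z)


def test_proportion_test_against_reference(rng):
    for _ in range(50):
        n1, n2 = rng.integers(10, 500, size=2)
        x1 = rng.integers(0, n1 + 1)
        x2 = rng.integers(0, n2 + 1)
        if x1 + x2 in (0, n1 + n2):
            continue
        assert proportion_test(x1, n1, x2, n2) == pytest.approx(
            min(_reference_prop_test(x1, n1, x2, n2), 1.0), abs=1e-12
        )


def test_proportion_test_validation():
    with pytest.raises(ValueError):
        proportion_test(1, 0, 1, 10)
    with pytest.raises(ValueError):
        proportion_test(11, 10, 1, 10)


# ---------------------------------------------------------------------------
# DAF extraction
# ---------------------------------------------------------------------------


def test_extract_daf_cases():
    af = pd.DataFrame(
        {
            "chrom": ["t", "t"],
            "pos": [5, 9],
            "ref": ["A", "C"],
            "alt": ["G", "T"],
            "af": [0.12, 0.4],
        }
    )
    sites = pd.DataFrame(
        {
            "chrom": ["t"] * 4,
            "pos": [5, 9, 20, 30],
            "ancestral_base": [0, 3, 0, 0],  # A, T, A, A
        }
    )
    ref = hio.encode_seq("A" * 20 + "G" + "A" * 10)  # derived base at 20
    out, mism = extract_daf(sites, af, ref)
    out = out.set_index("pos")
    assert out.loc[5, "daf"] == pytest.approx(0.12)  # anc == ref allele
    assert out.loc[9, "daf"] == pytest.approx(0.6)  # anc == alt allele
    assert out.loc[20, "daf"] == 1.0 and bool(out.loc[20, "fixed"])
    assert 30 not in out.index  # intact reference, no record
    assert mism == 0


def test_extract_daf_flags_allele_mismatch():
    af = pd.DataFrame(
        {"chrom": ["t"], "pos": [5], "ref": ["C"], "alt": ["G"], "af": [0.2]}
    )
    sites = pd.DataFrame({"chrom": ["t"], "pos": [5], "ancestral_base": [0]})
    with pytest.warns(UserWarning, match="mismatch"):
        out, mism = extract_daf(sites, af, hio.encode_seq("A" * 10))
    assert mism == 1 and len(out) == 0


# ---------------------------------------------------------------------------
# Recombination profiles
# ---------------------------------------------------------------------------


def test_recomb_profile_uniform_map_is_flat():
    rmap = hio.RecombMap.from_arrays("t", [0, 100_000], [1.0, 0.0])
    prof = recomb_profile(np.array([50_000]), rmap, "t", half_span=5000)
    assert prof.mean_rate.to_numpy() == pytest.approx(np.ones(len(prof)))
    assert prof.ci_hi.to_numpy() - prof.ci_lo.to_numpy() == pytest.approx(
        np.zeros(len(prof)), abs=1e-9
    )


def test_recomb_profile_hotspot_peak():
    rmap = hio.RecombMap.from_arrays(
        "t", [0, 49_000, 51_000, 100_000], [1.0, 10.0, 1.0, 0.0]
    )
    prof = recomb_profile(np.array([50_000]), rmap, "t", half_span=5000)
    center = prof[prof.offset == 0].iloc[0].mean_rate
    assert center == pytest.approx(10.0)  # 2 kb window inside the hotspot
    edge = prof[prof.offset == -5000].iloc[0].mean_rate
    assert edge == pytest.approx(1.0)


def test_recomb_profile_linear_in_rates():
    rmap1 = hio.RecombMap.from_arrays("t", [0, 40_000, 100_000], [1.0, 3.0, 0.0])
    rmap2 = hio.RecombMap.from_arrays("t", [0, 40_000, 100_000], [2.0, 6.0, 0.0])
    anchors = np.array([30_000, 50_000, 70_000])
    p1 = recomb_profile(anchors, rmap1, "t", half_span=4000)
    p2 = recomb_profile(anchors, rmap2, "t", half_span=4000)
    assert p2.mean_rate.to_numpy() == pytest.approx(2 * p1.mean_rate.to_numpy())


def test_recomb_profile_empty_anchor_set():
    rmap = hio.RecombMap.from_arrays("t", [0, 1000], [1.0, 0.0])
    with pytest.raises(ValueError):
        recomb_profile(np.array([]), rmap, "t")
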