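"""Window construction, the additive model, and BH FDR."""

import numpy as np
import pandas as pd
import pytest

from conftest import statsmodels_ols, toy_genotypes
from sexqtl import ciseqtl


def _probe_annot(rows):
    return pd.DataFrame(
        [(g, c, s) for _, g, c, s in rows],
        columns=["gene", "chromosome", "start"],
        index=pd.Index([r[0] for r in rows], name="probe_id"))


def test_window_boundary_closed_at_one_megabase():
    gm = toy_genotypes({"rs1": ["AG"]}, ["s1"], chromosome="7",
                       positions={"rs1": 10_000_000})
    annot = _probe_annot([
        ("at_bound", "G1", "7", 11_000_000),       # exactly 1 Mb -> included
        ("past_bound", "G2", "7", 11_000_001),     # 1 Mb + 1 -> excluded
        ("other_chrom", "G3", "8", 10_000_000),    # same position, wrong chrom
        ("upstream", "G4", "7", 9_000_000),        # exactly -1 Mb -> included
    ])
    (w,) = ciseqtl.build_cis_windows(gm, ["rs1"], annot)
    assert w.probe_ids == ["at_bound", "upstream"]


def test_window_requires_coordinates():
    gm = toy_genotypes({"rs1": ["AG"]}, ["s1"])
    gm.snp_annotation.loc["rs1", "position"] = np.nan
    with pytest.raises(ValueError, match="coordinates"):
        ciseqtl.build_cis_windows(gm, ["rs1"], _probe_annot([]))


def test_additive_fit_matches_statsmodels_on_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = int(rng.integers(30, 300))
        d = rng.binomial(2, rng.uniform(0.2, 0.5), n).astype(float)
        if np.unique(d).size < 2 or min(np.bincount(d.astype(int))[
                np.bincount(d.astype(int)) > 0]) < 3:
            continue
        s = (rng.random(n) < 0.5).astype(float)
        y = rng.normal(0, 1, n) + 0.3 * d + 0.2 * s
        res = ciseqtl.fit_additive_model(d, y, s)
        assert res.testable
        X = np.column_stack([np.ones(n), d, s])
        beta, se, t, p = statsmodels_ols(X, y)
        assert res.beta == pytest.approx(beta[1], abs=1e-8)
        assert res.se == pytest.approx(se[1], abs=1e-8)
        assert res.t == pytest.approx(t[1], abs=1e-8)
        assert res.p == pytest.approx(p[1], abs=1e-8)


def test_exact_linear_expression_recovered():
    rng = np.random.default_rng(8)
    d = rng.binomial(2, 0.5, 40).astype(float)
    s = (np.arange(40) % 2).astype(float)
    y = 2.0 * d
    res = ciseqtl.fit_additive_model(d, y, s)
    assert res.beta == pytest.approx(2.0, abs=1e-10)
    assert res.p < 1e-6
    assert res.direction_vs_risk == "increased"


def test_sign_convention_decreased():
    rng = np.random.default_rng(9)
    d = rng.binomial(2, 0.5, 60).astype(float)
    s = (np.arange(60) % 2).astype(float)
    y = -0.5 * d + rng.normal(0, 0.1, 60)
    res = ciseqtl.fit_additive_model(d, y, s)
    assert res.beta < 0
    assert res.direction_vs_risk == "decreased"


def test_monomorphic_and_sparse_classes_untestable():
    s = np.array([0.0, 1.0] * 10)
    y = np.random.default_rng(1).normal(size=20)
    res = ciseqtl.fit_additive_model(np.zeros(20), y, s)
    assert not res.testable and "monomorphic" in res.reason
    d = np.array([0.0] * 18 + [1.0] * 2)
    res = ciseqtl.fit_additive_model(d, y, s)
    assert not res.testable and "below min count" in res.reason


def test_missing_dosage_dropped_pairwise(cohort):
    _, gm, _, sex = cohort
    d = gm.dosage("rs7574865").to_numpy().copy()
    y = np.random.default_rng(3).normal(size=d.size)
    d[:5] = np.nan
    res = ciseqtl.fit_additive_model(d, y, sex.to_numpy())
    assert res.n_used == d.size - 5


def test_bh_fdr_hand_computed():
    q = ciseqtl.bh_fdr([0.01, 0.02, 0.03])
    assert np.allclose(q, [0.03, 0.03, 0.03])
    assert ciseqtl.bh_fdr([0.2]) == pytest.approx([0.2])
    assert np.allclose(ciseqtl.bh_fdr([1.0, 1.0, 1.0]), 1.0)


def test_bh_fdr_matches_statsmodels_and_is_permutation_invariant():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(10)
    for _ in range(100):
        p = rng.uniform(0, 1, int(rng.integers(1, 60)))
        q = ciseqtl.bh_fdr(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, ref, atol=1e-12)
        perm = rng.permutation(p.size)
        assert np.allclose(ciseqtl.bh_fdr(p[perm])[np.argsort(perm)], q)


def test_bh_fdr_rejects_nan():
    with pytest.raises(ValueError, match="NaN"):
        ciseqtl.bh_fdr([0.1, np.nan])


def test_scan_finds_planted_additive_effect():
    """A planted per-allele effect of 0.8 SD tops the scan with FDR < 0.05."""
    import sexqtl
    from sexqtl.synthdata import ProbeSpec, SnpSpec, SynthConfig

    hits = 0
    for seed in range(10):
        probes = [ProbeSpec("target", "TG", "1", 1_200_000)] + [
            ProbeSpec(f"null{i}", f"N{i}", "1", 1_000_000 + 1_000 * i)
            for i in range(50)]
        cfg = SynthConfig(
            snp_specs=[SnpSpec("rs1", "1", 1_500_000, "A", "G", 0.3)],
            probe_specs=probes,
            effect_map={("rs1", "target"): (0.8, 0.0, 0.0)},
            n_x_snps=0, n_y_probes=0, seed=seed)
        gm, em, sex = sexqtl.simulate_cohort(cfg)
        norm = sexqtl.zscore_normalize(em)
        windows = ciseqtl.build_cis_windows(gm, ["rs1"], norm.probe_annotation)
        scan = ciseqtl.run_cis_scan(gm, norm, windows, sex)
        top = scan.sort_values("p").iloc[0]
        if top["probe"] == "target" and top["fdr"] < 0.05:
            hits += 1
    assert hits == 10


def test_scan_with_no_windows_is_empty(cohort):
    _, gm, em, sex = cohort
    import sexqtl
    norm = sexqtl.zscore_normalize(
        sexqtl.filter_probes(em, 6.0)[0])
    out = ciseqtl.run_cis_scan(gm, norm, [], sex)
    assert len(out) == 0
    assert "fdr" in out.columns
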