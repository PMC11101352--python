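import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from telomr import instruments as iv
from telomr.instruments import (
    GenomicMask,
    HBB_MASK,
    HLA_MASK,
    LDMatrix,
    af_concordance_filter,
    apply_region_masks,
    clump,
    minrank_clump,
    multi_trait_steiger_filter,
    steiger_filter,
    steiger_z,
    two_phase_mediation_clump,
)
from telomr.simulate import SimulationConfig, simulate_gwas_triplet
from telomr.sumstats import align_pair, harmonize

from conftest import identity_ld, make_sumstats


def ld_from(snps, positions, r_pairs):
    m = len(snps)
    r = np.eye(m)
    idx = {s: i for i, s in enumerate(snps)}
    for (a, b), val in r_pairs.items():
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = val
    return LDMatrix(snps, r, positions=positions, chromosomes=[1] * m)


def greedy_clump_oracle(df, ld, p2, kb, r2):
    """Independent re-statement of the greedy rule: repeatedly pick the
    remaining variant with smallest (p, pos, id) and discard linked
    neighbors.  Pure-python, set-based."""
    remaining = {
        row.SNP: (row.P, row.POS, row.SNP, row.CHR) for row in df.itertuples()
    }
    kept = []
    while remaining:
        best = min(remaining.values())
        p_i, pos_i, snp_i, chr_i = best
        kept.append(snp_i)
        del remaining[snp_i]
        for snp_j in list(remaining):
            p_j, pos_j, _, chr_j = remaining[snp_j]
            if (
                chr_j == chr_i
                and abs(pos_j - pos_i) <= kb * 1000
                and p_j < p2
                and ld.r2(snp_i, snp_j) >= r2
            ):
                del remaining[snp_j]
    return kept


class TestClump:
    def test_three_snp_example(self):
        # r2(1,2)=0.5 so rs2 absorbed by rs1; rs3 independent
        ss = make_sumstats(
            snps=["rs1", "rs2", "rs3"], ps=[1e-10, 1e-9, 1e-8],
            positions=[100_000, 150_000, 200_000],
        )
        ld = ld_from(["rs1", "rs2", "rs3"], [100_000, 150_000, 200_000],
                     {("rs1", "rs2"): np.sqrt(0.5), ("rs1", "rs3"): np.sqrt(0.001),
                      ("rs2", "rs3"): np.sqrt(0.001)})
        out = clump(ss, ld)
        assert out.variant_ids == ["rs1", "rs3"]

    def test_single_snp(self):
        ss = make_sumstats(snps=["rs1"], ps=[1e-9])
        assert clump(ss, identity_ld(ss)).variant_ids == ["rs1"]

    def test_outside_window_both_kept(self):
        ss = make_sumstats(snps=["rs1", "rs2"], ps=[1e-10, 1e-9],
                           positions=[100_000, 400_001])
        ld = ld_from(["rs1", "rs2"], [100_000, 400_001], {("rs1", "rs2"): np.sqrt(0.9)})
        assert set(clump(ss, ld).variant_ids) == {"rs1", "rs2"}

    def test_no_candidates_empty(self):
        ss = make_sumstats(ps=[1e-3, 1e-4, 0.5])
        out = clump(ss, identity_ld(ss))
        assert len(out) == 0

    def test_gw_threshold_boundary_strict(self):
        ss = make_sumstats(snps=["rs1", "rs2"], ps=[5e-8, 4.9e-8])
        out = clump(ss, identity_ld(ss))
        assert out.variant_ids == ["rs2"]  # 5e-8 not < 5e-8

    def test_pairwise_r2_invariant(self):
        cfg = SimulationConfig(n_snps=100, n_blocks=10, within_block_rho=0.6,
                               causal_fraction=0.5, seed=3)
        study = simulate_gwas_triplet(cfg)
        out = clump(study.exposure, study.ld)
        snps = out.variant_ids
        pos = {v: study.ld.positions[v] for v in snps}
        for i, a in enumerate(snps):
            for b in snps[i + 1:]:
                if abs(pos[a] - pos[b]) <= 250_000:
                    assert study.ld.r2(a, b) < 0.01

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(2, 16)
        snps = [f"rs{i}" for i in range(m)]
        positions = sorted(rng.integers(1, 600_000, size=m).tolist())
        base = rng.uniform(-0.9, 0.9, size=(m, m))
        r = (base + base.T) / 2
        np.fill_diagonal(r, 1.0)
        # shrink to keep |r|<=1 off-diagonal
        r = np.clip(r, -0.99, 0.99)
        np.fill_diagonal(r, 1.0)
        ld = LDMatrix(snps, r, positions=positions, chromosomes=[1] * m)
        ps = 10.0 ** rng.uniform(-12, -7.5, size=m)
        ss = make_sumstats(snps=snps, ps=ps.tolist(), positions=positions)
        got = clump(ss, ld).variant_ids
        want = greedy_clump_oracle(ss.table, ld, p2=0.01, kb=250, r2=0.01)
        assert got == sorted(want, key=lambda s: got.index(s) if s in got else -1)
        assert set(got) == set(want)


class TestMasks:
    def test_hla_interior_removed(self):
        ss = make_sumstats(snps=["rs1"], chrom=6, positions=[30_000_000])
        ivs = clump(ss, identity_ld(ss))
        out = apply_region_masks(ivs, [HLA_MASK])
        assert len(out) == 0

    def test_hla_boundary_exclusive_below(self):
        ss = make_sumstats(snps=["rs1"], chrom=6, positions=[24_999_999])
        ivs = clump(ss, identity_ld(ss))
        out = apply_region_masks(ivs, [HLA_MASK])
        assert out.variant_ids == ["rs1"]

    def test_hbb_bounds_inclusive(self):
        ss = make_sumstats(snps=["rs1", "rs2", "rs3"], chrom=11,
                           positions=[5_246_695, 5_246_696, 5_248_301])
        ivs = clump(ss, identity_ld(ss))
        out = apply_region_masks(ivs, [HBB_MASK])
        assert out.variant_ids == ["rs1"]

    def test_empty_mask_identity(self):
        ss = make_sumstats()
        ivs = clump(ss, identity_ld(ss))
        out = apply_region_masks(ivs, [])
        assert out.variant_ids == ivs.variant_ids

    def test_invalid_mask(self):
        with pytest.raises(ValueError):
            GenomicMask("bad", 1, 100, 50)


class TestAFFilter:
    def _pair(self, eaf_exp, eaf_out):
        a = make_sumstats(snps=["rs1"], eafs=[eaf_exp])
        b = make_sumstats(snps=["rs1"], eafs=[eaf_out])
        return align_pair(a, b)

    def test_boundary_removed_at_005(self):
        assert len(af_concordance_filter(self._pair(0.30, 0.36))) == 0

    def test_exact_boundary_inclusive(self):
        # >= semantics checked with a binary-exact threshold
        pair = self._pair(0.25, 0.3125)
        assert len(af_concordance_filter(pair, max_diff=0.0625)) == 0

    def test_below_boundary_kept(self):
        assert len(af_concordance_filter(self._pair(0.30, 0.349))) == 1

    def test_equal_kept(self):
        assert len(af_concordance_filter(self._pair(0.3, 0.3))) == 1

    def test_missing_eaf_retained_flagged(self):
        pair = self._pair(np.nan, 0.3)
        out = af_concordance_filter(pair)
        assert len(out) == 1
        assert bool(out["af_flagged"].iloc[0])


class TestSteiger:
    def test_symmetry_zero(self):
        assert steiger_z(0.05, 1000, 0.05, 1000) == pytest.approx(0.0)

    def test_closed_form_positive(self):
        z = steiger_z(0.05, 100_000, 0.01, 100_000)
        expect = (np.arctanh(0.05) - np.arctanh(0.01)) / np.sqrt(2 / 99_997)
        assert z == pytest.approx(expect)
        assert z > 1.96

    def test_antisymmetric_counterpart(self):
        z = steiger_z(0.01, 100_000, 0.05, 100_000)
        assert z < -1.96

    def test_n_guard(self):
        with pytest.raises(ValueError):
            steiger_z(0.1, 3, 0.1, 100)

    def _pair_with_r(self, r_exp, r_out, n=100_000):
        # construct raw beta/se reproducing the requested standardized r
        def raw(r):
            z = r * np.sqrt((n - 2) / (1 - r**2))
            return z * 0.01, 0.01

        be, se_e = raw(r_exp)
        bo, se_o = raw(r_out)
        a = make_sumstats(snps=["rs1"], betas=[be], ses=[se_e], ns=[n])
        b = make_sumstats(snps=["rs1"], betas=[bo], ses=[se_o], ns=[n])
        return align_pair(a, b)

    def test_filter_removes_reverse(self):
        pair = self._pair_with_r(0.01, 0.05)
        assert len(steiger_filter(pair)) == 0

    def test_filter_keeps_forward(self):
        pair = self._pair_with_r(0.05, 0.01)
        assert len(steiger_filter(pair)) == 1

    def test_boundary_exactly_removed(self):
        # engineer Z == threshold: equal r gives Z=0, so use threshold 0
        pair = self._pair_with_r(0.03, 0.03)
        assert len(steiger_filter(pair, threshold=0.0)) == 0  # Z <= threshold removed

    def test_threshold_minus_inf_identity(self):
        pair = self._pair_with_r(0.01, 0.05)
        assert len(steiger_filter(pair, threshold=-np.inf)) == 1

    def test_planted_reverse_snps_removed(self):
        cfg = SimulationConfig(
            n_snps=100, n_blocks=100, causal_fraction=0.5, reverse_fraction=0.2,
            reverse_effect=0.1, reverse_leak=0.3, theta_direct=0.1,
            n_exp=50_000, n_med=50_000, n_out=50_000, seed=21,
        )
        study = simulate_gwas_triplet(cfg)
        labels = study.truth.snp_effects.set_index("SNP")["label"]
        pair = align_pair(study.exposure, study.outcome)
        kept = steiger_filter(pair)
        kept_labels = labels.loc[kept["SNP"]].tolist()
        assert "reverse" not in kept_labels
        # forward-causal SNPs survive
        assert kept_labels.count("valid") >= 0.9 * (labels == "valid").sum()


class TestMultiTraitSteiger:
    def test_panel_identical_to_exposure_retained(self):
        ss = make_sumstats(ps=[1e-10, 1e-9, 1e-10])
        ivs = clump(ss, identity_ld(ss))
        out = multi_trait_steiger_filter(ss, [ss.copy()], ivs)
        assert set(out.variant_ids) == set(ivs.variant_ids)

    def test_empty_panel_identity(self):
        ss = make_sumstats(ps=[1e-10, 1e-9, 1e-10])
        ivs = clump(ss, identity_ld(ss))
        out = multi_trait_steiger_filter(ss, [], ivs)
        assert out.variant_ids == ivs.variant_ids

    def test_absent_snp_excluded(self):
        ss = make_sumstats(ps=[1e-10, 1e-9, 1e-10])
        ivs = clump(ss, identity_ld(ss))
        panel_trait = make_sumstats("other", snps=["rs1", "rs2"],
                                    betas=[1e-4, 1e-4], ps=[0.9, 0.9])
        out = multi_trait_steiger_filter(ss, [panel_trait], ivs)
        assert "rs3" not in out.variant_ids
        assert set(out.variant_ids) == {"rs1", "rs2"}

    def test_planted_pleiotropic_removed(self):
        exposure = make_sumstats(
            "exp", snps=["rs1", "rs2"], betas=[0.05, 0.05], ses=[0.004, 0.004],
            ps=[1e-30, 1e-30], ns=[50_000, 50_000],
            positions=[100_000, 500_000],
        )
        # rs2 hits trait B much harder than the exposure
        trait_b = make_sumstats(
            "B", snps=["rs1", "rs2"], betas=[0.001, 0.2], ses=[0.004, 0.004],
            ps=[0.8, 1e-300], ns=[50_000, 50_000], positions=[100_000, 500_000],
        )
        ivs = clump(exposure, identity_ld(exposure))
        out = multi_trait_steiger_filter(exposure, [trait_b], ivs)
        assert out.variant_ids == ["rs1"]

    def test_subset_of_plain_steiger_when_panel_has_outcome(self):
        cfg = SimulationConfig(n_snps=60, n_blocks=60, causal_fraction=0.5,
                               theta_direct=0.2, seed=9)
        study = simulate_gwas_triplet(cfg)
        ivs = clump(study.exposure, study.ld)
        multi = multi_trait_steiger_filter(study.exposure, [study.outcome], ivs)
        pair = align_pair(study.exposure, study.outcome)
        pair = pair[pair["SNP"].isin(ivs.variant_ids)]
        plain = steiger_filter(pair)
        assert set(multi.variant_ids) <= set(plain["SNP"])


class TestTwoPhaseClump:
    def _fixture(self, r2_link, med_p=1e-9, exp_p=1e-8):
        snps = ["e1", "m1"]
        pos = [100_000, 150_000]
        exp = make_sumstats("exp", snps=["e1"], ps=[exp_p], positions=[100_000])
        med = make_sumstats("med", snps=["e1", "m1"], ps=[0.5, med_p],
                            positions=pos)
        ld = ld_from(snps, pos, {("e1", "m1"): np.sqrt(r2_link)})
        return exp, med, ld

    def test_linked_mediator_snp_dropped(self):
        exp, med, ld = self._fixture(0.5)
        e_ivs, m_ivs = two_phase_mediation_clump(exp, med, ld)
        assert e_ivs.variant_ids == ["e1"]
        assert m_ivs.variant_ids == []

    def test_unlinked_both_retained(self):
        exp, med, ld = self._fixture(0.001)
        e_ivs, m_ivs = two_phase_mediation_clump(exp, med, ld)
        assert e_ivs.variant_ids == ["e1"]
        assert m_ivs.variant_ids == ["m1"]

    def test_priority_overrides_smaller_mediator_p(self):
        exp, med, ld = self._fixture(0.9, med_p=1e-20, exp_p=1e-8)
        e_ivs, m_ivs = two_phase_mediation_clump(exp, med, ld)
        assert e_ivs.variant_ids == ["e1"]
        assert m_ivs.variant_ids == []

    def test_disjoint_sets(self):
        cfg = SimulationConfig(n_snps=200, n_blocks=20, within_block_rho=0.5,
                               alpha_EM=0.4, mediator_snp_fraction=0.2,
                               h2_med=0.1, seed=13)
        study = simulate_gwas_triplet(cfg)
        e_ivs, m_ivs = two_phase_mediation_clump(study.exposure, study.mediator, study.ld)
        assert not set(e_ivs.variant_ids) & set(m_ivs.variant_ids)


class TestMinrankClump:
    def test_min_rank_priority(self):
        # s1 is rank 1 for exposure A; s2 is rank 2 for both; in LD -> s1 kept
        a = make_sumstats("A", snps=["s1", "s2"], ps=[1e-12, 1e-9],
                          positions=[100_000, 150_000])
        b = make_sumstats("B", snps=["s1", "s2"], ps=[1e-9, 1e-10],
                          positions=[100_000, 150_000])
        ld = ld_from(["s1", "s2"], [100_000, 150_000], {("s1", "s2"): np.sqrt(0.8)})
        out = minrank_clump([a, b], ld)
        # s1: ranks (1, 2) -> min 1; s2: ranks (2, 1) -> min 1; tie broken by
        # smaller min p (s1: 1e-12)
        assert out.variant_ids == ["s1"]

    def test_single_exposure_reduces_to_clump(self):
        cfg = SimulationConfig(n_snps=100, n_blocks=10, within_block_rho=0.5,
                               causal_fraction=0.5, seed=17)
        study = simulate_gwas_triplet(cfg)
        single = minrank_clump([study.exposure], study.ld)
        plain = clump(study.exposure, study.ld)
        assert set(single.variant_ids) == set(plain.variant_ids)

    def test_identical_exposures_equal_single(self):
        cfg = SimulationConfig(n_snps=100, n_blocks=10, within_block_rho=0.5,
                               causal_fraction=0.5, seed=19)
        study = simulate_gwas_triplet(cfg)
        double = minrank_clump([study.exposure, study.exposure.copy()], study.ld)
        single = minrank_clump([study.exposure], study.ld)
        assert double.variant_ids == single.variant_ids


class TestFilterOrderStability:
    def test_pure_predicates_commute(self):
        rng = np.random.default_rng(4)
        m = 30
        snps = [f"rs{i}" for i in range(m)]
        pos = rng.integers(1, 50_000_000, size=m).tolist()
        chroms = rng.choice([6, 11], size=m).tolist()
        a = make_sumstats(snps=snps, positions=pos,
                          eafs=rng.uniform(0.05, 0.95, m).tolist(),
                          betas=rng.normal(0, 0.05, m).tolist(),
                          ses=[0.01] * m, ns=[20_000] * m)
        a.table["CHR"] = chroms
        b = make_sumstats(snps=snps, positions=pos,
                          eafs=rng.uniform(0.05, 0.95, m).tolist(),
                          betas=rng.normal(0, 0.05, m).tolist(),
                          ses=[0.01] * m, ns=[20_000] * m)
        b.table["CHR"] = chroms
        pair = align_pair(a, b)

        def mask_rows(df):
            inside = HLA_MASK.contains(df["CHR"], df["POS"]) | HBB_MASK.contains(
                df["CHR"], df["POS"]
            )
            return df.loc[~inside].reset_index(drop=True)

        orders = [
            lambda df: steiger_filter(af_concordance_filter(mask_rows(df))),
            lambda df: mask_rows(steiger_filter(af_concordance_filter(df))),
            lambda df: af_concordance_filter(steiger_filter(mask_rows(df))),
        ]
        results = [set(order(pair)["SNP"]) for order in orders]
        assert results[0] == results[1] == results[2]


def test_ld_matrix_validation():
    with pytest.raises(ValueError):
        LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.4, 1.0]]))
    with pytest.raises(ValueError):
        LDMatrix(["a", "b"], np.array([[1.0, 1.5], [1.5, 1.0]]))
    with pytest.raises(ValueError):
        LDMatrix(["a"], np.array([[0.9]]))


def test_ld_missing_pair_is_zero():
    ld = LDMatrix(["a", "b"], np.eye(2))
    assert ld.r2("a", "zzz") == 0.0


def test_ld_triplet_roundtrip(tmp_path):
    trip = pd.DataFrame({"id_a": ["a", "a"], "id_b": ["b", "c"], "r": [0.5, -0.2]})
    ld = LDMatrix.from_triplets(trip)
    assert ld.r2("a", "b") == pytest.approx(0.25)
    path = tmp_path / "ld.tsv"
    ld.to_square_tsv(path)
    ld2 = LDMatrix.from_square_tsv(path)
    np.testing.assert_allclose(ld.r, ld2.r)
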