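"""Locus filtering, Weir-Cockerham theta and PCoA."""

import numpy as np
import pandas as pd
import pytest

import batdialect as bd
from batdialect.geno import GenotypeMatrix, MISSING


def make_genotypes(calls, colonies):
    calls = np.asarray(calls, dtype=np.int8)
    ids = [f"i{k}" for k in range(calls.shape[0])]
    loci = [f"L{j}" for j in range(calls.shape[1])]
    return GenotypeMatrix(ids, dict(zip(ids, colonies)), loci, calls)


def wc_theta_oracle(counts_1, counts_2):
    """Scalar Weir-Cockerham (1984) two-population theta from genotype
    counts (n_ref_hom, n_het, n_alt_hom) per population, single locus.
    Written independently of the vectorised implementation."""
    import math
    r = 2
    ns, ps, hs = [], [], []
    for (aa, ab, bb) in (counts_1, counts_2):
        n = aa + ab + bb
        ns.append(n)
        ps.append((2 * bb + ab) / (2 * n))
        hs.append(ab / n)
    n_bar = sum(ns) / r
    n_c = (r * n_bar - sum(n * n for n in ns) / (r * n_bar)) / (r - 1)
    p_bar = sum(n * p for n, p in zip(ns, ps)) / (r * n_bar)
    s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * n_bar)
    h_bar = sum(n * h for n, h in zip(ns, hs)) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    return a / (a + b + c)


def genotypes_from_counts(counts):
    """Expand (n00, n01, n11) genotype counts into call values."""
    return [0] * counts[0] + [1] * counts[1] + [2] * counts[2]


class TestFilterLoci:
    def test_toy_matrix_maf_filter(self):
        # 4 individuals x 3 loci with alt-allele freqs 0.5, 0.125, 0
        calls = np.array([
            [2, 1, 0],
            [0, 0, 0],
            [1, 0, 0],
            [1, 0, 0],
        ])
        g = make_genotypes(calls, ["a", "a", "b", "b"])
        out, rep = bd.filter_loci(g, maf_min=0.2, drop_monomorphic=False)
        assert out.n_loci == 1 and out.loci_ids == ["L0"]
        assert rep.removed_by_rule["maf"] == 2
        assert rep.n_loci_in == 3 and rep.n_loci_out == 1

    def test_monomorphic_and_call_rate_rules(self):
        calls = np.array([
            [0, MISSING, 1],
            [0, MISSING, 1],
            [0, MISSING, 0],
            [0, 2, 2],
            [0, 2, 1],
        ])
        g = make_genotypes(calls, list("aabbb"))
        out, rep = bd.filter_loci(g, call_rate_min=0.5, drop_monomorphic=True)
        # L0 monomorphic, L1 60% missing, L2 survives
        assert out.loci_ids == ["L2"]
        assert rep.removed_by_rule == {"call_rate": 1, "maf": 0,
                                       "monomorphic": 1}

    def test_removing_everything_is_an_error(self):
        g = make_genotypes(np.zeros((4, 2), dtype=int), list("aabb"))
        with pytest.raises(ValueError, match="every locus"):
            bd.filter_loci(g, drop_monomorphic=True)


class TestPairwiseFst:
    def test_fixed_alternate_alleles_give_theta_one(self):
        calls = np.array([[0] * 6] * 4 + [[2] * 6] * 4)
        g = make_genotypes(calls, ["a"] * 4 + ["b"] * 4)
        res = bd.pairwise_fst(g)
        assert res.matrix.values[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("c1,c2", [
        ((4, 0, 0), (0, 0, 4)),
        ((2, 4, 2), (1, 2, 5)),
        ((5, 2, 1), (3, 3, 2)),
    ])
    def test_matches_hand_coded_component_oracle(self, c1, c2):
        calls = np.array([genotypes_from_counts(c1)
                          + genotypes_from_counts(c2)]).T
        g = make_genotypes(calls, ["a"] * sum(c1) + ["b"] * sum(c2))
        res = bd.pairwise_fst(g)
        assert res.matrix.values[0, 1] == pytest.approx(
            wc_theta_oracle(c1, c2), abs=1e-12)

    def test_hwe_populations_with_equal_frequencies_give_theta_near_zero(self):
        rng = np.random.default_rng(1)
        n, m = 20, 500
        calls = rng.binomial(2, 0.5, size=(2 * n, m))
        g = make_genotypes(calls, ["a"] * n + ["b"] * n)
        theta = bd.pairwise_fst(g).matrix.values[0, 1]
        assert abs(theta) < 0.02

    def test_theta_invariant_to_allele_relabelling(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(16, 60)).astype(np.int8)
        g = make_genotypes(calls, ["a"] * 8 + ["b"] * 8)
        theta = bd.pairwise_fst(g).matrix.values[0, 1]
        flipped = calls.copy()
        flip = rng.random(60) < 0.5
        flipped[:, flip] = 2 - flipped[:, flip]
        g2 = make_genotypes(flipped, ["a"] * 8 + ["b"] * 8)
        assert bd.pairwise_fst(g2).matrix.values[0, 1] == pytest.approx(theta)

    def test_missing_genotypes_excluded_locus_wise(self):
        calls = np.array([
            [0, MISSING], [0, 0], [0, 0],
            [2, MISSING], [2, 2], [2, 2],
        ])
        g = make_genotypes(calls, ["a"] * 3 + ["b"] * 3)
        res = bd.pairwise_fst(g)
        assert res.matrix.values[0, 1] == pytest.approx(1.0)

    def test_matrix_is_exactly_symmetric(self, nt_sites):
        g = bd.simulate_genotypes(nt_sites, n_per_site=6, n_loci=80, seed=3)
        m = bd.pairwise_fst(g).matrix.values
        assert np.array_equal(m, m.T)


class TestPcoa:
    def test_recovers_planar_configuration_up_to_rotation(self):
        from scipy.spatial import procrustes
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = bd.pcoa(bd.DistanceMatrix([f"p{i}" for i in range(5)], d),
                      n_axes=2)
        _, _, disparity = procrustes(pts, res.coordinates)
        assert disparity < 1e-15
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_zero_matrix_gives_no_signal(self):
        d = bd.DistanceMatrix(list("abcd"), np.zeros((4, 4)))
        res = bd.pcoa(d)
        assert res.coordinates.size == 0 or np.allclose(res.coordinates, 0.0)

    def test_translation_invariance_of_input_distances(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        labels = [f"p{i}" for i in range(6)]

        def dist(p):
            return np.linalg.norm(p[:, None] - p[None, :], axis=-1)

        r1 = bd.pcoa(bd.DistanceMatrix(labels, dist(pts)), n_axes=3)
        r2 = bd.pcoa(bd.DistanceMatrix(labels, dist(pts + 100.0)), n_axes=3)
        assert np.allclose(r1.eigenvalues, r2.eigenvalues, atol=1e-8)

    def test_allele_sharing_distance_separates_divergent_colonies(self, nt_sites):
        g = bd.simulate_genotypes(nt_sites, n_per_site=5, n_loci=300,
                                  sigma_drift=1.5, range_km=400, seed=6)
        d = bd.allele_sharing_distance(g)
        res = bd.pcoa(d, n_axes=2)
        df = res.to_frame()
        df["colony"] = [g.colony_of[i] for i in g.individual_ids]
        # strong drift: among-colony variance on axis 1 dominates
        grand = df["PCo1"].var()
        within = df.groupby("colony")["PCo1"].var().mean()
        assert within < grand
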