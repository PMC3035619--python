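"""Breed-of-origin inference: scan grid, marker enumeration, interval
conditioning against independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

import eqtlcross as ec
from eqtlcross.maps import haldane, recombination_fraction
from eqtlcross.origin_prob import (F2_PRIOR, _marker_origin_single,
                                   origin_probabilities_at)
from eqtlcross.synthetic_cross import GenotypeTable, Pedigree


# ---------------------------------------------------------------------------
# Scan grid
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_chrom, per_chrom, k, expected", [
    (1, 3, 11, 25),        # 3 + 11*2
    (1, 1, 11, 1),         # single marker, no intervals
    (2, 2, 5, 14),         # 2*(2 + 5)
])
def test_grid_counts(n_chrom, per_chrom, k, expected):
    lmap = ec.LinkageMap.uniform(n_chrom, per_chrom, 10.0)
    assert len(ec.build_scan_grid(lmap, k)) == expected


def test_study_scale_grid_is_1279():
    """124 markers on 19 linkage groups with 11 inter-marker positions."""
    counts = [7] * 10 + [6] * 9  # 124 markers, 3-9 per chromosome in spirit
    rows = [(f"M{c}_{m}", str(c), m * 20.0)
            for c, n in enumerate(counts, 1) for m in range(n)]
    lmap = ec.LinkageMap(pd.DataFrame(rows, columns=["marker", "chromosome", "cM"]))
    assert lmap.n_markers == 124
    assert len(ec.build_scan_grid(lmap, 11)) == 1279


def test_grid_positions_sorted_and_markers_unique(small_map):
    grid = ec.build_scan_grid(small_map, 4)
    for chrom in small_map.chromosomes:
        sub = grid.chromosome_positions(chrom)
        assert sub["cM"].is_monotonic_increasing
        markers = sub[sub["kind"] == "marker"]
        assert len(markers) == len(small_map.chromosome_markers(chrom))


# ---------------------------------------------------------------------------
# Marker-level enumeration
# ---------------------------------------------------------------------------

def _tiny_family(f2, sire_f1, dam_f1, s_gf, s_gm, d_gf, d_gm):
    """One-marker pedigree/genotype pair built by hand."""
    rows = [
        ("GS", None, None, "F0", "M", "Duroc", None),
        ("GM", None, None, "F0", "F", "Pietrain", None),
        ("GS2", None, None, "F0", "M", "Duroc", None),
        ("GM2", None, None, "F0", "F", "Pietrain", None),
        ("S1", "GS", "GM", "F1", "M", "cross", None),
        ("D1", "GS2", "GM2", "F1", "F", "cross", None),
        ("X", "S1", "D1", "F2", "M", "cross", "L1"),
    ]
    ped = Pedigree(pd.DataFrame(
        rows, columns=["id", "sire", "dam", "generation", "sex", "breed", "litter"]))
    lmap = ec.LinkageMap(pd.DataFrame(
        {"marker": ["m1"], "chromosome": ["1"], "cM": [0.0]}))
    ordered = {"X": np.array([f2]), "S1": np.array([sire_f1]),
               "D1": np.array([dam_f1]), "GS": np.array([s_gf]),
               "GM": np.array([s_gm]), "GS2": np.array([d_gf]),
               "GM2": np.array([d_gm])}
    geno = GenotypeTable(lmap, ordered, np.array([True]))
    return ped, geno, lmap


def test_fully_traceable_duroc_alleles_give_DD():
    """Both F2 alleles trace uniquely to the Duroc founders -> (1,0,0)."""
    ped, geno, lmap = _tiny_family(
        f2=(1, 1), sire_f1=(1, 3), dam_f1=(1, 3),
        s_gf=(1, 1), s_gm=(3, 3), d_gf=(1, 1), d_gm=(3, 3))
    inf = ec.infer_marker_origins(ped, geno, lmap)
    np.testing.assert_allclose(inf.triples[0, 0], [1, 0, 0], atol=1e-12)


def test_uninformative_marker_gives_f2_prior():
    ped, geno, lmap = _tiny_family(
        f2=(1, 1), sire_f1=(1, 1), dam_f1=(1, 1),
        s_gf=(1, 1), s_gm=(1, 1), d_gf=(1, 1), d_gm=(1, 1))
    inf = ec.infer_marker_origins(ped, geno, lmap)
    np.testing.assert_allclose(inf.triples[0, 0], F2_PRIOR, atol=1e-12)


def test_mendelian_inconsistency_flagged_and_prior():
    ped, geno, lmap = _tiny_family(
        f2=(9, 9), sire_f1=(1, 3), dam_f1=(1, 3),
        s_gf=(1, 1), s_gm=(3, 3), d_gf=(1, 1), d_gm=(3, 3))
    inf = ec.infer_marker_origins(ped, geno, lmap)
    assert inf.inconsistent[0, 0]
    np.testing.assert_allclose(inf.triples[0, 0], F2_PRIOR)


def _enumeration_oracle(f2, sire_f1, s_gf, s_gm, dam_f1, d_gf, d_gm):
    """Independent brute force over every latent configuration.

    Enumerates F0 transmitted alleles, F1 phases and F1 homolog choices
    directly (rather than phase weights) and accumulates the joint law of
    (origin pair, observed F2 genotype), then conditions on the data.
    """
    joint = {}
    f2_obs = tuple(sorted(f2))
    for sA in s_gf:                    # allele the Duroc grandsire passed
        for sB in s_gm:                # allele the Pietrain granddam passed
            if tuple(sorted((sA, sB))) != tuple(sorted(sire_f1)):
                continue
            for dA in d_gf:
                for dB in d_gm:
                    if tuple(sorted((dA, dB))) != tuple(sorted(dam_f1)):
                        continue
                    for hs, allele_s in ((0, sA), (1, sB)):
                        for hd, allele_d in ((0, dA), (1, dB)):
                            obs = tuple(sorted((allele_s, allele_d)))
                            if obs != f2_obs:
                                continue
                            joint[(hs, hd)] = joint.get((hs, hd), 0) + 1
    total = sum(joint.values())
    if total == 0:
        return None
    pDD = joint.get((0, 0), 0) / total
    pPP = joint.get((1, 1), 0) / total
    return pDD, 1 - pDD - pPP, pPP


@pytest.mark.parametrize("seed", range(30))
def test_marker_enumeration_matches_bruteforce(seed):
    """Random one-marker families: implementation == exhaustive oracle."""
    rng = np.random.default_rng(seed)

    def draw_pair(pool):
        return tuple(rng.choice(pool, 2))

    s_gf, d_gf = draw_pair([1, 2]), draw_pair([1, 2])
    s_gm, d_gm = draw_pair([2, 3]), draw_pair([2, 3])  # partially overlapping pools
    sire_f1 = (s_gf[rng.integers(2)], s_gm[rng.integers(2)])
    dam_f1 = (d_gf[rng.integers(2)], d_gm[rng.integers(2)])
    f2 = (sire_f1[rng.integers(2)], dam_f1[rng.integers(2)])

    triple, _, ok = _marker_origin_single(
        f2, sire_f1, s_gf, s_gm, dam_f1, d_gf, d_gm)
    oracle = _enumeration_oracle(f2, sire_f1, s_gf, s_gm, dam_f1, d_gf, d_gm)
    assert ok and oracle is not None
    np.testing.assert_allclose(triple, oracle, atol=1e-12)


# ---------------------------------------------------------------------------
# Interval conditioning
# ---------------------------------------------------------------------------

def _haplotype_oracle(x, marker_pos, joints, map_function="haldane"):
    """Exhaustive gamete-pair haplotype enumeration at the informative
    markers nearest to x plus x itself (interval-mapping conditioning).

    Enumerates all (paternal, maternal) state assignments at the chosen
    loci, chains each gamete independently with map-function transition
    probabilities, weights by the markers' joint evidence, and returns
    the normalized 2x2 joint at x.
    """
    joints = np.asarray(joints, float)
    informative = [i for i in range(len(marker_pos))
                   if np.abs(joints[i] - 0.25).max() > 1e-9]
    pos = [marker_pos[i] for i in informative]
    left = [i for i in range(len(pos)) if pos[i] <= x]
    right = [i for i in range(len(pos)) if pos[i] >= x]
    loci = []  # (position, evidence 2x2 or None for x)
    if left:
        loci.append((pos[left[-1]], joints[informative[left[-1]]]))
    loci.append((x, None))
    if right and (not left or right[0] != left[-1]):
        loci.append((pos[right[0]], joints[informative[right[0]]]))
    x_idx = [i for i, (_, ev) in enumerate(loci) if ev is None][0]
    score = np.zeros((2, 2))
    n = len(loci)
    for pat in itertools.product((0, 1), repeat=n):
        for mat in itertools.product((0, 1), repeat=n):
            prob = 0.25  # uniform start per gamete
            for k in range(n - 1):
                r = float(recombination_fraction(
                    loci[k + 1][0] - loci[k][0], map_function))
                prob *= (1 - r) if pat[k] == pat[k + 1] else r
                prob *= (1 - r) if mat[k] == mat[k + 1] else r
            weight = 1.0
            for k, (_, ev) in enumerate(loci):
                if ev is not None:
                    weight *= ev[pat[k], mat[k]]
            score[pat[x_idx], mat[x_idx]] += prob * weight
    total = score.sum()
    return np.full((2, 2), 0.25) if total == 0 else score / total


def test_midpoint_both_flanks_DD():
    """Midpoint of a 20 cM interval with certain DD flanks: the classic
    (1-r10)^2/(1-r20) conditional, squared across gametes ~ 0.980."""
    marker_pos = np.array([0.0, 20.0])
    gp = np.array([[1.0, 1.0], [1.0, 1.0]])  # both gametes D at both flanks
    (pDD, pDP, pPP), ca = origin_probabilities_at(10.0, marker_pos, gp)
    r10, r20 = haldane(10.0), haldane(20.0)
    per_gamete = (1 - r10) ** 2 / (1 - r20)
    assert pDD == pytest.approx(per_gamete ** 2, abs=1e-12)
    assert pDD == pytest.approx(0.980, abs=5e-4)
    assert ca == pytest.approx(pDD - pPP)


def test_position_at_informative_marker_returns_state():
    marker_pos = np.array([0.0, 20.0])
    gp = np.array([[1.0, 0.0], [0.3, 0.9]])
    (pDD, pDP, pPP), _ = origin_probabilities_at(0.0, marker_pos, gp)
    # paternal gamete D with certainty, maternal gamete P with certainty
    assert pDD == pytest.approx(0.0, abs=1e-12)
    assert pDP == pytest.approx(1.0, abs=1e-12)
    (pDD, _, pPP), _ = origin_probabilities_at(20.0, marker_pos, gp)
    assert pPP == pytest.approx((1 - 0.3) * (1 - 0.9))


def test_no_informative_markers_gives_prior():
    marker_pos = np.array([0.0, 20.0])
    gp = np.full((2, 2), 0.5)
    triple, ca = origin_probabilities_at(10.0, marker_pos, gp)
    np.testing.assert_allclose(triple, F2_PRIOR)
    assert ca == 0.0


def _random_joint_evidence(rng, m):
    """Marker evidence mixing uniform, degenerate, product and coupled
    joints — the states real enumeration posteriors can take."""
    joints = np.empty((m, 2, 2))
    for i in range(m):
        kind = rng.integers(4)
        if kind == 0:
            joints[i] = 0.25
        elif kind == 1:  # degenerate single state
            joints[i] = 0.0
            joints[i][rng.integers(2), rng.integers(2)] = 1.0
        elif kind == 2:  # certain heterozygote, gamete unresolved
            joints[i] = [[0.0, 0.5], [0.5, 0.0]]
        else:            # random product evidence
            p, q = rng.uniform(0, 1, 2)
            joints[i] = np.outer([p, 1 - p], [q, 1 - q])
    return joints


@pytest.mark.parametrize("map_function", ["haldane", "kosambi"])
@pytest.mark.parametrize("seed", range(20))
def test_interval_conditioning_matches_haplotype_oracle(seed, map_function):
    """Chromosomes with <= 4 markers, arbitrary evidence: the
    implementation reproduces exhaustive haplotype enumeration to 1e-10."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(1, 5))
    marker_pos = np.sort(rng.uniform(0, 100, m))
    joints = _random_joint_evidence(rng, m)
    for x in rng.uniform(0, 100, 5):
        (pDD, pDP, pPP), ca = origin_probabilities_at(
            x, marker_pos, joints, map_function)
        J = _haplotype_oracle(x, marker_pos, joints, map_function)
        assert pDD == pytest.approx(J[0, 0], abs=1e-10)
        assert pPP == pytest.approx(J[1, 1], abs=1e-10)
        assert pDP == pytest.approx(J[0, 1] + J[1, 0], abs=1e-10)
        assert pDD + pDP + pPP == pytest.approx(1.0, abs=1e-12)
        assert ca == pytest.approx(pDD - pPP)


def test_additive_coefficient_examples():
    assert ec.additive_coefficient((1, 0, 0)) == 1.0
    assert ec.additive_coefficient(F2_PRIOR) == 0.0
    assert ec.additive_coefficient((0.980, 0.019, 0.001)) == pytest.approx(0.979)


# ---------------------------------------------------------------------------
# Whole-grid properties
# ---------------------------------------------------------------------------

def test_ca_continuous_and_exact_at_markers(paper_inference, small_map,
                                            paper_genotypes, paper_pedigree):
    """c_a hits the true +/-1/0 code at fully informative markers and the
    triples stay normalized over a dense grid."""
    grid = ec.build_scan_grid(small_map, 5)
    ca, triples = ec.compute_ca_matrix(paper_inference, grid,
                                       return_triples=True)
    np.testing.assert_allclose(triples.sum(axis=2), 1.0, atol=1e-9)
    marker_cols = [i for i, r in enumerate(grid.positions.itertuples())
                   if r.kind == "marker"]
    f2_ids = paper_inference.f2_ids
    chroms = grid.positions["chromosome"].to_numpy()
    cms = grid.positions["cM"].to_numpy()
    errs = []
    for i, f2 in enumerate(f2_ids[:30]):
        for j in marker_cols:
            truth_code = paper_genotypes.origin_code_at(f2, chroms[j], cms[j])
            errs.append(abs(ca.iloc[i, j] - truth_code))
    assert np.mean(errs) < 1e-9

    # continuity: c_a evaluated on a 0.2 cM lattice has no jumps
    chrom = small_map.chromosomes[0]
    sub = small_map.chromosome_markers(chrom)
    mpos = sub["cM"].to_numpy(float)
    joints = paper_inference.joints[0, sub.index.to_numpy()]
    xs = np.arange(0.0, mpos[-1] + 1e-9, 0.2)
    vals = np.array([ec.origin_probabilities_at(x, mpos, joints)[1] for x in xs])
    assert np.abs(np.diff(vals)).max() < 0.05
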