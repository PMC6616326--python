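"""Interval mapping: conditional probabilities, LOD scan, permutations, peaks."""

import numpy as np
import pytest

from vigorscan import (
    GeneticMap,
    GenotypeMatrix,
    LineMeans,
    call_qtl_peaks,
    conditional_genotype_probs,
    default_genetic_map,
    haldane_r,
    interval_mapping_scan,
    least_square_means,
    permutation_threshold,
    ril_expansion,
    simulate_ril_population,
)
from vigorscan.qtl_mapping import PermutationThreshold


def _two_marker_map(d_cM=20.0):
    return GeneticMap(names=("m1", "m2"), chromosomes=("1", "1"), positions_cM=(0.0, d_cM))


def _probs_at(probs, q):
    i = int(np.flatnonzero(np.isclose(probs.positions_cM, q))[0])
    return probs.p_aa[:, i]


def flanking_oracle(gl, gr, d_left, d_right):
    """Enumerate the two genotype states given flanking calls (RIL Markov chain)."""
    rl = float(ril_expansion(haldane_r(d_left)))
    rr = float(ril_expansion(haldane_r(d_right)))
    w_aa = ((1 - rl) if gl == 1 else rl) * ((1 - rr) if gr == 1 else rr)
    w_bb = (rl if gl == 1 else (1 - rl)) * (rr if gr == 1 else (1 - rr))
    return w_aa / (w_aa + w_bb)


# ------------------------------------------------------------ map functions


def test_haldane_and_ril_expansion_endpoints():
    assert haldane_r(0.0) == 0.0
    assert haldane_r(1e9) == pytest.approx(0.5)
    assert ril_expansion(0.0) == 0.0
    assert ril_expansion(0.5) == pytest.approx(0.5)


# ------------------------------------------------------- conditional probs


def test_probability_at_observed_marker_matches_call():
    geno = GenotypeMatrix(line_ids=("A", "B"), calls=np.array([[1.0, 0.0], [0.0, 1.0]]))
    probs = conditional_genotype_probs(_two_marker_map(), geno, step_cM=5.0)
    np.testing.assert_allclose(_probs_at(probs, 0.0), [1.0, 0.0])
    np.testing.assert_allclose(_probs_at(probs, 20.0), [0.0, 1.0])


def test_midpoint_between_two_aa_markers_matches_enumeration_oracle():
    geno = GenotypeMatrix(line_ids=("A",), calls=np.array([[1.0, 1.0]]))
    probs = conditional_genotype_probs(_two_marker_map(20.0), geno, step_cM=10.0)
    assert _probs_at(probs, 10.0)[0] == pytest.approx(flanking_oracle(1, 1, 10, 10), abs=1e-12)


@pytest.mark.parametrize("gl,gr", [(1, 0), (0, 1), (0, 0)])
def test_interior_probabilities_match_oracle_for_all_flank_cases(gl, gr):
    geno = GenotypeMatrix(line_ids=("A",), calls=np.array([[float(gl), float(gr)]]))
    probs = conditional_genotype_probs(_two_marker_map(24.0), geno, step_cM=6.0)
    for q in (6.0, 12.0, 18.0):
        assert _probs_at(probs, q)[0] == pytest.approx(
            flanking_oracle(gl, gr, q, 24.0 - q), abs=1e-12
        )


def test_missing_flank_falls_back_to_single_marker_conditioning():
    geno = GenotypeMatrix(line_ids=("A",), calls=np.array([[1.0, np.nan]]))
    probs = conditional_genotype_probs(_two_marker_map(20.0), geno, step_cM=10.0)
    expected = 1.0 - float(ril_expansion(haldane_r(10.0)))
    assert _probs_at(probs, 10.0)[0] == pytest.approx(expected, abs=1e-12)
    # at the missing marker itself, conditioning comes from the left flank only
    expected_end = 1.0 - float(ril_expansion(haldane_r(20.0)))
    assert _probs_at(probs, 20.0)[0] == pytest.approx(expected_end, abs=1e-12)


def test_probabilities_stay_in_unit_interval_and_classes_sum_to_one():
    pop = simulate_ril_population(3, n_lines=40)
    probs = conditional_genotype_probs(pop.gmap, pop.genotypes, 2.0)
    assert np.all(probs.p_aa >= 0.0) and np.all(probs.p_aa <= 1.0)
    # two genotype classes: P(AA) + P(BB) = 1 by construction of the output
    assert np.allclose(probs.p_aa + (1.0 - probs.p_aa), 1.0)


def test_step_must_be_positive():
    geno = GenotypeMatrix(line_ids=("A",), calls=np.array([[1.0, 1.0]]))
    with pytest.raises(ValueError):
        conditional_genotype_probs(_two_marker_map(), geno, step_cM=0.0)


# ---------------------------------------------------------------- the scan


def _means_from(pop, trait="PH_mm"):
    return least_square_means(list(pop.phenotypes), trait)


def test_null_phenotype_scans_near_zero():
    pop = simulate_ril_population(11, n_lines=100, qtl=[("1", 48.0, 0.0)])
    probs = conditional_genotype_probs(pop.gmap, pop.genotypes, 1.0)
    scan = interval_mapping_scan(probs, _means_from(pop), "PH_mm")
    assert scan.lod.min() >= 0.0
    assert scan.lod.max() < 2.5  # genome-wide max under the null, typical seed


def test_lod_at_marker_equals_closed_form():
    pop = simulate_ril_population(13, n_lines=80, qtl=[("3", 48.0, 3.0)], heritability=0.6)
    means = _means_from(pop)
    probs = conditional_genotype_probs(pop.gmap, pop.genotypes, 1.0)
    scan = interval_mapping_scan(probs, means, "PH_mm")
    # closed form at a fully informative marker: LOD = (n/2) log10(1/(1-R^2))
    chroms = np.asarray(scan.chromosomes, dtype=object)
    j_map = [i for i, name in enumerate(pop.gmap.names) if name == "C3M09"][0]
    marker_pos = pop.gmap.positions_cM[j_map]
    i_scan = int(np.flatnonzero((chroms == "3") & np.isclose(scan.positions_cM, marker_pos))[0])
    x = 2.0 * pop.genotypes.calls[:, j_map] - 1.0
    y = np.array([m.lsmean for m in sorted(means, key=lambda m: m.line_id)])
    lines_sorted = sorted(pop.genotypes.line_ids)
    assert lines_sorted == sorted(m.line_id for m in means)
    order = np.argsort(np.asarray(pop.genotypes.line_ids))
    r2 = np.corrcoef(x[order], y)[0, 1] ** 2
    expected = (len(y) / 2.0) * np.log10(1.0 / (1.0 - r2))
    assert scan.lod[i_scan] == pytest.approx(expected, abs=1e-9)


def test_perfect_association_exceeds_any_threshold():
    pop = simulate_ril_population(17, n_lines=60)
    geno = pop.genotypes
    j = 5
    means = [
        LineMeans(lid, "PH_mm", float(geno.calls[i, j]), 1)
        for i, lid in enumerate(geno.line_ids)
    ]
    probs = conditional_genotype_probs(pop.gmap, geno, 1.0)
    scan = interval_mapping_scan(probs, means, "PH_mm")
    assert scan.lod.max() > 100.0  # epsilon-floored, far above any threshold


def test_planted_qtl_localized_within_5cM():
    hits = 0
    for seed in range(1, 51):
        pop = simulate_ril_population(seed, qtl=[("5", 48.0, 5.0)], heritability=0.2)
        probs = conditional_genotype_probs(pop.gmap, pop.genotypes, 1.0)
        scan = interval_mapping_scan(probs, _means_from(pop), "PH_mm")
        j = int(np.argmax(scan.lod))
        if scan.chromosomes[j] == "5" and abs(scan.positions_cM[j] - 48.0) <= 5.0:
            hits += 1
    assert hits >= 45  # >= 90% of 50 seeds


def test_effect_estimate_within_25pct_of_truth():
    errors = []
    for seed in range(1, 51):
        pop = simulate_ril_population(seed, qtl=[("2", 48.0, 5.0)], heritability=0.5)
        means = _means_from(pop)
        probs = conditional_genotype_probs(pop.gmap, pop.genotypes, 1.0)
        scan = interval_mapping_scan(probs, means, "PH_mm")
        thr = PermutationThreshold(alpha=0.05, n_perm=1, threshold_lod=3.0, seed=0)
        peaks = call_qtl_peaks(scan, thr, 1.5, probs, means)
        target = [p for p in peaks if p.chromosome == "2"]
        assert target, f"no chromosome-2 peak for seed {seed}"
        errors.append(abs(abs(target[0].effect) - 5.0) / 5.0)
    assert np.median(errors) <= 0.25


# ------------------------------------------------------------ permutations


def test_single_permutation_threshold_equals_its_max():
    pop = simulate_ril_population(19, n_lines=50)
    means = _means_from(pop)
    probs = conditional_genotype_probs(pop.gmap, pop.genotypes, 2.0)
    thr = permutation_threshold(probs, means, "PH_mm", n_perm=1, alpha=0.05, seed=4)
    # recompute that single permutation by hand
    x, y = np.asarray(probs.p_aa), None
    rng = np.random.default_rng(4)
    order = rng.permutation(len(means))
    lids = list(probs.line_ids)
    by_line = {m.line_id: m.lsmean for m in means}
    y = np.array([by_line[lid] for lid in lids])[order]
    scan = interval_mapping_scan(
        probs, [LineMeans(lid, "PH_mm", float(v), 1) for lid, v in zip(lids, y)], "PH_mm"
    )
    assert thr.threshold_lod == pytest.approx(scan.lod.max(), abs=1e-9)


def test_same_seed_gives_identical_threshold():
    pop = simulate_ril_population(23, n_lines=60)
    means = _means_from(pop)
    probs = conditional_genotype_probs(pop.gmap, pop.genotypes, 2.0)
    t1 = permutation_threshold(probs, means, "PH_mm", n_perm=50, alpha=0.05, seed=7)
    t2 = permutation_threshold(probs, means, "PH_mm", n_perm=50, alpha=0.05, seed=7)
    assert t1.threshold_lod == t2.threshold_lod


def test_threshold_grows_with_genome_size():
    wins = 0
    for seed in range(20):
        pop = simulate_ril_population(100 + seed, qtl=[("1", 48.0, 0.0)])
        means = _means_from(pop)
        probs12 = conditional_genotype_probs(pop.gmap, pop.genotypes, 2.0)
        t12 = permutation_threshold(probs12, means, "PH_mm", n_perm=100, alpha=0.05, seed=seed)
        chr1 = np.asarray(pop.gmap.chromosomes, dtype=object) == "1"
        map1 = GeneticMap(
            names=tuple(np.asarray(pop.gmap.names)[chr1]),
            chromosomes=tuple(np.asarray(pop.gmap.chromosomes)[chr1]),
            positions_cM=tuple(np.asarray(pop.gmap.positions_cM)[chr1]),
        )
        geno1 = GenotypeMatrix(line_ids=pop.genotypes.line_ids, calls=pop.genotypes.calls[:, chr1])
        probs1 = conditional_genotype_probs(map1, geno1, 2.0)
        t1 = permutation_threshold(probs1, means, "PH_mm", n_perm=100, alpha=0.05, seed=seed)
        if t12.threshold_lod >= t1.threshold_lod:
            wins += 1
    assert wins >= 18  # more tests -> higher genome-wide threshold, paired seeds


# ------------------------------------------------------------------- peaks


def test_all_below_threshold_yields_no_peaks():
    pop = simulate_ril_population(29, n_lines=60, qtl=[("1", 48.0, 0.0)])
    means = _means_from(pop)
    probs = conditional_genotype_probs(pop.gmap, pop.genotypes, 1.0)
    scan = interval_mapping_scan(probs, means, "PH_mm")
    thr = PermutationThreshold(alpha=0.05, n_perm=1, threshold_lod=scan.lod.max() + 1.0, seed=0)
    assert call_qtl_peaks(scan, thr) == []


def test_single_clean_peak_at_argmax():
    pop = simulate_ril_population(31, qtl=[("7", 48.0, 6.0)], heritability=0.8)
    means = _means_from(pop)
    probs = conditional_genotype_probs(pop.gmap, pop.genotypes, 1.0)
    scan = interval_mapping_scan(probs, means, "PH_mm")
    thr = PermutationThreshold(alpha=0.05, n_perm=1, threshold_lod=3.0, seed=0)
    peaks = [p for p in call_qtl_peaks(scan, thr) if p.chromosome == "7"]
    assert len(peaks) == 1
    j = int(np.argmax(scan.lod))
    assert peaks[0].peak_cM == scan.positions_cM[j]
    lo, hi = peaks[0].support_interval_cM
    assert lo <= peaks[0].peak_cM <= hi


def test_three_qtl_architecture_recovery():
    hits = 0
    for seed in range(1, 21):
        pop = simulate_ril_population(
            seed, qtl=[("1", 48.0, 4.0), ("4", 36.0, 4.0), ("12", 60.0, 4.0)], heritability=0.5
        )
        means = _means_from(pop)
        probs = conditional_genotype_probs(pop.gmap, pop.genotypes, 1.0)
        scan = interval_mapping_scan(probs, means, "PH_mm")
        thr = permutation_threshold(probs, means, "PH_mm", n_perm=200, alpha=0.05, seed=seed)
        peaks = call_qtl_peaks(scan, thr, 1.5, probs, means)
        counts = {}
        for p in peaks:
            counts[p.chromosome] = counts.get(p.chromosome, 0) + 1
        if all(counts.get(c, 0) == 1 for c in ("1", "4", "12")):
            hits += 1
    assert hits >= 16  # >= 80% of seeds


def test_map_validation():
    with pytest.raises(ValueError):
        GeneticMap(names=("a", "a"), chromosomes=("1", "1"), positions_cM=(0.0, 1.0))
    with pytest.raises(ValueError):
        GeneticMap(names=("a", "b"), chromosomes=("1", "1"), positions_cM=(5.0, 1.0))
    with pytest.raises(ValueError):
        GenotypeMatrix(line_ids=("A",), calls=np.array([[0.5]]))
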