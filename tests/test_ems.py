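"""Ordination, EMS statistics, null model, classification and compartments."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microems.core import IncidenceMatrix, ValidationError
from microems.ems import (
    ClumpingResult,
    NullModelSpec,
    NullStat,
    OrdinationError,
    boundary_clumping,
    boundary_counts,
    classify,
    clumping_null_test,
    coherence,
    ems_report,
    embedded_absences,
    fill_ranges,
    morisita_index,
    ordinate,
    r1_null,
    replacements,
    score_covariate_correlation,
    split_compartments,
    turnover,
)
from microems.synthetic import MetacommunityScenario, generate_incidence

from conftest import make_incidence
from _oracles import (
    absences_bruteforce,
    ca_first_axis_eigh,
    morisita_bruteforce,
    replacements_bruteforce,
)


def random_incidence(rng, T=8, S=10, p=0.4):
    while True:
        v = (rng.random((T, S)) < p).astype(np.int8)
        if (v.sum(axis=0) > 0).all() and (v.sum(axis=1) > 0).all():
            return make_incidence(v)


class TestOrdinate:
    def test_matches_dense_eigen_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            inc = random_incidence(rng, 10, 14)
            res = ordinate(inc)
            u, v, lam = ca_first_axis_eigh(inc.values)
            assert res.eigenvalue == pytest.approx(lam, abs=1e-8)
            for mine, oracle in ((res.site_scores, u), (res.species_scores, v)):
                diff = min(
                    np.abs(mine - oracle).max(), np.abs(mine + oracle).max()
                )
                assert diff < 1e-8

    def test_block_diagonal_groups_blocks(self):
        rng = np.random.default_rng(3)
        blocks = np.zeros((10, 12), dtype=np.int8)
        blocks[:5, :6] = (rng.random((5, 6)) < 0.8).astype(np.int8)
        blocks[5:, 6:] = (rng.random((5, 6)) < 0.8).astype(np.int8)
        blocks[0, 0] = blocks[4, 5] = blocks[5, 6] = blocks[9, 11] = 1
        perm = rng.permutation(10)
        inc = make_incidence(blocks[perm])
        ordered = ordinate(inc).ordered
        member = [inc.site_ids.index(s) for s in ordered.site_ids]
        block_of = (perm >= 5).astype(int)[member]
        switches = (np.diff(block_of) != 0).sum()
        assert switches == 1  # each block contiguous in the ordering

    def test_recovers_gradient_order(self):
        sc = MetacommunityScenario(
            "gleasonian", n_sites=30, n_species=80, seed=21
        )
        inc = generate_incidence(sc).drop_empty()
        true_order = np.array([int(s[4:]) for s in inc.site_ids])
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(inc.site_ids))
        shuffled = IncidenceMatrix(
            inc.values[perm],
            [inc.site_ids[i] for i in perm],
            inc.species_ids,
        )
        ordered = ordinate(shuffled).ordered
        got = np.array([int(s[4:]) for s in ordered.site_ids])
        rho = stats.spearmanr(got, np.arange(len(got))).statistic
        assert abs(rho) > 0.95

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        inc = random_incidence(rng, 9, 11)
        res = ordinate(inc)
        perm_r = rng.permutation(9)
        perm_c = rng.permutation(11)
        shuffled = IncidenceMatrix(
            inc.values[np.ix_(perm_r, perm_c)],
            [inc.site_ids[i] for i in perm_r],
            [inc.species_ids[j] for j in perm_c],
        )
        res2 = ordinate(shuffled)
        ids = res.ordered.site_ids
        ids2 = res2.ordered.site_ids
        assert ids == ids2 or ids == ids2[::-1]

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(OrdinationError, match="non-trivial"):
            ordinate(make_incidence(np.ones((4, 4), dtype=np.int8)))

    def test_empty_rows_rejected(self):
        v = np.array([[1, 1], [0, 0], [1, 0]], dtype=np.int8)
        with pytest.raises(OrdinationError, match="empty site"):
            ordinate(make_incidence(v))


class TestCountingPrimitives:
    def test_contiguous_matrix_has_zero_absences(self):
        v = np.array(
            [[1, 1, 0], [1, 1, 0], [0, 1, 1]], dtype=np.int8
        )
        assert embedded_absences(v) == 0

    def test_single_gap_column(self):
        v = np.array([[1, 1], [0, 1], [1, 1]], dtype=np.int8)
        # one embedded absence in column 0; rows are all contiguous
        assert embedded_absences(v) == 1
        assert embedded_absences(v, margins="columns") == 1

    def test_absences_match_bruteforce(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            v = random_incidence(rng).values
            assert embedded_absences(v) == absences_bruteforce(v)
            assert embedded_absences(v, margins="columns") == absences_bruteforce(
                v, margins="columns"
            )

    def test_checkerboard_pair_replacement(self):
        v = np.array([[1, 0], [0, 1]], dtype=np.int8)
        assert replacements(v) == 1

    def test_nested_matrix_has_zero_replacements(self):
        v = np.array(
            [[1, 1, 1], [1, 1, 0], [1, 0, 0]], dtype=np.int8
        )
        assert replacements(v) == 0

    def test_replacements_match_bruteforce(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            v = random_incidence(rng).values
            assert replacements(v) == replacements_bruteforce(v)

    def test_fill_ranges_fills_gaps_only(self):
        v = np.array([[1, 0], [0, 0], [1, 1]], dtype=np.int8)
        filled = fill_ranges(v)
        assert filled[:, 0].tolist() == [1, 1, 1]
        assert filled[:, 1].tolist() == [0, 0, 1]


class TestMorisita:
    def test_all_boundaries_one_site(self):
        counts = np.array([0, 0, 8, 0, 0])
        assert morisita_index(counts) == pytest.approx(5.0)

    def test_one_boundary_per_site(self):
        counts = np.ones(6, dtype=int)
        assert morisita_index(counts) == 0.0

    def test_matrix_morisita_matches_direct_formula(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            inc = random_incidence(rng, 10, 20)
            mine = boundary_clumping(inc).morisita
            assert mine == pytest.approx(morisita_bruteforce(inc.values), abs=1e-12)

    def test_chi_square_record(self):
        inc = random_incidence(np.random.default_rng(15), 10, 20)
        rec = boundary_clumping(inc, df_convention="sites")
        assert rec.df == 9
        assert 0 <= rec.p <= 1
        rec2 = boundary_clumping(inc, df_convention="species")
        assert rec2.df == len(inc.species_ids) - 1

    def test_too_few_boundaries_rejected(self):
        with pytest.raises(ValidationError):
            morisita_index(np.array([1, 0, 0]))


class TestR1Null:
    def test_row_sums_conserved(self):
        rng = np.random.default_rng(16)
        inc = random_incidence(rng, 10, 15)
        target = inc.values.sum(axis=1)
        for null in r1_null(inc, NullModelSpec(n_permutations=50, seed=1)):
            assert (null.sum(axis=1) == target).all()

    def test_zero_marginal_never_sampled(self):
        v = np.array([[1, 1, 0], [1, 0, 0], [0, 1, 0]], dtype=np.int8)
        inc = make_incidence(v)
        for null in r1_null(inc, NullModelSpec(n_permutations=50, seed=2)):
            assert null[:, 2].sum() == 0

    def test_inclusion_frequency_matches_enumeration(self):
        # 2 sites x 3 species with marginals (2, 1, 1) and richness (2, 2):
        # each row draws 2 of 3 species without replacement with weights
        # (2, 1, 1). Exact enumeration of ordered draws gives
        # P({a,b}) = (2/4)(1/2) + (1/4)(2/3) = 5/12 = P({a,c}),
        # P({b,c}) = (1/4)(1/3) + (1/4)(1/3) = 1/6, so per-row inclusion
        # probabilities are (5/6, 7/12, 7/12).
        inc = IncidenceMatrix(
            np.array([[1, 1, 0], [1, 0, 1]], dtype=np.int8), ["s0", "s1"], list("abc")
        )
        n = 10000
        freq = np.zeros(3)
        for null in r1_null(inc, NullModelSpec(n_permutations=n, seed=3)):
            freq += null.sum(axis=0)
        p_hat = freq / (2 * n)
        expected = np.array([5 / 6, 7 / 12, 7 / 12])
        se = np.sqrt(expected * (1 - expected) / (2 * n))
        assert (np.abs(p_hat - expected) < 3 * se + 1e-9).all()

    def test_reproducible_under_seed(self):
        inc = random_incidence(np.random.default_rng(17))
        a = list(r1_null(inc, NullModelSpec(n_permutations=3, seed=9)))
        b = list(r1_null(inc, NullModelSpec(n_permutations=3, seed=9)))
        for x, y in zip(a, b):
            assert (x == y).all()


class TestStatsAndReport:
    def test_coherence_and_turnover_records(self):
        sc = MetacommunityScenario("clementsian", 20, 40, n_compartments=2, seed=30)
        inc = generate_incidence(sc)
        ordered = ordinate(inc).ordered
        coh = coherence(ordered, NullModelSpec(n_permutations=49, seed=4))
        turn = turnover(ordered, NullModelSpec(n_permutations=49, seed=5))
        assert coh.observed == 0  # perfect compartments have no gaps
        assert coh.observed < coh.null_mean
        assert turn.observed > turn.null_mean
        assert coh.p is not None and coh.p < 0.05

    def test_axis_reversal_invariance(self):
        rng = np.random.default_rng(31)
        inc = random_incidence(rng, 10, 15)
        ordered = ordinate(inc).ordered
        flipped = IncidenceMatrix(
            ordered.values[::-1, ::-1].copy(),
            ordered.site_ids[::-1],
            ordered.species_ids[::-1],
        )
        assert embedded_absences(ordered.values) == embedded_absences(flipped.values)
        assert replacements(ordered.values) == replacements(flipped.values)
        assert boundary_clumping(ordered).morisita == pytest.approx(
            boundary_clumping(flipped).morisita
        )

    def test_degenerate_null_flagged(self):
        # 2x2 identity-like matrix: the r1 null can produce constant counts
        v = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=np.int8)
        inc = make_incidence(v)
        ordered = ordinate(inc).ordered
        with pytest.warns(UserWarning):
            stat = coherence(
                ordered,
                NullModelSpec(n_permutations=2, seed=1, reordinate_nulls=False),
            )
        # with 2 permutations the null sd may vanish; either a degenerate
        # flag or a finite p is acceptable, but the record must say which
        assert stat.degenerate == (stat.p is None)


def _stat(observed, null_mean, p, z=None):
    return NullStat(
        observed=observed,
        null_mean=null_mean,
        null_sd=1.0,
        z=(observed - null_mean) if z is None else z,
        p=p,
        p_empirical=p,
        n_permutations=99,
    )


def _clump(morisita, p):
    return ClumpingResult(morisita, 0.0, 10, p, p / 2, 1 - p / 2, 20)


class TestClassify:
    def test_paper_style_clementsian(self):
        coh = _stat(44120, 52216, 0.0001)
        turn = _stat(6764076, 552825, 0.0001)
        clump = _clump(72.41, 0.0001)
        mc = _stat(72.41, 1.2, 0.0001, z=20.0)
        assert classify(coh, turn, clump, clumping_null=mc) == "clementsian"

    def test_nonsignificant_coherence_is_random(self):
        assert (
            classify(_stat(100, 101, 0.4), _stat(5, 4, 0.5), _clump(1.0, 0.9))
            == "random"
        )

    def test_negative_coherence_is_checkerboard(self):
        assert (
            classify(_stat(200, 100, 0.001), _stat(5, 4, 0.5), _clump(1.0, 0.9))
            == "checkerboard"
        )

    def test_negative_turnover_is_nested(self):
        coh = _stat(50, 100, 0.001)
        turn = _stat(10, 1000, 0.001)
        assert classify(coh, turn, _clump(5.0, 0.001)) == "nested"

    def test_gleasonian_when_clumping_nonsignificant(self):
        coh = _stat(50, 100, 0.001)
        turn = _stat(2000, 1000, 0.001)
        mc = _stat(1.3, 1.25, 0.7, z=0.2)
        assert classify(coh, turn, _clump(1.3, 0.2), clumping_null=mc) == "gleasonian"

    def test_evenly_spaced_when_hyperdispersed(self):
        coh = _stat(50, 100, 0.001)
        turn = _stat(2000, 1000, 0.001)
        mc = _stat(0.7, 1.2, 0.001, z=-5.0)
        assert (
            classify(coh, turn, _clump(0.7, 0.001), clumping_null=mc)
            == "evenly_spaced"
        )

    def test_quasi_prefix(self):
        coh = _stat(50, 100, 0.001)
        turn = _stat(1100, 1000, 0.4)
        mc = _stat(1.0, 1.0, 0.9, z=0.0)
        assert (
            classify(coh, turn, _clump(1.0, 0.9), quasi=True, clumping_null=mc)
            == "quasi-gleasonian"
        )

    def test_degenerate_is_indeterminate(self):
        bad = NullStat(1, 1, 0.0, None, None, None, 99, degenerate=True)
        assert classify(bad, _stat(1, 1, 0.5), _clump(1.0, 0.5)) == "indeterminate"


class TestCompartments:
    def test_auto_boundary_on_two_compartment_matrix(self):
        sc = MetacommunityScenario(
            "clementsian", 30, 60, n_compartments=2, boundary_noise=0.02, seed=40
        )
        inc = generate_incidence(sc)
        truth = sc.site_compartments()
        ords = ordinate(inc)
        split = split_compartments(
            ords, "auto", null=NullModelSpec(n_permutations=49, seed=6)
        )
        child_sites = [set(c.site_ids) for c in split.children]
        comp0 = {f"site{i:03d}" for i in np.flatnonzero(truth == 0)}
        comp1 = {f"site{i:03d}" for i in np.flatnonzero(truth == 1)}
        assert {frozenset(comp0), frozenset(comp1)} == {
            frozenset(child_sites[0]), frozenset(child_sites[1])
        }

    def test_children_clementsian_with_subcompartments(self):
        # 4 compartments grouped 2+2: splitting at the middle edge leaves
        # each child with 2 compartments of its own
        sc = MetacommunityScenario(
            "clementsian", 40, 80, n_compartments=4, boundary_noise=0.02, seed=41
        )
        inc = generate_incidence(sc)
        ords = ordinate(inc)
        split = split_compartments(
            ords, 20, null=NullModelSpec(n_permutations=99, seed=7)
        )
        for rep in split.reports:
            assert rep is not None
            assert rep.classification == "clementsian"

    def test_tiny_child_refused(self):
        rng = np.random.default_rng(42)
        inc = random_incidence(rng, 4, 8)
        ords = ordinate(inc)
        with pytest.warns(UserWarning, match="refused"):
            split = split_compartments(ords, 1, null=NullModelSpec(seed=1))
        assert split.reports[0] is None

    def test_invalid_boundary_rejected(self):
        rng = np.random.default_rng(43)
        inc = random_incidence(rng, 6, 8)
        with pytest.raises(ValidationError):
            split_compartments(ordinate(inc), 6)


class TestCovariateCorrelation:
    def _ordination(self):
        sc = MetacommunityScenario("gleasonian", 20, 40, seed=50)
        return ordinate(generate_incidence(sc).drop_empty())

    def _metadata(self, ords, values):
        sites = ords.ordered.site_ids
        return pd.DataFrame({"cov": values}, index=sites)

    def test_perfect_correlation(self):
        ords = self._ordination()
        scores = ords.site_scores[ords.row_order]
        md = self._metadata(ords, scores)
        assert score_covariate_correlation(ords, md, "cov")["r"] == pytest.approx(1.0)
        md_neg = self._metadata(ords, -scores)
        assert score_covariate_correlation(ords, md_neg, "cov")["r"] == pytest.approx(-1.0)

    def test_zero_variance_missing(self):
        ords = self._ordination()
        md = self._metadata(ords, np.zeros(len(ords.ordered.site_ids)))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = score_covariate_correlation(ords, md, "cov")
        assert out["r"] is None

    def test_null_p_uniform(self):
        # independent covariates: p-values uniform (KS not rejected at 0.01)
        ords = self._ordination()
        n = len(ords.ordered.site_ids)
        rng = np.random.default_rng(51)
        ps = []
        for _ in range(1000):
            md = self._metadata(ords, rng.normal(size=n))
            ps.append(score_covariate_correlation(ords, md, "cov")["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestStructureRecoveryNoiseFree:
    @pytest.mark.parametrize(
        "label,kw",
        [
            ("clementsian", dict(n_compartments=2)),
            ("gleasonian", {}),
            ("nested", {}),
            ("checkerboard", {}),
        ],
    )
    def test_canonical_label_recovered(self, label, kw):
        sc = MetacommunityScenario(label, 24, 60, boundary_noise=0.0, seed=60, **kw)
        rep = ems_report(generate_incidence(sc), NullModelSpec(seed=61))
        assert rep.classification == label

    def test_noise_monotonicity(self):
        # recovery of the clean label cannot improve as noise grows
        rates = []
        for noise in (0.0, 0.15, 0.3):
            hits = 0
            for r in range(20):
                sc = MetacommunityScenario(
                    "clementsian", 30, 80, n_compartments=2,
                    boundary_noise=noise, seed=70 + r,
                )
                rep = ems_report(
                    generate_incidence(sc), NullModelSpec(seed=170 + r)
                )
                hits += rep.classification == "clementsian"
            rates.append(hits / 20)
        # allow one replicate of sampling slack between adjacent levels
        assert rates[0] >= rates[1] - 0.05
        assert rates[1] >= rates[2] - 0.05
        assert rates[0] >= rates[2]
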