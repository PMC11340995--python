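import numpy as np
import pytest

from scharm.core_io import AcquisitionSetting, Cohort, upper_triangle_index, vectorize
from scharm.errors import DesignError, FormatError
from scharm.harmonization import (
    ExtrapolationWarning,
    build_design,
    fit,
    fit_edges,
    harmonize,
    load_model,
    round_half_away,
    save_model,
)
from scharm.synthetic import (
    HBHR,
    LBLR,
    SimulationConfig,
    generate,
    generate_continuous,
)

from .conftest import make_connectome, random_symmetric_counts

GRID = [AcquisitionSetting(1.25, 1000), AcquisitionSetting(1.25, 3000),
        AcquisitionSetting(2.3, 1000), AcquisitionSetting(2.3, 3000)]


def noiseless_config(**overrides):
    return SimulationConfig(**{
        "n_regions": 10, "n_subjects": 10, "noise_sd": 0.0, "subject_sd": 0.0,
        "nonlinearity": 0.0, "seed": 11, **overrides,
    })


class TestDesign:
    def test_full_grid_has_rank_4(self):
        _, rank = build_design(GRID)
        assert rank == 4

    def test_two_settings_rank_2(self):
        _, rank = build_design([GRID[0], GRID[3]])
        assert rank == 2

    def test_repeated_single_setting_rank_1(self):
        _, rank = build_design([GRID[0]] * 5)
        assert rank == 1

    def test_empty_rejected(self):
        with pytest.raises(DesignError):
            build_design([])


class TestRounding:
    @pytest.mark.parametrize("x, expected", [
        (2.5, 3.0), (-2.5, -3.0), (2.4, 2.0), (-2.4, -2.0), (0.5, 1.0), (0.0, 0.0),
    ])
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(np.array([x]))[0] == expected


class TestFit:
    def test_recovers_generative_betas_continuous(self):
        scans, truth = generate_continuous(noiseless_config())
        model = fit_edges([s.setting for s in scans],
                          np.stack([s.values for s in scans]),
                          tuple(f"R{i:03d}" for i in range(10)))
        assert np.abs(model.betas[:, 1:] - truth.true_betas).max() < 1e-8

    def test_subject_effects_enter_intercept_only(self):
        # nonzero subject offsets shift beta0 by their mean, slopes untouched
        scans, truth = generate_continuous(noiseless_config(subject_sd=4.0))
        model = fit_edges([s.setting for s in scans],
                          np.stack([s.values for s in scans]),
                          tuple(f"R{i:03d}" for i in range(10)))
        assert np.abs(model.betas[:, 1:] - truth.true_betas).max() < 1e-8

    def test_constant_cohort_gives_zero_slopes(self, rng):
        m = random_symmetric_counts(rng, 6)
        cohort = Cohort()
        for s in range(2):
            for st_ in GRID:
                cohort.add(make_connectome(m, subject_id=f"s{s}", setting=st_))
        model = fit(cohort)
        np.testing.assert_allclose(model.betas[:, 1:], 0.0, atol=1e-9)
        index = upper_triangle_index(6)
        np.testing.assert_allclose(model.betas[:, 0], vectorize(m, index),
                                   atol=1e-9)

    def test_rank_deficient_design_names_settings(self, rng):
        cohort = Cohort()
        for s in range(4):
            cohort.add(make_connectome(random_symmetric_counts(rng, 5),
                                       subject_id=f"s{s}", setting=GRID[0]))
        with pytest.raises(DesignError, match="rank"):
            fit(cohort)

    def test_non_traveling_matches_traveling_when_noiseless(self):
        base = noiseless_config(n_subjects=16)
        trav_scans, truth = generate_continuous(base)
        single_scans, _ = generate_continuous(
            noiseless_config(n_subjects=16, design="single"))
        labels = tuple(f"R{i:03d}" for i in range(10))
        m_trav = fit_edges([s.setting for s in trav_scans],
                           np.stack([s.values for s in trav_scans]), labels)
        m_single = fit_edges([s.setting for s in single_scans],
                             np.stack([s.values for s in single_scans]), labels)
        assert np.abs(m_trav.betas - m_single.betas).max() < 1e-8


class TestHarmonize:
    @pytest.fixture
    def model(self):
        cohort, _ = generate(SimulationConfig(n_regions=12, n_subjects=8, seed=3))
        return fit(cohort), cohort

    def test_identity_when_target_equals_source(self, model):
        m, cohort = model
        for c in list(cohort)[:8]:
            out = harmonize(c, m, c.setting)
            assert np.array_equal(out.matrix, c.matrix)

    def test_hand_computed_correction(self):
        # single edge: b1=4, b2=0.01, b3=0; (2.3,1000) -> (1.25,3000), y=100
        labels = ("A", "B")
        index = upper_triangle_index(2)
        from scharm.harmonization import HarmonizationModel
        m = HarmonizationModel(
            edge_index=index, region_labels=labels,
            betas=np.array([[0.0, 4.0, 0.01, 0.0]]),
            training_settings=[(s, 1) for s in GRID],
            n_observations=4, design_rank=4,
        )
        c = make_connectome(np.array([[0, 100], [100, 0]]), labels=labels,
                            setting=AcquisitionSetting(2.3, 1000))
        out = harmonize(c, m, AcquisitionSetting(1.25, 3000))
        # 100 + 4*(-1.05) + 0.01*2000 = 115.8 -> 116
        assert out.matrix[0, 1] == 116

    def test_negative_corrections_clamp_to_zero(self):
        labels = ("A", "B")
        index = upper_triangle_index(2)
        from scharm.harmonization import HarmonizationModel
        m = HarmonizationModel(
            edge_index=index, region_labels=labels,
            betas=np.array([[0.0, 0.0, -0.005, 0.0]]),  # -10 over bval +2000
            training_settings=[(s, 1) for s in GRID],
            n_observations=4, design_rank=4,
        )
        c = make_connectome(np.array([[0, 3], [3, 0]]), labels=labels,
                            setting=AcquisitionSetting(2.3, 1000))
        out = harmonize(c, m, AcquisitionSetting(2.3, 3000))
        assert out.matrix[0, 1] == 0

    def test_affine_covariate_reparameterization_invariance(self):
        scans, _ = generate_continuous(noiseless_config(subject_sd=2.0,
                                                        noise_sd=1.0))
        labels = tuple(f"R{i:03d}" for i in range(10))
        values = np.stack([s.values for s in scans])
        settings = [s.setting for s in scans]

        def remap(s):  # res -> 2*res + 1, bval -> bval/1000 + 3
            return AcquisitionSetting(res=2 * s.res + 1, bval=s.bval / 1000 + 3)

        m_raw = fit_edges(settings, values, labels)
        m_txf = fit_edges([remap(s) for s in settings], values, labels)
        src, dst = LBLR, HBHR
        corr_raw = m_raw.correction(src, dst)
        corr_txf = m_txf.correction(remap(src), remap(dst))
        assert np.abs(corr_raw - corr_txf).max() < 1e-8

    def test_path_consistency_continuous_and_rounded(self, model):
        m, cohort = model
        ap1, ap2, ap3 = GRID[2], GRID[0], GRID[1]
        c = next(iter(cohort.subset(setting=ap1)))
        # continuous: corrections are differences of one linear function
        direct = m.correction(ap1, ap3)
        via = m.correction(ap1, ap2) + m.correction(ap2, ap3)
        assert np.abs(direct - via).max() < 1e-9
        # after rounding, the two routes differ by at most 1 per edge
        one_hop = harmonize(c, m, ap3)
        two_hop = harmonize(harmonize(c, m, ap2), m, ap3)
        assert np.abs(one_hop.matrix - two_hop.matrix).max() <= 1

    def test_extrapolation_warns_but_proceeds(self, model):
        m, cohort = model
        c = next(iter(cohort))
        with pytest.warns(ExtrapolationWarning):
            out = harmonize(c, m, AcquisitionSetting(2.3, 8000))
        assert (out.matrix >= 0).all()

    def test_output_is_valid_connectome(self, model):
        m, cohort = model
        out = harmonize(next(iter(cohort)), m, HBHR)
        assert np.array_equal(out.matrix, out.matrix.T)
        assert (np.diag(out.matrix) == 0).all()
        assert out.setting == HBHR


class TestRecoveryUnderNoise:
    def test_beta_rmse_shrinks_with_observations(self):
        """OLS slope error scales down as observations grow."""
        labels = tuple(f"R{i:03d}" for i in range(10))
        rmses = []
        for n_subjects in (5, 45):
            errs = []
            for seed in range(10):
                scans, truth = generate_continuous(SimulationConfig(
                    n_regions=10, n_subjects=n_subjects, noise_sd=5.0,
                    subject_sd=0.0, seed=100 + seed))
                model = fit_edges([s.setting for s in scans],
                                  np.stack([s.values for s in scans]), labels)
                errs.append(np.sqrt(np.mean(
                    (model.betas[:, 1:] - truth.true_betas) ** 2)))
            rmses.append(np.mean(errs))
        # 9x the data -> ~3x smaller RMSE; allow generous slack
        assert rmses[1] < rmses[0] / 2


class TestPersistence:
    def test_round_trip_reproduces_predictions(self, tmp_path):
        cohort, _ = generate(SimulationConfig(n_regions=8, n_subjects=6, seed=5))
        model = fit(cohort)
        path = tmp_path / "model.tsv"
        save_model(model, path)
        back = load_model(path)
        assert np.array_equal(back.betas, model.betas)  # bit-exact
        probe = next(iter(cohort))
        a = harmonize(probe, model, HBHR)
        b = harmonize(probe, back, HBHR)
        assert np.array_equal(a.matrix, b.matrix)

    def test_edge_row_count_matches_parcellation(self, tmp_path):
        cohort, _ = generate(SimulationConfig(n_regions=4, n_subjects=5, seed=5))
        model = fit(cohort)
        save_model(model, tmp_path / "m.tsv")
        rows = [l for l in (tmp_path / "m.tsv").read_text().splitlines()
                if not l.startswith("#")]
        assert len(rows) - 1 == 6  # header + 4*3/2 edges

    def test_missing_beta_column_rejected(self, tmp_path):
        cohort, _ = generate(SimulationConfig(n_regions=4, n_subjects=5, seed=5))
        model = fit(cohort)
        path = tmp_path / "m.tsv"
        save_model(model, path)
        lines = path.read_text().splitlines()
        broken = [("\t".join(l.split("\t")[:-1]) if not l.startswith("#") else l)
                  for l in lines]
        path.write_text("\n".join(broken) + "\n")
        with pytest.raises(FormatError):
            load_model(path)
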