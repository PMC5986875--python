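import json

import numpy as np
import pytest

from cgreg import admix_sim as sim
from cgreg import founder_panel as fp
from cgreg import trial_harness as th


@pytest.fixture(scope="module")
def small_study():
    """Fast four-population study: founders, panel, admixed cohort, truth."""
    geno, labels, freqs = sim.make_synthetic_founders(4, 600, 60, 0.15, rng=101)
    panel = fp.estimate_frequencies(geno, labels)
    scheme = sim.BreedingScheme(n_rounds=3, n_pairs=40, n_crossovers=10, seed=202)
    admixed, truths = sim.breed(geno, labels, scheme)
    truth = sim.truths_to_frame(truths, labels.populations)
    return geno, labels, panel, admixed, truth


@pytest.fixture(scope="module")
def dense_study():
    """Marker-rich study with the true frequency panel, for near-exact checks."""
    geno, labels, freqs = sim.make_synthetic_founders(4, 2000, 60, 0.15, rng=101)
    panel = fp.FounderPanel.from_frame(freqs)
    truth = sim.truths_to_frame(
        [
            sim.AncestryTruth(
                ind,
                np.eye(len(labels.populations))[
                    labels.populations.index(labels.assignments[ind])
                ],
            )
            for ind in geno.individual_ids
        ],
        labels.populations,
    )
    return geno, labels, panel, truth


class TestFullTrial:
    def test_equality_mode_scores_whole_cohort(self, small_study):
        _, _, panel, admixed, truth = small_study
        res = th.run_full_trial(panel, admixed, truth, modes=("equality",))
        rep = res.reports["equality"]
        assert rep.n_individuals == admixed.n_individuals
        assert rep.correlation > 0.9
        assert res.error_correlation is None

    def test_both_modes_report_error_correlation(self, small_study):
        _, _, panel, admixed, truth = small_study
        res = th.run_full_trial(panel, admixed, truth, modes=("equality", "inequality"))
        assert -1 <= res.error_correlation <= 1
        # relaxing the sum constraint can only reduce the residual, and the
        # two modes should give nearly the same summary statistics
        eq, le = res.reports["equality"], res.reports["inequality"]
        assert abs(eq.mae - le.mae) <= 0.05
        assert abs(eq.correlation - le.correlation) <= 0.02

    def test_unadmixed_founders_recovered_nearly_exactly(self, dense_study):
        """Pure founders score almost exactly as unit vectors; the residual
        reflects genotype sampling noise around the expected allele content."""
        geno, labels, panel, truth = dense_study
        res = th.run_full_trial(panel, geno, truth, modes=("equality",))
        assert res.reports["equality"].mse <= 1e-3


class TestType1Trial:
    def test_excluded_population_not_scored_and_mass_reassigned(self, small_study):
        _, _, panel, admixed, truth = small_study
        res = th.run_type1_trial(panel, admixed, truth, excluded="pop2")
        assert "pop2" not in res.estimates.columns
        assert res.overall.n_populations == 3
        # inequality constraint still holds for every individual
        assert (res.estimates.sum(axis=1) <= 1 + 1e-6).all()

    def test_zero_category_individuals_unaffected_by_exclusion(self, small_study):
        _, _, panel, admixed, truth = small_study
        res = th.run_type1_trial(panel, admixed, truth, excluded="pop2")
        full = th.run_full_trial(panel, admixed, truth, modes=("inequality",))
        kept = [p for p in panel.population_names if p != "pop2"]
        from cgreg import eval_metrics as em

        full_by_cat = em.metrics_by_category(
            truth, full.proportions["inequality"].reindex(columns=kept), "pop2", kept
        )
        if "0%" in res.by_category:
            assert res.by_category["0%"].mae == pytest.approx(
                full_by_cat["0%"].mae, abs=0.01
            )

    def test_unknown_excluded_population_errors(self, small_study):
        _, _, panel, admixed, truth = small_study
        with pytest.raises(ValueError, match="not in panel"):
            th.run_type1_trial(panel, admixed, truth, excluded="nope")


class TestType2Trial:
    def test_only_carriers_used_and_focal_scored(self, small_study):
        geno, labels, panel, admixed, truth = small_study
        res = th.run_type2_trial(
            panel, geno, labels, admixed, truth, focal="pop1", background_size=100, seed=3
        )
        assert res.n_used == int((truth["pop1"] > 0).sum())
        assert res.report.n_populations == 1
        assert res.report.correlation > 0.8

    def test_pure_focal_individuals_estimated_near_one(self, dense_study):
        geno, labels, panel, truth = dense_study
        pure_ids = labels.individuals_of("pop1")[:10]
        pure = geno.subset_individuals(pure_ids)
        res = th.run_type2_trial(
            panel, geno, labels, pure, truth.loc[pure_ids],
            focal="pop1", background_size=100, seed=3,
        )
        assert (res.estimates["pop1"] >= 0.95).all()

    def test_no_qualifying_individuals_errors(self, small_study):
        geno, labels, panel, admixed, truth = small_study
        zero_truth = truth.copy()
        zero_truth["pop1"] = 0.0
        with pytest.raises(ValueError, match="carry"):
            th.run_type2_trial(panel, geno, labels, admixed, zero_truth, focal="pop1")


class TestPanelCorrelations:
    def test_identical_columns_correlate_perfectly(self):
        freqs = np.random.default_rng(0).uniform(0.1, 0.9, size=(100, 1))
        panel = fp.FounderPanel(
            [f"m{i}" for i in range(100)], ["A", "B"], np.hstack([freqs, freqs])
        )
        corr = th.panel_correlations(panel)
        assert corr.loc["A", "B"] == pytest.approx(1.0)
        assert np.allclose(np.diag(corr), 1.0)

    def test_split_population_more_correlated_than_diverged_ones(self):
        geno, labels, _ = sim.make_synthetic_founders(2, 800, 100, 0.2, rng=55)
        # split pop1's individuals in half and treat halves as two populations
        ids = labels.individuals_of("pop1")
        import cgreg.genotype_io as gio

        split = gio.PopulationLabels.from_pairs(
            [(i, "h1") for i in ids[:50]]
            + [(i, "h2") for i in ids[50:]]
            + [(i, "far") for i in labels.individuals_of("pop2")]
        )
        panel = fp.estimate_frequencies(geno, split)
        corr = th.panel_correlations(panel)
        assert corr.loc["h1", "h2"] > corr.loc["h1", "far"]

    def test_constant_column_warns(self):
        panel = fp.FounderPanel(
            ["m0", "m1"], ["A", "B"], np.array([[0.5, 0.1], [0.5, 0.9]])
        )
        with pytest.warns(UserWarning, match="constant"):
            corr = th.panel_correlations(panel)
        assert np.isnan(corr.loc["A", "B"])


class TestConfigDrivenRun:
    def test_run_trial_writes_outputs_and_is_deterministic(self, small_study, tmp_path):
        geno, labels, *_ = small_study
        cfg = th.TrialConfig(
            trial_type="full",
            constraint="equality",
            scheme=sim.BreedingScheme(n_rounds=2, n_pairs=20, n_crossovers=5, seed=4),
            outdir=str(tmp_path / "run1"),
        )
        th.run_trial(cfg, geno, labels)
        report1 = json.loads((tmp_path / "run1" / "report.json").read_text())
        props1 = (tmp_path / "run1" / "proportions.tsv").read_text()
        cfg2 = th.TrialConfig(
            trial_type="full",
            constraint="equality",
            scheme=sim.BreedingScheme(n_rounds=2, n_pairs=20, n_crossovers=5, seed=4),
            outdir=str(tmp_path / "run2"),
        )
        th.run_trial(cfg2, geno, labels)
        assert json.loads((tmp_path / "run2" / "report.json").read_text()) == report1
        assert (tmp_path / "run2" / "proportions.tsv").read_text() == props1
        assert (tmp_path / "run1" / "run.log").exists()

    def test_yaml_config_round_trip(self, tmp_path):
        cfg_path = tmp_path / "trial.yaml"
        cfg_path.write_text(
            "trial_type: type1\n"
            "excluded_population: pop2\n"
            "scheme: {n_rounds: 2, n_pairs: 10, n_crossovers: 5, seed: 1}\n"
        )
        cfg = th.load_config(cfg_path)
        assert cfg.trial_type == "type1"
        assert cfg.excluded_population == "pop2"
        assert cfg.scheme.n_rounds == 2

    def test_type1_requires_excluded_population(self):
        with pytest.raises(ValueError, match="excluded"):
            th.TrialConfig(trial_type="type1")


class TestPanelSizeMonotonicity:
    def test_larger_reference_panels_do_not_hurt_accuracy(self):
        """More reference individuals per population should not raise MSE.

        The admixed cohort is held fixed; only the reference subset used to
        estimate panel frequencies varies, isolating panel sampling noise.
        """
        from cgreg import genotype_io as gio

        geno, labels, _ = sim.make_synthetic_founders(3, 500, 400, 0.15, rng=500)
        scheme = sim.BreedingScheme(n_rounds=2, n_pairs=50, n_crossovers=10, seed=7)
        admixed, truths = sim.breed(geno, labels, scheme)
        truth = sim.truths_to_frame(truths, labels.populations)
        mses = []
        for n_ref in (50, 400):
            ids = [i for p in labels.populations for i in labels.individuals_of(p)[:n_ref]]
            sub = geno.subset_individuals(ids)
            sub_labels = gio.PopulationLabels(
                {i: labels.assignments[i] for i in ids}, labels.populations
            )
            panel = fp.estimate_frequencies(sub, sub_labels)
            res = th.run_full_trial(panel, admixed, truth, modes=("equality",))
            mses.append(res.reports["equality"].mse)
        assert mses[1] <= mses[0]
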