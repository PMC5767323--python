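"""Two-stage inference: single-site thermogram fits and the linkage fit."""

import numpy as np
import pytest

from itclink import (
    BindingParameters,
    BindingSignalAbsentError,
    LinkageDataset,
    LinkageParameters,
    NoiseModel,
    Thermogram,
    TitrationProtocol,
    UnderdeterminedError,
    bootstrap_linkage,
    compare_variants,
    fit_linkage,
    fit_single_site,
    get_preset,
    injection_heat_series,
    kdapp_linkage,
    simulate_linkage_dataset,
)


def make_thermogram(kd=0.97, delta_h=-10.0, n=1.0, offset=0.0, **prot_kw):
    defaults = dict(cell_volume=200.0, injection_volume=2.0, n_injections=19,
                    cell_macromolecule_total=5.0, cell_conc_basis="monomer",
                    monomer_per_site=2, syringe_titrant_total=50.0)
    defaults.update(prot_kw)
    prot = TitrationProtocol(**defaults)
    return injection_heat_series(
        prot, BindingParameters(kd=kd, delta_h=delta_h, n_stoich=n, q_offset=offset)
    )


class TestSingleSiteFit:
    def test_noise_free_round_trip(self):
        fit = fit_single_site(make_thermogram(kd=0.97, delta_h=-10.0))
        assert fit.converged
        assert fit.kdapp == pytest.approx(0.97, rel=1e-3)
        assert fit.delta_h == pytest.approx(-10.0, rel=1e-3)
        assert fit.n_stoich == pytest.approx(1.0, rel=1e-3)

    def test_round_trip_with_offset_and_stoichiometry(self):
        fit = fit_single_site(make_thermogram(kd=2.0, delta_h=5.0, n=0.9, offset=0.2))
        assert fit.converged
        assert fit.kdapp == pytest.approx(2.0, rel=1e-4)
        assert fit.n_stoich == pytest.approx(0.9, rel=1e-4)
        assert fit.q_offset == pytest.approx(0.2, abs=1e-6)

    def test_flat_thermogram_rejected(self):
        prot = TitrationProtocol(n_injections=19)
        tg = Thermogram(heats=np.zeros(19), protocol=prot)
        with pytest.raises(BindingSignalAbsentError, match="binding signal absent"):
            fit_single_site(tg)

    def test_too_few_injections_rejected(self):
        prot = TitrationProtocol(n_injections=4, cell_volume=200.0)
        tg = injection_heat_series(prot, BindingParameters(kd=1.0, delta_h=-10.0))
        with pytest.raises(UnderdeterminedError):
            fit_single_site(tg)

    def test_low_c_titration_flagged_non_identifiable(self):
        # SS120-like: Kd 6.7 uM with 2.5 uM sites -> c ~ 0.37
        fit = fit_single_site(make_thermogram(kd=6.7))
        assert fit.converged
        assert fit.c_value == pytest.approx(2.5 / 6.7, rel=1e-3)
        assert not fit.identifiable

    def test_well_designed_titration_identifiable(self):
        fit = fit_single_site(make_thermogram(kd=0.97))
        assert fit.identifiable  # c ~ 2.6

    def test_fixing_parameters(self):
        tg = make_thermogram(kd=1.5, delta_h=-12.0, n=1.0, offset=0.0)
        fit = fit_single_site(tg, fix_n_stoich=1.0, fix_q_offset=0.0)
        assert fit.n_stoich == 1.0 and fit.q_offset == 0.0
        assert fit.se_n_stoich == 0.0 and fit.se_q_offset == 0.0
        assert fit.kdapp == pytest.approx(1.5, rel=1e-6)

    def test_first_injection_excluded_fit(self):
        tg = make_thermogram(kd=0.97).exclude_first()
        fit = fit_single_site(tg)
        assert fit.kdapp == pytest.approx(0.97, rel=1e-3)


class TestLinkageFit:
    @pytest.mark.parametrize("name", ["MIT9313", "SS120", "MED4"])
    def test_noise_free_round_trip(self, name):
        preset = get_preset(name)
        ds = simulate_linkage_dataset(preset)
        fit = fit_linkage(ds)
        t = preset.truth
        assert fit.converged
        assert fit.params.kd_intrinsic == pytest.approx(t.kd_intrinsic, rel=1e-6)
        assert fit.params.kd_oxo == pytest.approx(t.kd_oxo, rel=1e-6)
        assert fit.params.alpha == pytest.approx(t.alpha, rel=1e-6)

    def test_effective_recomputed_from_params(self, mit9313_truth):
        fit = fit_linkage(simulate_linkage_dataset(get_preset("MIT9313")))
        eff = fit.effective
        assert eff.kd_eff == pytest.approx(fit.params.kd_intrinsic / fit.params.alpha)
        assert eff.kd_oxo_eff == pytest.approx(fit.params.kd_oxo / fit.params.alpha)

    def test_flat_dataset_flags_no_linkage(self):
        ds = LinkageDataset.from_arrays([0, 1, 5, 10], [5.0, 5.0, 5.0, 5.0])
        fit = fit_linkage(ds)
        assert fit.no_detectable_linkage
        assert fit.params.alpha == pytest.approx(1.0)
        assert fit.params.kd_intrinsic == pytest.approx(5.0)

    def test_two_points_underdetermined(self):
        ds = LinkageDataset.from_arrays([0, 10], [5.0, 1.0])
        with pytest.raises(UnderdeterminedError, match="underdetermined"):
            fit_linkage(ds)

    def test_weighted_equals_unweighted_for_equal_ses(self, mit9313_truth):
        oxo = np.array([0.0, 1.0, 5.0, 10.0, 2.0, 7.5])
        rng = np.random.default_rng(11)
        kdapp = kdapp_linkage(oxo, mit9313_truth) * np.exp(rng.normal(0, 0.03, oxo.size))
        se = np.full(oxo.size, 0.05)
        ds = LinkageDataset.from_arrays(oxo, kdapp, se)
        fw = fit_linkage(ds, log_scale=False, weighting="inverse_variance")
        fu = fit_linkage(ds, log_scale=False, weighting="none")
        assert fw.params.kd_intrinsic == pytest.approx(fu.params.kd_intrinsic, rel=1e-6)
        assert fw.params.alpha == pytest.approx(fu.params.alpha, rel=1e-6)

    def test_fixed_alpha_for_mutated_promoter(self):
        # mutated-promoter series: constant Kd_app, alpha pinned to 1
        ds = LinkageDataset.from_arrays([0, 1, 5, 10], [2.1, 2.1, 2.1, 2.1])
        fit = fit_linkage(ds, fix_alpha=1.0)
        assert fit.params.alpha == 1.0
        assert fit.params.kd_intrinsic == pytest.approx(2.1, rel=1e-6)
        assert fit.no_detectable_linkage

    def test_negative_cooperativity_recovered(self):
        truth = LinkageParameters(2.0, 15.0, 0.3)
        oxo = [0.0, 1.0, 3.0, 10.0, 30.0]
        ds = LinkageDataset.from_arrays(oxo, kdapp_linkage(np.array(oxo), truth))
        fit = fit_linkage(ds)
        assert fit.params.alpha == pytest.approx(0.3, rel=1e-6)


class TestBootstrap:
    def test_deterministic_under_seed(self):
        ds = simulate_linkage_dataset(
            get_preset("MIT9313"), np.linspace(0, 10, 8),
            NoiseModel(kdapp_noise_cv=0.03, seed=5),
        )
        a = bootstrap_linkage(ds, n_boot=100, seed=7)
        b = bootstrap_linkage(ds, n_boot=100, seed=7)
        assert a.intervals == b.intervals

    def test_noise_free_intervals_degenerate(self):
        ds = simulate_linkage_dataset(get_preset("MIT9313"), np.linspace(0, 10, 8))
        bs = bootstrap_linkage(ds, n_boot=100, seed=1)
        lo, hi = bs.intervals["kd_intrinsic"]
        assert (hi - lo) / bs.estimates["kd_intrinsic"] < 1e-6

    def test_seed_required(self):
        ds = simulate_linkage_dataset(get_preset("MIT9313"))
        with pytest.raises(ValueError):
            bootstrap_linkage(ds, n_boot=100, seed=None)


class TestCompareVariants:
    def fits_from_presets(self):
        return {n: fit_linkage(simulate_linkage_dataset(get_preset(n)))
                for n in ("MIT9313", "SS120", "MED4")}

    def test_fold_differences_match_reported_comparison(self):
        """SS120 and MED4 bind the promoter ~7x and ~5x more weakly than
        MIT9313 (intrinsic Kd ratios)."""
        df = compare_variants(self.fits_from_presets(), "MIT9313")
        assert df.loc["SS120", "kd_fold_vs_ref"] == pytest.approx(6.7 / 0.97, rel=1e-5)
        assert df.loc["MED4", "kd_fold_vs_ref"] == pytest.approx(4.8 / 0.97, rel=1e-5)
        assert round(df.loc["SS120", "kd_fold_vs_ref"]) == 7
        assert round(df.loc["MED4", "kd_fold_vs_ref"]) == 5
        assert df.loc["MIT9313", "kd_fold_vs_ref"] == pytest.approx(1.0)

    def test_identical_fits_all_unity(self):
        fit = fit_linkage(simulate_linkage_dataset(get_preset("MIT9313")))
        df = compare_variants({"a": fit, "b": fit}, "a")
        assert df["kd_fold_vs_ref"].tolist() == pytest.approx([1.0, 1.0])
        assert df["alpha_fold_vs_ref"].tolist() == pytest.approx([1.0, 1.0])

    def test_missing_reference_rejected(self):
        with pytest.raises(KeyError, match="reference"):
            compare_variants(self.fits_from_presets(), "PCC9511")
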