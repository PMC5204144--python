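"""Stem-to-genus trait derivation: growth, size, mortality, SEs, adjustment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phylodemog.census_io import CensusObservation, StemRecord
from phylodemog import demographic_traits as dt
from phylodemog.allometry import basal_area


def make_stem(diams, dates=None, genus="Inga", species=None, plot="p1",
              growth_form="tree", tape=True, new_poms=None, stem_id="s1"):
    dates = dates if dates is not None else [2000.0 + 5 * i for i in range(len(diams))]
    new_poms = new_poms or {}
    obs = [
        CensusObservation(
            date=t, diameter=d, pom_height=1.3 + 0.5 * sum(1 for j in new_poms if j <= i),
            alive=True, method_tape=tape, new_pom_diameter=new_poms.get(i),
        )
        for i, (t, d) in enumerate(zip(dates, diams))
    ]
    return StemRecord(stem_id=stem_id, plot_id=plot, genus=genus, species=species,
                      growth_form=growth_form, observations=obs)


class TestEffectiveDiameterSeries:
    def test_no_pom_change_is_identity(self):
        s = make_stem([20.0], dates=[2000.0])
        assert dt.effective_diameter_series(s) == [(2000.0, 20.0)]

    def test_pom_change_takes_arithmetic_mean(self):
        s = make_stem([20.0, 22.0], dates=[2000.0, 2005.0], new_poms={1: 21.0})
        assert dt.effective_diameter_series(s) == [(2000.0, 20.0), (2005.0, 21.5)]

    def test_successive_pom_changes_averaged_independently(self):
        s = make_stem([20.0, 22.0, 24.0], dates=[2000.0, 2005.0, 2010.0],
                      new_poms={1: 21.0, 2: 23.0})
        assert dt.effective_diameter_series(s) == [
            (2000.0, 20.0), (2005.0, 21.5), (2010.0, 23.5)
        ]

    def test_pom_change_without_new_diameter_errors(self):
        s = make_stem([20.0, 22.0], dates=[2000.0, 2005.0])
        object.__setattr__(s.observations[1], "pom_height", 1.8)  # frozen dataclass
        with pytest.raises(ValueError, match="without new_pom_diameter"):
            dt.effective_diameter_series(s)


class TestStemGrowthSummary:
    def test_single_interval(self):
        s = make_stem([10.0, 11.0], dates=[2000.0, 2002.0])
        g = dt.stem_growth_summary(s, wd=0.6, e=0.0)
        assert g.mean_growth_d == pytest.approx(0.5)
        assert g.max_growth_d == pytest.approx(0.5)

    def test_two_intervals_hand_arithmetic(self):
        # rates 1.0 and 0.5 cm/yr -> mean 0.75, max 1.0
        s = make_stem([10.0, 12.0, 13.0], dates=[2000.0, 2002.0, 2004.0])
        g = dt.stem_growth_summary(s, wd=0.6, e=0.0)
        assert g.mean_growth_d == pytest.approx(0.75)
        assert g.max_growth_d == pytest.approx(1.0)
        assert g.max_size_d == pytest.approx(13.0)
        assert g.max_size_ba == pytest.approx(basal_area(13.0))

    def test_max_size_is_max_over_censuses(self):
        s = make_stem([10.0, 12.0, 11.5])
        assert dt.stem_growth_summary(s, 0.6, 0.0).max_size_d == pytest.approx(12.0)

    def test_single_census_has_size_but_no_growth(self):
        g = dt.stem_growth_summary(make_stem([15.0], dates=[2000.0]), 0.6, 0.0)
        assert not g.has_growth
        assert g.max_size_d == pytest.approx(15.0)

    def test_growth_on_all_scales_and_invariant(self):
        s = make_stem([10.0, 13.0, 14.0])
        g = dt.stem_growth_summary(s, 0.6, 0.0)
        for m in ("d", "ba", "agb"):
            assert getattr(g, f"max_growth_{m}") >= getattr(g, f"mean_growth_{m}")


class TestGrowthExclusions:
    def test_reasons(self):
        stems = [
            make_stem([10.0, 9.0], stem_id="neg"),                     # mean < 0
            make_stem([10.0, 56.0], dates=[2000.0, 2005.0], stem_id="fast"),  # 9.2 cm/yr
            make_stem([10.0, 11.0], growth_form="palm", stem_id="palm"),
            make_stem([10.0, 11.0], tape=False, stem_id="caliper"),
            make_stem([10.0, 11.0], stem_id="ok"),
        ]
        summaries = [dt.stem_growth_summary(s, 0.6, 0.0) for s in stems]
        kept, excluded = dt.apply_growth_exclusions(summaries)
        assert {s.stem_id for s in kept} == {"ok"}
        reasons = {s.stem_id: s.exclusion_reason for s in excluded}
        assert reasons == {"neg": "negative", "fast": "implausible",
                           "palm": "palm", "caliper": "not_tape"}

    def test_palms_keep_size_traits(self):
        palms = [dt.stem_growth_summary(
            make_stem([10.0 + i, 12.0 + i], growth_form="palm", stem_id=f"p{i}"), 0.6, 0.0)
            for i in range(20)]
        kept, excluded = dt.apply_growth_exclusions(palms)
        assert kept == []
        ests, _ = dt.genus_potential_size(palms, "d", min_n=20)
        assert len(ests) == 1  # size trait still emitted from the same stems


class TestPotentialSize:
    def test_printed_quantile_example(self):
        # 20 stems at 10..29 cm: h = 19*0.95 + 1 = 19.05 -> 28.05
        summaries = [dt.stem_growth_summary(make_stem([float(d)], dates=[2000.0],
                                                      stem_id=f"s{d}"), 0.6, 0.0)
                     for d in range(10, 30)]
        ests, _ = dt.genus_potential_size(summaries, "d", min_n=20)
        assert ests[0].value == pytest.approx(28.05)
        assert ests[0].n_stems == 20

    def test_below_threshold_omitted(self):
        summaries = [dt.stem_growth_summary(make_stem([float(d)], dates=[2000.0],
                                                      stem_id=f"s{d}"), 0.6, 0.0)
                     for d in range(10, 29)]  # 19 stems
        ests, omitted = dt.genus_potential_size(summaries, "d", min_n=20)
        assert ests == [] and omitted == ["Inga"]

    def test_degenerate_distribution(self):
        summaries = [dt.stem_growth_summary(make_stem([15.0], dates=[2000.0],
                                                      stem_id=f"s{i}"), 0.6, 0.0)
                     for i in range(20)]
        ests, _ = dt.genus_potential_size(summaries, "d", min_n=20)
        assert ests[0].value == pytest.approx(15.0)

    def test_wood_density_product_variant(self):
        summaries = [dt.stem_growth_summary(make_stem([float(d)], dates=[2000.0],
                                                      stem_id=f"s{d}"), 0.6, 0.0)
                     for d in range(10, 30)]
        ests, _ = dt.genus_potential_size(summaries, "d", min_n=20, genus_wd={"Inga": 0.5})
        by_name = {e.trait_name: e.value for e in ests}
        assert by_name["max_dxwd"] == pytest.approx(28.05 * 0.5)


class TestGenusGrowth:
    def test_constant_mean_growth(self):
        summaries = [dt.stem_growth_summary(
            make_stem([10.0, 11.5], dates=[2000.0, 2005.0], stem_id=f"s{i}"), 0.6, 0.0)
            for i in range(20)]
        ests, _ = dt.genus_growth_traits(summaries, min_n=20)
        by_name = {e.trait_name: e.value for e in ests}
        assert by_name["meangr_d"] == pytest.approx(0.3)

    def test_max_growth_quantile_example(self):
        # stem max growths 0.1..2.0 -> 95th pct 1.905
        summaries = []
        for i in range(1, 21):
            rate = 0.1 * i
            summaries.append(dt.stem_growth_summary(
                make_stem([10.0, 10.0 + 5 * rate], dates=[2000.0, 2005.0],
                          stem_id=f"s{i}"), 0.6, 0.0))
        ests, _ = dt.genus_growth_traits(summaries, min_n=20)
        by_name = {e.trait_name: e.value for e in ests}
        assert by_name["maxgr_d"] == pytest.approx(1.905)

    def test_threshold_counts_stems_after_exclusions(self):
        stems = [make_stem([10.0, 11.0], stem_id=f"t{i}") for i in range(19)]
        stems += [make_stem([10.0, 11.0], growth_form="palm", stem_id=f"p{i}")
                  for i in range(6)]
        summaries = [dt.stem_growth_summary(s, 0.6, 0.0) for s in stems]
        kept, _ = dt.apply_growth_exclusions(summaries)
        ests, omitted = dt.genus_growth_traits(kept, min_n=20)
        assert ests == [] and omitted == ["Inga"]


class TestMortality:
    def test_equal_time_no_covariate_closed_form(self):
        rec = pd.DataFrame({
            "genus": "A", "species": "A x", "t": 5.0,
            "survived": [False] * 10 + [True] * 90, "d0": 20.0,
        })
        fit = dt.fit_genus_mortality(rec, min_n=100, fix_beta=0.0)
        assert fit.estimates[0].value == pytest.approx(100 * (-np.log(0.9) / 5), abs=1e-8)
        assert fit.estimates[0].value == pytest.approx(2.11, abs=0.005)

    def test_zero_deaths_reports_boundary_zero(self):
        rec = pd.DataFrame({
            "genus": "A", "species": "A x", "t": 5.0, "survived": True,
            "d0": np.linspace(10, 40, 120),
        })
        fit = dt.fit_genus_mortality(rec, min_n=100)
        assert fit.estimates[0].value == 0.0
        assert fit.estimates[0].flags.get("boundary") is True

    def test_below_threshold_genus_dropped(self):
        rec = pd.DataFrame({
            "genus": ["A"] * 120 + ["B"] * 50, "species": "x", "t": 5.0,
            "survived": ([False] * 12 + [True] * 108) + [True] * 50,
            "d0": 20.0,
        })
        fit = dt.fit_genus_mortality(rec, min_n=100, fix_beta=0.0)
        assert [e.genus for e in fit.estimates] == ["A"]

    def test_simulation_recovery_with_size_effect(self):
        rng = np.random.default_rng(17)
        n, G = 4000, 4
        gidx = rng.integers(G, size=n)
        alpha = np.array([-4.4, -4.0, -3.7, -3.4])
        beta = -0.3
        d0 = np.exp(rng.normal(np.log(15), 0.45, n))
        z = (np.log(d0) - np.log(d0).mean()) / np.log(d0).std(ddof=1)
        m = np.exp(alpha[gidx] + beta * z)
        t = rng.uniform(4, 12, n)
        surv = rng.random(n) < np.exp(-m * t)
        rec = pd.DataFrame({"genus": [f"G{i}" for i in gidx], "species": "x",
                            "t": t, "survived": surv, "d0": d0})
        fit = dt.fit_genus_mortality(rec, min_n=100, compute_se=True)
        se = np.sqrt(np.diag(fit.diagnostics["param_cov"]))
        est = np.concatenate([fit.alphas.to_numpy(), [fit.beta]])
        truth = np.concatenate([alpha, [beta]])
        assert np.all(np.abs(est - truth) < 4 * se)


class TestMortalityRecords:
    def test_monitoring_span_and_survival_status(self):
        alive = make_stem([10.0, 12.0, 13.0], dates=[2000.0, 2004.0, 2009.0])
        dead = StemRecord(
            stem_id="d1", plot_id="p1", genus="Inga", species=None, growth_form="tree",
            observations=[
                CensusObservation(2000.0, 11.0, 1.3, True),
                CensusObservation(2006.0, None, 1.3, False),
            ],
        )
        rec = dt.mortality_records([alive, dead])
        assert rec.loc[rec.stem_id == "s1", "t"].item() == pytest.approx(9.0)
        assert rec.loc[rec.stem_id == "s1", "survived"].item()
        assert rec.loc[rec.stem_id == "d1", "t"].item() == pytest.approx(6.0)
        assert not rec.loc[rec.stem_id == "d1", "survived"].item()

    def test_demography_plot_filter(self):
        s1 = make_stem([10.0, 12.0], plot="keep", stem_id="a")
        s2 = make_stem([10.0, 12.0], plot="drop", stem_id="b")
        rec = dt.mortality_records([s1, s2], demography_plot_ids={"keep"})
        assert rec["stem_id"].tolist() == ["a"]


class TestPlotAdjustment:
    def test_no_plot_effect_noiseless_identity(self):
        # two genera x three plots, identical everywhere: adjusted == unadjusted
        genera = ["A"] * 30 + ["B"] * 30
        plots = (["p1", "p2", "p3"] * 10) * 2
        values = [1.0] * 30 + [2.0] * 30
        res = dt.plot_adjusted_traits(values, genera, plots, kind="mean")
        pd.testing.assert_series_equal(res.adjusted, res.unadjusted,
                                       check_names=False, atol=1e-6)

    def test_known_offsets_recovered(self):
        rng = np.random.default_rng(23)
        genera_means = {"A": 0.2, "B": 0.4, "C": 0.8}
        offsets = {"p1": 0.4, "p2": -0.4, "p3": 0.0, "p4": 0.2, "p5": -0.2}
        rows = []
        for g, mu in genera_means.items():
            for p, off in offsets.items():
                for _ in range(60):
                    rows.append((g, p, mu * np.exp(off + rng.normal(0, 0.2))))
        g, p, v = zip(*rows)
        res = dt.plot_adjusted_traits(v, g, p, kind="mean")
        # adjusted values recover the generating genus means (average plot)
        for genus, mu in genera_means.items():
            assert res.adjusted[genus] == pytest.approx(mu, rel=0.05)
        # BLUP offsets track the generating plot offsets
        off_est = res.plot_offsets - res.plot_offsets.mean()
        off_true = pd.Series(offsets) - np.mean(list(offsets.values()))
        assert off_est.sub(off_true).abs().max() < 0.1
        assert res.kendall_tau is not None and res.kendall_tau > 0.9

    def test_quantile_kind_subtracts_offsets_before_quantile(self):
        # plot p2 systematically 50% larger; adjustment must undo it exactly
        genera = ["A"] * 40
        plots = ["p1"] * 20 + ["p2"] * 20
        base = np.linspace(10, 29, 20)
        values = np.concatenate([base, base * 1.5])
        res = dt.plot_adjusted_traits(values, genera, plots, kind="quantile")
        spread_adj = res.adjusted["A"]
        assert abs(np.log(spread_adj) - np.log(res.unadjusted["A"])) < 0.25

    def test_single_plot_returns_unadjusted_with_warning(self):
        with pytest.warns(UserWarning, match="single plot"):
            res = dt.plot_adjusted_traits([1.0, 2.0, 3.0], ["A", "A", "B"],
                                          ["p1", "p1", "p1"], kind="mean")
        assert res.adjusted_is_unadjusted

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            dt.plot_adjusted_traits([1.0, 0.0], ["A", "A"], ["p1", "p2"])


class TestIntragenericSe:
    def test_two_species_closed_form(self):
        ses = dt.intrageneric_se({"A": [0.5, 0.7]})
        assert ses["A"] == pytest.approx(np.std([0.5, 0.7], ddof=1) / np.sqrt(2))
        assert ses["A"] == pytest.approx(0.1)

    def test_single_species_genus_imputed_with_mean(self):
        ses = dt.intrageneric_se({"A": [0.4, 0.6], "B": [0.1, 0.2, 0.3, 0.6], "C": [0.5]})
        assert ses["C"] == pytest.approx(np.mean([ses["A"], ses["B"]]))

    def test_imputed_value_matches_printed_example(self):
        # genera with SEs 0.1 and 0.3 -> missing genus receives their mean, 0.2
        # (sd/sqrt(2) = 0.1 needs species values +-0.1 around the mean)
        ses = dt.intrageneric_se({"A": [0.9, 1.1], "B": [0.7, 1.3], "C": [0.5]})
        assert ses["A"] == pytest.approx(0.1)
        assert ses["B"] == pytest.approx(0.3)
        assert ses["C"] == pytest.approx(0.2)

    def test_no_multispecies_genus_errors(self):
        with pytest.raises(ValueError, match="cannot be imputed"):
            dt.intrageneric_se({"A": [0.5]})


class TestWoodDensity:
    WD = {"Inga edulis": 0.4, "Inga alba": 0.8, "Protium grande": 0.61, "Ocotea": 0.55}

    def test_genus_mean_of_species(self):
        ests, omitted = dt.genus_wood_density(self.WD, ["Inga", "Protium", "Ocotea", "Virola"])
        by = {e.genus: e for e in ests}
        assert by["Inga"].value == pytest.approx(0.6)
        assert by["Protium"].value == pytest.approx(0.61)
        assert by["Ocotea"].value == pytest.approx(0.55)  # bare-genus fallback entry
        assert omitted == ["Virola"]

    def test_stem_assignment_prefers_exact_species(self):
        assert dt.assign_wood_density("Inga", "Inga edulis", self.WD) == (0.4, "species")
        assert dt.assign_wood_density("Inga", "Inga unknown", self.WD) == (
            pytest.approx(0.6), "genus")
        assert dt.assign_wood_density("Virola", None, self.WD) is None

    def test_fold_range(self):
        assert dt.fold_range([0.15, 0.3, 1.2]) == pytest.approx(8.0)
        with pytest.raises(ValueError):
            dt.fold_range([0.0, 1.0])
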