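"""Baselines, incorporation scoring, summaries and holobiont assembly."""

import numpy as np
import pandas as pd
import pytest

from spongetrace import experiment as exp
from spongetrace import tracer
from spongetrace.constants import DEFAULT_REGISTRY

AIR = DEFAULT_REGISTRY.standard("N")


def make_samples(rows):
    base = dict(organism="coral", species="Acropora cervicornis",
                fraction="coral_host", treatment="enriched", timepoint="T0",
                tank_id="t", delta13C=-15.0, delta15N=5.0, pctC=30.0,
                pctN=14.007, dry_mass_mg=1.0)
    recs = []
    for i, r in enumerate(rows):
        rec = dict(base)
        rec["sample_id"] = f"s{i}"
        rec.update(r)
        recs.append(rec)
    return pd.DataFrame(recs)[exp.SAMPLE_COLUMNS]


class TestDesign:
    def test_timeline(self):
        d = exp.ExperimentDesign()
        assert d.timepoint_hours == {"T0": 0.0, "PULSE": 3.0, "T3": 7.0, "T6": 10.0}
        assert d.chase_exposure_hours == {"T3": 3.0, "T6": 6.0}

    def test_exposure_consistent_with_timeline(self):
        d = exp.ExperimentDesign(pulse_h=2, rinse_h=0.5, chase_h=8)
        for tp, h in d.chase_exposure_hours.items():
            assert h == d.timepoint_hours[tp] - (d.pulse_h + d.rinse_h)


class TestValidate:
    def test_design_invariants_enforced(self):
        df = make_samples([
            {},  # valid
            {"organism": "sponge", "fraction": "symbiodiniaceae",
             "species": "Aplysina fulva"},
            {"timepoint": "PULSE"},                       # coral at PULSE
            {"organism": "sponge", "fraction": "sponge_tissue",
             "species": "Aplysina fulva", "treatment": "control"},
            {"delta15N": -1000.5},
        ])
        clean, rejects = exp.validate_samples(df)
        assert len(clean) == 1 and len(rejects) == 4
        assert rejects.reason.str.contains("sponge_tissue").any()
        assert rejects.reason.str.contains("PULSE").any()
        assert rejects.reason.str.contains("control").any()


class TestBaselines:
    def test_mean_of_two_in_atom_fraction_space(self):
        df = make_samples([{"delta15N": 4.0}, {"delta15N": 6.0}])
        b = exp.compute_baselines(df)
        row = b[(b.element == "N")].iloc[0]
        f_expected = np.mean([tracer.delta_to_atom_fraction(4.0, AIR),
                              tracer.delta_to_atom_fraction(6.0, AIR)])
        assert row.atom_fraction == pytest.approx(f_expected, abs=1e-15)
        assert row.n == 2
        # delta of the mean F, close to (but not defined as) 5 permil
        assert row.delta == pytest.approx(5.0, abs=1e-3)

    def test_single_sample_baseline_is_that_sample(self):
        df = make_samples([{"delta15N": 7.5, "pctN": 14.007, "dry_mass_mg": 2.0}])
        b = exp.compute_baselines(df)
        row = b[b.element == "N"].iloc[0]
        assert row.atom_fraction == pytest.approx(
            tracer.delta_to_atom_fraction(7.5, AIR))
        assert row.element_umol == pytest.approx(20.0, rel=1e-6)

    def test_missing_baseline_named_in_error(self):
        df = make_samples([{"timepoint": "T3"}])
        b = exp.compute_baselines(make_samples([{}]))
        df2 = df.assign(species="Orbicella faveolata")
        with pytest.raises(KeyError, match="Orbicella faveolata"):
            exp.compute_incorporation_table(df2, b)

    def test_unknown_policy(self):
        with pytest.raises(ValueError):
            exp.compute_baselines(make_samples([{}]), policy="nope")

    def test_simulator_background_recovered(self, sim_default):
        """Baselines from noisy T0 cohorts sit within noise/sqrt(n) of the
        configured true background atom fraction."""
        res = sim_default
        b = exp.compute_baselines(res.samples)
        sigma_f = {el: 0.1 / 1000 * DEFAULT_REGISTRY.standard(el).ratio
                   / (1 + DEFAULT_REGISTRY.standard(el).ratio) ** 2
                   for el in ("C", "N")}
        for sp, co in res.config.corals.items():
            for fr, fp in co.fractions.items():
                for el in ("C", "N"):
                    row = b[(b.species == sp) & (b.fraction == fr)
                            & (b.element == el)].iloc[0]
                    true_f = tracer.delta_to_atom_fraction(
                        fp.background_delta[el], DEFAULT_REGISTRY.standard(el))
                    assert abs(row.atom_fraction - true_f) < \
                        4 * sigma_f[el] / np.sqrt(row.n)

    def test_policies_agree_without_drift(self, sim_default):
        """Zero-drift controls: time-matched-control baselines match the
        T0 baselines within measurement noise."""
        res = sim_default
        b0 = exp.compute_baselines(res.samples, "t0_mean")
        bc = exp.compute_baselines(res.samples, "time_matched_control")
        sigma_f = {el: 0.1 / 1000 * DEFAULT_REGISTRY.standard(el).ratio
                   / (1 + DEFAULT_REGISTRY.standard(el).ratio) ** 2
                   for el in ("C", "N")}
        for r in bc.itertuples(index=False):
            r0 = b0[(b0.species == r.species) & (b0.fraction == r.fraction)
                    & (b0.element == r.element)].iloc[0]
            tol = 4 * sigma_f[r.element] * (1 / np.sqrt(r.n) + 1 / np.sqrt(r0.n))
            assert abs(r.atom_fraction - r0.atom_fraction) < tol


class TestIncorporation:
    def make_scored(self):
        t0 = [{"delta15N": 5.0}, {"delta15N": 5.0}]
        t3 = [{"timepoint": "T3", "tank_id": "E1", "delta15N": 1005.0,
               "pctN": 14.007, "dry_mass_mg": 1.0}]
        df = make_samples(t0 + t3)
        b = exp.compute_baselines(df)
        return exp.compute_incorporation_table(df, b)

    def test_hand_built_excess_and_rate(self):
        """1005 vs 5 permil on 10 umol N at T3: excess ~ 0.0364 umol and
        rate = excess / 0.01 mmol / 3 h."""
        inc = self.make_scored()
        row = inc[(inc.element == "N") & (inc.timepoint == "T3")].iloc[0]
        assert row.excess_umol == pytest.approx(0.03636, abs=5e-5)
        assert row.delta_change == pytest.approx(1000.0, abs=1e-9)
        assert row.rate == pytest.approx(row.excess_umol / 0.01 / 3.0)

    def test_sample_identical_to_baseline_scores_zero(self):
        df = make_samples([{}, {"timepoint": "T3", "tank_id": "E1"}])
        b = exp.compute_baselines(df)
        inc = exp.compute_incorporation_table(df, b)
        assert np.allclose(inc.excess_umol, 0.0, atol=1e-15)
        assert np.allclose(inc.rate.dropna(), 0.0, atol=1e-12)

    def test_rate_only_for_chase_timepoints(self):
        inc = self.make_scored()
        assert inc[inc.timepoint == "T0"].rate.isna().all()
        assert inc[inc.timepoint == "T3"].rate.notna().all()

    def test_definition_closure(self, sim_default):
        """rate * exposure * baseline_mmol == excess for every scored
        chase sample (definition of the rate)."""
        res = sim_default
        b = exp.compute_baselines(res.samples)
        inc = exp.compute_incorporation_table(res.samples, b)
        chase = inc.dropna(subset=["rate"])
        assert len(chase) > 0
        recon = chase.rate * chase.exposure_h * chase.baseline_element_umol / 1000.0
        assert np.allclose(recon, chase.excess_umol, rtol=1e-12, atol=1e-18)

    def test_control_delta_change_centred_on_zero(self, sim_default):
        """Zero-drift controls: group mean delta change is 0 within
        3 * 0.1 permil / sqrt(n)."""
        res = sim_default
        b = exp.compute_baselines(res.samples)
        inc = exp.compute_incorporation_table(
            res.samples, b, treatments=("control",))
        ctrl = inc[inc.timepoint.isin(["T3", "T6"])]
        for (sp, fr, el), grp in ctrl.groupby(["species", "fraction", "element"]):
            # the baseline itself is noisy too; fold both contributions in
            tol = 3 * 0.1 * (1 / np.sqrt(len(grp)) + 1 / np.sqrt(5))
            assert abs(grp.delta_change.mean()) < tol


class TestSummaries:
    def test_linear_interpolation_quartiles(self):
        df = pd.DataFrame({"species": "s", "fraction": "f", "timepoint": "T6",
                           "element": "N", "excess_umol": [1, 2, 3, 4, 5.0]})
        out = exp.summarize_groups(df)
        row = out.iloc[0]
        assert (row["q1"], row["median"], row["q3"]) == (2.0, 3.0, 4.0)
        assert row.n_outliers == 0

    def test_single_value_group(self):
        df = pd.DataFrame({"species": "s", "fraction": "f", "timepoint": "T6",
                           "element": "N", "excess_umol": [7.0]})
        row = exp.summarize_groups(df).iloc[0]
        assert row["q1"] == row["median"] == row["q3"] == row["mean"] == 7.0
        assert row.whisker_low == row.whisker_high == 7.0
        assert row.n_outliers == 0

    def test_outlier_beyond_fence(self):
        """{1,2,3,100}: IQR fence leaves 100 as the lone outlier."""
        df = pd.DataFrame({"species": "s", "fraction": "f", "timepoint": "T6",
                           "element": "N", "excess_umol": [1, 2, 3, 100.0]})
        row = exp.summarize_groups(df).iloc[0]
        assert row.n_outliers == 1
        assert row.outliers == "100.0"
        assert row.whisker_high == 3.0


def fold_input(c_excess, n_excess, species="Acropora cervicornis"):
    rows = []
    for fr in ("coral_host", "symbiodiniaceae"):
        rows += [
            {"species": species, "fraction": fr, "timepoint": "T6",
             "treatment": "enriched", "element": "C", "excess_umol": c_excess / 2},
            {"species": species, "fraction": fr, "timepoint": "T6",
             "treatment": "enriched", "element": "N", "excess_umol": n_excess / 2},
        ]
    return pd.DataFrame(rows)


class TestFoldRatioAndTotals:
    def test_equal_excess_gives_one(self):
        out = exp.fold_ratio_n_vs_c(fold_input(0.01, 0.01))
        assert out.fold_ratio.iloc[0] == pytest.approx(1.0)

    def test_ten_fold(self):
        out = exp.fold_ratio_n_vs_c(fold_input(0.002, 0.02))
        assert out.fold_ratio.iloc[0] == pytest.approx(10.0)

    def test_rescaling_invariance(self):
        a = exp.fold_ratio_n_vs_c(fold_input(0.004, 0.05)).fold_ratio.iloc[0]
        b = exp.fold_ratio_n_vs_c(fold_input(0.004 * 37, 0.05 * 37)).fold_ratio.iloc[0]
        assert a == pytest.approx(b)

    def test_nonpositive_denominator_flagged(self):
        out = exp.fold_ratio_n_vs_c(fold_input(-0.002, 0.02))
        assert not out.defined.iloc[0]
        assert len(out) == 1    # flagged, not dropped

    def test_holobiont_totals_sum_of_fraction_means(self):
        df = pd.DataFrame([
            {"species": "s", "fraction": "coral_host", "timepoint": "T6",
             "treatment": "enriched", "element": "N", "excess_umol": 0.0004},
            {"species": "s", "fraction": "symbiodiniaceae", "timepoint": "T6",
             "treatment": "enriched", "element": "N", "excess_umol": 0.02},
        ])
        row = exp.assemble_holobiont_totals(df).iloc[0]
        assert row.holobiont_total_umol == pytest.approx(0.0204)
        assert row.complete

    def test_missing_fraction_flagged_incomplete(self):
        df = pd.DataFrame([
            {"species": "s", "fraction": "coral_host", "timepoint": "T6",
             "treatment": "enriched", "element": "N", "excess_umol": 0.0004},
        ])
        row = exp.assemble_holobiont_totals(df).iloc[0]
        assert not row.complete
        assert np.isnan(row.holobiont_total_umol)

    def test_zero_tables_zero_totals(self):
        df = fold_input(0.0, 0.0)
        df["excess_umol"] = 0.0
        out = exp.assemble_holobiont_totals(df)
        assert (out.holobiont_total_umol == 0).all()
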