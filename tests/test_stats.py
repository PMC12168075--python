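"""Cleavage-yield statistics, the guanosine preference and its null model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rnacleave as rc
from rnacleave.simulate import CleavagePropensityModel
from rnacleave.stats import (
    charge_density,
    deprotonated_fraction,
    dissociation_yield,
    effective_preference_factor,
    fold_change_correlation,
    g_sites,
    charge_value_distribution,
    mean_charge_difference,
    render_cleavage_map,
    site_specific_yields,
)


def uniform_aggregate(seq):
    """Synthetic aggregated table with equal abundance at every c/y index."""
    rows = []
    for k in range(1, len(seq)):
        rows.append({"ion_type": "c", "index": k, "base_loss": None,
                     "abundance": 1.0, "by_charge": {1: 1.0}})
        rows.append({"ion_type": "y", "index": k, "base_loss": None,
                     "abundance": 1.0, "by_charge": {1: 1.0}})
    return pd.DataFrame(rows)


class TestGSites:
    def test_18mer_topology(self, rna1):
        assert g_sites(rna1) == [4, 8, 9, 12, 15, 16]

    def test_modified_guanosine_counts_by_default(self):
        assert g_sites(rc.reference_rna(2)) == g_sites(rc.reference_rna(1))

    def test_inosine_excluded_by_default(self):
        seq5 = rc.reference_rna(5)  # I at 5, 9, 13
        assert g_sites(seq5) == [9, 15, 16]
        assert g_sites(seq5, include_inosine=True) == [4, 8, 9, 12, 15, 16]


class TestSiteYields:
    def test_uniform_null_equal_yields(self, rna1):
        table = site_specific_yields(uniform_aggregate(rna1), rna1, 7)
        combined = table.data["yield_c"] + table.data["yield_y"]
        assert np.allclose(combined, 100.0 / 17)
        assert combined.sum() == pytest.approx(100.0)

    def test_single_fragment_pair(self, rna1):
        agg = pd.DataFrame(
            [
                {"ion_type": "c", "index": 4, "base_loss": None,
                 "abundance": 3.0, "by_charge": {2: 3.0}},
                {"ion_type": "y", "index": 14, "base_loss": None,
                 "abundance": 1.0, "by_charge": {5: 1.0}},
            ]
        )
        table = site_specific_yields(agg, rna1, 7)
        assert table.data.loc[3, "yield_c"] + table.data.loc[3, "yield_y"] == (
            pytest.approx(100.0)
        )
        assert table.data.drop(index=3)[["yield_c", "yield_y"]].sum().sum() == 0

    def test_base_loss_pooled_into_parent(self, rna1):
        agg = pd.DataFrame(
            [
                {"ion_type": "c", "index": 4, "base_loss": None,
                 "abundance": 2.0, "by_charge": {2: 2.0}},
                {"ion_type": "c", "index": 4, "base_loss": "A",
                 "abundance": 1.0, "by_charge": {2: 1.0}},
                {"ion_type": "y", "index": 14, "base_loss": None,
                 "abundance": 1.0, "by_charge": {5: 1.0}},
            ]
        )
        table = site_specific_yields(agg, rna1, 7)
        assert table.data.loc[3, "yield_c"] == pytest.approx(75.0)

    def test_other_ion_types_excluded_from_normalization(self, rna1):
        agg = uniform_aggregate(rna1)
        extra = pd.DataFrame(
            [{"ion_type": "w", "index": 5, "base_loss": None,
              "abundance": 100.0, "by_charge": {1: 100.0}}]
        )
        table = site_specific_yields(pd.concat([agg, extra]), rna1, 7)
        assert (table.data["yield_c"] + table.data["yield_y"]).sum() == (
            pytest.approx(100.0)
        )

    def test_no_cy_signal_rejected(self, rna1):
        with pytest.raises(ValueError, match="no c/y"):
            site_specific_yields(pd.DataFrame(
                columns=["ion_type", "index", "base_loss", "abundance", "by_charge"]
            ), rna1, 7)

    def test_simulated_boosted_sites_follow_ground_truth(self, noiseless_run, rna1):
        _, truth, _, assignments = noiseless_run
        table = site_specific_yields(
            rc.aggregate_charge_states(assignments), rna1, 7
        )
        shares = truth.model.expected_site_shares(rna1, 7)
        combined = (table.data["yield_c"] + table.data["yield_y"]).to_numpy()
        assert np.allclose(combined, 100 * shares, atol=1.0)


class TestNullModel:
    def test_random_expectations_match_topologies(self, rna1, rna10):
        t1 = site_specific_yields(uniform_aggregate(rna1), rna1, 7)
        t10 = site_specific_yields(uniform_aggregate(rna10), rna10, 4)
        assert round(t1.random_expectation) == 35  # 6 of 17 sites
        assert round(t10.random_expectation) == 29  # 2 of 7 sites

    def test_no_guanosine_zero_expectation(self):
        seq = rc.parse_sequence("ACUCAUC")
        table = site_specific_yields(uniform_aggregate(seq), seq, 3)
        assert table.random_expectation == 0.0
        assert table.overall_g_yield == 0.0

    def test_expectation_independent_of_abundances(self, rna1):
        rng = np.random.default_rng(0)
        agg = uniform_aggregate(rna1)
        agg["abundance"] = rng.uniform(0.1, 10.0, len(agg))
        table = site_specific_yields(agg, rna1, 7)
        assert table.random_expectation == pytest.approx(100 * 6 / 17)


class TestChargeBookkeeping:
    @pytest.mark.parametrize("n,big_n,expected", [(7, 18, 0.39), (11, 27, 0.41), (0, 18, 0.0)])
    def test_charges_per_nt(self, n, big_n, expected):
        assert charge_density(n, big_n) == expected

    def test_deprotonated_phosphodiester_fraction(self):
        assert deprotonated_fraction(13, 27) == pytest.approx(50.0)
        assert deprotonated_fraction(5, 27) == pytest.approx(19.2, abs=0.1)


class TestPreferenceFactor:
    def test_null_yield_recovers_unity(self, rna1):
        y_null = 100 * 6 / 17
        assert effective_preference_factor(y_null, rna1) == pytest.approx(1.0)

    def test_sixty_percent_gives_2p75(self, rna1):
        assert effective_preference_factor(60.0, rna1) == pytest.approx(2.75)

    @given(st.floats(0.05, 50.0))
    def test_round_trip_through_analytic_yield(self, gamma):
        seq = rc.reference_rna(1)
        n_g, s = 6, 17
        y = 100 * n_g * gamma / (n_g * gamma + (s - n_g))
        assert effective_preference_factor(y, seq) == pytest.approx(gamma, rel=1e-9)

    @pytest.mark.parametrize("y", [0.0, 100.0, -5.0])
    def test_degenerate_yields_rejected(self, y, rna1):
        with pytest.raises(ValueError):
            effective_preference_factor(y, rna1)


class TestFoldChange:
    def test_identical_runs_on_diagonal(self, noiseless_run):
        _, _, _, assignments = noiseless_run
        pairs, fold = fold_change_correlation(assignments, assignments, 4, big_n=18)
        assert fold == pytest.approx(1.0)
        assert np.allclose(pairs["signal_ref"], pairs["signal_mod"])

    def test_absent_site_rejected(self, noiseless_run):
        _, _, _, assignments = noiseless_run
        sub = [a for a in assignments if a.ion.index not in (4, 14)]
        with pytest.raises(ValueError, match="absent"):
            fold_change_correlation(sub, sub, 4, big_n=18)


class TestChargeValues:
    def test_single_fragment_histogram(self, noiseless_run):
        _, _, _, assignments = noiseless_run
        one = [a for a in assignments if a.ion.ion_type == "c" and a.ion.index == 8][:1]
        dist = charge_value_distribution(one)
        assert len(dist) == 1
        assert dist.iloc[0]["charge"] == one[0].ion.charge

    def test_propensity_change_leaves_mean_charges(self, rna1, no_noise):
        """Suppressing one site must not shift the charge values of the
        fragments (same partition law)."""
        from rnacleave.simulate import simulate_cad_spectrum

        candidates = rc.enumerate_fragments(rna1, "cy", max_charge=7)
        dists = []
        for overrides, seed in (({}, 21), ({4: 0.1}, 22)):
            model = CleavagePropensityModel(
                base_loss_fraction=0, ay_channel_fraction=0,
                site_overrides=overrides,
            )
            peaks, _ = simulate_cad_spectrum(
                rna1, 7, model, n_ions=100_000, noise=no_noise, seed=seed
            )
            asn = rc.match_fragments(peaks, candidates)
            dists.append(charge_value_distribution(asn))
        assert mean_charge_difference(dists[0], dists[1]) < 0.1

    def test_empty_runs_rejected_in_comparison(self):
        empty = charge_value_distribution([])
        with pytest.raises(ValueError, match="no shared"):
            mean_charge_difference(empty, empty)


class TestDissociationYield:
    def test_no_precursor_is_full_dissociation(self, noiseless_run):
        _, _, _, assignments = noiseless_run
        assert dissociation_yield(assignments, big_n=18) == pytest.approx(100.0)

    def test_no_fragments_is_zero(self, rna1, no_noise):
        from rnacleave.simulate import simulate_cad_spectrum

        model = CleavagePropensityModel(precursor_survival=1.0, base_loss_fraction=0)
        peaks, _ = simulate_cad_spectrum(
            rna1, 7, model, n_ions=1000, noise=no_noise, seed=1
        )
        asn = rc.match_fragments(peaks, [rc.precursor_ion(rna1, 7)])
        assert dissociation_yield(asn) == pytest.approx(0.0)

    def test_survival_fraction_recovered(self, rna1, no_noise):
        from rnacleave.simulate import simulate_cad_spectrum

        model = CleavagePropensityModel(
            precursor_survival=0.35, base_loss_fraction=0, ay_channel_fraction=0
        )
        peaks, _ = simulate_cad_spectrum(
            rna1, 7, model, n_ions=100_000, noise=no_noise, seed=33
        )
        candidates = rc.enumerate_fragments(rna1, "cy", max_charge=7)
        candidates.append(rc.precursor_ion(rna1, 7))
        asn = rc.match_fragments(peaks, candidates)
        assert dissociation_yield(asn) == pytest.approx(65.0, abs=2.0)

    def test_nothing_assigned_rejected(self):
        with pytest.raises(ValueError, match="no species"):
            dissociation_yield([])


class TestCleavageMap:
    def test_renders_sequence_and_marks(self, noiseless_run, rna1):
        _, _, _, assignments = noiseless_run
        table = site_specific_yields(
            rc.aggregate_charge_states(assignments), rna1, 7
        )
        text = render_cleavage_map(table)
        assert str(rna1) in text
        assert "site  4" in text and "overall 5'-of-G yield" in text
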