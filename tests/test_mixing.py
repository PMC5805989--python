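"""Mixing ratio matrices, bootstrap CIs and NGM growth ranking."""

import numpy as np
import pandas as pd
import pytest

from contactdiaries.io_model import CONTACT_AGE_GROUPS, PARTICIPANT_AGE_GROUPS
from contactdiaries.mixing import (
    bootstrap_ci,
    contact_rate_matrix,
    dominant_eigenvalue,
    mixing_ratio_matrix,
    ngm_growth_rank,
)
from contactdiaries.synthetic import census_series

from conftest import diary, event, make_panel, participant

CENSUS = pd.Series(
    {"0-5": 0.055, "6-19": 0.145, "20-39": 0.305, "40-64": 0.365, "65+": 0.130}
)

AGE_OF_GROUP = {"5-19": 12.0, "20-39": 30.0, "40-64": 50.0, "65+": 70.0}


def proportionate_panel(n_per_group=10, contacts_per_participant=200, seed=None):
    """Panel whose contacts follow the census proportions.

    With the default 200 contacts each participant's split is *exactly*
    proportionate (200 × census is integral); with ``seed`` set, each
    participant's split is drawn multinomially instead (proportionate in
    expectation, heterogeneous across participants).
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    exact = (CENSUS * contacts_per_participant).round().astype(int)
    parts, diaries, events = [], [], []
    i = 0
    for group, age in AGE_OF_GROUP.items():
        for _ in range(n_per_group):
            pid = f"p{i}"
            parts.append(participant(pid, age=age))
            diaries.append(diary(pid))
            counts = (
                exact
                if rng is None
                else pd.Series(
                    rng.multinomial(contacts_per_participant, CENSUS.to_numpy()),
                    index=CENSUS.index,
                )
            )
            for j, (cg, c) in enumerate(counts.items()):
                if c > 0:
                    events.append(event(pid, eid=f"{pid}-e{j}", group_size=int(c),
                                        contact_age=cg, location="locA"))
            i += 1
    return make_panel(parts, diaries, events)


class TestRatioMatrix:
    def test_proportionate_contacts_give_unit_ratios(self):
        m = mixing_ratio_matrix(proportionate_panel(), CENSUS, "R1")
        assert np.allclose(m.ratio.to_numpy(), 1.0, atol=1e-12)

    def test_two_group_hand_example(self):
        # group-A participants report 3 within-group and 1 cross-group
        # contacts under a 50/50 census → cells (3/4)/0.5 = 1.5 and 0.5
        eps = 1e-9
        census = pd.Series(
            {"0-5": eps, "6-19": eps, "20-39": 0.5, "40-64": 0.5, "65+": eps}
        )
        panel = make_panel(
            [participant("p1", age=30.0)],
            [diary("p1")],
            [
                event("p1", eid="e1", group_size=3, contact_age="20-39"),
                event("p1", eid="e2", group_size=1, contact_age="40-64"),
            ],
        )
        m = mixing_ratio_matrix(panel, census, "R1")
        assert m.ratio.loc["20-39", "20-39"] == pytest.approx(1.5, rel=1e-6)
        assert m.ratio.loc["20-39", "40-64"] == pytest.approx(0.5, rel=1e-6)

    def test_rowwise_share_reconstruction(self, small_panel, small_config):
        census = census_series(small_config)
        m = mixing_ratio_matrix(small_panel, census, "R2")
        recon = (m.ratio * census).sum(axis=1)
        observed_groups = recon.dropna().index
        assert len(observed_groups) > 0
        assert np.allclose(recon.dropna().to_numpy(), 1.0)

    def test_invariant_to_uniform_scaling_of_contact_counts(self):
        panel = proportionate_panel(n_per_group=3, contacts_per_participant=40, seed=11)
        scaled_events = panel.events.copy()
        scaled_events["group_size"] *= 7
        scaled = make_panel(
            panel.participants.to_dict("records"),
            panel.diaries.to_dict("records"),
            scaled_events.to_dict("records"),
        )
        a = mixing_ratio_matrix(panel, CENSUS, "R1").ratio
        b = mixing_ratio_matrix(scaled, CENSUS, "R1").ratio
        pd.testing.assert_frame_equal(a, b)

    def test_young_children_participants_are_excluded(self):
        panel = make_panel(
            [participant("p1", age=3.0), participant("p2", age=30.0)],
            [diary("p1"), diary("p2")],
            [event("p1", eid="e1"), event("p2", eid="e2")],
        )
        m = mixing_ratio_matrix(panel, CENSUS, "R1")
        assert set(m.ratio.index) == set(PARTICIPANT_AGE_GROUPS)
        # 3-year-old's contacts appear nowhere
        assert np.nansum(m.ratio.to_numpy() > 0) > 0
        assert m.ratio.loc["20-39"].notna().any()

    def test_assortative_generator_shows_own_group_excess(self, small_panel, small_config):
        census = census_series(small_config)
        m = mixing_ratio_matrix(small_panel, census, "R1")
        own = {"5-19": "6-19", "20-39": "20-39", "40-64": "40-64", "65+": "65+"}
        for pg, cg in own.items():
            assert m.ratio.loc[pg, cg] > 1.0


class TestBootstrap:
    def test_point_estimate_unchanged_and_deterministic(self, small_panel, small_config):
        census = census_series(small_config)
        plug_in = mixing_ratio_matrix(small_panel, census, "R1").ratio
        a = bootstrap_ci(small_panel, census, "R1", n_boot=50, seed=5)
        b = bootstrap_ci(small_panel, census, "R1", n_boot=50, seed=5)
        pd.testing.assert_frame_equal(a.ratio, plug_in)
        pd.testing.assert_frame_equal(a.ci_low, b.ci_low)
        pd.testing.assert_frame_equal(a.ci_high, b.ci_high)
        valid = a.ratio.notna()
        assert (a.ci_low[valid] <= a.ratio[valid]).all().all()
        assert (a.ci_high[valid] >= a.ratio[valid]).all().all()

    def test_single_participant_gives_degenerate_ci(self):
        panel = make_panel(
            [participant("p1", age=30.0)],
            [diary("p1")],
            [event("p1", eid="e1", group_size=4, contact_age="20-39")],
        )
        m = bootstrap_ci(panel, CENSUS, "R1", n_boot=20, seed=0)
        assert m.ci_low.loc["20-39", "20-39"] == pytest.approx(
            m.ratio.loc["20-39", "20-39"]
        )
        assert m.ci_high.loc["20-39", "20-39"] == pytest.approx(
            m.ratio.loc["20-39", "20-39"]
        )

    def test_n_boot_below_two_is_an_error(self, small_panel, small_config):
        with pytest.raises(ValueError):
            bootstrap_ci(small_panel, census_series(small_config), "R1", n_boot=1)

    def test_ci_width_shrinks_with_sample_size(self):
        wide = bootstrap_ci(
            proportionate_panel(n_per_group=5, contacts_per_participant=20, seed=1),
            CENSUS, "R1", n_boot=200, seed=2,
        )
        narrow = bootstrap_ci(
            proportionate_panel(n_per_group=60, contacts_per_participant=20, seed=1),
            CENSUS, "R1", n_boot=200, seed=2,
        )
        w_wide = (wide.ci_high - wide.ci_low).to_numpy()
        w_narrow = (narrow.ci_high - narrow.ci_low).to_numpy()
        assert np.nanmean(w_narrow) < np.nanmean(w_wide)


class TestGrowthRates:
    def test_single_group_eigenvalue_is_the_contact_rate(self):
        assert dominant_eigenvalue([[3.7]]) == pytest.approx(3.7)

    def test_symmetric_two_by_two_closed_form(self):
        assert dominant_eigenvalue([[2.0, 1.0], [1.0, 2.0]]) == pytest.approx(3.0)

    def test_matches_characteristic_polynomial_roots(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            m = rng.uniform(0, 5, size=(4, 4))
            roots = np.roots(np.poly(m))
            assert dominant_eigenvalue(m) == pytest.approx(
                float(np.max(np.abs(roots))), rel=1e-9
            )

    def test_perron_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            m = rng.uniform(0, 10, size=(5, 5))
            lam = dominant_eigenvalue(m)
            assert m.sum(axis=1).min() - 1e-9 <= lam <= m.sum(axis=1).max() + 1e-9

    @pytest.mark.parametrize("bad", [[[1, 2, 3]], [[1, -2], [3, 4]]])
    def test_invalid_matrices_are_errors(self, bad):
        with pytest.raises(ValueError):
            dominant_eigenvalue(bad)

    def test_wave_ranking_orders_by_scaled_growth(self):
        base = pd.DataFrame(np.full((4, 4), 1.0))
        matrices = {"R1": base, "R2": base * 3, "R3": base * 2}
        rank = ngm_growth_rank(matrices)
        assert list(rank["wave"]) == ["R2", "R3", "R1"]
        assert rank.loc[0, "growth_factor"] == pytest.approx(12.0)

    def test_contact_rate_matrix_is_square_and_nonnegative(self, small_panel):
        m = contact_rate_matrix(small_panel, "R1")
        assert m.shape == (4, 4)
        assert (m.to_numpy() >= 0).all()
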