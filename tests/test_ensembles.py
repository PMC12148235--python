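import math

import numpy as np
import pandas as pd
import pytest

from papillasim import Trajectory, count_turns
from papillasim.ensembles import (PhaseDiagram, TURN_THRESHOLDS,
                                  compare_distributions,
                                  cumulative_distribution, default_grid,
                                  experimental_distribution,
                                  landing_weights, mean_turn_number,
                                  phase_diagram)


def helix_trajectory(R0=4.0, phi_deg=63.0, h=37.0, ds=0.05):
    """Analytic constant-angle helix on a cylinder (oracle input)."""
    phi = math.radians(phi_deg)
    s = np.arange(0.0, h / math.cos(phi) + ds, ds)
    theta = s * math.sin(phi) / R0
    z = s * math.cos(phi)
    pts = np.stack([R0 * np.cos(theta), R0 * np.sin(theta), z], axis=1)
    tans = np.stack([-math.sin(phi) * np.sin(theta),
                     math.sin(phi) * np.cos(theta),
                     math.cos(phi) * np.ones_like(theta)], axis=1)
    return Trajectory(s=s, points=pts, tangents=tans,
                      phi=np.full_like(s, phi_deg),
                      outcome="reached_base")


class TestCountTurns:
    def test_meridian_is_zero(self):
        s = np.arange(0.0, 50.0, 0.1)
        pts = np.stack([np.full_like(s, 5.0), np.zeros_like(s), s], axis=1)
        tr = Trajectory(s=s, points=pts,
                        tangents=np.tile([0.0, 0.0, 1.0], (len(s), 1)),
                        phi=np.zeros_like(s), outcome="reached_base")
        assert count_turns(tr, 40.0) == pytest.approx(0.0, abs=1e-12)

    def test_helix_closed_form(self):
        """Turns of a constant-angle helix: T = h tan(phi) / (2 pi R0)."""
        R0, phi_deg, h = 4.0, 63.0, 37.0
        tr = helix_trajectory(R0, phi_deg, h)
        expected = h * math.tan(math.radians(phi_deg)) / (2 * math.pi * R0)
        assert count_turns(tr, h) == pytest.approx(expected, rel=1e-6)

    def test_caged_is_sentinel(self):
        tr = helix_trajectory()
        tr.outcome = "caged"
        tr.turn_number = math.inf
        assert count_turns(tr, 37.0) == math.inf

    def test_unstarted_trajectory_rejected(self):
        tr = Trajectory(s=np.array([0.0]), points=np.zeros((1, 3)),
                        tangents=np.zeros((1, 3)), phi=np.array([0.0]))
        with pytest.raises(ValueError):
            count_turns(tr, 40.0)


class TestWeights:
    @pytest.mark.parametrize("mode", ["area", "projected"])
    def test_weights_normalised(self, ktn_shape, mode):
        z0, _ = default_grid(ktn_shape)
        w = landing_weights(ktn_shape, z0, mode)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w >= 0)

    def test_projected_mode_covers_head_only(self, ktn_shape):
        z0, _ = default_grid(ktn_shape)
        w = landing_weights(ktn_shape, z0, "projected")
        assert np.all(w[z0 > ktn_shape.Lhead + 2.5] == 0.0)

    def test_area_weights_obey_hat_box_theorem(self, wt_shape):
        """The WT head is a hemisphere, so equal-height z-bands within it
        have equal surface area (Archimedes): the analytic band integrals
        must reproduce that."""
        z0 = np.array([1.375, 4.125, 6.875])   # edges 0/2.75/5.5/8.25
        w = landing_weights(wt_shape, z0, "area")
        assert w[0] == pytest.approx(w[1], rel=1e-8)

    def test_unknown_mode_rejected(self, ktn_shape):
        with pytest.raises(ValueError):
            landing_weights(ktn_shape, np.array([5.0]), "uniform")


class TestCumulativeDistribution:
    def test_single_cell_is_step_function(self, ktn_shape):
        pd_ = PhaseDiagram(z0=np.array([10.0]), phi0=np.array([30.0]),
                           turns=np.array([[1.2]]),
                           outcomes=np.array([["reached_base"]]),
                           shape=ktn_shape)
        dist = cumulative_distribution(pd_)
        assert list(dist.F) == [0, 0, 0, 1, 1, 1]   # steps at T=1.5 bin

    def test_monotone_and_closed(self, ktn_pd0):
        dist = cumulative_distribution(ktn_pd0)
        assert np.all(np.diff(dist.F) >= -1e-15)
        assert np.all((0 <= dist.F) & (dist.F <= 1))
        assert dist.to_frame()["F"].iloc[-1] == 1.0

    def test_caged_only_in_top_bin(self, ktn_shape):
        pd_ = PhaseDiagram(z0=np.array([10.0]), phi0=np.array([30.0, 60.0]),
                           turns=np.array([[0.3, np.inf]]),
                           outcomes=np.array([["reached_base", "caged"]]),
                           shape=ktn_shape)
        dist = cumulative_distribution(pd_)
        assert dist.F[-1] == pytest.approx(0.5)

    def test_guidance_separation(self, wt_pd_by_mu):
        """Longitudinal guidance shifts mass to low turn numbers."""
        F1 = {mu: cumulative_distribution(p).F[2]
              for mu, p in wt_pd_by_mu.items()}
        assert F1[0.1] > F1[0.0]

    def test_mean_turn_monotone_in_mu(self, wt_pd_by_mu):
        mus = sorted(wt_pd_by_mu)
        means = [mean_turn_number(wt_pd_by_mu[mu]) for mu in mus]
        assert all(b <= a + 1e-9 for a, b in zip(means, means[1:]))

    def test_weighting_choice_does_not_change_conclusions(self, wt_pd_by_mu):
        """The attachment-probability model (uniform per area vs projected
        head area) shifts F moderately but preserves the guidance effect:
        both modes order the mu=0 and mu=0.1 distributions the same way."""
        for mode in ("area", "projected"):
            F0 = cumulative_distribution(wt_pd_by_mu[0.0], mode).F
            F1 = cumulative_distribution(wt_pd_by_mu[0.1], mode).F
            assert F1[2] > F0[2]
            assert np.all(np.diff(F1) >= -1e-15)
        Fa = cumulative_distribution(wt_pd_by_mu[0.1], "area").F
        Fp = cumulative_distribution(wt_pd_by_mu[0.1], "projected").F
        assert np.abs(Fa - Fp).max() <= 0.25


class TestPhaseDiagramStructure:
    def test_default_grid(self, ktn_shape):
        z0, phi0 = default_grid(ktn_shape)
        assert z0[0] == 0.5 and np.all(np.diff(z0[1:]) == 5.0)
        assert z0[-1] <= 2 * ktn_shape.Lhead
        assert phi0[0] == 0.0 and phi0[-1] == 180.0 and len(phi0) == 37

    def test_pole_rows_have_low_turns(self, ktn_pd0, ktn_shape):
        """Trajectories from near the pole reach the base with T <= 0.5
        whatever their initial direction."""
        rows = ktn_pd0.z0 / ktn_shape.Lhead <= 0.25
        assert np.all(ktn_pd0.turns[rows] <= 0.6)

    def test_circumferential_band_turns_elevated(self, ktn_pd0, ktn_shape):
        rows = ktn_pd0.z0 / ktn_shape.Lhead >= 0.25
        band = (ktn_pd0.phi0 > 50) & (ktn_pd0.phi0 < 130)
        sub = ktn_pd0.turns[np.ix_(rows, band)]
        assert np.median(np.minimum(sub, 2.75)) > 1.0

    def test_wt_and_ktn_diagrams_agree_cellwise(self, wt_shape, ktn_shape):
        """The two genotype shapes yield nearly the same diagram on a
        matched normalized grid (category agreement >= 80%)."""
        edges = np.array(TURN_THRESHOLDS)
        cats = {}
        for shape in (wt_shape, ktn_shape):
            z0 = np.array([0.05, 0.4, 0.8, 1.2, 1.6]) * shape.Lhead
            p = phase_diagram(shape, mu=0.0, z0_grid=z0, dphi0=15.0)
            cats[shape.descriptors.genotype] = np.digitize(
                np.nan_to_num(p.turns, posinf=99.0), edges)
        exact = (cats["WT"] == cats["ktn1-5"]).mean()
        within_one = (np.abs(cats["WT"] - cats["ktn1-5"]) <= 1).mean()
        assert exact >= 0.7
        assert within_one >= 0.9

    def test_csv_roundtrip(self, tmp_path, ktn_pd0):
        path = tmp_path / "pd.csv"
        ktn_pd0.to_csv(path)
        back = PhaseDiagram.from_csv(path)
        assert np.allclose(back.z0, ktn_pd0.z0)
        finite = np.isfinite(ktn_pd0.turns)
        assert np.allclose(back.turns[finite], ktn_pd0.turns[finite])
        assert np.all(~np.isfinite(back.turns[~finite]))


class TestExperimentalComparison:
    def make_counts(self, fracs, n):
        counts = np.round(np.array(fracs) * n).astype(int)
        labels = [f"{t:g}" for t in TURN_THRESHOLDS] + [">2.5"]
        return pd.DataFrame({"T_bin": labels, "count": counts})

    def test_identical_distributions_have_zero_delta(self, ktn_pd0):
        dist = cumulative_distribution(ktn_pd0)
        F = np.concatenate([dist.F, [1.0]])
        dens = np.diff(np.concatenate([[0.0], F]))
        counts = self.make_counts(dens, 100000)
        merged = compare_distributions(dist, counts)
        assert np.abs(merged["delta"]).max() < 1e-4

    def test_binomial_sem(self):
        counts = self.make_counts([0.2, 0.2, 0.1, 0.1, 0.1, 0.1, 0.2], 251)
        exp = experimental_distribution(counts)
        n = counts["count"].sum()
        for _, row in exp.iterrows():
            p = row["F_exp"]
            assert row["SEM_exp"] == pytest.approx(
                math.sqrt(p * (1 - p) / n))

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            experimental_distribution(
                pd.DataFrame({"T_bin": [], "count": []}))
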