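import numpy as np
import pandas as pd
import pytest

from comedclust.errors import DataError
from comedclust.exposure import ExposureProfile, N_WINDOWS, window_trajectory
from comedclust.hca import ClusterAssignment
from comedclust.summarize import (
    derive_indications_from_atc,
    paracetamol_only_count,
    summarize_clusters,
    write_covariate_table,
    write_summary,
    write_trajectories,
)

P = "N02BE01"


def make_profile(pid, window_sets):
    return ExposureProfile(pid, tuple(frozenset(s) for s in window_sets))


@pytest.fixture()
def assigned_cohort(fixture_cohort):
    profiles, covariates, planted = fixture_cohort
    return profiles, planted, covariates


class TestSummarize:
    def test_single_profile_single_cluster(self):
        p = make_profile("P1", [{P}] * 3 + [set()] * 7)
        a = ClusterAssignment(("P1",), np.array([1]), 1)
        s = summarize_clusters([p], a)
        (c,) = s.clusters
        assert (c.n, c.percent) == (1, 100.0)
        np.testing.assert_allclose(c.trajectory, p.window_counts())
        assert c.mean_exposure == pytest.approx(0.3)

    def test_two_equal_clusters_percentages(self):
        profiles = [make_profile(f"P{i}", [{P}] * N_WINDOWS) for i in range(4)]
        a = ClusterAssignment(tuple(p.pregnancy_id for p in profiles),
                              np.array([1, 1, 2, 2]), 2)
        s = summarize_clusters(profiles, a)
        assert [c.percent for c in s.clusters] == [50.0, 50.0]

    def test_counts_and_weighted_means_are_consistent(self, assigned_cohort):
        profiles, planted, _ = assigned_cohort
        s = summarize_clusters(profiles, planted)
        assert sum(c.n for c in s.clusters) == s.cohort_n == len(profiles)
        assert sum(c.percent for c in s.clusters) == pytest.approx(100.0)
        weighted = sum(c.n * c.mean_exposure for c in s.clusters) / s.cohort_n
        assert weighted == pytest.approx(s.cohort_mean_exposure)

    def test_union_trajectory_is_weighted_mean(self, assigned_cohort):
        profiles, planted, _ = assigned_cohort
        s = summarize_clusters(profiles, planted)
        c1, c2 = s.clusters[0], s.clusters[1]
        ids = planted.members(1) + planted.members(2)
        union = window_trajectory(profiles, ids)
        np.testing.assert_allclose(
            union, (c1.n * c1.trajectory + c2.n * c2.trajectory) / (c1.n + c2.n)
        )

    def test_tripled_rate_cluster_has_max_mean_exposure(self):
        # a planted cluster with tripled per-window Bernoulli rates should
        # top the mean-exposure ranking
        from comedclust.simulate import ClusterSpec, CohortConfig, generate_cohort

        rates = {"M01AE01": 0.2, "J01CA04": 0.2}
        config = CohortConfig(
            300,
            21,
            (
                ClusterSpec("usual", 0.5, rates),
                ClusterSpec("tripled", 0.5, {c: 3 * r for c, r in rates.items()}),
            ),
        ).validate()
        profiles, _, planted = generate_cohort(config)
        s = summarize_clusters(profiles, planted)
        by_name = dict(zip(planted.names, s.clusters))
        assert by_name["tripled"].mean_exposure == max(
            c.mean_exposure for c in s.clusters
        )

    def test_dominant_class_flags_enriched_clusters(self, assigned_cohort):
        profiles, planted, _ = assigned_cohort
        s = summarize_clusters(profiles, planted)
        by_name = dict(zip(planted.names, s.clusters))
        assert by_name["high intensity use, more asthma"].dominant_class == "R03"
        assert (
            by_name["moderate intensity use, more mental illness"].dominant_class
            == "N06"
        )

    def test_assignment_must_cover_profiles(self):
        p = make_profile("P1", [{P}] * N_WINDOWS)
        a = ClusterAssignment(("P1", "P2"), np.array([1, 2]), 2)
        with pytest.raises(DataError, match="missing from profiles"):
            summarize_clusters([p], a)


class TestParacetamolOnly:
    def test_counting_rules(self):
        profiles = [
            make_profile("A", [{P}] * 3 + [set()] * 7),        # paracetamol only
            make_profile("B", [{P, "M01AE01"}] + [set()] * 9),  # has a co-medication
            make_profile("C", [{P}] * N_WINDOWS),               # paracetamol only
        ]
        a = ClusterAssignment(("A", "B", "C"), np.array([1, 1, 2]), 2)
        assert paracetamol_only_count(profiles, a, 1) == 1
        assert paracetamol_only_count(profiles, a, 2) == 1
        with pytest.raises(DataError, match="unknown cluster"):
            paracetamol_only_count(profiles, a, 3)

    def test_invariant_to_window_placement(self):
        # any placement of paracetamol across windows counts the same
        for windows in ([0], [4, 9], list(range(10))):
            sets = [set() for _ in range(N_WINDOWS)]
            for w in windows:
                sets[w] = {P}
            profiles = [make_profile("A", sets)]
            a = ClusterAssignment(("A",), np.array([1]), 1)
            assert paracetamol_only_count(profiles, a, 1) == 1


class TestCovariates:
    def test_crosstab_counts_and_missing(self):
        profiles = [make_profile(f"P{i}", [{P}] * N_WINDOWS) for i in range(6)]
        a = ClusterAssignment(
            tuple(p.pregnancy_id for p in profiles), np.array([1, 1, 1, 2, 2, 2]), 2
        )
        cov = pd.DataFrame(
            {
                "pregnancy_id": [p.pregnancy_id for p in profiles],
                "smoking": ["yes", "no", None, "yes", "yes", "yes"],
            }
        )
        s = summarize_clusters(profiles, a, cov)
        t = s.covariate_counts
        c1_yes = t[(t.variable == "smoking") & (t.cluster == 1) & (t.category == "yes")]
        assert int(c1_yes["n"].iloc[0]) == 1
        # percentages on the non-missing denominator (2 valid in cluster 1)
        assert float(c1_yes["percent"].iloc[0]) == pytest.approx(50.0)
        miss = s.covariate_missing
        assert int(miss[(miss.variable == "smoking") & (miss.cluster == 1)]["n_missing"].iloc[0]) == 1
        # counts + missing add up to the cluster size
        assert (
            int(t[(t.variable == "smoking") & (t.cluster == 1)]["n"].sum()) + 1 == 3
        )

    def test_cluster_shifted_covariates_show_up(self, assigned_cohort):
        profiles, planted, covariates = assigned_cohort
        s = summarize_clusters(profiles, planted, covariates)
        t = s.covariate_counts
        assert set(t.variable) >= {
            "maternal_age", "bmi", "smoking", "mental_illness", "asthma",
            "child_gender", "birthweight", "gestational_week",
        }

    def test_atc_indication_proxy(self):
        profiles = [
            make_profile("A", [{P, "R03AC02"}] + [set()] * 9),
            make_profile("B", [{P, "N06AB04"}] + [set()] * 9),
            make_profile("C", [{P}] * N_WINDOWS),
        ]
        proxy = derive_indications_from_atc(profiles).set_index("pregnancy_id")
        assert proxy.loc["A", "asthma"] == "yes"
        assert proxy.loc["B", "mental_illness"] == "yes"
        assert proxy.loc["C", "asthma"] == proxy.loc["C", "mental_illness"] == "no"


class TestWriters:
    def test_writers_produce_readable_tables(self, tmp_path, assigned_cohort):
        profiles, planted, covariates = assigned_cohort
        s = summarize_clusters(profiles, planted, covariates)
        write_trajectories(s, tmp_path / "traj.csv")
        traj = pd.read_csv(tmp_path / "traj.csv")
        assert traj.shape == (planted.k, 11)
        write_covariate_table(s, tmp_path / "table.csv")
        table = pd.read_csv(tmp_path / "table.csv")
        assert {"variable", "category", "cluster1_n", f"cluster{planted.k}_pct"} <= set(
            table.columns
        )
        write_summary(s, tmp_path / "summary.yaml")
        import yaml

        doc = yaml.safe_load((tmp_path / "summary.yaml").read_text())
        assert doc["cohort_n"] == len(profiles)
        assert len(doc["clusters"]) == planted.k
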