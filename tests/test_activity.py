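"""Label joining and one-sided rank-sum comparisons."""
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ernascope.activity import compare_groups, join_activity, stratified_summary
from ernascope.io_formats import SignalTrack, ValidationError


def permutation_oracle_p(a, b):
    """Pr[rank-sum(a) >= observed] by explicit permutation of pooled values.

    Re-ranks the pooled vector for every labelling; independent of the
    implementation's combination-over-fixed-midranks route.
    """
    pooled = list(a) + list(b)
    n, n_a = len(pooled), len(a)

    def ranksum(values, idx_set):
        order = sorted(range(n), key=lambda i: values[i])
        ranks = [0.0] * n
        i = 0
        while i < n:
            j = i
            while j + 1 < n and values[order[j + 1]] == values[order[i]]:
                j += 1
            mid = (i + j) / 2 + 1
            for t in range(i, j + 1):
                ranks[order[t]] = mid
            i = j + 1
        return sum(ranks[i] for i in idx_set)

    observed = ranksum(pooled, range(n_a))
    from itertools import combinations

    hits = total = 0
    for comb in combinations(range(n), n_a):
        total += 1
        if ranksum(pooled, comb) >= observed - 1e-9:
            hits += 1
    return hits / total


class TestCompareGroups:
    def test_maximal_separation_exact(self):
        # a wholly above b with 3+3: only 1 of C(6,3)=20 labellings ties
        # or beats the observed rank-sum
        r = compare_groups([10, 12, 14], [1, 2, 3])
        assert r.p_value == pytest.approx(1 / 20)
        assert r.method == "exact"

    def test_identical_groups_p_at_least_half(self):
        r = compare_groups([4, 5, 6], [4, 5, 6])
        assert r.p_value >= 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([], [1])

    @given(
        st.lists(st.integers(0, 6), min_size=1, max_size=8),
        st.lists(st.integers(0, 6), min_size=1, max_size=8),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_permutation_oracle_with_ties(self, a, b):
        if len(a) + len(b) > 12:
            return
        r = compare_groups(a, b)
        assert r.p_value == pytest.approx(permutation_oracle_p(a, b), abs=1e-12)

    @given(
        st.lists(st.integers(0, 100), min_size=2, max_size=6, unique=True),
        st.lists(st.integers(101, 200), min_size=2, max_size=6, unique=True),
    )
    @settings(max_examples=50, deadline=None)
    def test_tie_free_case_matches_scipy_exact(self, a, b):
        from scipy import stats

        r = compare_groups(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="greater", method="exact")
        assert r.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)

    @given(
        st.lists(st.integers(0, 50), min_size=1, max_size=6),
        st.lists(st.integers(0, 50), min_size=1, max_size=6),
    )
    @settings(max_examples=60, deadline=None)
    def test_invariant_under_monotone_transform(self, a, b):
        f = lambda v: [3.0 * x**3 + 2 for x in v]  # strictly increasing
        assert compare_groups(a, b).p_value == pytest.approx(
            compare_groups(f(a), f(b)).p_value, abs=1e-12
        )

    def test_large_sample_effect_detected(self, rng):
        a = rng.poisson(200, size=50)
        b = rng.poisson(50, size=50)
        r = compare_groups(a, b)
        assert r.method == "normal" and r.p_value < 0.01


class TestJoinActivity:
    def _elements_df(self):
        return pd.DataFrame(
            {"id": ["E1", "E2"], "chrom": ["c", "c"], "start": [0, 100],
             "end": [50, 150], "summit": [25, 125]}
        )

    def test_left_join_keeps_unlabelled(self):
        labels = pd.DataFrame(
            [["E1", "6-8h", "mesoderm", "active"]],
            columns=["id", "stage", "tissue", "status"],
        )
        out = join_activity(self._elements_df(), labels)
        assert out.loc[out["id"] == "E1", "status"].iloc[0] == "active"
        assert out.loc[out["id"] == "E2", "status"].isna().all()

    def test_unknown_id_skipped_with_log(self, caplog):
        labels = pd.DataFrame(
            [["EX", "6-8h", "mesoderm", "active"]],
            columns=["id", "stage", "tissue", "status"],
        )
        with caplog.at_level("WARNING"):
            out = join_activity(self._elements_df(), labels)
        assert out["status"].isna().all()
        assert any("unknown element ids" in r.message for r in caplog.records)

    def test_conflicting_labels_rejected(self):
        labels = pd.DataFrame(
            [["E1", "6-8h", "mesoderm", "active"],
             ["E1", "6-8h", "mesoderm", "inactive"]],
            columns=["id", "stage", "tissue", "status"],
        )
        with pytest.raises(ValidationError, match="conflicting"):
            join_activity(self._elements_df(), labels)

    def test_multiple_stages_allowed(self):
        labels = pd.DataFrame(
            [["E1", "3-4h", "embryo", "inactive"],
             ["E1", "6-8h", "embryo", "active"]],
            columns=["id", "stage", "tissue", "status"],
        )
        out = join_activity(self._elements_df(), labels)
        assert (out["id"] == "E1").sum() == 2


class TestStratifiedSummary:
    def _cohort(self, rng, n=50, active_lam=200, inactive_lam=50):
        track = SignalTrack()
        rows = []
        for i in range(2 * n):
            status = "active" if i < n else "inactive"
            lam = active_lam if i < n else inactive_lam
            pos = 1000 + i * 1000
            track.add("c", "+", pos, int(rng.poisson(lam)))
            rows.append(
                {"id": f"e{i}", "chrom": "c", "start": pos - 200,
                 "end": pos + 200, "summit": pos, "stage": "6-8h",
                 "tissue": "embryo", "status": status}
            )
        return pd.DataFrame(rows), track

    def test_fourfold_effect_significant(self, rng):
        annotated, track = self._cohort(rng)
        summary, comparisons = stratified_summary(
            annotated, track, "6-8h", "embryo"
        )
        row = comparisons[(comparisons["group_a"] == "active")
                          & (comparisons["group_b"] == "inactive")]
        assert row["p_value"].iloc[0] < 0.01
        assert set(summary["status"]) == {"active", "inactive"}

    def test_single_status_no_comparisons(self, rng):
        annotated, track = self._cohort(rng, n=5)
        annotated = annotated[annotated["status"] == "active"]
        summary, comparisons = stratified_summary(
            annotated, track, "6-8h", "embryo"
        )
        assert len(summary) == 1 and comparisons.empty

    def test_null_p_values_roughly_uniform(self, rng):
        # identically distributed groups: Pr[p <= 0.05] ~ 0.05
        hits = 0
        n_sim = 300
        for _ in range(n_sim):
            a = rng.poisson(50, size=25)
            b = rng.poisson(50, size=25)
            if compare_groups(a, b).p_value <= 0.05:
                hits += 1
        assert hits / n_sim < 0.09
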