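import numpy as np
import pytest

import gaitpose as gp
from gaitpose.agreement import (
    PairedOutcomes,
    bland_altman,
    compare_sessions,
    compute_agreement,
    icc_2_1,
    match_frames,
    pearson,
)
from gaitpose.errors import AlignmentError, ContractError


def pairs_of(x, y, name="x", units="s"):
    return PairedOutcomes(np.asarray(x, float), np.asarray(y, float), name, units)


def icc_2_1_oracle(x, y):
    """Brute-force ICC(2,1): explicit two-way ANOVA with Python loops."""
    data = [[float(a), float(b)] for a, b in zip(x, y)]
    n, k = len(data), 2
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_err = sum(
        (data[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestICC:
    def test_perfect_agreement_is_one(self):
        x = [0.21, 0.25, 0.19, 0.23, 0.27]
        assert icc_2_1(pairs_of(x, x)) == pytest.approx(1.0)

    def test_matches_brute_force_anova_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(4, 30)
            x = rng.normal(0.5, 0.2, n)
            y = x + rng.normal(0, 0.05, n)
            assert icc_2_1(pairs_of(x, y)) == pytest.approx(
                icc_2_1_oracle(x, y), abs=1e-9
            )

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(12)
        x = rng.normal(0.6, 0.1, 25)
        y = x + rng.normal(0.01, 0.03, 25)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(25), 2),
                "rater": np.tile(["a", "b"], 25),
                "value": np.column_stack([x, y]).ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="value"
        )
        # absolute-agreement single-measures: labelled ICC2 or ICC(A,1)
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = float(ref.loc[mask, "ICC"].iloc[0])
        assert icc_2_1(pairs_of(x, y)) == pytest.approx(icc2, abs=1e-9)

    def test_uninformative_predictor_scores_low(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0.5, 0.2, 40)
        x = np.full(40, y.mean()) + rng.normal(0, 1e-6, 40)
        assert icc_2_1(pairs_of(x, y)) < 0.5

    def test_zero_between_subject_variance_rejected(self):
        with pytest.raises(ContractError, match="between-subject"):
            icc_2_1(pairs_of([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]))

    def test_symmetric_in_raters(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.5, 0.1, 20)
        y = x + rng.normal(0, 0.02, 20)
        assert icc_2_1(pairs_of(x, y)) == pytest.approx(
            icc_2_1(pairs_of(y, x)), abs=1e-12
        )

    def test_common_shift_leaves_icc_unchanged(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0.5, 0.1, 20)
        y = x + rng.normal(0, 0.02, 20)
        base = icc_2_1(pairs_of(x, y))
        assert icc_2_1(pairs_of(x + 5.0, y + 5.0)) == pytest.approx(base, abs=1e-9)

    def test_systematic_offset_lowers_absolute_agreement(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0.5, 0.1, 30)
        y = x + rng.normal(0, 0.01, 30)
        base = icc_2_1(pairs_of(x, y))
        offset = icc_2_1(pairs_of(x, y + 0.2))
        assert offset < base  # ICC(2,1) penalises bias, unlike Pearson


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert pearson(pairs_of(x, 2 * x + 1)) == pytest.approx(1.0)
        assert pearson(pairs_of(x, -x)) == pytest.approx(-1.0)

    def test_power_law_linearised_by_log10(self):
        x = np.array([0.5, 0.6, 0.7, 0.8, 0.9])
        y = x ** 3
        assert pearson(pairs_of(x, y), log10_transform=True) == pytest.approx(1.0)
        assert pearson(pairs_of(x, y)) < 1.0 - 1e-9

    def test_log10_rejects_nonpositive_values(self):
        with pytest.raises(ContractError, match="positive"):
            pearson(pairs_of([1.0, -2.0, 3.0], [1.0, 2.0, 3.0]), log10_transform=True)

    def test_constant_stream_is_nan(self):
        r = pearson(pairs_of([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
        assert np.isnan(r)


class TestBlandAltman:
    def test_identical_streams(self):
        ba = bland_altman(pairs_of([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_pure_offset(self):
        ba = bland_altman(pairs_of([1.1, 2.1, 3.1], [1.0, 2.0, 3.0]))
        assert ba.bias == pytest.approx(0.1)
        assert ba.loa_low == pytest.approx(0.1, abs=1e-9)
        assert ba.loa_high == pytest.approx(0.1, abs=1e-9)

    def test_limits_are_bias_plus_minus_1p96_sd(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0.5, 0.1, 200)
        d = rng.normal(0.02, 0.01, 200)
        ba = bland_altman(pairs_of(y + d, y))
        sd = np.std(d, ddof=1)
        assert ba.loa_high - ba.bias == pytest.approx(1.96 * sd, abs=1e-12)
        assert ba.bias - ba.loa_low == pytest.approx(1.96 * sd, abs=1e-12)


class TestPairedOutcomes:
    def test_too_few_pairs_rejected(self):
        with pytest.raises(ContractError):
            pairs_of([1.0, 2.0], [1.0, 2.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ContractError):
            pairs_of([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])

    def test_mean_error_is_absolute(self):
        st = compute_agreement(pairs_of([1.1, 1.9, 3.1, 3.9], [1.0, 2.0, 3.0, 4.0]))
        assert st.mean_error == pytest.approx(0.1)
        assert st.signed_mean_error == pytest.approx(0.0, abs=1e-12)


class TestMatchFrames:
    def test_one_to_one_nearest(self):
        pairs, unmatched = match_frames([10, 52, 99], [11, 50, 200], tol=5)
        assert pairs == [(10, 11), (52, 50)]
        assert unmatched == [200]

    def test_detected_frame_used_once(self):
        pairs, unmatched = match_frames([10], [9, 11], tol=5)
        assert len(pairs) == 1 and len(unmatched) == 1


@pytest.fixture(scope="module")
def jitter_report():
    from conftest import make_bout

    bout = make_bout(duration_s=30.0, stride_time_jitter_cv=0.03, seed=5)
    predicted = gp.analyze_session(bout.run, bout.static)
    reference = gp.session_from_truth(bout.truth)
    return compare_sessions(predicted, reference)


class TestCompareSessions:
    def test_report_schema(self, jitter_report):
        for col in ("side", "outcome", "n", "mean_error", "icc_2_1",
                    "pearson_r", "ba_bias", "ba_loa_low", "ba_loa_high"):
            assert col in jitter_report.columns
        assert set(jitter_report["side"]) == {"left", "right"}

    def test_jittered_bout_time_outcomes_agree(self, jitter_report):
        times = jitter_report[
            jitter_report["outcome"].isin(["contact_time", "swing_time", "step_time"])
        ]
        assert len(times) == 6  # three outcomes per side
        # single-bout contact-time variance is small relative to the 1/240 s
        # detection quantum, so the per-bout bar is the 0.75 "excellent
        # reliability" threshold; step time has ample variance and stays high
        assert (times["icc_2_1"] >= 0.75).all()
        assert (times[times["outcome"] == "step_time"]["icc_2_1"] >= 0.98).all()
        assert (times["mean_error"] <= 0.014).all()

    def test_pooled_clean_bouts_icc_high_and_shuffled_low(self):
        """Pool matched per-stride times over three clean bouts at different
        cadences; detection agrees (ICC >= 0.95) while a shuffled reference
        does not (< 0.5) -- the statistic discriminates."""
        from gaitpose.agreement import _match_strides
        from conftest import make_bout

        streams = {"contact_time": ([], []), "swing_time": ([], []),
                   "step_time": ([], [])}
        for cad, duty, seed in ((160.0, 0.30, 1), (170.0, 0.34, 2), (180.0, 0.38, 3)):
            bout = make_bout(duration_s=20.0, cadence_spm=cad, duty_factor=duty,
                             seed=seed)
            predicted = gp.analyze_session(bout.run, bout.static)
            reference = gp.session_from_truth(bout.truth)
            for side in ("left", "right"):
                matched = _match_strides(
                    predicted.sides[side].strides,
                    reference.sides[side].strides,
                    bout.run.fps,
                )
                assert len(matched) >= 20
                for name, (pv, rv) in streams.items():
                    for p, r in matched:
                        a, b = getattr(p, name), getattr(r, name)
                        if a is not None and b is not None:
                            pv.append(a)
                            rv.append(b)
        rng = np.random.default_rng(0)
        for name, (pv, rv) in streams.items():
            icc = icc_2_1(pairs_of(pv, rv, name))
            assert icc >= 0.95, name
            shuffled = rng.permutation(rv)
            assert icc_2_1(pairs_of(pv, shuffled, name)) < 0.5, name

    def test_fps_mismatch_rejected(self, clean_bout):
        predicted = gp.analyze_session(clean_bout.run, clean_bout.static)
        reference = gp.session_from_truth(clean_bout.truth)
        reference.fps = 120.0
        with pytest.raises(AlignmentError, match="fps"):
            compare_sessions(predicted, reference)

    def test_unalignable_sessions_rejected(self, clean_bout):
        predicted = gp.analyze_session(clean_bout.run, clean_bout.static)
        reference = gp.session_from_truth(clean_bout.truth)
        for side in reference.sides.values():
            for s in side.strides:
                s.ic_frame += 10_000  # push every reference IC out of tolerance
        with pytest.raises(AlignmentError, match="aligned"):
            compare_sessions(predicted, reference)
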