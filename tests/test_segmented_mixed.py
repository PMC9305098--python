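import numpy as np
import pandas as pd
import pytest

from focalsf.lmm import fit_random_intercept
from focalsf.segmented_mixed import (
    davies_test,
    fit_segmented_lmm,
    breakpoint_report,
)
from focalsf.synthetic import simulate_focal_records

PSI, S1, DELTA = -9.0, 0.002, 0.013


def records(rng, n_subjects=40, n_locations=60, sigma_b=0.015, sigma_e=0.02):
    return simulate_focal_records(
        n_subjects, n_locations, PSI, S1, DELTA, sigma_b, sigma_e, rng
    )


class TestFitSegmented:
    def test_recovers_known_breakpoint(self, rng):
        df = records(rng)
        res = fit_segmented_lmm(df, "fCD")
        assert res.converged
        assert res.psi == pytest.approx(PSI, abs=1.5)
        assert res.fvfd_at_bp == res.psi  # struct-on-fVFD orientation
        assert res.slope_before == pytest.approx(S1, abs=0.002)
        assert res.slope_change == pytest.approx(DELTA, abs=0.004)
        assert res.ci_psi[0] < res.psi < res.ci_psi[1]
        assert res.ci_slope_before[0] < res.slope_before < res.ci_slope_before[1]

    def test_recovers_variance_components(self, rng):
        df = records(rng, n_subjects=60, sigma_b=0.03, sigma_e=0.02)
        res = fit_segmented_lmm(df, "fCD")
        assert res.sigma_b == pytest.approx(0.03, rel=0.35)
        assert res.sigma_e == pytest.approx(0.02, rel=0.15)

    def test_exact_recovery_when_noise_vanishes(self, rng):
        df = records(rng, sigma_b=0.0, sigma_e=1e-6)
        res = fit_segmented_lmm(df, "fCD")
        assert res.psi == pytest.approx(PSI, abs=0.02)
        assert res.slope_before == pytest.approx(S1, rel=0.01)
        assert res.slope_change == pytest.approx(DELTA, rel=0.01)

    def test_matches_grid_search_oracle_without_grouping(self, rng):
        # sigma_b = 0 and one record per subject: plain segmented least
        # squares; oracle = dense grid over psi + OLS at each candidate
        df = simulate_focal_records(
            300, 1, PSI, S1, DELTA, 0.0, 0.01, rng
        )
        df["subject_id"] = [f"P{i}" for i in range(len(df))]
        res = fit_segmented_lmm(df, "fCD")
        x = df["fVFD_db"].to_numpy()
        y = df["fCD"].to_numpy()
        x_range = x.max() - x.min()
        best = (None, np.inf)
        for psi in np.linspace(np.quantile(x, 0.02), np.quantile(x, 0.98), 2001):
            X = np.column_stack([np.ones_like(x), x, (x - psi) * (x > psi)])
            beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ beta) ** 2).sum())
            if rss < best[1]:
                best = (psi, rss)
        assert abs(res.psi - best[0]) < 1e-3 * x_range

    def test_fvfd_on_struct_orientation(self, rng):
        # regress fVFD on the predictor; breakpoint maps back through the line
        n = 2000
        subjects = np.repeat([f"S{i}" for i in range(40)], n // 40)
        x = rng.uniform(0.05, 0.25, n)
        psi_x = 0.15
        y = -20 + 40 * (x - 0.05) + 80 * np.clip(x - psi_x, 0, None)
        y += np.repeat(rng.normal(0, 1.0, 40), n // 40) + rng.normal(0, 1.0, n)
        df = pd.DataFrame({"subject_id": subjects, "fVFD_db": y, "fCD": x})
        res = fit_segmented_lmm(df, "fCD", orientation="fvfd_on_struct")
        assert res.psi == pytest.approx(psi_x, abs=0.02)
        line = res.fvfd_at_bp
        assert line == pytest.approx(-20 + 40 * (psi_x - 0.05), abs=1.5)

    def test_no_break_reduces_to_plain_mixed_slope(self, rng):
        df = simulate_focal_records(30, 50, PSI, 0.01, 0.0, 0.01, 0.02, rng)
        x = df["fVFD_db"].to_numpy()
        y = df["fCD"].to_numpy()
        g = df["subject_id"].to_numpy()
        plain = fit_random_intercept(y, np.column_stack([np.ones_like(x), x]), g)
        res = fit_segmented_lmm(df, "fCD")
        assert plain.beta[1] == pytest.approx(0.01, abs=0.002)
        # the dominant segment tracks the single true slope and the
        # slope-change CI covers zero (no identifiable break)
        assert res.slope_before == pytest.approx(plain.beta[1], abs=0.004)
        assert res.ci_slope_change[0] <= 0.0 <= res.ci_slope_change[1]

    def test_null_slope_change_ci_covers_zero(self, rng):
        # no-break data: the slope-change CI should cover 0 in >= 90% of sims
        covered = 0
        reps = 200
        for _ in range(reps):
            df = simulate_focal_records(20, 15, PSI, 0.01, 0.0, 0.01, 0.02, rng)
            res = fit_segmented_lmm(df, "fCD")
            covered += res.ci_slope_change[0] <= 0.0 <= res.ci_slope_change[1]
        assert covered / reps >= 0.90

    def test_invariant_to_subject_relabeling_and_row_order(self, rng):
        df = records(rng, n_subjects=20, n_locations=30)
        res1 = fit_segmented_lmm(df, "fCD")
        relabeled = df.copy()
        mapping = {s: f"Z{i}" for i, s in enumerate(reversed(sorted(df.subject_id.unique())))}
        relabeled["subject_id"] = relabeled["subject_id"].map(mapping)
        relabeled = relabeled.sample(frac=1, random_state=0)
        res2 = fit_segmented_lmm(relabeled, "fCD")
        assert res1.psi == pytest.approx(res2.psi, abs=1e-8)
        assert res1.slope_before == pytest.approx(res2.slope_before, abs=1e-10)

    def test_psi_init_outside_support_rejected(self, rng):
        df = records(rng, n_subjects=10, n_locations=20)
        with pytest.raises(ValueError, match="support"):
            fit_segmented_lmm(df, "fCD", psi_init=99.0)

    def test_unknown_predictor(self, rng):
        with pytest.raises(ValueError, match="unknown predictor"):
            fit_segmented_lmm(records(rng, 5, 10), "fX")


class TestDaviesTest:
    def test_strong_break_detected(self, rng):
        df = records(rng, n_subjects=46, n_locations=74)
        assert davies_test(df, "fCD") < 0.001

    def test_scale_equivariance(self, rng):
        df = records(rng, n_subjects=20, n_locations=30)
        p1 = davies_test(df, "fCD")
        scaled = df.copy()
        scaled["fCD"] = scaled["fCD"] * 7.5
        assert davies_test(scaled, "fCD") == pytest.approx(p1, rel=1e-9)

    def test_linear_null_not_rejected_on_average(self, rng):
        rejections = 0
        for _ in range(40):
            df = simulate_focal_records(25, 20, PSI, 0.01, 0.0, 0.01, 0.02, rng)
            rejections += davies_test(df, "fCD") < 0.05
        assert rejections <= 8

    def test_k_grid_validation(self, rng):
        with pytest.raises(ValueError, match="k_grid"):
            davies_test(records(rng, 5, 10), "fCD", k_grid=3)

    def test_collinear_candidates_rejected(self, rng):
        n = 100
        df = pd.DataFrame({
            "subject_id": [f"S{i % 10}" for i in range(n)],
            "fVFD_db": rng.choice([-10.0, 0.0], n),
            "fCD": rng.uniform(0, 1, n),
        })
        with pytest.raises(ValueError, match="collinear"):
            davies_test(df, "fCD")


class TestReport:
    def test_echoes_fields(self, rng):
        res = fit_segmented_lmm(records(rng, 20, 30), "fCD", with_davies=True)
        table = breakpoint_report({"fCD": res})
        row = table.iloc[0]
        assert row["slope_before"] == res.slope_before
        assert row["fvfd_at_bp"] == res.fvfd_at_bp
        assert row["slope_change_ci"] == list(res.ci_slope_change)
        assert row["note"] == ""
        assert 0 < row["davies_p"] <= 1

    def test_nonconverged_annotated(self, rng):
        import dataclasses

        res = fit_segmented_lmm(records(rng, 20, 30), "fCD")
        res = dataclasses.replace(res, converged=False)
        table = breakpoint_report({"fCD": res})
        assert table.iloc[0]["note"] == "DID NOT CONVERGE"

    def test_ci_ordering_enforced(self, rng):
        import dataclasses

        res = fit_segmented_lmm(records(rng, 20, 30), "fCD")
        bad = dataclasses.replace(res, ci_slope_before=(res.slope_before + 1, res.slope_before + 2))
        with pytest.raises(AssertionError, match="CI does not contain"):
            breakpoint_report({"fCD": bad})
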