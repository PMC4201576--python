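import numpy as np
import pandas as pd
import pytest

import refstab as rs
from refstab.exceptions import InsufficientDataError, ValidationError
from refstab.normfinder import (
    combination_pseudocandidate,
    decompose_variance,
    enumerate_combination_stability,
    log_matrix,
    stability_scores,
)


def _matrix(n_cand, n_per_group, sigmas=None, deltas=None, rng=None,
            n_groups=2):
    """Random log2 matrix with planted per-candidate noise and group shifts."""
    rng = rng or np.random.default_rng(0)
    sigmas = np.asarray(sigmas if sigmas is not None else [0.2] * n_cand)
    deltas = np.asarray(deltas if deltas is not None else np.zeros(n_cand))
    cols, labels, data = [], {}, []
    n_total = n_per_group * n_groups
    y = (10.0 + rng.normal(size=(n_cand, n_total)) * sigmas[:, None])
    for g in range(n_groups):
        sl = slice(g * n_per_group, (g + 1) * n_per_group)
        if g > 0:
            y[:, sl] += deltas[:, None]
        for j in range(sl.start, sl.stop):
            cols.append(f"g{g}a{j}")
            labels[f"g{g}a{j}"] = f"grp{g}"
    mat = pd.DataFrame(y, index=[f"C{i}" for i in range(n_cand)], columns=cols)
    return mat, pd.Series(labels)


class TestLogMatrix:
    def test_log2_values_and_missing_handling(self, default_sim):
        _, abundance, _ = default_sim
        frame = abundance.frame.copy()
        # exclude one well -> that animal dropped listwise
        victim = frame.iloc[0]
        frame.loc[frame.index[0], "excluded"] = True
        mat = log_matrix(rs.AbundanceDataset(frame))
        assert victim.animal_id not in mat.columns
        full = log_matrix(abundance)
        assert full.shape[1] == 192
        row = frame.loc[(frame.animal_id == "A01_002") & (frame.candidate == "HPRT")]
        assert mat.loc["HPRT", "A01_002"] == pytest.approx(
            np.log2(float(row.intensity.iloc[0])))

    def test_non_positive_intensity_rejected(self):
        frame = pd.DataFrame([{
            "animal_id": "a", "experiment": 1, "strain": "s", "sex": "M",
            "genotype": "WT", "dose_ug_per_kg": 0.0, "time_h": 6.0,
            "blot_id": "b", "candidate": "A", "intensity": 1.0,
            "excluded": False}])
        ds = rs.AbundanceDataset(frame)
        ds.frame.loc[0, "intensity"] = -1.0  # bypass constructor check
        with pytest.raises(ValidationError):
            log_matrix(ds)


class TestDecomposeVariance:
    def test_insufficient_candidates_or_replication(self):
        mat, groups = _matrix(2, 5)
        with pytest.raises(InsufficientDataError):
            decompose_variance(mat, groups)
        mat, groups = _matrix(3, 5)
        groups.iloc[:] = ["grp0"] * 9 + ["grp1"]
        groups.index = mat.columns
        with pytest.raises(InsufficientDataError):
            decompose_variance(mat, groups)

    def test_duplicated_candidates_score_identically(self):
        mat, groups = _matrix(3, 6, sigmas=[0.1, 0.2, 0.3])
        dup = mat.copy()
        dup.loc["C1"] = dup.loc["C0"]
        comp = decompose_variance(dup, groups)
        assert comp.rho["C0"] == pytest.approx(comp.rho["C1"], rel=1e-12)

    def test_inter_group_differences_sum_to_zero(self):
        mat, groups = _matrix(5, 8, sigmas=[0.1, 0.2, 0.3, 0.1, 0.4],
                              deltas=[0.0, 0.5, -0.2, 0.1, 0.3])
        comp = decompose_variance(mat, groups)
        assert np.allclose(comp.d.sum(axis=0), 0.0, atol=1e-12)
        assert (np.abs(comp.d_tilde.to_numpy())
                <= np.abs(comp.d.to_numpy()) + 1e-15).all()
        assert (comp.sigma2.to_numpy() >= 0).all()
        assert (comp.rho >= 0).all()

    def test_variance_estimator_is_unbiased(self):
        """Mean of the untruncated intra-group variance estimate over many
        replicates recovers the planted variances within 5%."""
        sigmas = np.array([0.10, 0.20, 0.30, 0.15])
        acc = np.zeros((4, 2))
        reps = 1000
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            mat, groups = _matrix(4, 10, sigmas=sigmas, rng=rng)
            comp = decompose_variance(mat, groups)
            acc += comp.sigma2_raw.to_numpy()
        mean_est = (acc / reps).mean(axis=1)
        assert np.allclose(mean_est, sigmas ** 2, rtol=0.05)

    def test_anova_residual_oracle(self):
        """On any design the candidate-mean of the untruncated variance
        estimates equals the classical two-way ANOVA residual mean square
        per group (independent statsmodels fit)."""
        import statsmodels.formula.api as smf

        mat, groups = _matrix(5, 7, sigmas=[0.1, 0.25, 0.18, 0.3, 0.12],
                              deltas=[0.2, -0.1, 0.0, 0.4, -0.3])
        comp = decompose_variance(mat, groups)
        for g in comp.n_per_group.index:
            cols = groups[groups == g].index
            long = (mat[cols].stack().rename("y").reset_index()
                    .set_axis(["candidate", "animal", "y"], axis=1))
            fit = smf.ols("y ~ C(candidate) + C(animal)", data=long).fit()
            resid_ms = fit.ssr / fit.df_resid
            assert comp.sigma2_raw[g].mean() == pytest.approx(resid_ms, abs=1e-9)

    def test_expected_rho_monotone_in_planted_sigma(self):
        """Raising one candidate's intra-group SD (same seeds) never lowers
        its Monte-Carlo mean stability value."""
        means = []
        for sigma_c2 in (0.15, 0.3):
            tot = 0.0
            for seed in range(200):
                rng = np.random.default_rng(seed)
                mat, groups = _matrix(3, 8, sigmas=[0.1, 0.2, 1.0], rng=rng)
                # scale C2's pre-drawn unit noise to the target sigma
                mat.loc["C2"] = 10.0 + (mat.loc["C2"] - 10.0) * (sigma_c2 / 1.0)
                tot += decompose_variance(mat, groups).rho["C2"]
            means.append(tot / 200)
        assert means[1] >= means[0]


class TestScaleInvariance:
    def test_global_rescaling_changes_nothing(self, default_sim):
        _, abundance, _ = default_sim
        scaled = abundance.frame.copy()
        scaled["intensity"] *= 37.5
        s1 = stability_scores(abundance, cohort="training")
        s2 = stability_scores(rs.AbundanceDataset(scaled), cohort="training")
        pd.testing.assert_series_equal(s1, s2, rtol=1e-9)

    def test_single_blot_rescaling_changes_nothing(self, default_sim):
        """A per-blot multiplicative shift is absorbed by the per-animal
        sample effects, leaving every stability score untouched."""
        _, abundance, _ = default_sim
        scaled = abundance.frame.copy()
        mask = scaled["blot_id"] == "blot06"
        scaled.loc[mask, "intensity"] *= 5.0
        s1 = stability_scores(abundance, cohort="overall")
        s2 = stability_scores(rs.AbundanceDataset(scaled), cohort="overall")
        pd.testing.assert_series_equal(s1, s2, rtol=1e-9)


class TestCombinations:
    def test_pseudocandidate_arithmetic(self):
        mat = pd.DataFrame({"an1": [np.log2(4), np.log2(16)]},
                           index=["A", "B"])
        ps = combination_pseudocandidate(mat, ["A", "B"])
        assert ps["an1"] == pytest.approx(3.0)  # log2 sqrt(4*16) = 3

    def test_singleton_is_identity(self):
        mat, _ = _matrix(3, 5)
        ps = combination_pseudocandidate(mat, ["C1"])
        pd.testing.assert_series_equal(ps, mat.loc["C1"], check_names=False)

    def test_full_subset_is_row_mean(self):
        mat, _ = _matrix(4, 5)
        ps = combination_pseudocandidate(mat, list(mat.index))
        pd.testing.assert_series_equal(ps, mat.mean(axis=0), check_names=False)

    def test_enumeration_covers_all_subsets(self, fitted):
        combos = fitted.stability_combinations["training"]
        assert len(combos) == 127
        assert combos["combination"].is_unique

    def test_singleton_scores_match_per_candidate_scores(self, fitted, default_sim):
        _, abundance, _ = default_sim
        combos = fitted.stability_combinations["validation"]
        singles = combos.loc[combos.n_members == 1].set_index("combination")
        direct = stability_scores(abundance, cohort="validation")
        for cand, row in singles.iterrows():
            assert row["stability"] == pytest.approx(direct[cand], rel=1e-10)

    def test_expected_score_decreases_with_subset_size(self):
        """For independent equal-variance null candidates, larger
        geometric-mean panels average out noise: Monte-Carlo mean stability
        decreases with subset size."""
        sums = np.zeros(4)
        counts = np.zeros(4)
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            cands = {f"C{i}": rs.CandidateParams(10.0, 0.25) for i in range(4)}
            cfg = rs.SyntheticConfig(candidates=cands, blot_effect_sd=0.2,
                                     seed=1000 + seed)
            ab, _ = rs.simulate_dataset(cfg)
            combos = enumerate_combination_stability(
                ab, cohort="overall", candidates=list(cands))
            agg = combos.groupby("n_members")["stability"].sum()
            sums[agg.index - 1] += agg.to_numpy()
            counts += combos.groupby("n_members").size().to_numpy()
        means = sums / counts
        assert (np.diff(means) < 0).all()
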