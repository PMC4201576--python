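import json
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import refstab as rs
from refstab.concordance import (
    mrna_combination_stability,
    protein_mrna_concordance,
    spearman_as89,
    stability_score_concordance,
)
from refstab.exceptions import InsufficientDataError, ValidationError

distinct_values = st.lists(
    st.integers(min_value=-10**6, max_value=10**6),
    min_size=5, max_size=20, unique=True)


class TestSpearmanAS89:
    def test_monotone_function_gives_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        res = spearman_as89(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(10.0)
        res = spearman_as89(x, x[::-1])
        assert res.rho == pytest.approx(-1.0)

    @settings(deadline=None, max_examples=40)
    @given(x=distinct_values)
    def test_invariant_under_strictly_monotone_transform(self, x):
        x = np.asarray(x, dtype=float)
        rng = np.random.default_rng(0)
        y = rng.permutation(x)
        r1 = spearman_as89(x, y)
        r2 = spearman_as89(np.exp(x / 1e6), y ** 3)
        assert r1.rho == pytest.approx(r2.rho, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_constant_input_is_undefined(self):
        res = spearman_as89([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(res.rho) and np.isnan(res.p)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            spearman_as89([1, 2, 3, 4], [1, 2, 3])

    def test_edgeworth_close_to_exact_enumeration_n8(self):
        """The Edgeworth tail approximation stays within 0.005 of the exact
        permutation distribution at n = 8 (all 40320 orderings)."""
        rng = np.random.default_rng(17)
        worst = 0.0
        for _ in range(200):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            pe = spearman_as89(x, y, method="exact").p
            pa = spearman_as89(x, y, method="edgeworth").p
            worst = max(worst, abs(pe - pa))
        assert worst <= 0.005

    def test_matches_r_cor_test(self, tmp_path):
        """Independent oracle: R's cor.test implements AS89 for Spearman."""
        rng = np.random.default_rng(5)
        cases = []
        for n in (8, 15, 40, 120):
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            cases.append((x.tolist(), y.tolist()))
        (tmp_path / "cases.json").write_text(json.dumps(cases))
        script = tmp_path / "oracle.R"
        script.write_text(
            'library(jsonlite)\n'
            f'cases <- fromJSON("{tmp_path}/cases.json", simplifyVector=FALSE)\n'
            'ps <- sapply(cases, function(c) suppressWarnings(\n'
            '  cor.test(unlist(c[[1]]), unlist(c[[2]]),\n'
            '           method="spearman", exact=TRUE)$p.value))\n'
            f'writeLines(toJSON(ps, digits=NA), "{tmp_path}/out.json")\n')
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        expected = json.loads((tmp_path / "out.json").read_text())
        for (x, y), p_r in zip(cases, expected):
            p = spearman_as89(np.array(x), np.array(y)).p
            assert p == pytest.approx(p_r, rel=1e-8, abs=1e-12)


class TestProteinMrnaConcordance:
    def test_sign_flips_exactly_when_cq_negated(self, default_sim):
        _, abundance, cq = default_sim
        tab1 = protein_mrna_concordance(abundance, cq)
        flipped = cq.frame.copy()
        flipped["mean_cq"] = -flipped["mean_cq"]
        tab2 = protein_mrna_concordance(abundance, rs.CqDataset(flipped))
        assert np.allclose(tab1["spearman_rho"], -tab2["spearman_rho"])
        assert np.allclose(tab1["p_as89"], tab2["p_as89"])

    def test_planted_coupling_recovered(self):
        cfg = rs.default_config(seed=21, mrna_coupling=0.9)
        abundance, cq = rs.simulate_dataset(cfg)
        tab = protein_mrna_concordance(abundance, cq).set_index("gene")
        # positive protein/abundance coupling appears as negative rho vs Cq
        assert tab.loc["HPRT", "spearman_rho"] == pytest.approx(-0.9, abs=0.05)

    def test_constant_cq_gives_undefined_marker(self, default_sim):
        _, abundance, cq = default_sim
        frame = cq.frame.copy()
        frame.loc[frame.gene == "ACTB", "mean_cq"] = 20.0
        tab = protein_mrna_concordance(abundance, rs.CqDataset(frame))
        assert np.isnan(tab.set_index("gene").loc["ACTB", "spearman_rho"])

    def test_too_few_paired_animals_rejected(self, default_sim):
        _, abundance, cq = default_sim
        few = cq.frame.groupby("gene").head(3)
        with pytest.raises(InsufficientDataError):
            protein_mrna_concordance(abundance, rs.CqDataset(few))


class TestStabilityScoreConcordance:
    def test_identical_vectors_give_one(self, fitted):
        combos = fitted.stability_combinations["overall"]
        res = stability_score_concordance(combos, combos)
        assert res.rho == pytest.approx(1.0)

    def test_key_mismatch_rejected(self, fitted):
        combos = fitted.stability_combinations["overall"]
        other = combos.copy()
        other.loc[0, "combination"] = "NOT+REAL"
        with pytest.raises(ValidationError):
            stability_score_concordance(combos, other)

    def test_independent_vectors_center_on_zero(self):
        rng = np.random.default_rng(3)
        rhos = []
        combos = [f"C{i}" for i in range(20)]
        for _ in range(300):
            a = pd.DataFrame({"combination": combos,
                              "stability": rng.normal(size=20)})
            b = pd.DataFrame({"combination": combos,
                              "stability": rng.normal(size=20)})
            rhos.append(stability_score_concordance(a, b).rho)
        # MC error of the mean ~ 1/sqrt(19*300) ~ 0.013
        assert abs(np.mean(rhos)) < 0.04

    def test_mrna_path_reuses_protein_code(self):
        """With strong protein-mRNA coupling the Cq panel inherits the
        treatment structure and its combination stabilities concord
        positively with the protein ones through the shared code path."""
        cfg = rs.default_config(seed=21, mrna_coupling=0.9)
        abundance, cq = rs.simulate_dataset(cfg)
        prot = rs.ReferenceStabilityModel(abundance).fit()
        combos = mrna_combination_stability(cq, abundance)
        assert len(combos) == 127
        res = stability_score_concordance(
            prot.stability_combinations["overall"], combos)
        assert res.rho > 0.3
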