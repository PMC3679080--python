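import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tilesplice.expression import gene_expression
from tilesplice.mapping import map_probes
from tilesplice.preprocess import preprocess
from tilesplice.simulate import PlantedEvent, SimulationConfig, simulate
from tilesplice.splicing import (
    classify_splice_type,
    compute_thresholds,
    fisher_combine,
    gate_genes,
    intron_test,
    probe_level_tests,
)


def fisher_oracle(p):
    """Independent brute-force reference: -2*sum(ln p) vs chi-square tail."""
    x2 = -2.0 * sum(np.log(v) for v in p)
    return float(sps.chi2.sf(x2, 2 * len(p)))


class TestProbeLevelTests:
    def test_symmetric_null_gives_half(self):
        t = np.array([[5.0, 5.0, 5.0, 5.0]])
        p_up, p_down = probe_level_tests(t, t.copy())
        assert p_up[0] == pytest.approx(0.5)
        assert p_down[0] == pytest.approx(0.5)

    def test_strong_direction(self):
        t = np.full((1, 4), 8.0)
        c = np.full((1, 4), 2.0)
        p_up, p_down = probe_level_tests(t, c)
        assert p_up[0] < 1e-10 and p_down[0] > 1 - 1e-10

    def test_complement_identity_exact(self, rng):
        t = rng.normal(0, 1, size=(50, 4))
        c = rng.normal(0, 1, size=(50, 4))
        p_up, p_down = probe_level_tests(t, c)
        np.testing.assert_array_equal(p_up + p_down, np.ones(50))

    def test_matches_t_distribution_oracle(self, rng):
        """p_up equals the pooled-t upper tail computed from first principles."""
        t = rng.normal(0, 1, size=(20, 4))
        c = rng.normal(0, 1, size=(20, 4))
        p_up, _ = probe_level_tests(t, c)
        for i in range(20):
            n1 = n2 = 4
            sp2 = ((n1 - 1) * t[i].var(ddof=1) + (n2 - 1) * c[i].var(ddof=1)) / (
                n1 + n2 - 2
            )
            t_stat = (t[i].mean() - c[i].mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            assert p_up[i] == pytest.approx(sps.t.sf(t_stat, 6), rel=1e-10)


class TestFisherCombine:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([1.0, 1.0], 1.0),
            ([0.2], 0.2),  # k=1 is the identity
            ([0.05, 0.05], 0.017478),  # chi2.sf(11.9829, 4) = e^{-x/2}(1+x/2), closed form at df 4
        ],
    )
    def test_known_values(self, p, expected):
        assert fisher_combine(np.array(p)) == pytest.approx(expected, abs=1e-4)

    def test_matches_oracle_across_k(self, rng):
        for k in range(1, 11):
            p = rng.uniform(0.001, 1, size=k)
            assert fisher_combine(p) == pytest.approx(fisher_oracle(p), abs=1e-10)

    def test_adding_uninformative_probe_changes_df(self, rng):
        p = rng.uniform(0.01, 0.5, size=3)
        with_extra = np.append(p, 1.0)
        assert fisher_combine(with_extra) == pytest.approx(
            fisher_oracle(with_extra), abs=1e-10
        )

    def test_zero_p_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            out = fisher_combine(np.array([0.0, 0.5]))
        assert 0 < out < 1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine(np.array([]))
        with pytest.raises(ValueError):
            fisher_combine(np.array([1.5]))


def _pipeline(exp):
    mapped, _ = map_probes(exp.probes, exp.models)
    norm = preprocess(exp.raw)
    tbl = gene_expression(norm, mapped)
    return mapped, norm, tbl


class TestGating:
    def test_gate_matches_brute_force(self, small_experiment):
        mapped, norm, tbl = _pipeline(small_experiment)
        eligible, thr = gate_genes(norm, mapped, tbl)
        expected = []
        for gene in tbl.index:
            r = tbl.loc[gene]
            if r["n_probes"] < 9 or r["n_intron_probes"] < 1 or r["flagged"]:
                continue
            if any(
                r[f"expression_{c}"] > thr.exon_expression_threshold
                and r[f"intron_mean_{c}"] < thr.intron_background_threshold
                for c in ("control", "treatment")
            ):
                expected.append(gene)
        assert eligible == expected

    def test_eight_probe_gene_ineligible(self, small_experiment):
        """The probe-count gate requires strictly more than eight probes."""
        mapped, norm, tbl = _pipeline(small_experiment)
        tbl = tbl.copy()
        some_gene = tbl.index[0]
        tbl.loc[some_gene, "n_probes"] = 8
        eligible, _ = gate_genes(norm, mapped, tbl)
        assert some_gene not in eligible

    def test_thresholds_are_global_medians(self, small_experiment):
        mapped, norm, _ = _pipeline(small_experiment)
        thr = compute_thresholds(norm, mapped)
        idx = {p: i for i, p in enumerate(norm.probe_ids)}
        exon_vals = np.concatenate(
            [norm.values[idx[p.probe_id]] for p in mapped if p.segment_kind == "exon"]
        )
        all_vals = np.concatenate([norm.values[idx[p.probe_id]] for p in mapped])
        assert thr.exon_expression_threshold == pytest.approx(np.median(exon_vals))
        assert thr.intron_background_threshold == pytest.approx(np.median(all_vals))
        assert np.isfinite(thr.exon_mode)


class TestIntronTest:
    def test_null_simulation_few_calls(self):
        """No planted events: BH at 0.1 yields essentially no significant introns."""
        exp = simulate(SimulationConfig(n_genes=100, exons_per_gene=(3, 5), seed=5))
        mapped, norm, tbl = _pipeline(exp)
        eligible, _ = gate_genes(norm, mapped, tbl)
        results = intron_test(norm, mapped, eligible)
        assert sum(r.significant for r in results) <= 2

    def test_planted_retention_recovered(self, small_experiment):
        mapped, norm, tbl = _pipeline(small_experiment)
        eligible, _ = gate_genes(norm, mapped, tbl)
        results = intron_test(norm, mapped, eligible)
        hit = [r for r in results if r.gene_id == "G0001" and r.intron_index == 1]
        assert len(hit) == 1 and hit[0].significant
        assert hit[0].direction == "higher_in_treatment"
        assert hit[0].presence == "treatment"
        assert hit[0].splice_type == "retained"

    def test_planted_partial_event_is_unknown(self, small_experiment):
        """Only half the intron's probes shift: must not be called retained."""
        mapped, norm, tbl = _pipeline(small_experiment)
        eligible, _ = gate_genes(norm, mapped, tbl)
        results = intron_test(norm, mapped, eligible)
        hit = [r for r in results if r.gene_id == "G0003" and r.intron_index == 2]
        assert len(hit) == 1 and hit[0].significant
        assert hit[0].splice_type == "unknown"

    def test_intron_p_is_min_of_directions(self, small_experiment):
        mapped, norm, tbl = _pipeline(small_experiment)
        eligible, _ = gate_genes(norm, mapped, tbl)
        for r in intron_test(norm, mapped, eligible):
            assert r.intron_p == min(r.combined_p_up, r.combined_p_down)
            np.testing.assert_array_equal(r.probe_p_up + r.probe_p_down, 1.0)

    def test_detection_power(self):
        """≥2 log2 shift, sd 0.25, ≥3 probes per intron, 4v4: recall ≥ 0.9."""
        events = tuple(
            PlantedEvent(gene=g, intron=1, event_type="retention", effect_size=2.0)
            for g in range(30)
        )
        exp = simulate(
            SimulationConfig(
                n_genes=60,
                exons_per_gene=(3, 3),
                intron_length=(110, 250),  # ≥3 probes per intron
                planted_events=events,
                seed=11,
            )
        )
        mapped, norm, tbl = _pipeline(exp)
        eligible, _ = gate_genes(norm, mapped, tbl)
        results = intron_test(norm, mapped, eligible)
        truth = set(zip(exp.truth_events["gene_id"], exp.truth_events["intron_index"]))
        called = {
            (r.gene_id, r.intron_index) for r in results if r.significant
        }
        recall = len(truth & called) / len(truth)
        assert recall >= 0.9


class TestClassify:
    def _result(self, p_up):
        from tilesplice.splicing import IntronTestResult

        p_up = np.asarray(p_up, dtype=float)
        return IntronTestResult(
            gene_id="G",
            intron_index=1,
            n_probes=len(p_up),
            probe_p_up=p_up,
            probe_p_down=1 - p_up,
            combined_p_up=0.001,
            combined_p_down=0.999,
            intron_p=0.001,
            direction="higher_in_treatment",
        )

    def test_all_probes_significant_is_retained(self):
        assert classify_splice_type(self._result([0.01, 0.02, 0.04, 0.001])) == "retained"

    def test_one_insignificant_probe_is_unknown(self):
        assert classify_splice_type(self._result([0.01, 0.02, 0.04, 0.3])) == "unknown"
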