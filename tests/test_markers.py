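"""ROC-AUC markers, the bimodal likelihood-ratio test, Bonferroni, signatures."""

import math

import numpy as np
import pandas as pd
import pytest

import scfidelity as sf
from scfidelity.markers import EmptySignatureWarning
from scfidelity.preprocess import NormalizedMatrix


def nm_from_columns(columns: dict[str, list[float]]) -> NormalizedMatrix:
    df = pd.DataFrame(columns)
    df.index = [f"c{i}" for i in range(df.shape[0])]
    return NormalizedMatrix(values=df, scale_factor=1e4)


def labels_for(nm: NormalizedMatrix, in_cells: list[str]) -> sf.ClusterAssignment:
    lab = pd.Series([0 if c in in_cells else 1 for c in nm.values.index], index=nm.values.index)
    return sf.ClusterAssignment(labels=lab, resolution=1.0, seed=0)


def auc_bruteforce(x_in: np.ndarray, x_out: np.ndarray) -> float:
    """All-pairs oracle: concordant + half credit for ties."""
    total = 0.0
    for a in x_in:
        for b in x_out:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(x_in) * len(x_out))


class TestRocAucMarkers:
    def test_hand_counted_pairs_with_tie(self):
        nm = nm_from_columns({"g": [3, 2, 1, 0, 2]})
        rec = sf.roc_auc_markers(nm, labels_for(nm, ["c0", "c1"]), 0)
        assert rec.loc["g", "auc"] == pytest.approx(5.5 / 6)

    def test_constant_gene_is_half(self):
        nm = nm_from_columns({"g": [1.0] * 6})
        rec = sf.roc_auc_markers(nm, labels_for(nm, ["c0", "c1"]), 0)
        assert rec.loc["g", "auc"] == pytest.approx(0.5)

    def test_perfect_separation_is_one(self):
        nm = nm_from_columns({"g": [2.0, 3.0, 0.0, 0.0]})
        rec = sf.roc_auc_markers(nm, labels_for(nm, ["c0", "c1"]), 0)
        assert rec.loc["g", "auc"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 201))
        n_in = int(rng.integers(1, n))
        values = np.round(rng.normal(size=n), 1)  # rounding forces ties
        nm = nm_from_columns({"g": values})
        in_cells = [f"c{i}" for i in range(n_in)]
        rec = sf.roc_auc_markers(nm, labels_for(nm, in_cells), 0)
        expected = auc_bruteforce(values[:n_in], values[n_in:])
        assert rec.loc["g", "auc"] == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        values = rng.gamma(2.0, size=40)
        nm1 = nm_from_columns({"g": values})
        nm2 = nm_from_columns({"g": np.exp(values)})
        in_cells = [f"c{i}" for i in range(15)]
        a = sf.roc_auc_markers(nm1, labels_for(nm1, in_cells), 0).loc["g", "auc"]
        b = sf.roc_auc_markers(nm2, labels_for(nm2, in_cells), 0).loc["g", "auc"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_clusters_rejected(self):
        nm = nm_from_columns({"g": [1.0, 2.0]})
        with pytest.raises(ValueError, match="no cells"):
            sf.roc_auc_markers(nm, labels_for(nm, []), 0)
        with pytest.raises(ValueError, match="every cell"):
            sf.roc_auc_markers(nm, labels_for(nm, ["c0", "c1"]), 0)

    def test_detection_fractions_reported(self):
        nm = nm_from_columns({"g": [1.0, 0.0, 2.0, 0.0]})
        rec = sf.roc_auc_markers(nm, labels_for(nm, ["c0", "c1"]), 0)
        assert rec.loc["g", "pct_in"] == pytest.approx(0.5)
        assert rec.loc["g", "pct_out"] == pytest.approx(0.5)


def loglik_oracle(x: np.ndarray) -> float:
    """Direct transcription of the mixture log-likelihood."""
    x = np.asarray(x, float)
    pos = x[x != 0]
    n, n_pos = len(x), len(pos)
    pi = n_pos / n
    ll = 0.0
    if n - n_pos:
        ll += (n - n_pos) * math.log(1 - pi)
    if n_pos:
        ll += n_pos * math.log(pi)
        mu = pos.mean()
        sd = pos.std(ddof=0)
        if n_pos < 2 or sd == 0:
            sd = 1.0
        for v in pos:
            ll += -0.5 * math.log(2 * math.pi) - math.log(sd) - (v - mu) ** 2 / (2 * sd**2)
    return ll


class TestBimodLRT:
    def test_identical_groups_give_null(self):
        x = np.array([0.0, 1.2, 0.0, 2.5, 3.0])
        stat, p = sf.bimod_lrt(x, x.copy())
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_all_zero_vs_all_positive_matches_likelihood_oracle(self):
        rng = np.random.default_rng(12)
        x_in = np.zeros(20)
        x_out = rng.normal(3.0, 1.0, 20)
        stat, p = sf.bimod_lrt(x_in, x_out)
        expected = 2 * (
            loglik_oracle(x_in) + loglik_oracle(x_out)
            - loglik_oracle(np.concatenate([x_in, x_out]))
        )
        assert stat == pytest.approx(expected, abs=1e-9)
        assert p < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_likelihood_oracle_on_random_mixtures(self, seed):
        rng = np.random.default_rng(seed)
        def draw(n):
            return np.where(rng.random(n) < 0.4, 0.0, rng.normal(2, 1, n))
        x_in, x_out = draw(30), draw(25)
        stat, _ = sf.bimod_lrt(x_in, x_out)
        expected = 2 * (
            loglik_oracle(x_in) + loglik_oracle(x_out)
            - loglik_oracle(np.concatenate([x_in, x_out]))
        )
        assert stat == pytest.approx(max(expected, 0.0), abs=1e-9)

    def test_statistic_symmetric_in_group_order(self):
        rng = np.random.default_rng(13)
        a = np.where(rng.random(15) < 0.3, 0.0, rng.normal(1, 1, 15))
        b = np.where(rng.random(20) < 0.6, 0.0, rng.normal(2, 1, 20))
        assert sf.bimod_lrt(a, b)[0] == pytest.approx(sf.bimod_lrt(b, a)[0], abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sf.bimod_lrt(np.array([]), np.array([1.0]))

    def test_sigma_floor_keeps_likelihood_finite(self):
        stat, p = sf.bimod_lrt(np.array([0.0, 2.0]), np.array([2.0, 2.0, 2.0]))
        assert math.isfinite(stat) and 0 <= p <= 1


class TestBonferroni:
    def test_cap_multiplication_and_identity(self):
        np.testing.assert_allclose(sf.bonferroni_adjust([0.01], 100), [1.0])
        np.testing.assert_allclose(sf.bonferroni_adjust([1e-6], 1000), [1e-3])
        np.testing.assert_allclose(sf.bonferroni_adjust([0.2, 0.5], 2), [0.4, 1.0])
        np.testing.assert_allclose(sf.bonferroni_adjust([0.3]), [0.3])

    def test_monotone_and_order_preserving(self):
        rng = np.random.default_rng(14)
        p = np.sort(rng.random(50))
        adj = sf.bonferroni_adjust(p, 200)
        assert (np.diff(adj) >= 0).all()
        assert (adj >= p).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sf.bonferroni_adjust([1.2])
        with pytest.raises(ValueError):
            sf.bonferroni_adjust([0.1, 0.2], 1)


class TestDeriveSignature:
    def test_planted_markers_recovered(self, bench_pipeline):
        """Signatures of the clusters recovering planted programs contain
        the planted markers."""
        nm, labels = bench_pipeline["nm"], bench_pipeline["labels"]
        truth, true_labels = bench_pipeline["truth"], bench_pipeline["true_labels"]
        for cl in range(labels.n_clusters):
            cells = labels.cells_in(cl)
            prog = true_labels.loc[cells].mode()[0]
            sig = sf.derive_signature(nm, labels, cl, auc_threshold=0.65)
            planted = [g for g in truth.marker_genes[prog] if g in nm.gene_ids]
            assert set(planted) <= set(sig.genes)

    def test_threshold_one_keeps_only_perfect_separators(self):
        nm = nm_from_columns({"perfect": [2.0, 3.0, 0.0, 0.0], "noisy": [2.0, 0.0, 1.0, 0.0]})
        sig = sf.derive_signature(nm, labels_for(nm, ["c0", "c1"]), 0, auc_threshold=0.999)
        assert sig.genes == ["perfect"]

    def test_sorted_by_decreasing_auc(self, bench_pipeline):
        sig = sf.derive_signature(
            bench_pipeline["nm"], bench_pipeline["labels"], 0, auc_threshold=0.6
        )
        aucs = [sig.aucs[g] for g in sig.genes]
        assert aucs == sorted(aucs, reverse=True)

    def test_empty_signature_warns_explicitly(self):
        nm = nm_from_columns({"g": [1.0, 1.0, 1.0, 1.0]})
        with pytest.warns(EmptySignatureWarning):
            sig = sf.derive_signature(nm, labels_for(nm, ["c0"]), 0, auc_threshold=0.9)
        assert len(sig) == 0


def test_de_table_orders_by_significance(bench_pipeline):
    nm, labels = bench_pipeline["nm"], bench_pipeline["labels"]
    table = sf.de_table(nm, labels.cells_in(0), labels.cells_in(1))
    assert (table["p_adjusted"] >= table["p_value"] - 1e-15).all()
    assert table["p_adjusted"].is_monotonic_increasing
    assert (table["lrt_statistic"] >= 0).all()
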