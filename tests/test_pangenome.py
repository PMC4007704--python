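import itertools

import numpy as np
import pytest

from pankit import pangenome
from pankit.errors import ConfigError, FitError
from pankit.pangenome import PangenomeCurve, PresenceMatrix


def matrix_from_sets(genome_sets):
    """Presence matrix from per-genome gene-family sets."""
    genomes = [f"G{i + 1}" for i in range(len(genome_sets))]
    fams = sorted(set().union(*genome_sets))
    counts = np.array([[1 if f in s else 0 for s in genome_sets] for f in fams])
    return PresenceMatrix(fams, genomes, counts)


def brute_force_medians(genome_sets):
    """Independent oracle: enumerate all orderings with plain set algebra."""
    g = len(genome_sets)
    pans, cores = [], []
    for perm in itertools.permutations(range(g)):
        pan_row, core_row = [], []
        seen: set = set()
        common = None
        for idx in perm:
            seen = seen | genome_sets[idx]
            common = genome_sets[idx] if common is None else common & genome_sets[idx]
            pan_row.append(len(seen))
            core_row.append(len(common))
        pans.append(pan_row)
        cores.append(core_row)

    def lower_median(col):
        s = sorted(col)
        return s[(len(s) - 1) // 2]

    med_pan = [lower_median([row[n] for row in pans]) for n in range(g)]
    med_core = [lower_median([row[n] for row in cores]) for n in range(g)]
    return med_pan, med_core


TOY = [{"a", "b", "c"}, {"a", "b", "d"}, {"a", "e"}]


class TestAccumulationCurves:
    def test_toy_three_genome_medians(self):
        curve = pangenome.accumulation_curves(matrix_from_sets(TOY))
        assert curve.exhaustive and curve.n_permutations == 6
        assert list(curve.median_pan) == [3, 4, 5]
        assert list(curve.median_core) == [3, 1, 1]
        assert brute_force_medians(TOY) == ([3, 4, 5], [3, 1, 1])

    def test_identical_genomes_have_no_new_genes(self):
        curve = pangenome.accumulation_curves(matrix_from_sets([{"a", "b"}, {"a", "b"}]))
        assert list(curve.median_pan) == [2, 2]
        assert list(curve.median_core) == [2, 2]
        assert curve.median_new[1] == 0

    @pytest.mark.parametrize("g,seed", [(4, 0), (5, 1), (5, 2)])
    def test_exhaustive_mode_equals_enumeration_oracle(self, g, seed):
        rng = np.random.default_rng(seed)
        universe = [f"f{i}" for i in range(15)]
        sets = [
            {f for f in universe if rng.random() < 0.5} | {"anchor"} for _ in range(g)
        ]
        curve = pangenome.accumulation_curves(matrix_from_sets(sets))
        med_pan, med_core = brute_force_medians(sets)
        assert list(curve.median_pan) == med_pan
        assert list(curve.median_core) == med_core

    def test_sampled_mode_monotone_with_constant_endpoints(self):
        rng = np.random.default_rng(7)
        counts = (rng.random((300, 13)) < 0.6).astype(int)
        counts[:, 0] |= counts.sum(axis=1) == 0
        m = PresenceMatrix([f"f{i}" for i in range(300)], [f"G{j}" for j in range(13)], counts)
        curve = pangenome.accumulation_curves(m, n_permutations=200, seed=5)
        assert not curve.exhaustive
        assert (np.diff(curve.pan, axis=1) >= 0).all()
        assert (np.diff(curve.core, axis=1) <= 0).all()
        assert len(set(curve.pan[:, -1])) == 1 and len(set(curve.core[:, -1])) == 1

    def test_median_stability_across_seeds(self):
        rng = np.random.default_rng(11)
        counts = (rng.random((500, 13)) < 0.5).astype(int)
        counts[:, 0] |= counts.sum(axis=1) == 0
        m = PresenceMatrix([f"f{i}" for i in range(500)], [f"G{j}" for j in range(13)], counts)
        c1 = pangenome.accumulation_curves(m, n_permutations=1000, seed=1)
        c2 = pangenome.accumulation_curves(m, n_permutations=1000, seed=2)
        assert (np.abs(c1.median_pan - c2.median_pan) <= 1).all()
        assert (np.abs(c1.median_core - c2.median_core) <= 1).all()

    def test_single_genome_rejected(self):
        with pytest.raises(ConfigError):
            pangenome.accumulation_curves(matrix_from_sets([{"a"}]))


def curve_from_model(kappa, alpha, g=13):
    """One-permutation curve whose new-gene series follows the model exactly."""
    n = np.arange(1, g + 1, dtype=float)
    new = kappa * n ** (-alpha)
    new[0] = 2 * kappa  # pan(1); excluded from the fit
    pan = np.cumsum(new)
    core = 800.0 * np.exp(-(n - 1) / 2.0) + 500.0
    return PangenomeCurve(pan=pan[None, :], core=core[None, :], new=new[None, :])


class TestFitModels:
    def test_exact_power_law_inversion(self):
        fit = pangenome.fit_models(curve_from_model(500.0, 1.4))
        assert fit.alpha == pytest.approx(1.4, abs=1e-6)
        assert fit.kappa_new == pytest.approx(500.0, rel=1e-6)
        assert fit.openness_call == "closed"

    def test_shallow_decay_is_open(self):
        fit = pangenome.fit_models(curve_from_model(300.0, 0.6))
        assert fit.alpha == pytest.approx(0.6, abs=1e-6)
        assert fit.openness_call == "open"

    def test_core_decay_parameters_recovered(self):
        fit = pangenome.fit_models(curve_from_model(500.0, 1.4))
        assert fit.core_a == pytest.approx(800.0, rel=1e-4)
        assert fit.core_tau == pytest.approx(2.0, rel=1e-4)
        assert fit.core_omega == pytest.approx(500.0, rel=1e-4)

    def test_degenerate_panel_raises_fit_error(self):
        m = matrix_from_sets([{"a", "b"}] * 4)
        curve = pangenome.accumulation_curves(m)
        with pytest.raises(FitError):
            pangenome.fit_models(curve)

    def test_too_few_genomes_rejected(self):
        with pytest.raises(ConfigError):
            pangenome.fit_models(
                pangenome.accumulation_curves(matrix_from_sets(TOY))
            )


class TestCurveReport:
    def test_toy_report_values(self):
        curve = pangenome.accumulation_curves(matrix_from_sets(TOY))
        assert int(curve.median_pan[-1]) == 5
        assert int(curve.median_core[-1]) == 1
        # average new-gene rate over the first two additions: (1 + 1) / 2
        assert pangenome.new_gene_rate(curve, k=2) == pytest.approx(1.0)

    def test_report_fields(self):
        curve = curve_from_model(500.0, 1.4)
        fit = pangenome.fit_models(curve)
        rep = pangenome.curve_report(curve, fit, k=9)
        assert rep["openness_call"] == "closed"
        assert rep["pan_final"] == int(curve.median_pan[-1])
        assert "N^(-1.4" in rep["new_gene_fit"]
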