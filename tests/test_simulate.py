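"""Synthetic-data generators: basis spectra, mixtures, melting, experiments."""

import numpy as np
import pytest

from g4flank.design import enumerate_loop_multisets
from g4flank.melting import compute_tm, first_derivative
from g4flank.simulate import (
    BasisModel,
    FlankingEffectModel,
    GaussianBand,
    TwoStateParams,
    basis_spectrum,
    folded_fraction,
    make_pairs,
    mix_spectra,
    saturation,
    synth_experiment,
    synth_melting,
)
from g4flank.spectra import conformation_index


class TestBasisSpectra:
    @pytest.mark.parametrize(
        "topology, check",
        [
            ("parallel", lambda r: r >= 0.9),
            ("antiparallel", lambda r: r < 0),
            ("hybrid", lambda r: 0 <= r < 0.5),
        ],
    )
    def test_pure_basis_lands_in_its_class(self, basis, topology, check):
        res = conformation_index(basis_spectrum(topology, basis))
        assert check(res.r)
        assert res.label == topology

    def test_unknown_topology_rejected(self, basis):
        with pytest.raises(ValueError):
            basis_spectrum("triplex", basis)

    def test_inconsistent_bands_fail_construction_gate(self):
        bands = {
            "parallel": (GaussianBand(290.0, 9.0, 1.0),),  # peak at the wrong band
            "antiparallel": (GaussianBand(292.0, 10.0, 0.7), GaussianBand(265.0, 9.0, -0.55)),
            "hybrid": (GaussianBand(290.0, 10.0, 0.65), GaussianBand(268.0, 9.0, 0.55)),
        }
        with pytest.raises(ValueError, match="outside its class"):
            BasisModel(bands=bands)


class TestMixSpectra:
    def test_pure_fraction_reproduces_basis(self, basis):
        m = mix_spectra((1.0, 0.0, 0.0), basis, noise_sd=0.0)
        assert np.allclose(m.values, basis_spectrum("parallel", basis).values)

    def test_even_mixture_is_pointwise_mean(self, basis):
        m = mix_spectra((0.5, 0.5, 0.0), basis, noise_sd=0.0)
        mean = 0.5 * (
            basis_spectrum("parallel", basis).values
            + basis_spectrum("hybrid", basis).values
        )
        assert np.allclose(m.values, mean)

    def test_off_simplex_rejected(self, basis):
        with pytest.raises(ValueError):
            mix_spectra((0.6, 0.6, 0.0), basis)
        with pytest.raises(ValueError):
            mix_spectra((1.2, -0.2, 0.0), basis)

    def test_r_monotone_along_parallel_antiparallel_edge(self, basis):
        rs = [
            conformation_index(mix_spectra((f, 0.0, 1.0 - f), basis)).r
            for f in np.linspace(0.0, 1.0, 41)
        ]
        assert all(b > a for a, b in zip(rs, rs[1:]))

    def test_interior_r_bounded_by_edge_mixtures(self, basis):
        # linearity: r of an interior point lies between r values reached on
        # the edges through the same parallel fraction
        f = (0.4, 0.35, 0.25)
        r_mix = conformation_index(mix_spectra(f, basis)).r
        r_edge_h = conformation_index(mix_spectra((0.4, 0.6, 0.0), basis)).r
        r_edge_a = conformation_index(mix_spectra((0.4, 0.0, 0.6), basis)).r
        lo, hi = sorted((r_edge_h, r_edge_a))
        assert lo <= r_mix <= hi

    def test_seeded_noise_is_reproducible(self, basis):
        a = mix_spectra((0.3, 0.3, 0.4), basis, noise_sd=0.05, rng=123)
        b = mix_spectra((0.3, 0.3, 0.4), basis, noise_sd=0.05, rng=123)
        assert np.array_equal(a.values, b.values)


class TestSynthMelting:
    def test_theta_is_half_at_tm(self):
        p = TwoStateParams(tm_true=55.0, dH=-40.0)
        assert folded_fraction(p, np.array([55.0]))[0] == pytest.approx(0.5)

    def test_theta_monotone_decreasing(self):
        p = TwoStateParams(tm_true=55.0, dH=-40.0)
        theta = folded_fraction(p, np.arange(20.0, 95.0, 0.5))
        assert np.all(np.diff(theta) < 0)
        assert theta[0] > 0.95 and theta[-1] < 0.05

    def test_compute_tm_recovers_generator_parameter(self):
        p = TwoStateParams(
            tm_true=55.0, dH=-40.0,
            baseline_folded=(1.0, 0.0), baseline_unfolded=(0.75, 0.0),
        )
        assert compute_tm(synth_melting(p)).tm == pytest.approx(55.0, abs=0.5)

    def test_steeper_enthalpy_narrows_derivative_peak(self):
        widths = {}
        for dH in (-30.0, -60.0):
            p = TwoStateParams(tm_true=55.0, dH=dH)
            c = synth_melting(p)
            d = np.abs(first_derivative(c, 1))
            above = c.temperatures[d >= 0.5 * d.max()]
            widths[dH] = above[-1] - above[0]
        assert widths[-60.0] < widths[-30.0]

    def test_positive_enthalpy_rejected(self):
        with pytest.raises(ValueError):
            TwoStateParams(tm_true=55.0, dH=10.0)

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            synth_melting(TwoStateParams(tm_true=25.0), grid=np.array([20.0, 25, 30, 35]))


class TestFlankingEffectModel:
    def test_saturation_halves_per_nucleotide(self):
        assert saturation(0) == 0.0
        assert saturation(1) == 0.5
        assert saturation(2) == 0.75
        assert saturation(5) == pytest.approx(1 - 2.0**-5)

    def test_shift_closed_form(self):
        eff = FlankingEffectModel(shift5=0.3, shift3=0.05)
        hybrid_baseline = (0.2, 0.6, 0.2)
        shifted5 = eff.shifted(hybrid_baseline, 2, 0, "a1c")  # sensitivity 1.0
        shifted3 = eff.shifted(hybrid_baseline, 0, 2, "a1c")
        assert shifted5[0] - 0.2 == pytest.approx(0.3 * 0.75)
        assert shifted3[0] - 0.2 == pytest.approx(0.05 * 0.75)
        assert shifted5.sum() == pytest.approx(1.0)

    def test_shift_clipped_to_simplex(self):
        eff = FlankingEffectModel(shift5=0.9, shift3=0.0)
        out = eff.shifted((0.8, 0.1, 0.1), 5, 0, "a1c")
        assert out[0] <= 1.0 and np.all(out >= 0)
        assert out.sum() == pytest.approx(1.0)

    def test_asymmetry_enforced(self):
        with pytest.raises(ValueError):
            FlankingEffectModel(shift5=0.1, shift3=0.2)

    def test_zero_shift_allowed(self):
        eff = FlankingEffectModel(shift5=0.0, shift3=0.0)
        out = eff.shifted((0.3, 0.4, 0.3), 2, 2, "a1c")
        assert np.allclose(out, (0.3, 0.4, 0.3))


class TestSynthExperiment:
    def pairs(self, n=12):
        return make_pairs(enumerate_loop_multisets(), "DT2", n)

    def test_bitwise_reproducible(self):
        a = synth_experiment(self.pairs(), FlankingEffectModel(seed=5))
        b = synth_experiment(self.pairs(), FlankingEffectModel(seed=5))
        assert a.manifest.equals(b.manifest)
        assert a.truth.equals(b.truth)
        for sid in a.spectra:
            assert np.array_equal(a.spectra[sid].values, b.spectra[sid].values)

    def test_truth_fractions_on_simplex(self):
        exp = synth_experiment(self.pairs(), FlankingEffectModel(seed=6))
        f = exp.truth[["f_parallel", "f_hybrid", "f_antiparallel"]].to_numpy()
        assert np.all(f >= 0)
        assert np.allclose(f.sum(axis=1), 1.0)

    def test_planted_category_ordering_recovered(self):
        """The 1bc category is built least sensitive; the recovered mean Δr
        ordering must match (a1c, ab1 above 1bc)."""
        exp = synth_experiment(
            make_pairs(enumerate_loop_multisets(), "5'T2"),
            FlankingEffectModel(seed=8),
        )
        man = exp.manifest
        deltas = {}
        for cat in ("1bc", "a1c", "ab1"):
            ds = []
            for pid, sub in man.groupby("pair_id"):
                bare = sub[(sub.flank5 == "") & (sub.flank3 == "")].iloc[0]
                if exp.truth[exp.truth.sample_id == bare.sample_id].category.iloc[0] != cat:
                    continue
                flanked = sub[(sub.flank5 != "") | (sub.flank3 != "")].iloc[0]
                r_b = conformation_index(exp.spectra[bare.sample_id]).r
                r_f = conformation_index(exp.spectra[flanked.sample_id]).r
                ds.append(r_f - r_b)
            deltas[cat] = np.mean(ds)
        assert deltas["a1c"] > deltas["1bc"]
        assert deltas["ab1"] > deltas["1bc"]

    def test_unpaired_designs_rejected(self):
        from g4flank.design import parse_name

        bare = parse_name("136")
        with pytest.raises(ValueError):
            synth_experiment([(bare, bare)], FlankingEffectModel())

    def test_written_files_round_trip(self, tmp_path):
        from g4flank.spectra import read_spectrum

        exp = synth_experiment(self.pairs(4), FlankingEffectModel(seed=9))
        manifest_path = exp.write(tmp_path)
        assert manifest_path.exists()
        import pandas as pd

        man = pd.read_csv(manifest_path, dtype=str, keep_default_na=False)
        row = man.iloc[0]
        s = read_spectrum(tmp_path / row.spectrum_file)
        assert np.allclose(s.values, exp.spectra[row.sample_id].values)
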