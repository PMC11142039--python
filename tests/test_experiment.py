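import warnings

import numpy as np
import pytest

from headbem import (
    Dipole,
    ExperimentConfig,
    build_phantom_3,
    build_phantom_5,
    canonical_dipoles,
    electrode_voltages,
    fibonacci_layout,
    nesting_check,
    phantom_variant,
    place_dipole,
    project_to_skin,
    run_study,
    solve_charges,
)
from headbem.experiment import model_comparison_3layer
from headbem.headmodel import ConductivitySet
from headbem.inverse import SingleDipoleModel


@pytest.fixture(scope="module")
def phantom5():
    return build_phantom_5(n_subdiv=2)


class TestPlaceDipole:
    def test_midcortical_radius(self, phantom5):
        # GM 78 mm, WM 70 mm -> halfway at 74 mm
        d = place_dipole(phantom5, [0, 0, 1], depth_fraction=0.5,
                         orientation="radial")
        assert np.linalg.norm(d.position) == pytest.approx(0.074, rel=1e-3)

    def test_radial_moment_along_nearest_gm_normal(self, phantom5):
        d = place_dipole(phantom5, [0, 0, 1], orientation="radial")
        gm = phantom5.interfaces[-2]
        d2 = np.einsum("mk,mk->m", gm.facet_centroid - d.position,
                       gm.facet_centroid - d.position)
        n = gm.facet_normal[int(np.argmin(d2))]
        np.testing.assert_allclose(d.moment / np.linalg.norm(d.moment), n,
                                   atol=1e-12)
        # which is radial up to the facet tilt of this resolution
        cos = d.moment @ d.position / (
            np.linalg.norm(d.moment) * np.linalg.norm(d.position)
        )
        assert cos > 0.98

    def test_tangential_moment_perpendicular(self, phantom5):
        d = place_dipole(phantom5, [0.3, 0.2, 0.93], orientation="tangential")
        gm = phantom5.interfaces[-2]
        d2 = np.einsum("mk,mk->m", gm.facet_centroid - d.position,
                       gm.facet_centroid - d.position)
        n = gm.facet_normal[int(np.argmin(d2))]
        assert abs(d.moment @ n) <= 1e-12 * np.linalg.norm(d.moment)

    def test_local_sigma_is_gm_for_cortical_wm_for_deep(self, phantom5):
        mid = place_dipole(phantom5, [0, 0, 1], depth_fraction=0.5)
        assert mid.local_sigma == phantom5.sigma_in[3]
        deep = place_dipole(phantom5, [0, 0, 1], radius_m=0.45 * 0.070)
        assert deep.local_sigma == phantom5.sigma_in[4]

    def test_invalid_depth_fraction(self, phantom5):
        with pytest.raises(ValueError):
            place_dipole(phantom5, [0, 0, 1], depth_fraction=1.5)

    def test_canonical_set(self):
        specs = canonical_dipoles()
        assert set(specs) == {"dip1", "dip2", "dip3", "dip4"}
        # all mid-cortical; montage depth increases dip1/2 -> dip3 -> dip4
        assert all(v["placement"] == ("cortical", 0.5)
                   for v in specs.values())
        z = {k: v["direction"][2] for k, v in specs.items()}
        assert z["dip4"] < z["dip3"] < min(z["dip1"], z["dip2"])


class TestPhantomVariants:
    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_nesting_preserved(self, seed):
        cfg = ExperimentConfig(seed=seed)
        rng = np.random.default_rng(seed)
        radii, centers = phantom_variant(cfg, rng)
        assert np.all(np.diff(radii) < 0)
        m = build_phantom_5(radii, "ITIS7", 1, centers_mm=centers)
        ok, msg = nesting_check(m)
        assert ok, msg

    def test_jitter_magnitudes_bounded(self):
        cfg = ExperimentConfig(seed=5)
        rng = np.random.default_rng(5)
        radii, centers = phantom_variant(cfg, rng)
        base = np.asarray(cfg.radii_5_mm)
        assert np.all(np.abs(np.asarray(radii) - base) / base < 0.05)
        assert max(np.linalg.norm(c) for c in centers) < 2.5  # mm


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = ExperimentConfig(n_variants=2, seed=42,
                               conductivity_sets=("VWB",))
        path = tmp_path / "c.yaml"
        cfg.to_yaml(path)
        back = ExperimentConfig.from_yaml(path)
        assert back == cfg

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text("n_variants: 2\nbogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            ExperimentConfig.from_yaml(path)

    def test_unknown_conductivity_set_rejected(self):
        cfg = ExperimentConfig(conductivity_sets=("ITIS", "XXX"))
        with pytest.raises(ValueError, match="XXX"):
            cfg.validate()


TINY = dict(
    n_variants=1, conductivity_sets=("ITIS",), dipoles=("dip1",),
    n_electrodes=32, n_subdiv_forward=1, n_subdiv_inverse=1,
    amr_max_steps=2, seed=11,
)


class TestRunStudy:
    def test_determinism_bit_identical(self):
        cfg = ExperimentConfig(**TINY)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = run_study(cfg)
            r2 = run_study(ExperimentConfig(**TINY))
        assert r1.per_case.to_csv() == r2.per_case.to_csv()
        assert r1.aggregate.to_csv() == r2.aggregate.to_csv()

    def test_report_structure_and_aggregates(self, tmp_path):
        cfg = ExperimentConfig(**{**TINY, "out_dir": str(tmp_path / "out")})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = run_study(cfg)
        assert set(rep.per_case.condition) == {"amr", "no-amr"}
        assert (rep.aggregate["mm_std"] >= 0).all()
        for (dip, cond), row in rep.aggregate.iterrows():
            sub = rep.per_case.query("dipole == @dip and condition == @cond").mm
            assert sub.min() - 1e-12 <= row.mm_mean <= sub.max() + 1e-12
        assert (tmp_path / "out" / "per_case.tsv").exists()
        assert (tmp_path / "out" / "config.yaml").exists()

    def test_matched_conductivity_pairing(self):
        from headbem.experiment import _COND_PAIRS

        for fam, (c5, c3) in _COND_PAIRS.items():
            assert c5.endswith("7") and c3.endswith("3")
            assert c5[:-1] == c3[:-1]


class TestDegenerateEquivalence:
    def test_five_layer_reduces_to_three_when_contrasts_vanish(self):
        """A 5-layer phantom whose CSF/GM/WM all share the BRAIN
        conductivity is electromagnetically a 3-layer model: fitting its
        EEG with the 3-layer model recovers the dipole to sub-mm."""
        sig3 = {"SKIN": 0.147, "SKULL": 0.0179, "BRAIN": 0.375}
        cond5 = ConductivitySet("degenerate", {
            "skin": sig3["SKIN"], "skull": sig3["SKULL"],
            "csf": sig3["BRAIN"], "gm": sig3["BRAIN"], "wm": sig3["BRAIN"],
        })
        m5 = build_phantom_5(conductivities=cond5, n_subdiv=2)
        m3 = build_phantom_3(conductivities=ConductivitySet("b3", sig3),
                             n_subdiv=2)
        dirs = fibonacci_layout(64, 0.65)
        el5 = project_to_skin(dirs, m5.interfaces[0])
        el3 = project_to_skin(dirs, m3.interfaces[0])
        dip = place_dipole(m5, [0.2, 0.1, 0.95], orientation="radial",
                           magnitude=2e-8)
        V = electrode_voltages(solve_charges(m5, dip), el5)
        res = SingleDipoleModel(V, m3, el3).fit(
            strategy="truth", seed_position=dip.position
        )
        err = res.error_vs(dip)
        assert err.distance_mm < 1.0
        assert err.rv < 1e-6


class TestModelComparison:
    def test_exact_self_consistency_without_amr(self):
        cfg = ExperimentConfig(**TINY)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = model_comparison_3layer(cfg)
        noamr = rep.per_case.query("condition == 'no-amr'")
        assert (noamr.mm < 1e-3).all()  # machine-precision recovery
        assert (noamr.rv < 1e-12).all()
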