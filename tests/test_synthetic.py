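"""Synthetic molecule generator: kernels, fields, labels, manifests."""

import numpy as np
import pandas as pd
import pytest

from voxhazard.cube import MoleculeGeometry, read_cube
from voxhazard.synthetic import (GenerationError, PaletteEntry, SyntheticConfig,
                                 default_grid_spec, electronegativity_field,
                                 generate_dataset, generate_molecule,
                                 generate_sample, promolecular_density)


def _point_grid_spec(points_shape=(3, 3, 3), step=1.0, origin=(-1.0, -1.0, -1.0)):
    return np.array(origin), np.eye(3) * step, points_shape


class TestGenerateMolecule:
    def test_deterministic_per_seed(self, tiny_synthetic_config):
        g1, l1 = generate_molecule(tiny_synthetic_config, 42)
        g2, l2 = generate_molecule(tiny_synthetic_config, 42)
        assert l1 == l2
        assert g1.atomic_numbers == g2.atomic_numbers
        np.testing.assert_array_equal(g1.positions, g2.positions)

    def test_single_element_palette_never_prohibited(self):
        config = SyntheticConfig(
            n_atoms_range=(1, 1),
            element_palette=(PaletteEntry(6, 1.0, 2.55),),
        )
        for seed in range(10):
            _, label = generate_molecule(config, seed)
            assert label == 1  # the motif needs two distinct elements

    def test_respects_min_separation(self, tiny_synthetic_config):
        geom, _ = generate_molecule(tiny_synthetic_config, 3)
        d = np.linalg.norm(
            geom.positions[:, None] - geom.positions[None, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() >= tiny_synthetic_config.min_atom_separation

    def test_forced_motif_labels_prohibited(self, two_element_palette):
        # box so tight that the two atoms must sit within the motif radius
        config = SyntheticConfig(
            n_atoms_range=(2, 2), box_edge=10.0, placement_margin=3.5,
            element_palette=two_element_palette, min_atom_separation=2.0,
            motif_distance=4.0,
        )
        labels = []
        for seed in range(30):
            geom, label = generate_molecule(config, seed)
            if len(set(geom.atomic_numbers)) == 2:
                # inner box has edge 3: any H-F pair is within 4 Bohr... only
                # when both elements present; mixed-element draws must be 0
                d = np.linalg.norm(geom.positions[0] - geom.positions[1])
                if d <= 4.0:
                    labels.append(label)
        assert labels and all(l == 0 for l in labels)

    def test_impossible_packing_raises(self):
        config = SyntheticConfig(
            n_atoms_range=(10, 10), box_edge=8.2, placement_margin=4.0,
            min_atom_separation=2.0, max_placement_attempts=20,
        )
        with pytest.raises(GenerationError):
            generate_molecule(config, 0)

    def test_label_balance_band(self):
        # sanity band on the planted-signal prevalence under the defaults
        config = SyntheticConfig()
        labels = [generate_molecule(config, s)[1] for s in range(2000)]
        prohibited = 1.0 - np.mean(labels)
        assert 0.3 <= prohibited <= 0.7


class TestPromolecularDensity:
    def test_single_atom_closed_form(self):
        geom = MoleculeGeometry((6,), (6.0,), np.zeros((1, 3)))
        spec = _point_grid_spec((3, 3, 5))
        grid = promolecular_density(geom, spec, widths={6: 1.0})
        # voxel (1, 1, 3): position (0, 0, 2), distance 2.0 from the atom
        pos = spec[0] + np.array([1, 1, 3]) @ spec[1]
        assert np.linalg.norm(pos) == pytest.approx(2.0)
        assert grid.values[1, 1, 3] == pytest.approx(6 * np.exp(-2.0), rel=1e-12)
        assert grid.values[1, 1, 3] == pytest.approx(0.8120, abs=5e-5)

    def test_far_field_decay(self):
        geom = MoleculeGeometry((8,), (8.0,), np.zeros((1, 3)))
        spec = (np.array([25.0, 0.0, 0.0]), np.eye(3), (2, 2, 2))
        grid = promolecular_density(geom, spec, widths={8: 1.0})
        assert grid.values.max() < 1e-7 * 8

    def test_mirror_symmetry(self):
        geom = MoleculeGeometry((6, 6), (6.0, 6.0),
                                np.array([[-1.5, 0, 0], [1.5, 0, 0]]))
        origin = np.array([-2.0, -2.0, -2.0])
        spec = (origin, np.eye(3), (5, 5, 5))
        grid = promolecular_density(geom, spec, widths={6: 0.8})
        np.testing.assert_allclose(grid.values, grid.values[::-1], atol=1e-10)

    def test_additivity_removing_an_atom_never_increases(self, rng):
        pos = rng.uniform(-2, 2, (4, 3))
        geom_all = MoleculeGeometry((6,) * 4, (6.0,) * 4, pos)
        geom_sub = MoleculeGeometry((6,) * 3, (6.0,) * 3, pos[:3])
        spec = _point_grid_spec((6, 6, 6), 0.8, (-2, -2, -2))
        full = promolecular_density(geom_all, spec, widths={6: 1.0})
        sub = promolecular_density(geom_sub, spec, widths={6: 1.0})
        assert np.all(full.values >= sub.values)
        assert np.all(full.values >= 0)


class TestElectronegativityField:
    def test_single_atom_constant(self):
        geom = MoleculeGeometry((8,), (8.0,), np.zeros((1, 3)))
        grid = electronegativity_field(geom, _point_grid_spec(),
                                       chis={8: 3.44}, widths={8: 1.0})
        np.testing.assert_allclose(grid.values, 3.44, rtol=1e-12)

    def test_midpoint_of_equal_width_pair_is_mean(self):
        geom = MoleculeGeometry((6, 8), (6.0, 8.0),
                                np.array([[-1.0, 0, 0], [1.0, 0, 0]]))
        spec = (np.array([0.0, 0.0, 0.0]), np.eye(3), (1, 1, 1))
        grid = electronegativity_field(geom, spec, chis={6: 2.2, 8: 3.0},
                                       widths={6: 1.0, 8: 1.0})
        assert grid.values[0, 0, 0] == pytest.approx(2.6, rel=1e-12)

    def test_bounded_by_palette_extremes(self, rng):
        pos = rng.uniform(-3, 3, (5, 3))
        zs = (1, 9, 6, 8, 7)
        geom = MoleculeGeometry(zs, tuple(float(z) for z in zs), pos)
        chis = {1: 2.2, 6: 2.55, 7: 3.04, 8: 3.44, 9: 3.98}
        grid = electronegativity_field(
            geom, _point_grid_spec((8, 8, 8), 1.0, (-3.5, -3.5, -3.5)),
            chis=chis, widths={z: 1.0 for z in zs})
        assert grid.values.min() >= 2.2 - 1e-12
        assert grid.values.max() <= 3.98 + 1e-12


class TestGenerateDataset:
    def test_files_manifest_and_determinism(self, tiny_synthetic_config, tmp_path):
        m1 = generate_dataset(6, tiny_synthetic_config, tmp_path / "a")
        m2 = generate_dataset(6, tiny_synthetic_config, tmp_path / "b")
        assert len(m1) == 6
        assert set(m1.columns) == {"id", "density_path", "en_path", "label"}
        assert set(m1["label"]) <= {0, 1}
        assert len(list((tmp_path / "a").glob("*.cube"))) == 12
        pd.testing.assert_frame_equal(m1, m2)  # relative paths: byte-identical
        text1 = (tmp_path / "a" / "manifest.csv").read_text()
        text2 = (tmp_path / "b" / "manifest.csv").read_text()
        assert text1 == text2

    def test_cubes_round_trip_fields(self, tiny_synthetic_config, tmp_path):
        generate_dataset(2, tiny_synthetic_config, tmp_path)
        sample = generate_sample(tiny_synthetic_config, tiny_synthetic_config.seed)
        _, grid = read_cube(tmp_path / "mol00000_density.cube")
        np.testing.assert_allclose(grid.values, sample.density.values, rtol=1e-6)

    def test_grid_spec_centers_box(self, tiny_synthetic_config):
        origin, axes, shape = default_grid_spec(tiny_synthetic_config)
        edge = tiny_synthetic_config.box_edge
        step = edge / shape[0]
        assert origin[0] == pytest.approx(-edge / 2 + step / 2)
        # last voxel center mirrors the first
        last = origin + (np.array(shape) - 1) @ axes
        np.testing.assert_allclose(last, -origin, atol=1e-12)


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(n_atoms_range=(0, 3))
    with pytest.raises(ValueError):
        SyntheticConfig(element_palette=())
    with pytest.raises(ValueError):
        SyntheticConfig(min_atom_separation=0.0)
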