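"""STAR reading/pairing/writing round trips and pairing set semantics."""

import numpy as np
import pandas as pd
import pytest

import rotascape as rs
from rotascape._star import read_star, write_star

CLASS_MAP = {"class": "rotClassLabel"}


def _write_half_star(path, ids, angles, extra_cols=None):
    df = pd.DataFrame({
        "rlnImageName": ids,
        "rlnAngleRot": [a[0] for a in angles],
        "rlnAngleTilt": [a[1] for a in angles],
        "rlnAnglePsi": [a[2] for a in angles],
    })
    for name, values in (extra_cols or {}).items():
        df[name] = values
    write_star({"particles": df}, path)
    return path


class TestStarFormat:
    def test_loop_round_trip(self, tmp_path):
        df = pd.DataFrame({"rlnImageName": ["a", "b"], "rlnAngleRot": [1.5, -3.25]})
        write_star({"particles": df}, tmp_path / "x.star")
        back = read_star(tmp_path / "x.star")["particles"]
        assert list(back.columns) == list(df.columns)
        assert np.allclose(back["rlnAngleRot"], df["rlnAngleRot"])

    def test_key_value_block_round_trip(self, tmp_path):
        meta = pd.Series({"rlnVoltage": 300, "rlnSphericalAberration": 2.7})
        write_star({"general": meta, "particles": pd.DataFrame({"a": [1]})},
                   tmp_path / "x.star")
        back = read_star(tmp_path / "x.star")
        assert back["general"]["rlnVoltage"] == 300

    def test_optics_block_passthrough(self, tmp_path):
        optics = pd.DataFrame({"rlnOpticsGroup": [1], "rlnImagePixelSize": [1.07]})
        particles = pd.DataFrame({
            "rlnImageName": ["0001@s.mrcs"], "rlnAngleRot": [3.0],
            "rlnAngleTilt": [10.0], "rlnAnglePsi": [5.0], "rlnOpticsGroup": [1],
        })
        write_star({"optics": optics, "particles": particles}, tmp_path / "x.star")
        table = rs.read_particle_star(tmp_path / "x.star")
        assert table.optics is not None
        rs.write_particle_star(table, tmp_path / "y.star", body="condensing")
        again = read_star(tmp_path / "y.star")
        assert np.allclose(again["optics"]["rlnImagePixelSize"], [1.07])


class TestReadParticleStar:
    def test_reads_angles_verbatim(self, tmp_path):
        angles = [(0.0, 0.0, 0.0), (90.0, 0.0, 0.0), (0.0, 90.0, 0.0)]
        path = _write_half_star(tmp_path / "m.star", ["a", "b", "c"], angles)
        table = rs.read_particle_star(path)
        assert len(table) == 3
        got = table.df[["rot", "tilt", "psi"]].to_numpy()
        assert np.allclose(got, angles)

    def test_missing_column_named_in_error(self, tmp_path):
        df = pd.DataFrame({"rlnImageName": ["a"], "rlnAngleRot": [0.0],
                           "rlnAnglePsi": [0.0]})
        write_star({"particles": df}, tmp_path / "bad.star")
        with pytest.raises(rs.ColumnError, match="rlnAngleTilt"):
            rs.read_particle_star(tmp_path / "bad.star")

    def test_empty_block_warns(self, tmp_path):
        path = _write_half_star(tmp_path / "e.star", [], [])
        with pytest.warns(UserWarning, match="empty"):
            table = rs.read_particle_star(path)
        assert len(table) == 0

    def test_expansion_index_from_file_order(self, tmp_path):
        path = _write_half_star(tmp_path / "d.star", ["a", "b", "a", "b"],
                                [(0, 0, 0)] * 4)
        table = rs.read_particle_star(path)
        assert table.df["expansion_index"].tolist() == [0, 0, 1, 1]

    def test_write_read_round_trip_on_simulated_scene(self, tmp_path):
        truth = rs.default_scene(n=50, seed=1)
        paths = rs.simulate_scene(truth, tmp_path / "scene")
        first = rs.read_particle_star(paths["cond"], column_map=CLASS_MAP)
        rs.write_particle_star(first, tmp_path / "again.star",
                               body="condensing", column_map=CLASS_MAP)
        second = rs.read_particle_star(tmp_path / "again.star", column_map=CLASS_MAP)
        assert first.df["particle_id"].tolist() == second.df["particle_id"].tolist()
        for col in ("rot", "tilt", "psi"):
            assert np.allclose(first.df[col], second.df[col], atol=1e-6)


class TestPairRefinements:
    def test_identical_ids_pair_fully(self, tmp_path):
        rng = np.random.default_rng(0)
        ids = [f"{i:04d}@s" for i in range(100)]
        angles = rng.uniform(0, 90, (100, 3))
        mod = rs.read_particle_star(_write_half_star(tmp_path / "m.star", ids, angles))
        cond = rs.read_particle_star(_write_half_star(tmp_path / "c.star", ids, angles))
        paired = rs.pair_refinements(mod, cond)
        assert len(paired) == 100

    def test_disjoint_ids_error(self, tmp_path):
        mod = rs.read_particle_star(_write_half_star(tmp_path / "m.star", ["a"], [(0, 0, 0)]))
        cond = rs.read_particle_star(_write_half_star(tmp_path / "c.star", ["b"], [(0, 0, 0)]))
        with pytest.raises(ValueError, match="no shared identifiers"):
            rs.pair_refinements(mod, cond)

    def test_partial_overlap_order_independent(self, tmp_path):
        """80 shared of 100/90 ids pair identically regardless of row order."""
        rng = np.random.default_rng(1)
        ids_mod = [f"p{i}" for i in range(100)]
        ids_cond = [f"p{i}" for i in range(20, 110)]
        shared = sorted(set(ids_mod) & set(ids_cond))
        assert len(shared) == 80

        def half(path, ids, seed):
            order = np.random.default_rng(seed).permutation(len(ids))
            ids_shuffled = [ids[i] for i in order]
            return rs.read_particle_star(_write_half_star(
                path, ids_shuffled, rng.uniform(0, 90, (len(ids), 3))))

        paired1 = rs.pair_refinements(half(tmp_path / "m1.star", ids_mod, 2),
                                      half(tmp_path / "c1.star", ids_cond, 3))
        paired2 = rs.pair_refinements(half(tmp_path / "m2.star", ids_mod, 4),
                                      half(tmp_path / "c2.star", ids_cond, 5))
        assert len(paired1) == 80
        assert set(paired1.df["particle_id"]) == set(shared)
        assert set(paired1.df["particle_id"]) == set(paired2.df["particle_id"])

    def test_paired_size_bounded_by_smaller_input(self, tmp_path):
        rng = np.random.default_rng(6)
        mod = rs.read_particle_star(_write_half_star(
            tmp_path / "m.star", [f"p{i}" for i in range(30)], rng.uniform(0, 9, (30, 3))))
        cond = rs.read_particle_star(_write_half_star(
            tmp_path / "c.star", [f"p{i}" for i in range(10, 40)], rng.uniform(0, 9, (30, 3))))
        paired = rs.pair_refinements(mod, cond)
        assert len(paired) <= min(len(mod), len(cond))

    def test_empty_table_rejected(self, tmp_path):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            empty = rs.read_particle_star(_write_half_star(tmp_path / "e.star", [], []))
        full = rs.read_particle_star(_write_half_star(tmp_path / "f.star", ["a"], [(0, 0, 0)]))
        with pytest.raises(ValueError, match="empty"):
            rs.pair_refinements(empty, full)


class TestWriteParticleStar:
    def test_selected_body_angles_written(self, paired_small, tmp_path):
        paired, _ = paired_small
        rs.write_particle_star(paired, tmp_path / "cond.star", body="condensing")
        back = rs.read_particle_star(tmp_path / "cond.star")
        assert np.allclose(back.df[["rot", "tilt", "psi"]].to_numpy(),
                           paired.euler_cond(), atol=1e-6)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rs.write_particle_star(rs.ParticleTable(pd.DataFrame()), "/tmp/x.star")
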