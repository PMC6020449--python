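"""Statistical merging of dose files, tallies and phase spaces."""

import numpy as np
import pytest

from rtmc.errors import EvaluationError, FormatError
from rtmc.reducer import (
    BinaryDoseLayout,
    DoseGrid,
    PhaseSpace,
    merge_binary_dose,
    merge_column_tallies,
    merge_phsp,
    read_binary_dose,
    read_phsp,
    region_uncertainty,
    write_binary_dose,
    write_phsp,
)

LAYOUT = BinaryDoseLayout(header_bytes=16, n_values=4, precision="double")


def _write(path, dose, sigma, header=b"HDRHDRHDRHDRHDR\n", layout=LAYOUT):
    write_binary_dose(path, header, np.asarray(dose), np.asarray(sigma), layout)
    return path


class TestMergeBinaryDose:
    def test_equal_weight_error_propagation(self, tmp_path):
        f1 = _write(tmp_path / "a.bin", [1.0] * 4, [0.20] * 4)
        f2 = _write(tmp_path / "b.bin", [3.0] * 4, [0.20] * 4)
        grid = merge_binary_dose([f1, f2], LAYOUT, [1000, 1000])
        assert grid.dose.ravel()[0] == pytest.approx(2.0)
        assert grid.sigma.ravel()[0] == pytest.approx(0.1414213562, rel=1e-6)
        assert grid.histories == 2000

    def test_history_weighted_merge(self, tmp_path):
        f1 = _write(tmp_path / "a.bin", [2.0] * 4, [0.1] * 4)
        f2 = _write(tmp_path / "b.bin", [6.0] * 4, [0.3] * 4)
        grid = merge_binary_dose([f1, f2], LAYOUT, [3000, 1000])
        assert grid.dose.ravel()[0] == pytest.approx(3.0)
        assert grid.sigma.ravel()[0] == pytest.approx(0.1060660172, rel=1e-6)

    def test_single_file_identity_and_header_copy(self, tmp_path):
        f1 = _write(tmp_path / "a.bin", [1.5, 0.0, 2.5, 9.0], [0.1, 0.0, 0.2, 0.3])
        out = tmp_path / "m.bin"
        grid = merge_binary_dose([f1], LAYOUT, [500], out_path=out)
        h_in, d_in, s_in = read_binary_dose(f1, LAYOUT)
        h_out, d_out, s_out = read_binary_dose(out, LAYOUT)
        assert h_out == h_in
        assert np.array_equal(d_out, d_in) and np.array_equal(s_out, s_in)
        assert np.array_equal(grid.dose.ravel(order="F"), d_in)

    def test_size_mismatch_is_format_error(self, tmp_path):
        bad = tmp_path / "bad.bin"
        bad.write_bytes(b"\0" * 10)
        with pytest.raises(FormatError):
            merge_binary_dose([bad], LAYOUT, [10])

    def test_permutation_invariance(self, tmp_path):
        rng = np.random.default_rng(3)
        files, hists = [], []
        for k in range(4):
            files.append(_write(tmp_path / f"{k}.bin", rng.random(4), rng.random(4) * 0.1))
            hists.append(int(rng.integers(100, 5000)))
        a = merge_binary_dose(files, LAYOUT, hists)
        order = [2, 0, 3, 1]
        b = merge_binary_dose([files[i] for i in order], LAYOUT,
                              [hists[i] for i in order])
        assert np.allclose(a.dose, b.dose, rtol=1e-14)
        assert np.allclose(a.sigma, b.sigma, rtol=1e-12)

    def test_associativity(self, tmp_path):
        rng = np.random.default_rng(4)
        files, hists = [], []
        for k in range(3):
            files.append(_write(tmp_path / f"{k}.bin", rng.random(4), rng.random(4) * 0.1))
            hists.append(int(rng.integers(100, 5000)))
        whole = merge_binary_dose(files, LAYOUT, hists)
        ab = merge_binary_dose(files[:2], LAYOUT, hists[:2], out_path=tmp_path / "ab.bin")
        two_step = merge_binary_dose([tmp_path / "ab.bin", files[2]], LAYOUT,
                                     [sum(hists[:2]), hists[2]])
        assert np.allclose(whole.dose, two_step.dose, rtol=1e-12)
        assert np.allclose(whole.sigma, two_step.sigma, rtol=1e-6)


class TestColumnTallies:
    def _table(self, path, values, sigmas):
        lines = [
            f"{i} {i * 0.5} {v} {s}" for i, (v, s) in enumerate(zip(values, sigmas))
        ]
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_equal_weight_matches_binary_formula(self, tmp_path):
        f1 = self._table(tmp_path / "a.txt", [1.0, 2.0, 3.0], [0.2, 0.2, 0.2])
        f2 = self._table(tmp_path / "b.txt", [3.0, 4.0, 5.0], [0.2, 0.2, 0.2])
        merged = merge_column_tallies([f1, f2], [100, 100], [2], [3])
        assert np.allclose(merged[:, 2], [2.0, 3.0, 4.0])
        assert np.allclose(merged[:, 3], 0.1414213562, rtol=1e-6)
        assert np.allclose(merged[:, 0], [0, 1, 2])  # keys copied

    def test_single_file_identity(self, tmp_path):
        f1 = self._table(tmp_path / "a.txt", [1.0, 2.0, 3.0], [0.1, 0.1, 0.1])
        merged = merge_column_tallies([f1], [100], [2], [3])
        assert np.allclose(merged[:, 2], [1.0, 2.0, 3.0])

    def test_key_mismatch_reports_row(self, tmp_path):
        f1 = self._table(tmp_path / "a.txt", [1.0, 2.0], [0.1, 0.1])
        f2 = tmp_path / "b.txt"
        f2.write_text("0 0.0 1.0 0.1\n9 0.5 2.0 0.1\n")
        with pytest.raises(FormatError, match="row 1"):
            merge_column_tallies([f1, f2], [100, 100], [2], [3])


def _phsp(n_hist, n_particles, rng):
    uvw = rng.normal(size=(n_particles, 3))
    uvw /= np.linalg.norm(uvw, axis=1, keepdims=True)
    rec = np.column_stack([
        np.ones(n_particles),
        rng.random(n_particles) * 6.0,
        rng.random((n_particles, 3)) * 100.0,
        uvw,
        np.ones(n_particles),
    ])
    return PhaseSpace(n_original_histories=n_hist, records=rec)


class TestPhaseSpace:
    def test_merge_sums_histories_and_particles(self, tmp_path):
        rng = np.random.default_rng(5)
        write_phsp(_phsp(1000, 10, rng), tmp_path / "a")
        write_phsp(_phsp(3000, 30, rng), tmp_path / "b")
        merged = merge_phsp([tmp_path / "a", tmp_path / "b"], out_path=tmp_path / "m")
        assert merged.n_original_histories == 4000
        assert merged.n_particles == 40
        back = read_phsp(tmp_path / "m")
        assert back.n_particles == 40
        assert np.array_equal(back.records, merged.records)

    def test_single_file_round_trip_identical(self, tmp_path):
        rng = np.random.default_rng(6)
        p = _phsp(500, 17, rng)
        write_phsp(p, tmp_path / "a")
        merged = merge_phsp([tmp_path / "a"])
        assert np.array_equal(merged.records, read_phsp(tmp_path / "a").records)
        assert merged.n_original_histories == 500

    def test_record_layout_mismatch_rejected(self, tmp_path):
        rng = np.random.default_rng(7)
        write_phsp(_phsp(100, 5, rng), tmp_path / "a")
        p8 = _phsp(100, 5, rng)
        p8.fields = tuple(list(p8.fields)[:-1])  # 8-field dialect
        p8.records = p8.records[:, :-1]
        write_phsp(p8, tmp_path / "b")
        with pytest.raises(FormatError):
            merge_phsp([tmp_path / "a", tmp_path / "b"])

    def test_non_unit_directions_rejected(self):
        rec = np.zeros((1, 9))
        rec[0, 5:8] = (0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            PhaseSpace(n_original_histories=1, records=rec)


class TestRegionUncertainty:
    def _grid(self, dose, sigma):
        dose = np.asarray(dose, dtype=float).reshape(-1, 1, 1)
        sigma = np.asarray(sigma, dtype=float).reshape(-1, 1, 1)
        return DoseGrid(dose=dose, sigma=sigma, spacing_mm=(1, 1, 1),
                        origin_mm=(0, 0, 0), histories=100)

    def test_constant_relative_uncertainty(self):
        g = self._grid([10.0] * 8, [0.2] * 8)  # sigma/dose = 0.02
        assert region_uncertainty(g, np.ones_like(g.dose, bool), k=2) == pytest.approx(4.0)

    def test_zero_coverage_factor(self):
        g = self._grid([10.0] * 8, [0.1] * 8)
        assert region_uncertainty(g, np.ones_like(g.dose, bool), k=0) == 0.0

    def test_half_max_threshold_excludes_low_dose(self):
        g = self._grid([10.0, 1.0], [0.1, 0.5])
        assert region_uncertainty(g, np.ones_like(g.dose, bool), k=2) == pytest.approx(2.0)

    def test_empty_or_cold_mask_rejected(self):
        g = self._grid([1.0, 1.0], [0.1, 0.1])
        with pytest.raises(EvaluationError):
            region_uncertainty(g, np.zeros_like(g.dose, bool))
        g0 = self._grid([0.0, 0.0], [0.0, 0.0])
        with pytest.raises(EvaluationError):
            region_uncertainty(g0, np.ones_like(g0.dose, bool))
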