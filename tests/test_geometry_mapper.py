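"""Node apportionment, seed derivation and template parameter binding."""

import filecmp
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtmc.errors import FormattingError, InfeasibleError, TemplateError
from rtmc.geometry_mapper import (
    DistributionMode,
    ParameterDescriptor,
    ParameterKind,
    ParametrizedModel,
    WorkItem,
    assign_seeds,
    bind_parameters,
    distribute_work,
    largest_remainder,
)
from rtmc.rtplan_model import StaticBeam


def _beams(mus):
    return [
        StaticBeam(f"b{i}", 10.0 * i, 0.0, 0.0, (0, 0, 0),
                   (-10, 10, -10, 10), (-10.0, -10.0), (10.0, 10.0), mu)
        for i, mu in enumerate(mus)
    ]


def oracle_largest_remainder(weights, total, floors):
    """Transparent reference apportionment: explicit argmax loops.

    Same contract as ``largest_remainder`` but written with repeated scans
    instead of sorting, as an independent check of the fast path.
    """
    n = len(weights)
    wsum = float(sum(weights))
    quotas = [total * w / wsum if wsum > 0 else total / n for w in weights]
    counts = [int(q) for q in quotas]
    rem = [q - c for q, c in zip(quotas, counts)]
    given = [False] * n
    for _ in range(total - sum(counts)):
        best = None
        for i in range(n):
            if given[i]:
                continue
            if best is None or rem[i] > rem[best] + 1e-15:
                best = i
        counts[best] += 1
        given[best] = True
    while any(counts[i] < floors[i] for i in range(n)):
        needy = min(i for i in range(n) if counts[i] < floors[i])
        donor = None
        for j in range(n):
            if counts[j] <= floors[j]:
                continue
            if donor is None or counts[j] - quotas[j] > counts[donor] - quotas[donor] + 1e-15:
                donor = j
        counts[donor] -= 1
        counts[needy] += 1
    return counts


class TestDistribute:
    def test_mu_weighted_exact_proportions(self):
        items = distribute_work(_beams([50, 30, 20]), 10,
                                DistributionMode.MU_WEIGHTED, 1000)
        per_beam = {}
        for it in items:
            per_beam[it.beam_id] = per_beam.get(it.beam_id, 0) + 1
        assert per_beam == {"b0": 5, "b1": 3, "b2": 2}

    def test_mu_weighted_remainder_to_lowest_index(self):
        counts = largest_remainder([1, 1, 1], 4, floors=[1, 1, 1])
        assert counts == [2, 1, 1]

    def test_equal_even_split(self):
        items = distribute_work(_beams([5, 500, 50]), 6, DistributionMode.EQUAL, 600)
        nodes = {}
        hist = {}
        for it in items:
            nodes[it.beam_id] = nodes.get(it.beam_id, 0) + 1
            hist[it.beam_id] = hist.get(it.beam_id, 0) + it.histories
        assert nodes == {"b0": 2, "b1": 2, "b2": 2}
        assert hist == {"b0": 200, "b1": 200, "b2": 200}

    def test_floor_repair_keeps_every_beam_alive(self):
        counts = largest_remainder([100, 1, 1, 1, 1], 6, floors=[1] * 5)
        assert sum(counts) == 6
        assert min(counts) >= 1
        assert counts[0] == 2

    def test_history_conservation_and_positivity(self):
        items = distribute_work(_beams([13, 1, 7]), 9,
                                DistributionMode.MU_WEIGHTED, 12345)
        assert sum(it.histories for it in items) == 12345
        assert all(it.histories > 0 for it in items)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(InfeasibleError):
            distribute_work(_beams([1, 1, 1]), 2, DistributionMode.EQUAL, 100)

    @settings(deadline=None, max_examples=100)
    @given(data=st.data())
    def test_apportionment_matches_oracle(self, data):
        n_beams = data.draw(st.integers(1, 8))
        mus = data.draw(
            st.lists(st.floats(0.1, 100.0), min_size=n_beams, max_size=n_beams)
        )
        n_nodes = data.draw(st.integers(n_beams, 5 * n_beams))
        got = largest_remainder(mus, n_nodes, floors=[1] * n_beams)
        assert got == oracle_largest_remainder(mus, n_nodes, [1] * n_beams)
        assert sum(got) == n_nodes and min(got) >= 1
        # quota deviation bound, allowing one unit per beam forced to floor
        quotas = [n_nodes * m / sum(mus) for m in mus]
        n_floored = sum(1 for c in got if c == 1)
        for c, q in zip(got, quotas):
            if c > 1:
                assert abs(c - q) < 1 + n_floored


class TestSeeds:
    def test_deterministic(self):
        assert assign_seeds(3, 42) == assign_seeds(3, 42)
        assert assign_seeds(3, 42) != assign_seeds(3, 43)

    def test_bulk_distinctness_and_positivity(self):
        pairs = assign_seeds(10_000, 42)
        flat = [v for p in pairs for v in p]
        assert len(set(flat)) == 20_000
        assert min(flat) >= 1
        assert max(flat) < 2**31

    def test_single_pair(self):
        (pair,) = assign_seeds(1, 7)
        assert len(pair) == 2 and all(v >= 1 for v in pair)


@pytest.fixture()
def template_model(tmp_path):
    tdir = tmp_path / "template"
    tdir.mkdir()
    (tdir / "run.in").write_text(
        "# header line\n"
        "TITLE demo run\n"
        "GEOM untouched tokens here\n"
        "NHIST 1000 # trailing comment\n"
        "ANGLE 0.0\n"
        "BANKA 0.0 0.0 0.0\n"
    )
    (tdir / "aux.txt").write_text("completely untouched\n")
    descriptors = [
        ParameterDescriptor("run.in", ParameterKind.HISTORIES, line=4, token=2, fmt="%d"),
        ParameterDescriptor("run.in", ParameterKind.GANTRY, line=5, token=2, fmt="%8.3f"),
        ParameterDescriptor("run.in", ParameterKind.MLC_BANK_A, line=6, token=2, fmt="%.1f"),
    ]
    return ParametrizedModel(
        template_dir=tdir,
        descriptors=descriptors,
        executable=["true"],
        output_spec=[("*.out", "COLUMN_TEXT")],
    )


def _item(histories=250_000):
    return WorkItem(node_id=0, beam_id="b0", histories=histories, seeds=(11, 13))


def _beam(gantry=30.0):
    return StaticBeam("b0", gantry, 0.0, 0.0, (0, 0, 0), (-10, 10, -10, 10),
                      (-1.0, -2.0, -3.0), (1.0, 2.0, 3.0), 10.0)


class TestBinding:
    def test_token_substitution_and_formatting(self, template_model, tmp_path):
        bound = bind_parameters(template_model, _beam(), _item(), tmp_path / "bound")
        lines = (bound / "run.in").read_text().split("\n")
        assert lines[3] == "NHIST 250000 # trailing comment"
        assert lines[4] == "ANGLE   30.000"  # %8.3f keeps the printf width
        assert lines[5] == "BANKA -1.0 -2.0 -3.0"

    def test_binding_purity(self, template_model, tmp_path):
        bound = bind_parameters(template_model, _beam(), _item(), tmp_path / "bound")
        assert (bound / "aux.txt").read_text() == "completely untouched\n"
        orig = (template_model.template_dir / "run.in").read_text().split("\n")
        new = (bound / "run.in").read_text().split("\n")
        assert len(orig) == len(new)
        changed = [i for i, (a, b) in enumerate(zip(orig, new)) if a != b]
        assert changed == [3, 4, 5]  # only descriptor lines differ

    def test_idempotent_rebinding_with_same_values(self, template_model, tmp_path):
        b1 = bind_parameters(template_model, _beam(), _item(), tmp_path / "b1")
        b2 = bind_parameters(template_model, _beam(), _item(), tmp_path / "b2")
        assert (b1 / "run.in").read_text() == (b2 / "run.in").read_text()

    def test_width_overflow_raises(self, template_model, tmp_path):
        beam = _beam(gantry=123.456789)
        item = _item()
        desc = ParameterDescriptor("run.in", ParameterKind.GANTRY, line=5, token=2,
                                   fmt="%6.3f")
        model = ParametrizedModel(template_model.template_dir, [desc],
                                  ["true"], [("*.out", "COLUMN_TEXT")])
        with pytest.raises(FormattingError):
            bind_parameters(model, beam, item, tmp_path / "bound")

    def test_missing_locator_fails_before_writing(self, template_model, tmp_path):
        desc = ParameterDescriptor("run.in", ParameterKind.MLC_BANK_B, line=99,
                                   token=1, fmt="%.1f")
        model = ParametrizedModel(template_model.template_dir,
                                  template_model.descriptors + [desc],
                                  ["true"], [("*.out", "COLUMN_TEXT")])
        dest = tmp_path / "bound"
        with pytest.raises(TemplateError, match="line 99"):
            bind_parameters(model, _beam(), _item(), dest)
        assert not dest.exists()

    def test_placeholder_substitution(self, tmp_path):
        tdir = tmp_path / "t"
        tdir.mkdir()
        (tdir / "cfg.in").write_text("output = @OUT@\n")
        model = ParametrizedModel(
            tdir,
            [ParameterDescriptor("cfg.in", ParameterKind.OUTPUT_PATH,
                                 placeholder="@OUT@", fmt="%s")],
            ["true"], [("*.out", "COLUMN_TEXT")],
        )
        bound = bind_parameters(model, _beam(), _item(), tmp_path / "b",
                                extra={"OUTPUT_PATH": "dose.bin"})
        assert (bound / "cfg.in").read_text() == "output = dose.bin\n"
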