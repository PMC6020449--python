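"""Shared fixtures: synthetic DICOM cases, phantoms and toy-engine runs."""

import numpy as np
import pytest

from rtmc.ct_phantom import VoxelPhantom
from rtmc.fixtures import CaseKind, FixtureSpec, make_case
from rtmc.geometry_mapper import WorkItem, bind_parameters, load_model
from rtmc.rtplan_model import StaticBeam
from rtmc.toy_engine import create_toy_model, toy_mc_run


@pytest.fixture(scope="session")
def case_dirs(tmp_path_factory):
    """One generated fixture case per technique (CT + plan + structures)."""
    root = tmp_path_factory.mktemp("cases")
    out = {}
    for kind in CaseKind:
        spec = FixtureSpec(case_kind=kind, seed=11)
        out[kind] = make_case(spec, root / kind.value)
        out[kind]["spec"] = spec
    return out


@pytest.fixture(scope="session")
def water_phantom():
    """Homogeneous 16^3 water cube, 10 mm voxels, centered on the origin."""
    n = 16
    return VoxelPhantom(
        material=np.full((n, n, n), 1, dtype=int),
        density=np.ones((n, n, n)),
        spacing_mm=(10.0, 10.0, 10.0),
        origin_mm=(-75.0, -75.0, -75.0),
        material_names={1: "WATER"},
    )


@pytest.fixture()
def open_beam():
    """A 40x40 mm fully open static beam at gantry 0."""
    return StaticBeam(
        beam_id="b1",
        gantry_deg=0.0,
        collimator_deg=0.0,
        table_deg=0.0,
        isocenter_mm=(0.0, 0.0, 0.0),
        jaws_mm=(-20.0, 20.0, -20.0, 20.0),
        mlc_a_mm=(-20.0,) * 5,
        mlc_b_mm=(20.0,) * 5,
        mu=100.0,
    )


@pytest.fixture(scope="session")
def toy_runner(tmp_path_factory, water_phantom):
    """Factory running the toy engine in-process on the water phantom.

    Returns a callable ``run(histories, seeds, beam=None, **model_kw)``
    giving the bound directory after execution.
    """
    root = tmp_path_factory.mktemp("toyruns")
    counter = {"n": 0}
    models = {}

    def run(histories, seeds, beam=None, **model_kw):
        key = tuple(sorted(model_kw.items()))
        if key not in models:
            mdir = root / f"model_{len(models)}"
            manifest = create_toy_model(
                mdir, water_phantom, n_leaves=5, sad_mm=1e7, **model_kw
            )
            models[key] = load_model(manifest)
        model = models[key]
        if beam is None:
            beam = StaticBeam(
                "b1", 0.0, 0.0, 0.0, (0.0, 0.0, 0.0),
                (-20.0, 20.0, -20.0, 20.0), (-20.0,) * 5, (20.0,) * 5, 100.0,
            )
        counter["n"] += 1
        item = WorkItem(node_id=counter["n"], beam_id=beam.beam_id,
                        histories=histories, seeds=seeds)
        bound = root / f"run_{counter['n']}"
        bind_parameters(model, beam, item, bound)
        toy_mc_run(bound, phantom=water_phantom)
        return bound, model

    return run
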