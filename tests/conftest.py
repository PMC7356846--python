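"""Shared fixtures: the toy image-classification pipeline, built once.

The session-scoped fixtures run the full desk-scale pipeline (40-molecule
bromine-motif library, 27 poses each at 64x64 px, two replicates) so that
dataset, model, evaluation and end-to-end tests share one rendering and one
training pass.
"""

from __future__ import annotations

import pytest

from molsnap import chem_prep, datasets, fixtures, model
from molsnap.snapshot import SnapshotConfig

TOY_PIXELS = (64, 64)
TOY_EPOCHS = 10


@pytest.fixture(scope="session")
def toy_records():
    return fixtures.make_toy_library(fixtures.ToyLibrarySpec(n_per_class=20,
                                                             seed=1))


@pytest.fixture(scope="session")
def toy_conformers(toy_records):
    out = {}
    for rec in toy_records:
        if not rec.kept:
            continue
        conf = chem_prep.embed_3d(rec, seed=1)
        assert isinstance(conf, chem_prep.Conformer3D), \
            f"embedding failed for {rec.compound_id}"
        out[rec.compound_id] = conf
    return out


@pytest.fixture(scope="session")
def toy_dataset(toy_records, toy_conformers, tmp_path_factory):
    """(manifest, root, plan) for the rendered two-replicate image dataset."""
    root = tmp_path_factory.mktemp("toy_dataset")
    plan = datasets.build_replicates(
        datasets.partition_groups(toy_records, n_groups=11, seed=1))
    config = SnapshotConfig(pixel_size=TOY_PIXELS)
    manifest = datasets.emit_dataset(toy_records, toy_conformers, plan, root,
                                     config)
    return manifest, root, plan


@pytest.fixture(scope="session")
def trained_toy_models(toy_dataset):
    """Replicate id -> (handle, epoch records, replicate manifest view)."""
    manifest, root, _ = toy_dataset
    out = {}
    for rep_id in ("01", "02"):
        view = model.replicate_view(manifest, rep_id)
        handle, records = model.train(
            view, model.TrainConfig(epochs=TOY_EPOCHS, seed=1), root=root)
        out[rep_id] = (handle, records, view)
    return out
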