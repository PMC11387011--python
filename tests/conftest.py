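"""Shared fixtures: small simulated collections and micro-trained models.

Everything is generated programmatically at session start; sizes are kept
small (32-64 px images, tens of isolates) so the whole suite stays fast
while still exercising the real code paths.
"""

import numpy as np
import pytest

import mycotax as mt


@pytest.fixture(scope="session")
def small_tree():
    """A modest 6-rank taxonomy: 2 phyla down to 8 species."""
    return mt.generate_taxonomy([2, 3, 4, 5, 6, 8], 1.0, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_tree):
    """60 isolates at 32 px (48 px hires), mild inheritance decay, some
    missing labels and confounder marks; stratified 70/30 split."""
    recs = mt.sample_isolates(small_tree, 60, [0, 0, 0, 0, 0.1, 0.3], seed=1)
    mt.attach_morphology(small_tree, recs, inheritance_decay=0.2, seed=2)
    imgs, hires = mt.render_isolate_images(recs, 32, seed=3, hires_size=48,
                                           confounder_prob=0.3)
    table = mt.impute_missing_labels(mt.records_to_table(recs).reset_index(drop=True))
    part = mt.split_train_test(table["phylum"].to_numpy(), 0.7, seed=4)
    return mt.ColonyDataset(imgs, table, part, images_hires=hires, records=recs)


@pytest.fixture(scope="session")
def separable_dataset(small_tree):
    """90 isolates with inheritance_decay=0: the phylum fully determines the
    colony look, so phylum classification is solvable to MCC 1."""
    recs = mt.sample_isolates(small_tree, 90, [0] * 6, seed=11)
    mt.attach_morphology(small_tree, recs, inheritance_decay=0.0, seed=12)
    imgs, _ = mt.render_isolate_images(recs, 32, seed=13)
    table = mt.impute_missing_labels(mt.records_to_table(recs).reset_index(drop=True))
    part = mt.split_train_test(table["phylum"].to_numpy(), 0.7, seed=14)
    return mt.ColonyDataset(imgs, table, part, records=recs)


@pytest.fixture(scope="session")
def trained_phylum_model(separable_dataset):
    """SL phylum classifier trained to convergence on the separable set."""
    var = mt.DatasetVariant("original", separable_dataset)
    model, history = mt.train_sl(var, "phylum", mt.BackboneSpec(),
                                 mt.TrainingConfig(epochs=6, seed=5))
    return model, history


@pytest.fixture(scope="session")
def group_scan(small_tree):
    """One full 3x4 group scan with confounder marks on every dish."""
    recs = mt.sample_isolates(small_tree, 12, [0] * 6, seed=21)
    mt.attach_morphology(small_tree, recs, inheritance_decay=0.2, seed=22)
    return mt.render_group_scan(recs, layout=(3, 4), cell_px=130,
                                confounder_prob=1.0, seed=23)
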