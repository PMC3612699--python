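"""Shared fixtures.

The trained networks are expensive (minutes), so they are session-scoped
and shared between the learning, sweep, completion and semantics tests.
All conditions are fixed here: the 10-category synthetic-shape task at
32 px for recognition/occlusion work, and an 8-category clustered task at
24 px for the semantics experiments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import recurvis as rv
from recurvis.learning import RecurrentModel
from recurvis.network import lesion_feedback

MAIN_EPOCHS = 60          # uniform training protocol across all variants
SEM_EPOCHS = 40


@pytest.fixture(scope="session")
def main_dataset():
    spec = rv.SyntheticDatasetSpec(n_categories=10, exemplars_per_category=4,
                                   renders_per_exemplar=4, image_size=32,
                                   seed=42)
    manifest, images = rv.make_synthetic_dataset(spec)
    train_m, test_m = rv.split_train_test(manifest, 1, seed=0)
    return {"spec": spec, "manifest": manifest, "images": images,
            "train": train_m, "test": test_m}


@pytest.fixture(scope="session")
def blob32():
    # 0.10 fractions keep the filter-width : image ratio of the 144-px
    # protocol geometry once floored to a 32-px grid
    return rv.build_blob_filter(32, 0.10, 0.10)


@pytest.fixture(scope="session")
def trained_recurrent(main_dataset):
    d = main_dataset
    clf = rv.RecurrentVisualClassifier(epochs=MAIN_EPOCHS, seed=0)
    clf.fit(d["images"][d["train"].index], d["train"]["category"].values)
    return clf


@pytest.fixture(scope="session")
def trained_bp(main_dataset):
    d = main_dataset
    out = {}
    for variant in ("sparse", "distrib"):
        clf = rv.BackpropVisualClassifier(variant=variant, epochs=MAIN_EPOCHS,
                                          seed=0)
        clf.fit(d["images"][d["train"].index], d["train"]["category"].values)
        out[variant] = clf
    return out


@pytest.fixture(scope="session")
def model_variants(trained_recurrent, trained_bp):
    """The four comparison models: full recurrent net, the same net with
    top-down transmission lesioned, and the two backprop networks."""
    rec = trained_recurrent.model_
    nf = RecurrentModel(net=lesion_feedback(rec.net), bank=rec.bank,
                        categories=rec.categories, kwta_pct=rec.kwta_pct,
                        v1_gain=rec.v1_gain, max_cycles=rec.max_cycles,
                        tol=rec.tol)
    return {"recurrent": rec, "no_feedback": nf,
            "bp_sparse": trained_bp["sparse"].model_,
            "bp_distrib": trained_bp["distrib"].model_}


@pytest.fixture(scope="session")
def sweep_items(main_dataset):
    """One render per trained exemplar (30 items): the occlusion-sweep and
    completion test set, drawn from trained objects."""
    d = main_dataset
    sub = d["train"].groupby(["category", "exemplar"]).head(1)
    return sub.reset_index(drop=True), d["images"][sub.index]


@pytest.fixture(scope="session")
def sem_setup():
    """Clustered look-alike dataset + shaped semantic patterns + the pair
    of networks trained with and without semantic plus-phase clamping.
    Category cat007 is held out of training; its cluster mate cat006 is
    trained, which is what gives the inference test a visually similar
    trained neighbour."""
    spec = rv.SyntheticDatasetSpec(n_categories=8, exemplars_per_category=3,
                                   renders_per_exemplar=3, image_size=24,
                                   seed=7, cluster_of=(0, 0, 1, 1, 2, 2, 3, 3))
    manifest, images = rv.make_synthetic_dataset(spec)
    target = rv.make_target_dm(8, clusters=[[0, 1], [2, 3], [4, 5], [6, 7]])
    shaped = rv.shape_patterns(rv.init_patterns(8, 40, 0.25, seed=1), target,
                               max_iters=400, seed=2)
    patterns = shaped.patterns.astype(float)

    train_m = manifest[manifest["category"] != "cat007"]
    models = {}
    for use_sem in (True, False):
        clf = rv.RecurrentVisualClassifier(
            epochs=SEM_EPOCHS, seed=0, pool_size=4, v2_size=120, v2_k=30,
            it_size=80, it_k=16, semantics_units=40, semantics_k=10,
            use_semantics=use_sem)
        clf.fit(images[train_m.index], train_m["category"].values,
                semantic_patterns=patterns[:7])
        models["with" if use_sem else "without"] = clf
    return {"spec": spec, "manifest": manifest, "images": images,
            "train": train_m, "target": target, "patterns": patterns,
            "models": models, "shaped": shaped}
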