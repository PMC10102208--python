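"""Shared fixtures: a planted-signal cohort run end-to-end once per session.

The planted pipeline renders a 60-slide synthetic cohort whose label is the
presence of >= 2 tumor-texture regions, extracts tiny-backbone features,
fits the 10-cluster model on the training partition and trains the MIL
classifier — the fixture is reused by the training, interpretation and
acceptance tests to keep the suite fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pytest

from moma import clustering, features, preprocess, synthesis, training
from moma.mil import MILClassifier, ModelConfig


@dataclass
class PlantedPipeline:
    manifest: "object"
    bags: dict
    labels: dict
    tumor_tiles: dict
    cluster_model: clustering.ClusterModel
    model: MILClassifier
    log: "object"
    train_ids: list
    val_ids: list
    test_ids: list
    assignments: dict = field(default_factory=dict)

    def triples(self, ids):
        return [(self.bags[s], self.assignments[s], self.labels[s]) for s in ids]


@pytest.fixture(scope="session")
def planted_pipeline() -> PlantedPipeline:
    specs, manifest = synthesis.simulate_labeled_cohort(
        60, grid=(4, 4), tile_px=64, m_tumor=2, seed=3)
    cfg = preprocess.PreprocessConfig(tile_size_px=64)
    backbone = features.get_backbone("tiny", seed=0)
    bags, labels, tumor = {}, {}, {}
    for i, spec in enumerate(specs):
        sid = manifest.iloc[i]["slide_id"]
        img, _ = synthesis.render_slide(spec, seed=100 + i)
        tiles = [t for t in preprocess.tile_slide(img, cfg, slide_id=sid)
                 if t.is_tissue]
        bags[sid] = features.extract_features(tiles, backbone)
        labels[sid] = int(manifest.iloc[i]["label"])
        tumor[sid] = {tuple(rc) for rc in json.loads(manifest.iloc[i]["tumor_tiles"])}
    manifest = training.split_cohort(manifest, seed=1)
    ids = {p: manifest.loc[manifest["partition"] == p, "slide_id"].tolist()
           for p in ("train", "val", "test")}
    cluster_model = clustering.fit_clusters(
        [bags[s] for s in ids["train"]], K=10, seed=0, training_set="train")
    assignments = {s: clustering.assign_clusters(bags[s], cluster_model)
                   for s in bags}
    pipe = PlantedPipeline(manifest=manifest, bags=bags, labels=labels,
                           tumor_tiles=tumor, cluster_model=cluster_model,
                           model=None, log=None, train_ids=ids["train"],
                           val_ids=ids["val"], test_ids=ids["test"],
                           assignments=assignments)
    model, log = training.train_classifier(
        pipe.triples(ids["train"]), pipe.triples(ids["val"]),
        ModelConfig.tiny(), training.TrainConfig(epochs=50, seed=0))
    pipe.model, pipe.log = model, log
    return pipe


@pytest.fixture(scope="session")
def concept_model():
    from moma import interpret
    rng = np.random.default_rng(0)
    pairs = [(synthesis.make_concept_texture(c, 64, int(rng.integers(2**31))), c)
             for c in synthesis.CONCEPTS for _ in range(250)]
    return interpret.train_concept_classifier(pairs, seed=0)
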