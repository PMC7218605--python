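"""Shared fixtures.

The desk-scale experiment (synthetic corpus, 200-code vocabulary, default
coder trained on ~20k certificates) is expensive, so it is built once per
session and shared by every test that needs a trained model.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import mortcode as mc
from mortcode.certificate import Certificate
from mortcode.coder import TrainedCoder
from mortcode.config import RunConfig
from mortcode.oracle import CauseModel
from mortcode.pipeline import simulate_splits, train_coder


@pytest.fixture(scope="session")
def vocab():
    return mc.make_synthetic_vocabulary(20, 10, seed=1)


@pytest.fixture(scope="session")
def cause_model(vocab):
    return mc.make_cause_model(vocab, seed=1)


@dataclass
class DeskRun:
    config: RunConfig
    model: CauseModel
    train_set: list[Certificate]
    val_set: list[Certificate]
    test_set: list[Certificate]
    coder: TrainedCoder


@pytest.fixture(scope="session")
def desk_run() -> DeskRun:
    """Simulate the desk corpus and train the default coder once."""
    cfg = RunConfig(seed=1)
    model, train_set, val_set, test_set = simulate_splits(cfg)
    coder = train_coder(cfg, model.vocab, train_set, val_set)
    return DeskRun(cfg, model, train_set, val_set, test_set, coder)


def promotion_subset(certs, model):
    """Indices of certificates where a registered promotion pair fires."""
    out = []
    for i, c in enumerate(certs):
        p1 = {x for line in c.part1 for x in line}
        p2 = {x for line in c.part2 for x in line}
        if any(t in p2 and p in p1 for t, p, _ in model.promotion_pairs):
            out.append(i)
    return out
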