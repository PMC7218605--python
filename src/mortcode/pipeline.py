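"""Reproducible experiment driver: simulate -> train -> evaluate -> recode.

These functions are the library face of the command-line interface; the
acceptance and example scripts call them directly.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .certificate import Certificate
from .coder import TrainedCoder, build_model, predict_proba_batch, train
from .config import RunConfig
from .evaluation import BaselineComparison, EvalReport, compare_with_baseline, evaluate
from .oracle import (
    CauseModel,
    generate_dataset,
    make_cause_model,
    oracle_code,
)
from .recoding import count_by_group, recode, trajectory_comparison
from .vocabulary import Vocabulary, make_synthetic_vocabulary

__all__ = [
    "simulate_splits",
    "build_desk_model",
    "train_coder",
    "evaluate_coder",
    "harmonization_experiment",
]


def _year_seed(seed: int, year: int) -> int:
    return int((seed * 100003 + year * 7919 + 17) % (2**31 - 1))


def simulate_splits(
    config: RunConfig,
) -> tuple[CauseModel, list[Certificate], list[Certificate], list[Certificate]]:
    """Generate the synthetic corpus and split it per year.

    For each calendar year, ``certs_per_year`` labeled certificates are
    generated, then ``val_per_year`` and ``test_per_year`` of them are
    randomly excluded into the validation and test sets (mirroring a
    stratified exclusion per year, so the year covariate is identically
    distributed across splits); the remainder goes to training.
    Deterministic in ``config.seed``.
    """
    sp = config.simulate
    if sp.val_per_year + sp.test_per_year > sp.certs_per_year:
        raise ValueError("per-year exclusions exceed the per-year corpus size")
    vocab = make_synthetic_vocabulary(sp.n_chapters, sp.codes_per_chapter, config.seed)
    model = make_cause_model(vocab, config.generator, seed=config.seed)
    base = config.sampler.base_year
    train_set: list[Certificate] = []
    val_set: list[Certificate] = []
    test_set: list[Certificate] = []
    for year in range(base, base + config.sampler.n_years):
        sampler = replace(config.sampler, fixed_year=year)
        certs = generate_dataset(
            model, sp.certs_per_year, _year_seed(config.seed, year),
            demographics_sampler=sampler, id_prefix=f"y{year}-",
        )
        rng = np.random.default_rng(_year_seed(config.seed + 1, year))
        order = rng.permutation(sp.certs_per_year)
        n_val, n_test = sp.val_per_year, sp.test_per_year
        val_set.extend(certs[i] for i in order[:n_val])
        test_set.extend(certs[i] for i in order[n_val:n_val + n_test])
        train_set.extend(certs[i] for i in order[n_val + n_test:])
    return model, train_set, val_set, test_set


def build_desk_model(config: RunConfig, vocab: Vocabulary) -> TrainedCoder:
    mc = config.model.to_model_config(V=vocab.size, seed=config.seed)
    return build_model(mc, vocab)


def train_coder(
    config: RunConfig,
    vocab: Vocabulary,
    train_set: list[Certificate],
    val_set: list[Certificate],
) -> TrainedCoder:
    coder = build_desk_model(config, vocab)
    opt = replace(config.opt, seed=config.seed)
    return train(coder, train_set, val_set, vocab, opt)


def evaluate_coder(
    config: RunConfig,
    coder: TrainedCoder,
    model: CauseModel,
    test_set: list[Certificate],
) -> tuple[EvalReport, BaselineComparison, np.ndarray]:
    """Full test-set report plus the reject-aware baseline comparison.

    The rule-based oracle (with its reject behaviour enabled) plays the
    role of the production baseline coder, scored on the identical
    certificates and covariates as the neural coder.
    """
    vocab = model.vocab
    golds = [c.gold_ucd for c in test_set]
    probs = predict_proba_batch(coder, test_set, vocab)
    ev = config.evaluation
    report = evaluate(
        probs, golds, vocab,
        ks=ev.ks, bootstrap_B=ev.bootstrap_B,
        bootstrap_seed=config.seed, n_bins=ev.n_bins,
    )
    baseline = [oracle_code(c, model) for c in test_set]
    pred_idx = probs.argmax(axis=1)
    preds = [vocab.code_at(int(i)) for i in pred_idx]
    comparison = compare_with_baseline(preds, baseline, golds)
    return report, comparison, probs


def harmonization_experiment(
    config: RunConfig,
    coder: TrainedCoder,
    model: CauseModel,
    corpus: list[Certificate],
):
    """Original vs. recoded-at-fixed-year trajectories for the cause group
    affected by the simulated year rule change.

    Returns (original_table, recoded_table, comparison_frame); the
    comparison frame's ``attrs`` carry the max year-over-year jump of each
    source.
    """
    group = model.rule_change_group()
    years = [c.year for c in corpus]
    original = count_by_group(
        [c.gold_ucd for c in corpus], years, [group], source="original"
    )
    recoded_ucds = recode(coder, corpus, model.vocab, config.recode.fixed_year)
    recoded = count_by_group(recoded_ucds, years, [group], source="recoded")
    comparison = trajectory_comparison(original, recoded)
    return original, recoded, comparison
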