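"""End-to-end experiment pipelines built from the library stages.

These wire together the simulators and the two decoding chains exactly the
way the CLI does, and exist so that scripted experiments, the examples and
the test-bench all exercise one code path:

* :func:`mi_chain_report` — simulate a cued motor-imagery dataset, apply
  the spatial chain, featurize, 80/20 stratified split, z-score on the
  training split, fit one classifier and return its evaluation report.
* :func:`p300_experiment` — simulate a labelled training session and a
  separate test session, fit the phase-1 target/nontarget classifier, and
  decode the test text.
"""

from __future__ import annotations

import numpy as np

from . import mi_classify, mi_features, p300_chain, spatial_filters
from .eeg_core import (
    MOTOR_STRIP_21,
    EventKind,
    extract_epochs,
    montage_from_positions,
    standard_positions,
)
from .mi_classify import EvalReport, ModelSpec
from .synthetic_data import MISimConfig, P300SimConfig, simulate_mi_dataset

__all__ = ["mi_chain_report", "p300_experiment"]


def mi_chain_report(
    erd_depth: float,
    n_per_class: int,
    seed: int,
    algorithm: str = "LR",
    channel_labels: list[str] | None = None,
    fs: float = 250.0,
    trial_s: float = 3.0,
    train_fraction: float = 0.8,
    use_car: bool = True,
    laplacian_size: str | None = "small",
    feature_cfg: mi_features.FeatureConfig | None = None,
) -> EvalReport:
    """Full motor-imagery chain on one simulated dataset.

    The default montage is the built-in 21-electrode motor strip (FC/C/CP
    rows), which carries all the class-discriminative rhythm structure the
    generator produces.
    """
    labels = list(channel_labels or MOTOR_STRIP_21)
    sim = MISimConfig(
        n_channels=len(labels),
        channel_labels=labels,
        fs=fs,
        trial_s=trial_s,
        erd_depth=erd_depth,
        seed=seed,
    )
    rec, _ = simulate_mi_dataset(sim, n_per_class=n_per_class)
    epochs, _dropped = extract_epochs(rec, EventKind.MI_CUE, 0.0, trial_s)
    montage = (
        montage_from_positions(standard_positions(labels))
        if laplacian_size
        else None
    )
    epochs = [
        spatial_filters.apply_spatial(
            ep, montage=montage, use_car=use_car, laplacian_size=laplacian_size
        )
        for ep in epochs
    ]
    X, y, _layout, flagged = mi_features.featurize_epochs(epochs, feature_cfg)
    X, y = X[~flagged], np.asarray([lab.value for lab in y])[~flagged]
    X_tr, X_te, y_tr, y_te = mi_classify.split_dataset(
        X, y, train_fraction, seed=seed
    )
    norm = mi_features.fit_normalizer(X_tr)
    model = mi_classify.train_model(
        mi_features.apply_normalizer(X_tr, norm), y_tr, ModelSpec(algorithm, seed=seed)
    )
    return mi_classify.evaluate_model(
        model, mi_features.apply_normalizer(X_te, norm), y_te
    )


def p300_experiment(
    train_text: str,
    test_text: str,
    seed: int,
    sim_kw: dict | None = None,
    algorithm: str = "RF",
    max_repetitions: int | None = None,
) -> str:
    """Train the speller decoder on one simulated session and decode another.

    Returns the decoded string for ``test_text``.  ``sim_kw`` overrides
    :class:`P300SimConfig` fields for both sessions; the two sessions use
    distinct sub-seeds derived from ``seed``.
    """
    from .synthetic_data import simulate_p300_session

    sim_kw = dict(sim_kw or {})
    rec_train = simulate_p300_session(
        train_text, P300SimConfig(seed=2 * seed + 1, **sim_kw)
    )
    rec_test = simulate_p300_session(
        test_text, P300SimConfig(seed=2 * seed + 2, **sim_kw)
    )
    vectors = p300_chain.preprocess_session(rec_train)
    model = p300_chain.train_p300(vectors, ModelSpec(algorithm, seed=seed))
    return p300_chain.spell_session(
        rec_test, model, max_repetitions=max_repetitions
    )
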