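"""End-to-end synthetic benchmark: generate, train, classify, evaluate.

This is the package's stand-in for a recorded-data study: three
independent synthetic sessions (train / validation / held-out test) are
generated from the default class templates, the classifier is trained on
mirror-augmented features from the ground-truth training cycles, and the
full pipeline (calibration, filtering, peak-based cycle detection,
feature extraction, prediction) is run on the held-out session.  Detected
cycles are matched to ground truth by midpoint containment and scored
with a confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import preprocessing as _pre
from .classifier import ClassifierFit, MlpModel, SubTechniqueClassifier, TrainConfig
from .cycles import detect_cycles
from .evaluation import ConfusionMatrix, build_confusion
from .features import augment_mirror, extract_features, feature_matrix
from .io import CLASSES, Cycle, SubTechnique
from .synth import SessionPlan, SynthSession, generate_session

__all__ = [
    "BenchmarkResult",
    "featurize_session",
    "match_to_truth",
    "run_benchmark",
]


def featurize_session(session: SynthSession):
    """Extract 94-features for every ground-truth cycle of a session."""
    chest_f = _pre.gaussian_filter(session.chest_accel, _pre.FEATURE_FILTER)
    feats = [extract_features(chest_f, c) for c in session.cycles]
    return session.labeled_cycles(feats)


def match_to_truth(
    detected: list[tuple[Cycle, SubTechnique]],
    session: SynthSession,
) -> list[tuple[SubTechnique, SubTechnique]]:
    """Pair each detected cycle with the ground-truth label of the cycle
    containing its midpoint.  Detected cycles outside any ground-truth
    cycle (lead-in/out partials) are dropped; EXC predictions are kept so
    they land in the excluded tally."""
    starts = np.asarray([c.start for c in session.cycles])
    ends = np.asarray([c.end for c in session.cycles])
    pairs: list[tuple[SubTechnique, SubTechnique]] = []
    for cyc, pred in detected:
        mid = 0.5 * (cyc.start + cyc.end)
        j = int(np.searchsorted(starts, mid, side="right")) - 1
        if 0 <= j < len(session.cycles) and mid < ends[j]:
            pairs.append((session.labels[j], pred))
    return pairs


@dataclass
class BenchmarkResult:
    fit: ClassifierFit
    test_confusion: ConfusionMatrix
    n_test_truth: int
    n_test_detected: int

    @property
    def model(self) -> MlpModel:
        return self.fit.model

    @property
    def holdout_accuracy_pct(self) -> float:
        return float(self.test_confusion.accuracy())


def _plan(cycles_per_class: int, noise: float, seed: int, **kw) -> SessionPlan:
    return SessionPlan(
        blocks=[(c, cycles_per_class) for c in CLASSES],
        noise=noise,
        seed=seed,
        **kw,
    )


def run_benchmark(
    seed: int = 0,
    train_cycles_per_class: int = 200,
    val_cycles_per_class: int = 50,
    test_cycles_per_class: int = 50,
    noise: float = 0.1,
    train_config: TrainConfig | None = None,
) -> BenchmarkResult:
    """The default 8-class synthetic benchmark.

    Train and validation features come from ground-truth cycles (training
    features mirror-augmented); the test session is scored through the
    full detection pipeline on its raw sensor streams.
    """
    seed = int(seed) % (2**31 - 1)
    train_sess = generate_session(_plan(train_cycles_per_class, noise, seed))
    val_sess = generate_session(_plan(val_cycles_per_class, noise, seed + 1))
    test_sess = generate_session(
        _plan(test_cycles_per_class, noise, seed + 2, misalignment_deg=10.0)
    )

    train_set = augment_mirror(featurize_session(train_sess))
    val_set = featurize_session(val_sess)
    Xt, yt = feature_matrix(train_set)
    Xv, yv = feature_matrix(val_set)

    config = train_config or TrainConfig(seed=seed)
    fit = SubTechniqueClassifier(Xt, yt, Xv, yv).fit(config)

    from .classifier import classify_session  # local import avoids cycle at module load

    detected = classify_session(fit.model, test_sess.arm_gyro, test_sess.chest_accel)
    pairs = match_to_truth(detected, test_sess)
    cm = build_confusion(pairs)
    return BenchmarkResult(
        fit=fit,
        test_confusion=cm,
        n_test_truth=len(test_sess.cycles),
        n_test_detected=sum(1 for c, _ in detected if not c.partial),
    )
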