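"""Bootstrap null distributions of classification accuracy.

A random classifier is simulated B times against the fixed observed
labels: the *naive* mode draws labels uniformly over the four analysis
classes (so its accuracy converges on the 25% chance level), the
*weighted* mode draws with probabilities equal to the observed class
frequencies (converging on sum(p_k^2)).  The 2.5th-97.5th percentile
interval of the replicate accuracies is the null band a fitted model's
training accuracy is compared against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .design import CLASS_ORDER
from .errors import EmptyCohortError, InvalidParameterError

__all__ = ["NullAccuracyResult", "null_accuracy", "compare_to_model"]


@dataclass(frozen=True)
class NullAccuracyResult:
    """Bootstrap accuracy distribution for one null-classifier mode."""

    mode: str
    replicates: int
    accuracies: np.ndarray
    ci: tuple[float, float]
    seed: int
    n_participants: int
    class_set: tuple[str, ...]

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())


def null_accuracy(
    observed: Sequence[str],
    mode: str = "naive",
    B: int = 10_000,
    seed: int = 0,
    class_set: Sequence[str] = CLASS_ORDER,
) -> NullAccuracyResult:
    """Null accuracy distribution of a random classifier.

    Observed labels are held fixed; each replicate assigns every
    participant a random label (uniform over ``class_set``, or weighted by
    the observed frequencies) and scores the agreement.
    """
    observed = list(observed)
    if not observed:
        raise EmptyCohortError("observed label list is empty")
    if mode not in ("naive", "weighted"):
        raise InvalidParameterError("mode must be 'naive' or 'weighted'")
    if B < 1:
        raise InvalidParameterError("B must be positive")
    if B < 100:
        warnings.warn(
            "fewer than 100 replicates give unstable percentile bounds",
            stacklevel=2,
        )
    class_set = tuple(class_set)
    index = {c: i for i, c in enumerate(class_set)}
    unknown = set(observed) - set(class_set)
    if unknown:
        raise InvalidParameterError(f"labels outside the class set: {sorted(unknown)}")
    obs = np.array([index[c] for c in observed])
    n, k = len(obs), len(class_set)
    rng = np.random.default_rng(seed)
    if mode == "naive":
        draws = rng.integers(0, k, size=(B, n))
    else:
        freqs = np.bincount(obs, minlength=k) / n
        draws = rng.choice(k, size=(B, n), p=freqs)
    accuracies = (draws == obs).mean(axis=1)
    lo, hi = np.percentile(accuracies, [2.5, 97.5])
    return NullAccuracyResult(
        mode=mode,
        replicates=B,
        accuracies=accuracies,
        ci=(float(lo), float(hi)),
        seed=seed,
        n_participants=n,
        class_set=class_set,
    )


def compare_to_model(result: NullAccuracyResult, model_accuracy: float) -> str:
    """Locate a model's accuracy relative to the null percentile band.

    Returns ``'above'`` when the accuracy strictly exceeds the upper bound
    (the model beats chance), ``'below'`` when it falls strictly under the
    lower bound, and ``'within'`` otherwise (bounds count as within).
    """
    if not 0.0 <= model_accuracy <= 1.0:
        raise InvalidParameterError("model_accuracy must lie in [0, 1]")
    lo, hi = result.ci
    if model_accuracy > hi:
        return "above"
    if model_accuracy < lo:
        return "below"
    return "within"
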