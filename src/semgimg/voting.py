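"""Majority voting over per-frame predictions, accuracy metrics and splits.

Per-frame gesture decisions are noisy; pooling the modal label over a
trailing window of consecutive frames trades observational latency for
accuracy.  All classifiers in this package emit the same
:class:`FramePredictions` contract, so voting and evaluation are shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FramePredictions",
    "SplitSpec",
    "VoteResult",
    "majority_vote",
    "vote_curve",
    "split",
    "accuracy",
    "fuse_streams",
    "SEGMENT",
]

#: Sentinel window meaning "majority vote over the entire segment".
SEGMENT = "segment"


@dataclass
class FramePredictions:
    """Per-frame class-probability vectors for one labelled segment."""

    probs: np.ndarray  # (n_frames, n_classes)
    label: int
    subject: int = 0
    trial: int = 0
    session: int = 0
    frames: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[0] < 1:
            raise ValueError("probs must be a non-empty (n_frames, n_classes) matrix")
        if self.probs.min() < -1e-9 or np.abs(self.probs.sum(axis=1) - 1).max() > 1e-6:
            raise ValueError("each row of probs must be a probability vector")
        if self.frames is None:
            self.frames = np.arange(self.probs.shape[0])
        self.frames = np.asarray(self.frames, dtype=np.intp)
        if self.frames.shape != (self.probs.shape[0],):
            raise ValueError("frames must align with probs rows")

    @property
    def n_frames(self) -> int:
        return self.probs.shape[0]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]

    @property
    def frame_labels(self) -> np.ndarray:
        """Hard per-frame decisions (argmax; ties to the smallest index)."""
        return self.probs.argmax(axis=1)


@dataclass(frozen=True)
class SplitSpec:
    """Cross-validation protocol at trial granularity.

    ``odd_even``: odd-numbered trials train, even-numbered test (one fold).
    ``leave_one_trial_out``: each trial of a session is the test set in turn.
    ``two_thirds``: first ceil(2N/3) trials train, remainder test; an
    explicit ``train_trials`` override may supply published repetition
    indices instead of the deterministic rule.
    """

    protocol: str
    per: str = "subject"  # {"subject", "session"}
    train_trials: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.protocol not in ("odd_even", "leave_one_trial_out", "two_thirds"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.per not in ("subject", "session"):
            raise ValueError("per must be 'subject' or 'session'")


@dataclass
class VoteResult:
    """Accuracy at one voting window, summarized over subjects."""

    window: int | str
    per_subject: dict[int, float]
    mean: float = field(init=False)
    std: float = field(init=False)

    def __post_init__(self) -> None:
        accs = np.array(list(self.per_subject.values()), dtype=np.float64)
        if accs.size == 0:
            raise ValueError("no per-subject accuracies")
        if accs.min() < 0 or accs.max() > 1:
            raise ValueError("accuracies must lie in [0, 1]")
        self.mean = float(accs.mean())
        self.std = float(accs.std(ddof=0))


def majority_vote(labels: Sequence[int], window: int) -> np.ndarray:
    """Modal label over the trailing window at each frame.

    Windows are truncated at the segment start, so output length equals
    input length and ``window=1`` is the identity.  Ties break to the
    smallest class index.
    """
    labels = np.asarray(labels, dtype=np.intp)
    if labels.ndim != 1 or labels.size == 0:
        raise ValueError("labels must be a non-empty 1-D sequence")
    if window < 1:
        raise ValueError("window must be at least 1 frame")
    n = labels.size
    n_classes = int(labels.max()) + 1
    # Prefix counts allow O(n * G) trailing-window modes.
    onehot = np.zeros((n + 1, n_classes), dtype=np.intp)
    onehot[np.arange(1, n + 1), labels] = 1
    cum = np.cumsum(onehot, axis=0)
    starts = np.maximum(np.arange(n) + 1 - window, 0)
    counts = cum[1:] - cum[starts]
    return counts.argmax(axis=1)


def segment_vote(labels: Sequence[int]) -> int:
    """Single modal label over an entire segment (ties to smallest index)."""
    labels = np.asarray(labels, dtype=np.intp)
    if labels.size == 0:
        raise ValueError("empty segment")
    return int(np.bincount(labels).argmax())


def fuse_streams(
    labels_image: Sequence[int], labels_difference: Sequence[int]
) -> int:
    """Pool frame decisions from image and difference-image streams, then vote.

    A T-frame segment contributes T image decisions and T-1 difference
    decisions, so the pooled vote covers 2T-1 decisions.
    """
    a = np.asarray(labels_image, dtype=np.intp)
    b = np.asarray(labels_difference, dtype=np.intp)
    if a.size and b.size and b.size != a.size - 1:
        raise ValueError(
            f"difference stream must have one fewer decision ({a.size} vs {b.size})"
        )
    pooled = np.concatenate([a, b])
    return segment_vote(pooled)


def _voted_correct(pred: FramePredictions, window: int | str) -> float:
    labels = pred.frame_labels
    if window == SEGMENT:
        return float(segment_vote(labels) == pred.label)
    voted = majority_vote(labels, int(window))
    return float(np.mean(voted == pred.label))


def accuracy(
    preds: Sequence[FramePredictions],
    level: str = "frame",
    window: int | None = None,
) -> VoteResult:
    """Recognition accuracy per subject, averaged with standard deviation.

    ``frame``: proportion of correctly recognized frames.
    ``voted``: correctness of trailing-window voted decisions (needs window).
    ``segment``: one whole-segment vote per trial.
    """
    if not preds:
        raise ValueError("no predictions")
    if level == "frame":
        win: int | str = 1
    elif level == "voted":
        if window is None:
            raise ValueError("voted accuracy requires a window")
        win = window
    elif level == "segment":
        win = SEGMENT
    else:
        raise ValueError(f"unknown level {level!r}")
    per_subject: dict[int, list[float]] = {}
    for p in preds:
        per_subject.setdefault(p.subject, []).append(_voted_correct(p, win))
    return VoteResult(
        window=win,
        per_subject={s: float(np.mean(v)) for s, v in sorted(per_subject.items())},
    )


def vote_curve(
    preds: Sequence[FramePredictions], windows: Sequence[int | str]
) -> list[VoteResult]:
    """Accuracy at each voting window (``SEGMENT`` means whole-segment vote)."""
    if not preds:
        raise ValueError("no predictions")
    results = []
    for w in windows:
        if w != SEGMENT:
            if int(w) < 1:
                raise ValueError("window must be at least 1 frame")
            if all(int(w) > p.n_frames for p in preds):
                raise ValueError(f"window {w} exceeds every segment length")
        results.append(
            accuracy(preds, "segment" if w == SEGMENT else "voted", None if w == SEGMENT else int(w))
        )
    return results


def split(dataset: Sequence, spec: SplitSpec) -> list[tuple[list, list]]:
    """Deterministic (train, test) folds over objects carrying trial metadata.

    Items need ``trial`` (1-based) and, for session-wise protocols,
    ``session`` attributes.  Folds are disjoint and cover every item.
    """
    items = list(dataset)
    if not items:
        raise ValueError("empty dataset")
    trials = sorted({int(it.trial) for it in items})
    if spec.protocol == "odd_even":
        train = [it for it in items if it.trial % 2 == 1]
        test = [it for it in items if it.trial % 2 == 0]
        if not train or not test:
            raise ValueError("odd_even split requires both odd and even trial numbers")
        return [(train, test)]
    if spec.protocol == "leave_one_trial_out":
        if spec.per == "session":
            groups = sorted({int(it.session) for it in items})
            folds = []
            for g in groups:
                in_group = [it for it in items if it.session == g]
                for t in sorted({int(it.trial) for it in in_group}):
                    test = [it for it in in_group if it.trial == t]
                    train = [it for it in in_group if it.trial != t]
                    folds.append((train, test))
            return folds
        return [
            ([it for it in items if it.trial != t], [it for it in items if it.trial == t])
            for t in trials
        ]
    # two_thirds
    if spec.train_trials is not None:
        train_set = set(spec.train_trials)
    else:
        n_train = int(np.ceil(2 * len(trials) / 3))
        train_set = set(trials[:n_train])
    train = [it for it in items if it.trial in train_set]
    test = [it for it in items if it.trial not in train_set]
    if not train or not test:
        raise ValueError("two_thirds split produced an empty fold")
    return [(train, test)]
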