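"""ROC evaluation of a profile's ability to separate actives from decoys."""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .compounds import CompoundRecord


@dataclass
class ROCResult:
    """ROC curve points from (0,0) to (1,1) and the trapezoidal AUC.

    The AUC equals the Mann-Whitney statistic: the probability that a
    random positive outscores a random negative, ties counted 1/2.
    """

    points: list[tuple[float, float]]
    auc: float
    n_pos: int
    n_neg: int

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.points, columns=["fpr", "tpr"]).to_csv(path, index=False)

    def summary_json(self) -> str:
        import json

        return json.dumps({"auc": self.auc, "n_pos": self.n_pos, "n_neg": self.n_neg})


def roc_auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> ROCResult:
    """ROC curve and AUC for positive-set scores vs decoy-set scores."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([pos, neg])
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    area = float(_trapezoid_auc(fpr, tpr))
    points = [(float(f), float(t)) for f, t in zip(fpr, tpr)]
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return ROCResult(points=points, auc=area, n_pos=int(pos.size), n_neg=int(neg.size))


def sample_decoys(pool: Sequence[CompoundRecord], k: int, seed: int) -> list[CompoundRecord]:
    """Uniform sample of k decoys without replacement, reproducible by seed."""
    if k > len(pool):
        raise ValueError(f"cannot sample {k} decoys from a pool of {len(pool)}")
    rng = random.Random(seed)
    return rng.sample(list(pool), k)
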