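"""Visit-level data model: labels, VRQOL imputation, and train/test splits.

A visit carries up to three modality blocks (glottal / acoustic / clinical),
the auditory-perceptual RBH ratings, the overall hoarseness score
H = max(R, B), and the binary label 1{H >= 2} used for classifier training.
Splitting reserves every multi-visit subject for the test set (they provide
the pre/post pairs for change analysis) and then tops the test set up toward
a uniform H distribution while keeping subjects disjoint between train and
test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SplitResult",
    "overall_hoarseness",
    "binarize_label",
    "impute_vrqol",
    "split_train_test",
]


def overall_hoarseness(r: int, b: int) -> int:
    """Overall hoarseness H = max(R, B) on the RBH scale."""
    r, b = int(r), int(b)
    if not (0 <= r <= 3 and 0 <= b <= 3):
        raise ValueError("R and B must be in {0, 1, 2, 3}")
    return max(r, b)


def binarize_label(h: int) -> int:
    """Binary target: 1 for moderate/severe hoarseness (H >= 2), else 0."""
    h = int(h)
    if not 0 <= h <= 3:
        raise ValueError("H must be in {0, 1, 2, 3}")
    return int(h >= 2)


def impute_vrqol(visits: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Fill missing VRQOL by ordinary least squares on the VHI.

    Fits VRQOL = intercept + slope * VHI on visits where both questionnaires
    are present and replaces missing VRQOL entries by the fitted value.
    Returns the imputed copy plus (slope, intercept).
    """
    if "VHI" not in visits or "VRQOL" not in visits:
        raise ValueError("visits must carry VHI and VRQOL columns")
    both = visits["VHI"].notna() & visits["VRQOL"].notna()
    if both.sum() < 2:
        raise ValueError("need at least 2 complete (VHI, VRQOL) pairs to fit")
    slope, intercept = np.polyfit(
        visits.loc[both, "VHI"].to_numpy(float),
        visits.loc[both, "VRQOL"].to_numpy(float),
        1,
    )
    out = visits.copy()
    missing = out["VRQOL"].isna() & out["VHI"].notna()
    out.loc[missing, "VRQOL"] = intercept + slope * out.loc[missing, "VHI"]
    return out, float(slope), float(intercept)


@dataclass
class SplitResult:
    """Subject-disjoint train/test split with pre/post visit pairs."""

    train_ids: list
    test_ids: list
    paired_test_ids: list  # list of (pre_visit_id, post_visit_id)
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "train_ids": list(self.train_ids),
                    "test_ids": list(self.test_ids),
                    "paired_test_ids": [list(p) for p in self.paired_test_ids],
                    "warnings": self.warnings,
                },
                fh,
                indent=1,
            )


def split_train_test(
    visits: pd.DataFrame, target_test_fraction: float = 0.2, seed: int = 0
) -> SplitResult:
    """Hold-out split with all repeat visits in test and H balanced there.

    Rules, in order: (1) every subject with more than one visit goes entirely
    to the test set (their ordered visit pairs feed the change analysis);
    (2) additional single-visit subjects are sampled greedily, always topping
    up the currently most under-represented H level among those still
    available — when a level (typically H = 3) is exhausted the next level
    down (H = 2) fills in; (3) everything else trains.  Subjects are never
    split across the two sets.  An infeasible target yields a best-effort
    split with a warning recorded.
    """
    if not {"subject_id", "visit_id", "H"}.issubset(visits.columns):
        raise ValueError("visits must carry subject_id, visit_id, H")
    rng = np.random.default_rng(seed)
    warnings: list[str] = []

    counts = visits.groupby("subject_id")["visit_id"].count()
    multi_subjects = set(counts[counts > 1].index)
    test_mask = visits["subject_id"].isin(multi_subjects)
    test_ids = list(visits.loc[test_mask, "visit_id"])

    target_n = int(round(target_test_fraction * len(visits)))
    pool = visits.loc[~test_mask].copy()
    # candidates grouped by H level, one visit per (single-visit) subject
    by_level: dict[int, list] = {
        h: list(pool.loc[pool["H"] == h, "visit_id"].sample(frac=1.0, random_state=rng.integers(2**31 - 1)))
        for h in range(4)
    }
    test_hist = visits.loc[test_mask, "H"].value_counts().reindex(range(4), fill_value=0).to_dict()

    while len(test_ids) < target_n:
        levels = sorted(range(4), key=lambda h: (test_hist[h], -h))
        chosen = None
        for h in levels:
            if by_level[h]:
                chosen = h
                break
            if h == 3 and by_level[2]:
                # too few severe visits: fill with moderate (H = 2) instead
                chosen = 2
                break
        if chosen is None:
            warnings.append(
                f"target test fraction infeasible: only {len(test_ids)} of {target_n} visits available"
            )
            break
        vid = by_level[chosen].pop()
        test_ids.append(vid)
        test_hist[chosen] += 1

    test_set = set(test_ids)
    train_ids = [v for v in visits["visit_id"] if v not in test_set]

    paired = []
    order_col = "visit_order" if "visit_order" in visits.columns else None
    for subj in sorted(multi_subjects):
        rows = visits[visits["subject_id"] == subj]
        if order_col:
            rows = rows.sort_values(order_col)
        ids = list(rows["visit_id"])
        for pre, post in zip(ids[:-1], ids[1:]):
            paired.append((pre, post))

    return SplitResult(
        train_ids=train_ids, test_ids=test_ids, paired_test_ids=paired, warnings=warnings
    )
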