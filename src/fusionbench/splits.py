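"""Subject-level, condition-stratified k-fold cross-validation design.

Splits are performed at the subject level (all sessions of a subject stay
in one role within a fold) and stratified across clinical conditions: the
test subjects of the k folds partition each condition's subjects into
groups whose sizes differ by at most one.  Within a fold, the non-test
subjects split 90/10 into training and validation (round-half-up, at least
one validation subject per condition).  Validation and test use exactly one
session per subject, chosen by the seeded shuffle; training keeps every
session of its subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .phantom import CohortManifest

__all__ = ["SplitPlan", "FoldSplit", "make_cv_splits"]

Pair = tuple[str, str]     # (subject_id, session_id)


@dataclass
class FoldSplit:
    train_pairs: list[Pair]
    val_pairs: list[Pair]
    test_pairs: list[Pair]

    def roles(self):
        return {"train": self.train_pairs, "val": self.val_pairs,
                "test": self.test_pairs}


@dataclass
class SplitPlan:
    k: int
    seed: int
    folds: list[FoldSplit] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "k": self.k, "seed": self.seed,
            "folds": [{role: [list(p) for p in pairs]
                       for role, pairs in f.roles().items()}
                      for f in self.folds],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "SplitPlan":
        d = json.loads(s)
        folds = [FoldSplit(
            train_pairs=[tuple(p) for p in f["train"]],
            val_pairs=[tuple(p) for p in f["val"]],
            test_pairs=[tuple(p) for p in f["test"]]) for f in d["folds"]]
        return cls(k=d["k"], seed=d["seed"], folds=folds)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "SplitPlan":
        return cls.from_json(Path(path).read_text())


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_cv_splits(manifest: CohortManifest, k: int, seed: int,
                   stratify_val: bool = True) -> SplitPlan:
    """Design the k-fold plan for a cohort manifest.

    Per condition, subjects are shuffled with the seeded generator and dealt
    into k folds whose sizes differ by at most one; fold f's subjects are
    its test set.  Of the remaining subjects, 10% (round-half-up, minimum
    one — per condition when ``stratify_val``) become validation.  One
    session per validation/test subject is kept: the first after the seeded
    shuffle of that subject's sessions.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    df = manifest.frame
    rng = np.random.default_rng(seed)

    # stable subject -> condition/sessions mapping
    by_cond: dict[str, list[str]] = {}
    sessions: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        sid = row["subject_id"]
        sessions.setdefault(sid, []).append(row["session_id"])
        if sid not in by_cond.get(row["condition"], []):
            by_cond.setdefault(row["condition"], [])
            if sid not in by_cond[row["condition"]]:
                by_cond[row["condition"]].append(sid)

    for cond, subs in by_cond.items():
        if len(subs) < k:
            raise ValueError(
                f"condition {cond!r} has {len(subs)} subjects, fewer than "
                f"k={k}")

    # deal shuffled subjects of each condition into folds (sizes +/- 1)
    fold_test: list[list[str]] = [[] for _ in range(k)]
    shuffled: dict[str, list[str]] = {}
    for cond, subs in by_cond.items():
        order = [subs[i] for i in rng.permutation(len(subs))]
        shuffled[cond] = order
        n = len(order)
        base, extra = divmod(n, k)
        start = 0
        for f in range(k):
            size = base + (1 if f < extra else 0)
            fold_test[f].extend(order[start:start + size])
            start += size

    def one_session(sid: str) -> Pair:
        ses = sorted(sessions[sid])
        pick = ses[int(rng.integers(0, len(ses)))]
        return (sid, pick)

    plan = SplitPlan(k=k, seed=seed)
    for f in range(k):
        test_subjects = fold_test[f]
        val_subjects: list[str] = []
        if stratify_val:
            for cond in by_cond:
                pool = [s for s in shuffled[cond]
                        if s not in test_subjects]
                n_val = max(1, _round_half_up(0.1 * len(pool)))
                val_subjects.extend(pool[:n_val])
        else:
            pool = [s for c in by_cond for s in shuffled[c]
                    if s not in test_subjects]
            n_val = max(1, _round_half_up(0.1 * len(pool)))
            val_subjects = pool[:n_val]
        train_subjects = [s for c in by_cond for s in shuffled[c]
                          if s not in test_subjects and s not in val_subjects]
        fold = FoldSplit(
            train_pairs=[(s, ses) for s in train_subjects
                         for ses in sorted(sessions[s])],
            val_pairs=[one_session(s) for s in val_subjects],
            test_pairs=[one_session(s) for s in test_subjects],
        )
        plan.folds.append(fold)
    return plan
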