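"""Balanced, subject-wise 5-fold window datasets from per-subject RR series.

Fixed-length windows of N consecutive RR intervals (N in {25, 50, 100} by
default) are cut from each subject's sinus-rhythm and AF series, labelled
0 = sinus rhythm / 1 = atrial fibrillation, partitioned subject-wise into
five train/test folds with three exclusive test subjects per fold, balanced
by random down-sampling of the majority class, and exported as CSV tables
(columns ``rr_001..rr_N, label``) plus a JSON manifest.

The subject-wise partition guarantees that no window of a test subject ever
appears in the corresponding training table, preventing identity leakage in
the cross-validated performance estimate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from afedge.ingest import Rhythm, RRSeries

logger = logging.getLogger(__name__)

LABEL_SR = 0
LABEL_AF = 1

_RHYTHM_LABEL = {Rhythm.SR: LABEL_SR, Rhythm.AF: LABEL_AF}


@dataclass(frozen=True)
class WindowSample:
    """One classification sample: N consecutive RR values plus its label."""

    features: np.ndarray
    label: int
    subject_id: str
    window_index: int


@dataclass(frozen=True)
class FoldSpec:
    """One subject-wise train/test partition."""

    fold_id: int
    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_subjects) & set(self.test_subjects):
            raise ValueError(f"fold {self.fold_id}: train and test subjects overlap")


@dataclass
class DatasetBundle:
    """All five balanced train/test tables for one window length."""

    n: int
    folds: list[FoldSpec]
    train_tables: dict[int, list[WindowSample]] = field(default_factory=dict)
    test_tables: dict[int, list[WindowSample]] = field(default_factory=dict)
    seed: int = 0
    stride: int | None = None


def window_sequences(rr: RRSeries, n: int, stride: int | None = None) -> list[WindowSample]:
    """Cut an RR series into fixed-length windows.

    Windows start at offsets 0, stride, 2*stride, ...; the default stride
    equals ``n`` (non-overlapping windows); a trailing remainder shorter
    than ``n`` is discarded.  The label comes from the series' rhythm.
    """
    if stride is None:
        stride = n
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if rr.rhythm not in _RHYTHM_LABEL:
        raise ValueError(f"cannot label windows of rhythm {rr.rhythm}")
    label = _RHYTHM_LABEL[rr.rhythm]
    values = rr.values
    out = []
    idx = 0
    for start in range(0, len(values) - n + 1, stride):
        out.append(WindowSample(values[start : start + n].copy(), label, rr.subject_id, idx))
        idx += 1
    return out


def assign_folds(
    subject_ids: Sequence[str],
    n_folds: int = 5,
    test_per_fold: int = 3,
    seed: int = 0,
) -> list[FoldSpec]:
    """Draw the subject-wise cross-validation partition.

    ``n_folds * test_per_fold`` distinct test subjects are drawn without
    replacement (seeded) and split into per-fold test sets; each fold trains
    on every subject not in its own test set.  Test sets of different folds
    are pairwise disjoint, so no subject is ever tested twice.
    """
    subjects = list(subject_ids)
    needed = n_folds * test_per_fold
    if needed > len(subjects):
        raise ValueError(
            f"{needed} test subjects requested but only {len(subjects)} available"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(subjects), size=needed, replace=False)
    folds = []
    for k in range(n_folds):
        test = tuple(subjects[i] for i in picked[k * test_per_fold : (k + 1) * test_per_fold])
        train = tuple(s for s in subjects if s not in set(test))
        folds.append(FoldSpec(k + 1, train, test))
    return folds


def balance_classes(samples: Sequence[WindowSample], seed: int = 0) -> list[WindowSample]:
    """Randomly down-sample the majority class to the minority count.

    The minority class is untouched; majority survivors keep their relative
    order.  If a class is absent there is nothing meaningful to balance and
    an empty list is returned with a warning.
    """
    idx_by_label: dict[int, list[int]] = {}
    for i, s in enumerate(samples):
        idx_by_label.setdefault(s.label, []).append(i)
    if len(idx_by_label) < 2:
        logger.warning(
            "cannot balance: only labels %s present", sorted(idx_by_label) or "none"
        )
        return []
    minority = min(len(v) for v in idx_by_label.values())
    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    for label in sorted(idx_by_label):
        idx = idx_by_label[label]
        if len(idx) > minority:
            chosen = rng.choice(len(idx), size=minority, replace=False)
            keep.update(idx[i] for i in chosen)
        else:
            keep.update(idx)
    return [samples[i] for i in sorted(keep)]


def samples_to_frame(samples: Sequence[WindowSample], n: int) -> pd.DataFrame:
    """Stack windows into the export table layout rr_001..rr_N, label."""
    cols = [f"rr_{i + 1:03d}" for i in range(n)]
    if not samples:
        return pd.DataFrame(columns=cols + ["label"])
    feats = np.stack([s.features for s in samples])
    df = pd.DataFrame(feats, columns=cols)
    df["label"] = [s.label for s in samples]
    return df


def build_bundle(
    rr_store: dict[str, list[RRSeries]],
    n: int,
    folds: list[FoldSpec],
    seed: int = 0,
    stride: int | None = None,
) -> DatasetBundle:
    """Window every subject's series and assemble balanced per-fold tables.

    Windows are pooled across each fold's subjects and balanced per table
    (train and test independently).
    """
    windows: dict[str, list[WindowSample]] = {
        subj: [w for series in series_list for w in window_sequences(series, n, stride)]
        for subj, series_list in rr_store.items()
    }
    bundle = DatasetBundle(n=n, folds=folds, seed=seed, stride=stride or n)
    for fold in folds:
        for part, subjects, tables in (
            ("train", fold.train_subjects, bundle.train_tables),
            ("test", fold.test_subjects, bundle.test_tables),
        ):
            pooled = [w for s in subjects for w in windows.get(s, [])]
            # distinct sub-seed per fold/part so balancing draws are independent
            sub_seed = (seed * 1000 + fold.fold_id * 10 + (0 if part == "train" else 1)) % (2**31)
            tables[fold.fold_id] = balance_classes(pooled, seed=sub_seed)
    return bundle


def export_csv(bundle: DatasetBundle, out_dir: str | Path) -> list[Path]:
    """Write one train and one test CSV per fold plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    manifest: dict = {
        "n": bundle.n,
        "seed": bundle.seed,
        "stride": bundle.stride,
        "folds": {},
    }
    for fold in bundle.folds:
        entry: dict = {
            "train_subjects": list(fold.train_subjects),
            "test_subjects": list(fold.test_subjects),
        }
        for part, tables in (("train", bundle.train_tables), ("test", bundle.test_tables)):
            samples = tables[fold.fold_id]
            df = samples_to_frame(samples, bundle.n)
            path = out_dir / f"rr{bundle.n}_fold{fold.fold_id}_{part}.csv"
            df.to_csv(path, index=False, float_format="%.6f")
            paths.append(path)
            labels = df["label"].to_numpy() if len(df) else np.empty(0, dtype=int)
            entry[f"{part}_counts"] = {
                "sr": int((labels == LABEL_SR).sum()),
                "af": int((labels == LABEL_AF).sum()),
            }
            entry[f"{part}_subject_windows"] = {
                s: sum(1 for w in samples if w.subject_id == s)
                for s in (fold.train_subjects if part == "train" else fold.test_subjects)
            }
        manifest["folds"][str(fold.fold_id)] = entry
    manifest_path = out_dir / f"rr{bundle.n}_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    paths.append(manifest_path)
    return paths


def build_all(
    rr_store: dict[str, list[RRSeries]],
    n_list: Sequence[int] = (25, 50, 100),
    n_folds: int = 5,
    test_per_fold: int = 3,
    seed: int = 0,
    stride: int | None = None,
    out_dir: str | Path | None = None,
) -> list[DatasetBundle]:
    """Build bundles for every window length, reusing one fold partition.

    The same subject partition is shared across window lengths so that
    performance differences between N = 25, 50 and 100 reflect the window
    length and not the subject draw.  With ``out_dir`` the tables are also
    exported to disk.
    """
    folds = assign_folds(sorted(rr_store), n_folds, test_per_fold, seed)
    bundles = []
    for n in n_list:
        bundle = build_bundle(rr_store, n, folds, seed=seed, stride=stride)
        if out_dir is not None:
            export_csv(bundle, out_dir)
        bundles.append(bundle)
    return bundles
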