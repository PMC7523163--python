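"""Manifest-to-training-structure rules: view filtering, label-scheme
mapping, and patient-grouped train/val/test fold assignment.

Fold fractions follow the convention "reserve ``test_frac`` of the records
for testing, then ``val_frac`` of the *remaining* records for validation",
with patients as atomic units: all radiographs of a patient land in one
fold, so achieved fractions can deviate from targets by at most the largest
per-patient record count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CHESTXRAY14_LABELS, DatasetManifest
from .errors import ConfigError, IntegrityError, ParameterError

logger = logging.getLogger(__name__)

__all__ = ["SplitSpec", "filter_views", "map_labels", "assign_folds",
           "fold_manifests", "DEFAULT_LABEL_SCHEME"]

KEPT_PROJECTIONS = ("PA", "AP")

#: A simple source-vocabulary -> canonical-category mapping; identity on the
#: 14 canonical names plus a few common aliases. "COVID" maps to the extra
#: 15th node rather than to any of the 14 categories.
DEFAULT_LABEL_SCHEME: dict[str, str] = {name: name for name in CHESTXRAY14_LABELS}
DEFAULT_LABEL_SCHEME.update({
    "Pleural Effusion": "Effusion",
    "Pleural thickening": "Pleural_Thickening",
    "COVID": "COVID",
    "COVID-19": "COVID",
})


@dataclass
class SplitSpec:
    """Record-id -> fold assignment with its provenance."""

    fold_of_record: dict[str, str]
    fractions: tuple[float, float]           # (test_frac, val_frac)
    seed: int
    fixed_test_ids: frozenset[str] = field(default_factory=frozenset)

    def records_in(self, fold: str) -> list[str]:
        return [rid for rid, f in self.fold_of_record.items() if f == fold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"record_id": list(self.fold_of_record),
             "fold": list(self.fold_of_record.values())}
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def filter_views(manifest: DatasetManifest) -> DatasetManifest:
    """Retain only PA and upright-AP radiographs.

    Lateral, AP-supine and unknown-projection records are dropped; counts
    per dropped category are logged.
    """
    kept, dropped = [], {}
    for i, rec in enumerate(manifest):
        if rec.projection in KEPT_PROJECTIONS:
            kept.append(i)
        else:
            dropped[rec.projection] = dropped.get(rec.projection, 0) + 1
    for proj, count in sorted(dropped.items()):
        logger.info("view filter dropped %d %s records", count, proj)
    if not kept:
        warnings.warn("view filter removed every record", stacklevel=2)
    return manifest.subset(kept)


def map_labels(source_labels, scheme: dict[str, str] | str = "default") -> np.ndarray:
    """Map a set of source-vocabulary labels to the {0,1}^15 head vector.

    The first 14 nodes are the ChestX-ray14 categories in canonical order;
    node 15 is COVID. Source labels absent from the scheme are dropped and
    logged.
    """
    if isinstance(scheme, str):
        if scheme != "default":
            raise ConfigError(f"unknown label scheme id {scheme!r}")
        scheme = DEFAULT_LABEL_SCHEME
    vec = np.zeros(15, dtype=int)
    index = {name: i for i, name in enumerate(CHESTXRAY14_LABELS)}
    for lab in source_labels:
        target = scheme.get(lab)
        if target is None:
            logger.info("dropping unmapped source label %r", lab)
        elif target == "COVID":
            vec[14] = 1
        else:
            vec[index[target]] = 1
    return vec


def assign_folds(manifest: DatasetManifest, fractions: tuple[float, float] = (0.05, 0.05),
                 seed: int = 0, fixed_test_ids=None) -> SplitSpec:
    """Patient-grouped greedy fold assignment.

    Patients are shuffled by ``seed`` and accumulated into the test fold
    while its record count is below ``test_frac * N``, then into validation
    while below ``val_frac * remaining``; the rest train. ``fixed_test_ids``
    (record ids, e.g. an upstream repository's frozen test partition) are
    forced into the test fold first; a patient with records both inside and
    outside the fixed set would be split and raises ``IntegrityError``.
    """
    test_frac, val_frac = fractions
    if not (0.0 < test_frac < 1.0 and 0.0 < val_frac < 1.0):
        raise ParameterError("fractions must lie in (0, 1)")
    fixed = frozenset(fixed_test_ids or ())

    patients: dict[str, list[str]] = {}
    for rec in manifest:
        patients.setdefault(rec.patient_id, []).append(rec.record_id)

    fold_of_record: dict[str, str] = {}
    n_total = len(manifest)
    n_test = 0

    fixed_patients = {rec.patient_id for rec in manifest if rec.record_id in fixed}
    for pid in fixed_patients:
        if any(rid not in fixed for rid in patients[pid]):
            raise IntegrityError(
                f"fixed_test_ids would split patient {pid!r} across folds")
        for rid in patients[pid]:
            fold_of_record[rid] = "test"
            n_test += 1

    rng = np.random.default_rng(seed)
    free = sorted(pid for pid in patients if pid not in fixed_patients)
    rng.shuffle(free)

    quota_test = test_frac * n_total
    i = 0
    while i < len(free) and n_test < quota_test:
        for rid in patients[free[i]]:
            fold_of_record[rid] = "test"
            n_test += 1
        i += 1

    remaining = n_total - n_test
    quota_val = val_frac * remaining
    n_val = 0
    while i < len(free) and n_val < quota_val:
        for rid in patients[free[i]]:
            fold_of_record[rid] = "val"
            n_val += 1
        i += 1

    for pid in free[i:]:
        for rid in patients[pid]:
            fold_of_record[rid] = "train"

    return SplitSpec(fold_of_record=fold_of_record, fractions=fractions,
                     seed=seed, fixed_test_ids=fixed)


def fold_manifests(manifest: DatasetManifest, split: SplitSpec):
    """Split a manifest into (train, val, test) sub-manifests."""
    idx = {"train": [], "val": [], "test": []}
    for i, rec in enumerate(manifest):
        idx[split.fold_of_record[rec.record_id]].append(i)
    return (manifest.subset(idx["train"]), manifest.subset(idx["val"]),
            manifest.subset(idx["test"]))
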