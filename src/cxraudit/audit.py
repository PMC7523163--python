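"""Internal-vs-external generalization auditing.

The generalization gap — internal-test AUROC minus external-test AUROC for
the same model — is the first-line symptom of shortcut learning: a model
exploiting source-specific confounds looks accurate on held-out data from
its own sources and collapses on data from new ones.

The confound-transfer audit probes the complementary failure mode: a
confound that is rendered the *same* way everywhere (e.g. a projection cue)
generalizes, so external validation alone cannot rule out that a model
rides on it. It trains fresh classifiers to predict a candidate attribute
(radiographic projection or the sex analogue) and reports internal and
external AUROC across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import assign_folds, fold_manifests
from .data import DatasetManifest, ImageRecord
from .errors import AuditError, SchemaError
from .models import TrainHyperparams, TrainedModelHandle, compute_auroc, train_classifier

__all__ = ["GapReport", "evaluate_generalization", "confound_transfer_audit"]

_ATTRIBUTE_POSITIVE = {"projection": "AP", "sex_analogue": "B"}


@dataclass
class GapReport:
    auroc_internal: float
    auroc_external: float
    n_internal: int
    n_external: int
    seeds: list[int] = field(default_factory=list)
    internal_replicates: list[float] = field(default_factory=list)
    external_replicates: list[float] = field(default_factory=list)

    @property
    def gap(self) -> float:
        return self.auroc_internal - self.auroc_external

    @property
    def internal_sd(self) -> float:
        return float(np.std(self.internal_replicates, ddof=1)) \
            if len(self.internal_replicates) > 1 else 0.0

    @property
    def external_sd(self) -> float:
        return float(np.std(self.external_replicates, ddof=1)) \
            if len(self.external_replicates) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "auroc_internal": self.auroc_internal,
            "auroc_external": self.auroc_external,
            "gap": self.gap,
            "internal_sd": self.internal_sd,
            "external_sd": self.external_sd,
            "n_internal": self.n_internal,
            "n_external": self.n_external,
            "seeds": self.seeds,
        }


def evaluate_generalization(model: TrainedModelHandle, internal_test: DatasetManifest,
                            external_test: DatasetManifest, node="covid") -> GapReport:
    """Score one trained model on held-out internal and external manifests."""
    clf = model.classifier
    if internal_test[0].image.shape != external_test[0].image.shape:
        raise SchemaError("internal and external manifests use different image sizes")
    j = clf._node_index(node)
    z_int = clf.logits(internal_test.images()[:, 0])[:, j]
    z_ext = clf.logits(external_test.images()[:, 0])[:, j]
    return GapReport(
        auroc_internal=compute_auroc(z_int, internal_test.covid_labels()),
        auroc_external=compute_auroc(z_ext, external_test.covid_labels()),
        n_internal=len(internal_test),
        n_external=len(external_test),
        seeds=[model.seed],
    )


def _attribute_labels(manifest: DatasetManifest, attribute: str) -> np.ndarray:
    if attribute not in _ATTRIBUTE_POSITIVE:
        raise AuditError(f"unknown attribute {attribute!r}")
    pos = _ATTRIBUTE_POSITIVE[attribute]
    return np.array([int(getattr(r, attribute) == pos) for r in manifest])


def _relabeled(manifest: DatasetManifest, attribute: str) -> DatasetManifest:
    labels = _attribute_labels(manifest, attribute)
    records = []
    for rec, lab in zip(manifest, labels):
        records.append(ImageRecord(
            image=rec.image, record_id=rec.record_id, patient_id=rec.patient_id,
            source_id=rec.source_id, covid_label=int(lab),
            aux_labels=rec.aux_labels, projection=rec.projection,
            sex_analogue=rec.sex_analogue, has_signal=rec.has_signal))
    return DatasetManifest(records)


def confound_transfer_audit(attribute: str, internal_data: DatasetManifest,
                            external_data: DatasetManifest, seed: int = 0,
                            n_replicates: int = 5, arch: str = "simple-cnn",
                            hp: TrainHyperparams | None = None,
                            fractions=(0.15, 0.15)) -> GapReport:
    """Train fresh classifiers to predict ``attribute`` and test transfer.

    ``n_replicates`` independent runs (seeds = seed + replicate index);
    the report carries per-replicate AUROCs and their mean +- sd. If the
    attribute is constant in either domain the audit cannot run.
    """
    for name, data in (("internal", internal_data), ("external", external_data)):
        labels = _attribute_labels(data, attribute)
        if labels.min() == labels.max():
            raise AuditError(f"attribute {attribute!r} is constant in {name} data")

    internal = _relabeled(internal_data, attribute)
    external = _relabeled(external_data, attribute)
    hp = hp or TrainHyperparams(max_epochs=10)

    internal_scores, external_scores, seeds = [], [], []
    for rep in range(n_replicates):
        rep_seed = seed + rep
        split = assign_folds(internal, fractions=fractions, seed=rep_seed)
        handle = train_classifier(internal, split, arch=arch,
                                  head_scheme="single1", hp=hp, seed=rep_seed)
        _, _, test_m = fold_manifests(internal, split)
        report = evaluate_generalization(handle, test_m, external, node="covid")
        internal_scores.append(report.auroc_internal)
        external_scores.append(report.auroc_external)
        seeds.append(rep_seed)

    return GapReport(
        auroc_internal=float(np.mean(internal_scores)),
        auroc_external=float(np.mean(external_scores)),
        n_internal=len(internal), n_external=len(external),
        seeds=seeds, internal_replicates=internal_scores,
        external_replicates=external_scores)
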