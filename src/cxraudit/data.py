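"""In-memory dataset containers and PNG/CSV manifest I/O.

An :class:`ImageRecord` bundles one grayscale image with the metadata the
audit needs: patient and source identity, the COVID label, 14 auxiliary
pathology labels (the ChestX-ray14 vocabulary), radiographic projection, a
sex-analogue attribute, and the generator's ground truth of whether genuine
pathology signal was rendered (``has_signal``).

A :class:`DatasetManifest` is an ordered collection of records with helpers
to view images as a training batch, the metadata as a pandas DataFrame, and
to round-trip through ``<dir>/images/*.png`` + ``<dir>/manifest.csv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import SchemaError

# The 14 ChestX-ray14 pathology categories, in canonical order; the
# classification head appends a 15th COVID node after these.
CHESTXRAY14_LABELS: tuple[str, ...] = (
    "Atelectasis", "Cardiomegaly", "Effusion", "Infiltration", "Mass",
    "Nodule", "Pneumonia", "Pneumothorax", "Consolidation", "Edema",
    "Emphysema", "Fibrosis", "Pleural_Thickening", "Hernia",
)

PROJECTIONS = ("PA", "AP", "lateral", "AP-supine", "unknown")


@dataclass
class ImageRecord:
    image: np.ndarray                       # 2-D float in [0, 1]
    record_id: str
    patient_id: str
    source_id: str
    covid_label: int
    aux_labels: np.ndarray = field(default_factory=lambda: np.zeros(14, dtype=int))
    projection: str = "PA"
    sex_analogue: str = "A"
    has_signal: int = 0

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2:
            raise SchemaError("ImageRecord.image must be a 2-D grayscale array")
        self.aux_labels = np.asarray(self.aux_labels, dtype=int)
        if self.aux_labels.shape != (14,):
            raise SchemaError("aux_labels must be a 14-vector")
        if self.projection not in PROJECTIONS:
            raise SchemaError(f"unknown projection {self.projection!r}")

    @property
    def label_vector(self) -> np.ndarray:
        """{0,1}^15 with the COVID node last."""
        return np.concatenate([self.aux_labels, [self.covid_label]]).astype(float)


class DatasetManifest:
    """An ordered list of :class:`ImageRecord` with batch/table views."""

    def __init__(self, records: Sequence[ImageRecord]):
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> ImageRecord:
        return self.records[i]

    def __iter__(self):
        return iter(self.records)

    def subset(self, indices: Iterable[int]) -> "DatasetManifest":
        return DatasetManifest([self.records[i] for i in indices])

    def images(self) -> np.ndarray:
        """Stack images into a (N, 1, H, W) batch."""
        return np.stack([r.image for r in self.records])[:, None, :, :]

    def labels(self, head_scheme: str = "multi15") -> np.ndarray:
        if head_scheme == "multi15":
            return np.stack([r.label_vector for r in self.records])
        if head_scheme == "single1":
            return np.array([[float(r.covid_label)] for r in self.records])
        raise SchemaError(f"unknown head scheme {head_scheme!r}")

    def covid_labels(self) -> np.ndarray:
        return np.array([r.covid_label for r in self.records])

    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "record_id": r.record_id,
                "patient_id": r.patient_id,
                "source_id": r.source_id,
                "covid": r.covid_label,
                "projection": r.projection,
                "sex_analogue": r.sex_analogue,
                "has_signal": r.has_signal,
            }
            for j in range(14):
                row[f"aux_{j + 1:02d}"] = int(r.aux_labels[j])
            rows.append(row)
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------ I/O

    def save(self, out_dir: str | Path) -> Path:
        """Write 8-bit grayscale PNGs plus manifest.csv; returns the csv path."""
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        frame = self.frame()
        paths = []
        for r in self.records:
            rel = f"images/{r.record_id}.png"
            arr = np.clip(np.round(r.image * 255.0), 0, 255).astype(np.uint8)
            iio.imwrite(out / rel, arr)
            paths.append(rel)
        frame.insert(0, "path", paths)
        csv_path = out / "manifest.csv"
        frame.to_csv(csv_path, index=False)
        return csv_path

    @classmethod
    def load(cls, directory: str | Path) -> "DatasetManifest":
        directory = Path(directory)
        frame = pd.read_csv(directory / "manifest.csv")
        required = {"path", "record_id", "patient_id", "source_id", "covid"}
        if not required.issubset(frame.columns):
            raise SchemaError(f"manifest.csv missing columns {required - set(frame.columns)}")
        records = []
        for _, row in frame.iterrows():
            img = iio.imread(directory / row["path"]).astype(np.float64) / 255.0
            aux = np.array([row.get(f"aux_{j + 1:02d}", 0) for j in range(14)], dtype=int)
            records.append(ImageRecord(
                image=img,
                record_id=str(row["record_id"]),
                patient_id=str(row["patient_id"]),
                source_id=str(row["source_id"]),
                covid_label=int(row["covid"]),
                aux_labels=aux,
                projection=str(row.get("projection", "unknown")),
                sex_analogue=str(row.get("sex_analogue", "A")),
                has_signal=int(row.get("has_signal", 0)),
            ))
        return cls(records)


def concat(manifests: Iterable[DatasetManifest]) -> DatasetManifest:
    records: list[ImageRecord] = []
    for m in manifests:
        records.extend(m.records)
    return DatasetManifest(records)
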