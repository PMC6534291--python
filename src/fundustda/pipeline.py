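"""End-to-end orchestration: fields -> diagrams -> features -> CV report.

`run_pipeline` ties the modules together for a whole cohort and writes the
artifact set (diagram CSVs, 66-column feature table, cross-validation
report).  Every output embeds a hash of the full configuration so that no
setting is silently defaulted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from .features import MODEL_FEATURE_SETS, build_feature_vector
from .persistence import (
    PersistenceDiagram,
    build_lower_star_filtration,
    compute_persistence,
    write_diagrams_csv,
)
from .preprocess import DEFAULT_CROP_THRESHOLD, standardize_image

logger = logging.getLogger("fundustda")

_MODELS = ("lasso-min", "lasso-1se", "svm1", "svm2", "all66")
_KERNELS = ("linear", "rbf")


class ConfigError(ValueError):
    """A pipeline option is outside its documented enumeration."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline settings, serializable and hashable.

    ``model`` chooses the classifier variables: ``lasso-min`` / ``lasso-1se``
    run L1 selection at the minimum-CV-error or one-standard-error penalty;
    ``svm1`` / ``svm2`` use the fixed published variable sets; ``all66``
    uses everything.
    """

    crop_threshold: float = DEFAULT_CROP_THRESHOLD
    include_essential: bool = True
    model: str = "lasso-min"
    kernel: str = "linear"
    svm_cost: float = 1.0
    cv_k: tuple[int, ...] = (1,)
    selection_inside: bool = False
    max_folds: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ConfigError(f"model must be one of {_MODELS}")
        if self.kernel not in _KERNELS:
            raise ConfigError(f"kernel must be one of {_KERNELS}")
        if not 0 <= self.crop_threshold <= 255:
            raise ConfigError("crop_threshold must lie in [0, 255]")
        if any(k < 1 for k in self.cv_k):
            raise ConfigError("cross-validation k must be >= 1")
        object.__setattr__(self, "cv_k", tuple(int(k) for k in self.cv_k))

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        data["cv_k"] = tuple(data.get("cv_k", (1,)))
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def field_to_diagrams(field: np.ndarray) -> tuple[PersistenceDiagram, PersistenceDiagram]:
    """Lower-star persistence of a standardized field."""
    return compute_persistence(build_lower_star_filtration(field))


def image_features(field: np.ndarray, include_essential: bool = True) -> pd.Series:
    """The 66-entry feature vector of one standardized field."""
    dgm0, dgm1 = field_to_diagrams(field)
    field_range = (float(np.min(field)), float(np.max(field)))
    return build_feature_vector(dgm0, dgm1, field_range, include_essential=include_essential)


def cohort_table(
    fields: list[np.ndarray],
    manifest: pd.DataFrame,
    include_essential: bool = True,
    out_dir: Path | None = None,
) -> pd.DataFrame:
    """Feature table for a cohort of standardized fields.

    ``manifest`` needs ``image_id`` and ``label`` columns aligned with
    ``fields``.  If ``out_dir`` is given, per-image diagram CSVs are
    written there.
    """
    rows = {}
    for fld, (_, meta) in zip(fields, manifest.iterrows()):
        dgm0, dgm1 = field_to_diagrams(fld)
        if out_dir is not None:
            write_diagrams_csv(Path(out_dir) / f"diagrams_{meta['image_id']}.csv", [dgm0, dgm1])
        field_range = (float(np.min(fld)), float(np.max(fld)))
        rows[meta["image_id"]] = build_feature_vector(
            dgm0, dgm1, field_range, include_essential=include_essential
        )
        logger.info("features computed for %s", meta["image_id"])
    table = pd.DataFrame(rows).T
    table.index.name = "image_id"
    table.insert(0, "label", manifest.set_index("image_id")["label"])
    return table


def classify_table(table: pd.DataFrame, config: PipelineConfig) -> dict:
    """Run variable selection and leave-k-out CV for every configured k."""
    if config.model in ("lasso-min", "lasso-1se"):
        rule = "min" if config.model == "lasso-min" else "one_se"
        features = None if config.selection_inside else clf.lasso_select(
            table, rule=rule, seed=config.seed
        )
    else:
        rule = "min"
        features = list(MODEL_FEATURE_SETS[config.model])
    reports = []
    for k in config.cv_k:
        report = clf.leave_k_out_cv(
            table,
            k=k,
            features=features,
            selection_inside=config.selection_inside,
            selection_rule=rule,
            max_folds=config.max_folds,
            seed=config.seed,
            kernel=config.kernel,
            cost=config.svm_cost,
        )
        reports.append(report.to_dict())
    return {
        "config_hash": config.config_hash,
        "model": config.model,
        "selected_features": features,
        "reports": reports,
    }


def load_field(path: str | Path, crop_threshold: float = DEFAULT_CROP_THRESHOLD) -> np.ndarray:
    """Load a standardized field from an image file or a .npy field dump.

    Raster images (PNG/JPEG/TIFF) go through the full preprocessing chain;
    ``.npy`` files are assumed to already contain grayscale fields and are
    only standardized.
    """
    path = Path(path)
    if path.suffix == ".npy":
        from .preprocess import normal_score_transform

        return normal_score_transform(np.load(path))
    from PIL import Image

    with Image.open(path) as img:
        rgb = np.asarray(img.convert("RGB"))
    return standardize_image(rgb, background_threshold=crop_threshold)


def run_pipeline(
    fields: list[np.ndarray],
    manifest: pd.DataFrame,
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict:
    """Full cohort analysis; writes features.csv, diagrams, cv_report.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(config.to_json())
    table = cohort_table(
        fields, manifest, include_essential=config.include_essential, out_dir=out_dir
    )
    with open(out_dir / "features.csv", "w") as fh:
        fh.write(f"# config_hash={config.config_hash}\n")
        table.to_csv(fh)
    result = classify_table(table, config)
    (out_dir / "cv_report.json").write_text(json.dumps(result, indent=2))
    logger.info("pipeline complete: %s", result["reports"])
    return result
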