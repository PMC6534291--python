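"""Fixed-length topological feature vectors.

One image yields exactly 66 statistics: for each homology dimension
(components, holes) a count, an average lifetime and an APF area, then for
each of six summary polygons (landscapes 1-3 and the 99/95/90% convex
peels) the five shape descriptors Cx, Cy, A, P, F:
``2 * (1 + 1 + 1 + 6 * 5) = 66``.

The registry fixes the names and their order (dimension-major,
statistic-minor), so feature tables are stable across runs and machines.
Named subsets reproduce the two variable sets retained by L1-penalised
selection in the published retinal study (``svm1`` and ``svm2``).
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
import pandas as pd

from .persistence import PersistenceDiagram
from .summaries import (
    DegenerateCloudError,
    PolygonSummary,
    apf_area,
    average_lifetime,
    convex_peel,
    count_points,
    landscape_polygon,
)

__all__ = [
    "FEATURE_NAMES",
    "MODEL_FEATURE_SETS",
    "UnknownFeatureError",
    "build_feature_vector",
    "select_named_features",
    "cohort_feature_table",
]

_DIMS = ("components", "holes")
_POLYGONS = ("landscape1", "landscape2", "landscape3", "peel99", "peel95", "peel90")
_POLY_STATS = ("Cx", "Cy", "A", "P", "F")
_PEEL_PROPORTIONS = {"peel99": 0.99, "peel95": 0.95, "peel90": 0.90}


def _registry() -> list[str]:
    names = []
    for dim in _DIMS:
        names.append(f"{dim}_count")
        names.append(f"{dim}_avg_lifetime")
        names.append(f"{dim}_apf_area")
        for poly in _POLYGONS:
            for stat in _POLY_STATS:
                names.append(f"{dim}_{poly}_{stat}")
    return names


#: The 66 canonical feature names, in canonical order.
FEATURE_NAMES: tuple[str, ...] = tuple(_registry())

#: Variable subsets of the two LASSO-informed classifiers from the retinal
#: study, plus the full vector.
MODEL_FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "svm1": (
        "components_count",
        "components_peel90_Cx",
        "components_peel90_P",
        "components_landscape3_F",
        "components_apf_area",
        "holes_peel99_Cy",
        "holes_landscape1_P",
        "holes_landscape2_Cy",
        "holes_landscape3_Cy",
    ),
    "svm2": (
        "components_count",
        "components_peel90_Cx",
        "components_landscape3_A",
        "components_apf_area",
        "holes_peel99_Cy",
        "holes_landscape1_P",
    ),
    "all66": FEATURE_NAMES,
}


class UnknownFeatureError(KeyError):
    """A requested feature name is not in the 66-name registry."""


class InvalidImageError(ValueError):
    """The dimension-0 diagram is empty: every field has a component."""


def _dimension_block(diagram: PersistenceDiagram, field_range: tuple[float, float]) -> list[float]:
    if len(diagram) == 0:
        block = [0.0, 0.0, 0.0]
    else:
        block = [
            float(count_points(diagram)),
            average_lifetime(diagram),
            apf_area(diagram, field_range),
        ]
    for poly in _POLYGONS:
        if len(diagram) == 0:
            summary = PolygonSummary(0, 0, 0, 0, 0, degenerate=True)
        elif poly.startswith("landscape"):
            summary = landscape_polygon(diagram, int(poly[-1]))
        else:
            try:
                summary = convex_peel(diagram, _PEEL_PROPORTIONS[poly])
            except DegenerateCloudError:
                summary = PolygonSummary(0, 0, 0, 0, 0, degenerate=True)
        if summary.degenerate:
            block.extend([0.0] * 5)
        else:
            block.extend(summary.as_tuple())
    return block


def build_feature_vector(
    dim0: PersistenceDiagram,
    dim1: PersistenceDiagram,
    field_range: tuple[float, float],
    include_essential: bool = True,
) -> pd.Series:
    """Assemble the 66-entry feature vector for one image.

    Parameters
    ----------
    dim0, dim1
        Component and hole diagrams of the same standardized field.
    field_range
        (min, max) of that field; the APF integration domain.
    include_essential
        Whether the capped essential component enters the summaries.

    Returns
    -------
    pandas.Series indexed by :data:`FEATURE_NAMES`, all entries finite.
    """
    if len(dim0) == 0:
        raise InvalidImageError("dimension-0 diagram is empty")
    if not include_essential:
        dim0 = dim0.without_essential()
        dim1 = dim1.without_essential()
    values = _dimension_block(dim0, field_range) + _dimension_block(dim1, field_range)
    vec = pd.Series(values, index=list(FEATURE_NAMES), dtype=np.float64)
    if not np.all(np.isfinite(vec.to_numpy())):
        raise ValueError("feature vector contains non-finite entries")
    return vec


def select_named_features(vector: pd.Series, names) -> pd.Series:
    """Sub-vector in the requested order, validated against the registry.

    ``names`` may be a model key (``svm1``, ``svm2``, ``all66``) or an
    explicit list of registry names; duplicates are rejected.
    """
    if isinstance(names, str):
        try:
            names = MODEL_FEATURE_SETS[names]
        except KeyError:
            raise UnknownFeatureError(
                f"unknown model {names!r}; choose from {sorted(MODEL_FEATURE_SETS)}"
            ) from None
    names = list(names)
    unknown = [n for n in names if n not in FEATURE_NAMES]
    if unknown:
        raise UnknownFeatureError(f"unknown features {unknown}; valid names: {list(FEATURE_NAMES)}")
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise UnknownFeatureError(f"duplicate feature names {dupes}")
    return vector.loc[names]


def cohort_feature_table(vectors: "OrderedDict[str, pd.Series] | dict", labels: dict) -> pd.DataFrame:
    """Stack per-image vectors into a table with image_id index and label column."""
    table = pd.DataFrame({k: v for k, v in vectors.items()}).T
    table.index.name = "image_id"
    table.insert(0, "label", pd.Series(labels))
    return table
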