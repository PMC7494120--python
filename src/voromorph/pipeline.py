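"""End-to-end extraction: raster image -> annotated graph -> feature table.

``extract_features`` is the one-call path from a mask or label image to
the per-boundary 40-metric table; ``GraphFeatureExtractor`` wraps it as a
stateless scikit-learn transformer over lists of images so extraction can
sit inside sklearn pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .annotate import Annotation, annotate
from .config import PipelineConfig
from .profiles import features_table
from .raster import (
    RasterImage,
    preprocess_binary,
    trace_binary_boundaries,
    trace_label_boundaries,
)
from .voronoi import ShapeGraph, build_graph, default_frame

__all__ = ["ExtractionResult", "extract_features", "GraphFeatureExtractor"]


@dataclass
class ExtractionResult:
    image_id: str
    boundaries: list
    graph: ShapeGraph
    annotation: Annotation
    features: pd.DataFrame


def extract_features(
    image: RasterImage,
    image_id: str = "image",
    config: PipelineConfig | None = None,
    preprocess: bool = False,
) -> ExtractionResult:
    """Trace, build and annotate the graph, and compute boundary features."""
    cfg = config or PipelineConfig()
    if image.mode == "binary":
        if preprocess:
            image = preprocess_binary(image, cfg.min_hole_area, cfg.min_object_area)
        boundaries = trace_binary_boundaries(image, shift=cfg.shift)
    else:
        boundaries = trace_label_boundaries(image)
    graph = build_graph(
        boundaries,
        frame=default_frame(image.shape, margin=cfg.frame_margin),
        merge_collinear=cfg.merge_collinear,
        spacing=cfg.sample_spacing,
    )
    ann = annotate(graph, boundaries)
    feats = features_table(ann, image_id=image_id)
    return ExtractionResult(
        image_id=image_id,
        boundaries=boundaries,
        graph=graph,
        annotation=ann,
        features=feats,
    )


class GraphFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer: list of RasterImages -> stacked per-boundary features.

    Stateless (``fit`` is a no-op); ``transform`` returns one DataFrame
    with an ``image_id`` column (positional ids unless the input is a
    dict of id -> image).
    """

    def __init__(self, config: PipelineConfig | None = None, preprocess: bool = False):
        self.config = config
        self.preprocess = preprocess

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        items = X.items() if isinstance(X, dict) else ((f"img{i:04d}", im) for i, im in enumerate(X))
        tables = [
            extract_features(
                im, image_id=str(key), config=self.config, preprocess=self.preprocess
            ).features
            for key, im in items
        ]
        return pd.concat(tables, ignore_index=True)
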