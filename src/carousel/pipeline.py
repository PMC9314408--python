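"""End-to-end composition helpers.

Thin convenience layer chaining the pipeline stages: sessions are split at
the shock sector, subsegmented at angular-speed change points, featurised,
and either clustered (discovery) or classified (transfer).  Each stage
remains available individually in its own module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clustering import fit_clusters, map_clusters_by_majority
from .features import FEATURE_NAMES, features_table
from .io import ArenaConfig, Segment, Trajectory
from .segmentation import SegmentationParams, segment_by_sector, subsegment_all

__all__ = ["segment_cohort", "featurize_cohort", "discover_strategies"]


def segment_cohort(trajectories: list[Trajectory], config: ArenaConfig,
                   params: SegmentationParams | None = None) -> list[Segment]:
    """Two-stage segmentation of every session; returns all subsegments."""
    params = params or SegmentationParams()
    stage1: list[Segment] = []
    for traj in trajectories:
        stage1.extend(segment_by_sector(traj, config,
                                        min_duration=params.min_subsegment_duration))
    return subsegment_all(stage1, params)


def featurize_cohort(segments: list[Segment], config: ArenaConfig) -> pd.DataFrame:
    """Feature table (ids + 11 features) of a list of subsegments."""
    return features_table(segments, config)


def discover_strategies(features: pd.DataFrame, k: int = 5, n_components: int = 8,
                        truth_labels=None):
    """Cluster the feature table; optionally map clusters to strategy names.

    With ``truth_labels`` (synthetic benchmarks) clusters are named by the
    plurality ground-truth label of their members and the returned frame
    gains a ``label`` column; without it, naming is the user's manual step.
    Returns ``(model, frame)`` where ``frame`` adds a ``cluster`` column.
    """
    X = features[list(FEATURE_NAMES)].to_numpy(float)
    model = fit_clusters(X, k=k, n_components=min(n_components, X.shape[1]))
    out = features.copy()
    out["cluster"] = model.labels
    if truth_labels is not None:
        mapping = map_clusters_by_majority(model.labels, np.asarray(truth_labels))
        out["label"] = [mapping[c] for c in model.labels]
    return model, out
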