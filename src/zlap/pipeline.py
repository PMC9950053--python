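"""End-to-end orchestration: simulated or parsed poses -> profiles -> screen calls.

These helpers chain the per-module operations so the command-line layer (and
tests) can run whole stages without repeating the plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import behavior_profile, group_stats, kinematics, profile_analysis
from .pose_io import StimulusSchedule, default_schedule
from .synthetic_data import SimulatedScreen

REFERENCE_COMPOUNDS = ["CsA", "FK506"]


def screen_features(screen: SimulatedScreen) -> dict[str, np.ndarray]:
    """Per-frame feature arrays (larvae x frames) for a simulated screen."""
    return kinematics.compute_feature_arrays(screen.pose, screen.wells)


def screen_feature_table(screen: SimulatedScreen) -> pd.DataFrame:
    """The full 33-column feature table of a simulated screen (all plates)."""
    plates = pd.Series(screen.plate_ids)
    n_frames = screen.pose["x_yolk"].shape[1]
    tables = []
    for plate_id in plates.unique():
        idx = np.flatnonzero((plates == plate_id).to_numpy())
        pose = {k: v[idx] for k, v in screen.pose.items()}
        wells = [screen.wells[i] for i in idx]
        feats = kinematics.compute_feature_arrays(pose, wells)
        tables.append(kinematics.feature_arrays_to_table(
            feats, wells, screen.schedule, plate_id, n_frames))
    return pd.concat(tables, ignore_index=True)


def screen_profiles(screen: SimulatedScreen) -> pd.DataFrame:
    """Behavioral profiles for every larva of a simulated screen."""
    feats = screen_features(screen)
    profiles = behavior_profile.profiles_from_arrays(feats, screen.schedule)
    profiles.insert(0, "well_id", [w.well_id for w in screen.wells])
    profiles.insert(0, "plate_id", screen.plate_ids)
    return profiles


@dataclass
class ScreenAnalysis:
    """All screen-level outputs derived from one profile set."""

    summary: pd.DataFrame               # long per-group mean/sd/n
    matrix: pd.DataFrame                # DMSO-standardized treatment x 25
    pca: profile_analysis.PCAResult
    k: int
    kmeans: profile_analysis.ClusterResult
    ward: profile_analysis.ClusterResult
    kmeans_reference_cluster: int | None
    ward_reference_cluster: int | None
    pvalues: pd.DataFrame | None = None


def analyze_screen(
    profiles: pd.DataFrame,
    treatment_map: pd.DataFrame,
    reference: str = "DMSO",
    reference_compounds: list[str] | None = None,
    seed: int = 0,
    k: int | None = None,
    variance_retained_pct: float = profile_analysis.VARIANCE_RETAINED_PCT,
    compute_pvalues: bool = False,
) -> ScreenAnalysis:
    """Standardize, decompose and cluster a screen's behavioral profiles.

    When ``k`` is None the cluster count is chosen by average silhouette
    width on the retained PCA axes.  The reference (CsA-type) cluster is the
    one containing all of ``reference_compounds`` in each clustering.
    """
    reference_compounds = reference_compounds or REFERENCE_COMPOUNDS
    summary = behavior_profile.group_summary(profiles, treatment_map)
    matrix = group_stats.dmso_standardize(summary, reference=reference)
    pca = profile_analysis.pca_profiles(matrix)
    d = pca.n_components_for(variance_retained_pct)
    scores = pca.scores.iloc[:, :d]
    if k is None:
        k = profile_analysis.choose_k_silhouette(scores, seed=seed)
    km = profile_analysis.kmeans_clusters(scores, k, seed=seed, matrix=matrix)
    ward = profile_analysis.hierarchical_clusters(matrix, k)
    refs_present = [r for r in reference_compounds if r in matrix.index]
    km_ref = ward_ref = None
    if refs_present:
        km_ref = profile_analysis.identify_reference_cluster(km, refs_present)
        ward_ref = profile_analysis.identify_reference_cluster(ward, refs_present)
    pvalues = None
    if compute_pvalues:
        pvalues = group_stats.test_treatments_against_reference(
            profiles, treatment_map, reference=reference)
    return ScreenAnalysis(summary=summary, matrix=matrix, pca=pca, k=k,
                          kmeans=km, ward=ward,
                          kmeans_reference_cluster=km_ref,
                          ward_reference_cluster=ward_ref,
                          pvalues=pvalues)


def cluster_precision_recall(
    labels: pd.Series,
    reference_cluster: int | None,
    truth: Mapping[str, str],
    positive_phenotype: str = "csa_like",
) -> tuple[float, float]:
    """Precision/recall of the reference cluster against ground-truth phenotypes.

    Treatments in the reference cluster are the predicted positives; the true
    positives are those with the target phenotype.  Returns (NaN, 0.0) when no
    reference cluster was identified.
    """
    actual = {t for t, p in truth.items() if p == positive_phenotype and t in labels.index}
    if reference_cluster is None:
        return float("nan"), 0.0
    predicted = set(labels.index[labels == reference_cluster])
    if not predicted or not actual:
        return float("nan"), float("nan")
    tp = len(predicted & actual)
    return tp / len(predicted), tp / len(actual)
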