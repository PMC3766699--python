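"""Feature filtering and descriptive statistics preceding differential analysis.

Covers the study's pre-analysis funnel: a detection filter for miRNAs (with a
class-exemption rule for miRNAs silent in exactly one tissue class), a
variability filter for genes, a mean-signal floor, transition pattern counts
at a fold-change threshold, unsupervised sample clustering with a per-patient
pairing score, a biogenesis-balance summary over differentially expressed
miRNAs, and Shannon-entropy profiling used to pick stable reference features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy import stats

from .io_formats import ExpressionMatrix, SampleSheet

DEFAULT_DETECTION_FLOOR = 1.0


def filter_mirnas_by_detection(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    detection: pd.DataFrame | None = None,
    min_detected: int = 20,
    detection_floor: float = DEFAULT_DETECTION_FLOOR,
) -> ExpressionMatrix:
    """Drop miRNAs detected in fewer than ``min_detected`` samples.

    A miRNA is exempt from the filter when all of its undetected samples fall
    within a single tissue class (a class-wide absence is treated as biology,
    not as an unreliable probe).  Detection evidence is either an explicit
    boolean matrix aligned with ``matrix`` or derived as value >
    ``detection_floor``.  Retained feature order is stable.
    """
    if detection is None:
        detected = matrix.data.gt(detection_floor)
    else:
        if list(detection.index) != matrix.feature_ids or list(detection.columns) != matrix.sample_ids:
            raise ValueError("detection matrix shape/labels do not match the expression matrix")
        detected = detection.astype(bool)
    tissue = pd.Series(sheet.tissue_of()).reindex(matrix.sample_ids)
    if tissue.isna().any():
        missing = tissue.index[tissue.isna()].tolist()
        raise ValueError(f"samples missing from sheet: {missing[:5]}")

    n_detected = detected.sum(axis=1)
    keep = n_detected >= min_detected
    undetected = ~detected
    for fid in matrix.data.index[~keep]:
        classes = set(tissue[undetected.loc[fid]])
        if len(classes) == 1:
            keep.loc[fid] = True  # class-exemption rule
    return ExpressionMatrix(matrix.data.loc[keep], matrix.feature_kind)


def filter_genes_by_variability(
    matrix: ExpressionMatrix, drop_fraction: float = 0.30
) -> ExpressionMatrix:
    """Keep the ``floor((1-drop_fraction)*n)`` most variable features.

    Variability is the sample variance of log2 values across all samples;
    ties keep the earlier input row (stable sort).
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must lie in [0, 1)")
    if matrix.n_samples < 2:
        raise ValueError("variability filter needs at least 2 samples")
    n_keep = int(np.floor((1 - drop_fraction) * matrix.n_features))
    variances = matrix.data.var(axis=1, ddof=1)
    order = np.argsort(-variances.to_numpy(), kind="stable")
    kept = np.sort(order[:n_keep])  # restore input order among the retained
    return ExpressionMatrix(matrix.data.iloc[kept], matrix.feature_kind)


def filter_by_mean_signal(
    matrix: ExpressionMatrix,
    floor: float = 5.0,
    sheet: SampleSheet | None = None,
    scope: str = "all",
) -> ExpressionMatrix:
    """Keep features whose mean log2 signal exceeds ``floor``.

    ``scope='all'`` averages over all samples; ``scope='any_class'`` keeps a
    feature when any tissue-class mean exceeds the floor (requires ``sheet``).
    """
    if matrix.n_features == 0:
        return matrix
    if scope == "all":
        keep = matrix.data.mean(axis=1) > floor
    elif scope == "any_class":
        if sheet is None:
            raise ValueError("scope='any_class' requires a sample sheet")
        tissue = pd.Series(sheet.tissue_of()).reindex(matrix.sample_ids)
        class_means = matrix.data.T.groupby(tissue.to_numpy()).mean().T
        keep = (class_means > floor).any(axis=1)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return ExpressionMatrix(matrix.data.loc[keep], matrix.feature_kind)


@dataclass
class TransitionPatternCounts:
    """Up/down/unchanged feature counts for each progression contrast."""

    counts: pd.DataFrame  # index: contrast, columns: up, down, unchanged
    fc_threshold: float

    def total(self, contrast: str) -> int:
        return int(self.counts.loc[contrast].sum())


def class_mean_log2fc(
    matrix: ExpressionMatrix, sheet: SampleSheet, class_a: str, class_b: str
) -> pd.Series:
    """Per-feature log2 fold change: mean(class A) - mean(class B)."""
    samples_a = sheet.samples_in_class(class_a, restrict_to=matrix.sample_ids)
    samples_b = sheet.samples_in_class(class_b, restrict_to=matrix.sample_ids)
    if not samples_a or not samples_b:
        raise ValueError(f"contrast {class_a} vs {class_b} has an empty class")
    return matrix.data[samples_a].mean(axis=1) - matrix.data[samples_b].mean(axis=1)


def transition_pattern_counts(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    fc_threshold: float = 1.0,
    contrasts: tuple[tuple[str, str], ...] = (("T", "N"), ("M", "T")),
) -> TransitionPatternCounts:
    """Count features up-, down-modulated or unchanged in each transition."""
    rows = {}
    for class_a, class_b in contrasts:
        fc = class_mean_log2fc(matrix, sheet, class_a, class_b)
        up = int((fc > fc_threshold).sum())
        down = int((fc < -fc_threshold).sum())
        rows[f"{class_a}v{class_b}"] = {
            "up": up, "down": down, "unchanged": matrix.n_features - up - down,
        }
    counts = pd.DataFrame(rows).T[["up", "down", "unchanged"]]
    return TransitionPatternCounts(counts, fc_threshold)


@dataclass
class ClusteringResult:
    """Agglomerative clustering of samples with the flat cut and pairing data."""

    sample_ids: list[str]
    merge_tree: np.ndarray            # scipy linkage matrix
    flat_clusters: pd.Series          # sample_id -> cluster label
    cophenetic: pd.DataFrame          # sample x sample cophenetic distances


def cluster_samples(
    matrix: ExpressionMatrix,
    metric: str = "correlation",
    method: str = "average",
    n_clusters: int = 3,
) -> ClusteringResult:
    """Hierarchical clustering of samples on feature profiles.

    Defaults to 1 - Pearson correlation distance with average linkage.  The
    tree is deterministic for a fixed input; sample order only permutes leaf
    labels.  Samples are sorted by ID before computing the tree so that the
    result is invariant to input column order.
    """
    if matrix.n_samples < 2:
        raise ValueError("clustering needs at least 2 samples")
    order = sorted(matrix.sample_ids)
    profiles = matrix.data[order].T.to_numpy()
    dist = pdist(profiles, metric=metric)
    dist = np.clip(dist, 0.0, None)  # correlation distance can dip below 0 numerically
    tree = linkage(dist, method=method)
    labels = fcluster(tree, t=n_clusters, criterion="maxclust")
    coph = squareform(cophenet(tree))
    return ClusteringResult(
        sample_ids=order,
        merge_tree=tree,
        flat_clusters=pd.Series(labels, index=order),
        cophenetic=pd.DataFrame(coph, index=order, columns=order),
    )


def patient_pairing_score(clustering: ClusteringResult, sheet: SampleSheet) -> float:
    """Fraction of T/M patients whose two samples are mutual nearest neighbors.

    For each patient contributing both a T and an M sample to the clustered
    matrix, the pair counts as 'paired' when each sample is the other's
    nearest neighbor in cophenetic distance (self excluded).  Undefined — and
    an error — when no patient contributes both tissues.
    """
    tissue = sheet.tissue_of()
    patient = sheet.patient_of()
    present = set(clustering.sample_ids)
    pairs: dict[str, dict[str, str]] = {}
    for sid in clustering.sample_ids:
        t = tissue.get(sid)
        if t in ("T", "M"):
            pairs.setdefault(patient[sid], {})[t] = sid
    eligible = {p: d for p, d in pairs.items() if {"T", "M"} <= set(d)}
    if not eligible:
        raise ValueError("no patient contributes both a T and an M sample")
    coph = clustering.cophenetic.copy()
    np.fill_diagonal(coph.values, np.inf)
    nearest = coph.idxmin(axis=1)
    n_paired = sum(
        1
        for d in eligible.values()
        if nearest[d["T"]] == d["M"] and nearest[d["M"]] == d["T"]
    )
    return n_paired / len(eligible)


def biogenesis_balance(
    dem_ids: list[str], matrix: ExpressionMatrix, sheet: SampleSheet
) -> pd.DataFrame:
    """Class-wise mean DEM expression and pairwise mean-equality t-tests.

    Pools all expression values of the differentially expressed miRNAs within
    each tissue class; a two-sided Welch t-test compares each class pair.  A
    balanced result (all p large) argues against a global shift in miRNA
    biogenesis during progression.
    """
    sub = matrix.subset_features(dem_ids)
    tissue = pd.Series(sheet.tissue_of()).reindex(sub.sample_ids)
    pools = {
        cls: sub.data.loc[:, (tissue == cls).to_numpy()].to_numpy().ravel()
        for cls in ("N", "T", "M")
    }
    rows = []
    classes = [c for c in ("N", "T", "M") if len(pools[c])]
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            _, p = stats.ttest_ind(pools[a], pools[b], equal_var=False)
            rows.append(
                {
                    "class_a": a,
                    "class_b": b,
                    "mean_a": float(np.mean(pools[a])),
                    "mean_b": float(np.mean(pools[b])),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)


def expression_entropy(profile: np.ndarray | pd.Series, n_bins: int = 10) -> float:
    """Shannon entropy (bits) of a profile over equal-width bins of its range.

    A constant profile has zero entropy by definition; the maximum is
    ``log2(n_bins)``.  Used to rank candidate reference features by stability
    (minimum entropy = most stable).
    """
    values = np.asarray(profile, dtype=float)
    if values.size == 0:
        raise ValueError("empty profile")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / values.size
    return float(-(p * np.log2(p)).sum())
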