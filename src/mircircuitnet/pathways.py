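"""Gene-set perturbation testing over DEM target genes.

A two-directional set-level test in the spirit of generally applicable
gene-set enrichment: per-gene two-sample t statistics for a contrast are
summarized per set as

    z = (mean_set - mean_universe) * sqrt(|S|) / sd_universe

with one-sided normal p-values for coordinated up- or down-shifts and a
two-sided variant covering perturbation in both directions.  Two enrichment
strategies restrict the tested universe: (A) all supported targets of the
selected DEMs, or (B) only the differentially expressed targets of the DEMs.
A sample-label permutation null is available for small cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, SampleSheet
from .sam_de import parse_contrast
from .target_support import bh_adjust

DIRECTIONS = ("up", "down", "two_way")


def gene_level_statistics(
    matrix: ExpressionMatrix, sheet: SampleSheet, contrast
) -> pd.Series:
    """Per-gene two-sample t statistic (class A minus class B)."""
    class_a, class_b = parse_contrast(contrast)
    samples_a = sheet.samples_in_class(class_a, restrict_to=matrix.sample_ids)
    samples_b = sheet.samples_in_class(class_b, restrict_to=matrix.sample_ids)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(f"contrast {class_a} vs {class_b}: each class needs >= 2 samples")
    t, _ = stats.ttest_ind(
        matrix.data[samples_a], matrix.data[samples_b], axis=1, equal_var=True
    )
    return pd.Series(t, index=matrix.data.index, name=f"{class_a}v{class_b}")


@dataclass
class GeneSetResult:
    set_name: str
    direction: str
    set_size_tested: int
    n_members_dropped: int
    z: float
    p: float
    strategy: str = ""
    significant: bool = False
    testable: bool = True


def gage_set_test(
    gene_stats: pd.Series, gene_set, direction: str = "two_way", set_name: str = ""
) -> GeneSetResult:
    """Set-level standardized mean shift of per-gene statistics.

    Members absent from the universe are dropped (and counted); a set with
    fewer than two present members is flagged untestable.  A set spanning the
    whole universe has z = 0 by construction.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    members = [g for g in gene_set if g in gene_stats.index]
    dropped = len(list(gene_set)) - len(members)
    if len(members) < 2:
        return GeneSetResult(set_name, direction, len(members), dropped,
                             np.nan, np.nan, testable=False)
    all_values = gene_stats.to_numpy(dtype=float)
    set_values = gene_stats.loc[members].to_numpy(dtype=float)
    sd_all = all_values.std(ddof=1)
    if sd_all == 0:
        return GeneSetResult(set_name, direction, len(members), dropped,
                             np.nan, np.nan, testable=False)
    z = (set_values.mean() - all_values.mean()) * np.sqrt(len(members)) / sd_all
    if direction == "up":
        p = float(stats.norm.sf(z))
    elif direction == "down":
        p = float(stats.norm.cdf(z))
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return GeneSetResult(set_name, direction, len(members), dropped, float(z), p)


def gage_set_test_permutation(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    contrast,
    gene_set,
    direction: str = "two_way",
    n_permutations: int = 1000,
    seed: int = 0,
    set_name: str = "",
) -> GeneSetResult:
    """Permutation-null variant: z recomputed under sample-label shuffles."""
    observed = gage_set_test(
        gene_level_statistics(matrix, sheet, contrast), gene_set,
        direction=direction, set_name=set_name,
    )
    if not observed.testable:
        return observed
    class_a, class_b = parse_contrast(contrast)
    samples_a = sheet.samples_in_class(class_a, restrict_to=matrix.sample_ids)
    samples_b = sheet.samples_in_class(class_b, restrict_to=matrix.sample_ids)
    cols = samples_a + samples_b
    X = matrix.data[cols]
    rng = np.random.default_rng(seed)
    na = len(samples_a)
    null_z = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(cols))
        shuffled = ExpressionMatrix(
            pd.DataFrame(X.to_numpy()[:, perm], index=X.index, columns=cols),
            matrix.feature_kind,
        )
        stats_i = gene_level_statistics(shuffled, sheet, contrast)
        null_z[i] = gage_set_test(stats_i, gene_set, direction="two_way").z
    if direction == "up":
        p = (1 + np.sum(null_z >= observed.z)) / (1 + n_permutations)
    elif direction == "down":
        p = (1 + np.sum(null_z <= observed.z)) / (1 + n_permutations)
    else:
        p = (1 + np.sum(np.abs(null_z) >= abs(observed.z))) / (1 + n_permutations)
    observed.p = float(p)
    return observed


def enrich_pathways(
    relations: pd.DataFrame,
    dems: pd.DataFrame,
    degs: pd.DataFrame | None,
    gene_sets: dict[str, list[str]],
    gene_stats: pd.Series,
    strategy: str = "A",
    direction: str = "two_way",
    alpha: float = 0.05,
    adjust: bool = False,
) -> list[GeneSetResult]:
    """Test every gene set against the DEM-target universe of a strategy.

    Strategy ``A``: universe = supported targets of the selected DEMs (their
    contrast statistics must be available).  Strategy ``B``: universe further
    restricted to targets that are themselves differentially expressed.
    Results with p < ``alpha`` are flagged significant; ``adjust=True``
    applies BH across the tested sets first.
    """
    if strategy not in ("A", "B"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if dems.empty:
        return []
    dem_ids = set(dems["feature_id"])
    targets = set(relations.loc[relations["mirna_id"].isin(dem_ids), "gene_id"])
    if strategy == "B":
        if degs is None or degs.empty:
            return []
        targets &= set(degs["feature_id"])
    universe = gene_stats.loc[gene_stats.index.isin(targets)]
    if len(universe) < 2:
        return []
    results = []
    for name, members in gene_sets.items():
        res = gage_set_test(universe, members, direction=direction, set_name=name)
        res.strategy = strategy
        results.append(res)
    tested = [r for r in results if r.testable]
    if adjust and tested:
        qs = bh_adjust([r.p for r in tested])
        for r, q in zip(tested, qs):
            r.p = float(q)
    for r in tested:
        r.significant = bool(r.p < alpha)
    return results


def results_to_frame(results: list[GeneSetResult]) -> pd.DataFrame:
    rows = [
        {
            "set_name": r.set_name, "strategy": r.strategy, "direction": r.direction,
            "set_size_tested": r.set_size_tested, "z": r.z, "p": r.p,
            "significant": r.significant, "testable": r.testable,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["set_name", "strategy", "direction", "set_size_tested",
                       "z", "p", "significant", "testable"],
    )
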