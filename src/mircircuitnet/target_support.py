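"""Expression support for predicted miRNA->target relations.

A predicted miRNA->gene pair is *supported* when the two expression profiles
are significantly negatively correlated across the samples profiled on both
assays: Pearson r, a two-sided t-transform p-value, Benjamini-Hochberg FDR
over all performed tests, and the requirement r < 0 at q below threshold.
A Storey-style q-value with pi0 estimation is available as an alternative
to plain BH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, SampleSheet


def match_samples(
    mirna_matrix: ExpressionMatrix,
    gene_matrix: ExpressionMatrix,
    sheet: SampleSheet | None = None,
) -> list[str]:
    """Samples profiled on both assays, in the miRNA matrix's column order."""
    gene_samples = set(gene_matrix.sample_ids)
    matched = [s for s in mirna_matrix.sample_ids if s in gene_samples]
    if not matched:
        raise ValueError("no samples shared between the miRNA and gene matrices")
    if sheet is not None:
        known = set(sheet.sample_ids)
        missing = [s for s in matched if s not in known]
        if missing:
            raise ValueError(f"matched samples missing from sheet: {missing[:5]}")
    return matched


def correlate(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p from t = r*sqrt(n-2)/sqrt(1-r^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("correlate needs two equal-length vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def storey_qvalues(pvalues, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values: BH scaled by pi0 = #{p > lambda} / (m * (1 - lambda))."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    pi0 = min(1.0, np.mean(p > lambda_) / (1.0 - lambda_))
    pi0 = max(pi0, 1.0 / p.size)
    return np.minimum(bh_adjust(p) * pi0, 1.0)


@dataclass
class SupportSummary:
    n_relations: int
    n_mirnas: int
    n_genes: int
    min_targets_per_mirna: int
    mean_targets_per_mirna: float
    max_targets_per_mirna: int
    conserved_fraction: float


def support_targets(
    mirna_matrix: ExpressionMatrix,
    gene_matrix: ExpressionMatrix,
    sheet: SampleSheet,
    predictions: pd.DataFrame,
    q_max: float = 0.01,
    direction: str = "negative",
    method: str = "bh",
) -> tuple[pd.DataFrame, dict]:
    """Test every prediction whose miRNA and gene survive upstream filtering.

    One correlation test per unique (miRNA, gene) pair over the matched
    samples; multiple predictions for the same pair (distinct sites) collapse
    to one test before correction.  Supported relations have ``q <= q_max``
    and, for the default negative direction, ``r < 0``.  Returns the relations
    sorted by r ascending plus a report counting skipped predictions.
    """
    if direction not in ("negative", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    if method not in ("bh", "storey"):
        raise ValueError(f"unknown method {method!r}")
    columns = ["mirna_id", "gene_id", "r", "p", "q", "conserved", "n"]
    report = {"n_predictions": int(len(predictions)), "n_tested": 0,
              "n_skipped_missing_feature": 0, "n_collapsed_duplicates": 0,
              "realized_r_cut": np.nan}
    if predictions.empty:
        return pd.DataFrame(columns=columns), report

    matched = match_samples(mirna_matrix, gene_matrix, sheet)
    n = len(matched)
    mirna_present = set(mirna_matrix.feature_ids)
    gene_present = set(gene_matrix.feature_ids)

    uniq = predictions.drop_duplicates(subset=["mirna_id", "gene_id"]).copy()
    report["n_collapsed_duplicates"] = int(len(predictions) - len(uniq))
    testable = uniq[
        uniq["mirna_id"].isin(mirna_present) & uniq["gene_id"].isin(gene_present)
    ].sort_values(["mirna_id", "gene_id"], kind="stable")  # order-invariant output
    report["n_skipped_missing_feature"] = int(len(uniq) - len(testable))
    if testable.empty:
        return pd.DataFrame(columns=columns), report

    M = mirna_matrix.data.loc[:, matched]
    G = gene_matrix.data.loc[:, matched]
    # standardized profiles -> correlation is a dot product per pair
    Mz = _rowwise_standardize(M.to_numpy())
    Gz = _rowwise_standardize(G.to_numpy())
    m_index = {fid: i for i, fid in enumerate(M.index)}
    g_index = {fid: i for i, fid in enumerate(G.index)}
    mi = testable["mirna_id"].map(m_index).to_numpy()
    gi = testable["gene_id"].map(g_index).to_numpy()
    r = np.einsum("ij,ij->i", Mz[mi], Gz[gi]) / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(p), 0.0, p)  # |r| == 1 exactly

    q = bh_adjust(p) if method == "bh" else storey_qvalues(p)
    report["n_tested"] = int(len(testable))

    out = pd.DataFrame(
        {
            "mirna_id": testable["mirna_id"].to_numpy(),
            "gene_id": testable["gene_id"].to_numpy(),
            "r": r,
            "p": p,
            "q": q,
            "conserved": testable["conserved"].to_numpy(),
            "n": n,
        }
    )
    keep = out["q"] <= q_max
    if direction == "negative":
        keep &= out["r"] < 0
    supported = out.loc[keep].sort_values(
        ["r", "mirna_id", "gene_id"], kind="stable"
    ).reset_index(drop=True)
    if not supported.empty:
        # realized r threshold: the weakest (largest) supported anti-correlation
        report["realized_r_cut"] = float(supported["r"].max())
    return supported, report


def _rowwise_standardize(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd == 0, np.nan, sd)
    return (values - mean) / sd


def summarize_support(relations: pd.DataFrame) -> SupportSummary:
    """Counts and per-miRNA target distribution over supported relations."""
    if relations.empty:
        return SupportSummary(0, 0, 0, 0, 0.0, 0, 0.0)
    per_mirna = relations.groupby("mirna_id").size()
    return SupportSummary(
        n_relations=int(len(relations)),
        n_mirnas=int(relations["mirna_id"].nunique()),
        n_genes=int(relations["gene_id"].nunique()),
        min_targets_per_mirna=int(per_mirna.min()),
        mean_targets_per_mirna=float(len(relations) / relations["mirna_id"].nunique()),
        max_targets_per_mirna=int(per_mirna.max()),
        conserved_fraction=float(relations["conserved"].mean()),
    )
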