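"""Significance Analysis of Microarrays (SAM) for two-class designs.

Implements the canonical permutation procedure: a relative-difference
statistic ``d = (mean_A - mean_B) / (s + s0)`` with a pooled standard error
``s`` and a variance-stabilizing fudge factor ``s0`` chosen to minimize the
coefficient of variation of the d spread across windows of ``s``; expected
order statistics from label permutations; asymmetric delta cutoffs; and an
FDR estimate ``pi0 * median permuted call count / observed call count`` with
``pi0`` taken from the central 50% of the permuted d distribution.  The delta
threshold is tuned to a target FDR and each feature receives a q-value equal
to the FDR at the loosest delta that calls it.

The paired design operates on within-patient differences (one-sample SAM)
with sign-flip permutations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, SampleSheet

S0_PERCENTILE_GRID = tuple(range(0, 101, 5))


@dataclass
class SamConfig:
    design: str = "unpaired"          # or "paired"
    n_permutations: int = 1000
    fdr_target: float = 0.01
    n_delta: int = 100                # resolution of the delta grid
    n_s_windows: int = 10             # windows for the s0 search
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("unpaired", "paired"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if not 0 < self.fdr_target < 1:
            raise ValueError("fdr_target must lie in (0, 1)")


@dataclass
class SamResult:
    """Per-feature results plus the delta-tuning table and tuned parameters."""

    table: pd.DataFrame          # feature_id, d, log2fc, mean_a, mean_b, q, called
    delta_table: pd.DataFrame    # delta, n_called, median_false, fdr
    s0: float
    pi0: float
    delta: float                 # chosen delta
    contrast: tuple[str, str]
    design: str
    expected_d: np.ndarray | None = None   # permutation order statistics (sorted)


def parse_contrast(contrast) -> tuple[str, str]:
    """Accept ('T','N') or the compact 'TvN' form."""
    if isinstance(contrast, str):
        parts = contrast.split("v")
        if len(parts) != 2:
            raise ValueError(f"cannot parse contrast {contrast!r}")
        return parts[0], parts[1]
    a, b = contrast
    return str(a), str(b)


def _pooled_se(values_a: np.ndarray, values_b: np.ndarray, axis=-1) -> np.ndarray:
    na = values_a.shape[axis]
    nb = values_b.shape[axis]
    ssa = np.sum((values_a - values_a.mean(axis=axis, keepdims=True)) ** 2, axis=axis)
    ssb = np.sum((values_b - values_b.mean(axis=axis, keepdims=True)) ** 2, axis=axis)
    return np.sqrt((1.0 / na + 1.0 / nb) * (ssa + ssb) / (na + nb - 2))


def sam_statistic(values_a, values_b, s0: float = 0.0) -> float:
    """Relative difference d = (mean_a - mean_b) / (pooled SE + s0)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    s = float(_pooled_se(a, b))
    if s + s0 == 0:
        raise ValueError("zero variance with s0=0: d undefined")
    return float((a.mean() - b.mean()) / (s + s0))


def _d_and_s(X: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray, s0: float):
    a = X[:, mask_a]
    b = X[:, mask_b]
    s = _pooled_se(a, b, axis=1)
    d = (a.mean(axis=1) - b.mean(axis=1)) / (s + s0)
    return d, s


def _window_spread_cv(d: np.ndarray, s: np.ndarray, n_windows: int) -> float:
    """CV across s-quantile windows of the median absolute deviation of d."""
    order = np.argsort(s, kind="stable")
    splits = np.array_split(order, n_windows)
    mads = []
    for idx in splits:
        if idx.size == 0:
            continue
        window = d[idx]
        mads.append(np.median(np.abs(window - np.median(window))))
    mads = np.asarray(mads)
    mean = mads.mean()
    if mean == 0:
        return np.inf
    return float(mads.std(ddof=0) / mean)


def estimate_s0(
    X: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    percentiles=S0_PERCENTILE_GRID,
    n_windows: int = 10,
) -> float:
    """Fudge factor: the s-percentile minimizing the CV of the d spread.

    For each candidate percentile of the per-feature pooled-SE distribution,
    d is recomputed with that s0 and the coefficient of variation of its
    spread (window-wise MAD) across s-quantile windows is measured; the
    smallest percentile attaining the minimum wins.
    """
    _, s = _d_and_s(X, mask_a, mask_b, 0.0)
    best_cv, best_s0 = np.inf, None
    for pct in percentiles:
        cand = float(np.percentile(s, pct))
        d_cand = (X[:, mask_a].mean(axis=1) - X[:, mask_b].mean(axis=1)) / (s + cand)
        cv = _window_spread_cv(d_cand, s, n_windows)
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, cand
    if best_s0 is None:  # all windows degenerate: fall back to the median s
        best_s0 = float(np.percentile(s, 50))
    return best_s0


def _unpaired_permutations(n: int, na: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean masks (n_perm x n) assigning ``na`` columns to group A."""
    total = comb(n, na)
    if total <= n_perm:
        combos = itertools.combinations(range(n), na)
        masks = np.zeros((total, n), dtype=bool)
        for i, cols in enumerate(combos):
            masks[i, list(cols)] = True
        return masks
    seen = set()
    masks = np.zeros((n_perm, n), dtype=bool)
    i = 0
    while i < n_perm:
        cols = tuple(sorted(rng.choice(n, size=na, replace=False).tolist()))
        if cols in seen:
            continue
        seen.add(cols)
        masks[i, list(cols)] = True
        i += 1
    return masks


def _permuted_d_unpaired(
    X: np.ndarray, masks: np.ndarray, na: int, nb: int, s0: float
) -> np.ndarray:
    """d for every permutation, vectorized over features and permutations."""
    A = masks.T.astype(float)           # n_samples x P
    B = 1.0 - A
    Xsq = X**2
    sum_a = X @ A
    sum_b = X @ B
    mean_a = sum_a / na
    mean_b = sum_b / nb
    ssa = Xsq @ A - na * mean_a**2
    ssb = Xsq @ B - nb * mean_b**2
    ssa = np.clip(ssa, 0.0, None)
    ssb = np.clip(ssb, 0.0, None)
    s = np.sqrt((1.0 / na + 1.0 / nb) * (ssa + ssb) / (na + nb - 2))
    return (mean_a - mean_b) / (s + s0)    # features x P


def _cutoffs(d_sorted: np.ndarray, dbar: np.ndarray, delta: float) -> tuple[float, float]:
    diff = d_sorted - dbar
    up = d_sorted[(diff >= delta) & (d_sorted > 0)]
    cut_up = up.min() if up.size else np.inf
    low = d_sorted[(diff <= -delta) & (d_sorted < 0)]
    cut_low = low.max() if low.size else -np.inf
    return cut_up, cut_low


def sam_fdr(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    contrast,
    config: SamConfig | None = None,
) -> SamResult:
    """Full SAM run for one contrast: statistics, delta tuning and q-values."""
    config = config or SamConfig()
    class_a, class_b = parse_contrast(contrast)
    rng = np.random.default_rng(config.seed)

    if config.design == "unpaired":
        samples_a = sheet.samples_in_class(class_a, restrict_to=matrix.sample_ids)
        samples_b = sheet.samples_in_class(class_b, restrict_to=matrix.sample_ids)
        if len(samples_a) < 2 or len(samples_b) < 2:
            raise ValueError(f"contrast {class_a} vs {class_b}: each class needs >= 2 samples")
        cols = samples_a + samples_b
        X = matrix.data[cols].to_numpy()
        na, nb = len(samples_a), len(samples_b)
        mask_a = np.zeros(len(cols), dtype=bool)
        mask_a[:na] = True
        mask_b = ~mask_a
        s0 = estimate_s0(X, mask_a, mask_b, n_windows=config.n_s_windows)
        d_obs, _ = _d_and_s(X, mask_a, mask_b, s0)
        mean_a = X[:, mask_a].mean(axis=1)
        mean_b = X[:, mask_b].mean(axis=1)
        masks = _unpaired_permutations(len(cols), na, config.n_permutations, rng)
        d_perm = _permuted_d_unpaired(X, masks, na, nb, s0)
    else:
        X, mean_a, mean_b, d_obs, d_perm, s0 = _paired_sam(
            matrix, sheet, class_a, class_b, config, rng
        )

    log2fc = mean_a - mean_b
    m = d_obs.size
    order = np.argsort(d_obs, kind="stable")
    d_sorted = d_obs[order]
    d_perm_sorted = np.sort(d_perm, axis=0)
    dbar = d_perm_sorted.mean(axis=1)

    q25, q75 = np.percentile(d_perm, [25, 75])
    pi0 = min(1.0, np.mean((d_obs >= q25) & (d_obs <= q75)) / 0.5)

    max_delta = float(np.max(np.abs(d_sorted - dbar))) if m else 0.0
    deltas = np.linspace(0.0, max_delta * 1.001, config.n_delta)

    delta_rows = []
    # call sets are nested in delta; record the tightest delta still calling
    # each feature — its FDR there is the lowest FDR at which it is called
    last_called_at = np.full(m, -1)
    for di, delta in enumerate(deltas):
        cut_up, cut_low = _cutoffs(d_sorted, dbar, delta)
        called = (d_obs >= cut_up) | (d_obs <= cut_low)
        n_called = int(called.sum())
        false_counts = np.sum((d_perm >= cut_up) | (d_perm <= cut_low), axis=0)
        median_false = float(np.median(false_counts))
        fdr = 0.0 if n_called == 0 else min(1.0, pi0 * median_false / n_called)
        delta_rows.append(
            {"delta": float(delta), "n_called": n_called,
             "median_false": median_false, "fdr": fdr}
        )
        last_called_at[called] = di

    delta_table = pd.DataFrame(delta_rows)
    # enforce monotone non-increasing FDR in delta (running min from loose to tight)
    delta_table["fdr"] = np.minimum.accumulate(delta_table["fdr"].to_numpy())

    ok = delta_table["fdr"] <= config.fdr_target
    chosen_idx = int(ok.idxmax()) if ok.any() else len(deltas) - 1
    chosen_delta = float(delta_table.loc[chosen_idx, "delta"])

    fdr_by_delta = delta_table["fdr"].to_numpy()
    q = np.ones(m)
    has = last_called_at >= 0
    q[has] = fdr_by_delta[last_called_at[has]]

    cut_up, cut_low = _cutoffs(d_sorted, dbar, chosen_delta)
    called_final = (d_obs >= cut_up) | (d_obs <= cut_low)

    table = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "d": d_obs,
            "log2fc": log2fc,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "q": q,
            "called": called_final,
        }
    )
    return SamResult(
        table=table,
        delta_table=delta_table,
        s0=float(s0),
        pi0=float(pi0),
        delta=chosen_delta,
        contrast=(class_a, class_b),
        design=config.design,
        expected_d=dbar,
    )


def _paired_sam(matrix, sheet, class_a, class_b, config, rng):
    """One-sample SAM on within-patient differences with sign-flip permutations."""
    patient = sheet.patient_of()
    tissue = sheet.tissue_of()
    by_patient: dict[str, dict[str, str]] = {}
    for sid in matrix.sample_ids:
        t = tissue.get(sid)
        if t in (class_a, class_b):
            by_patient.setdefault(patient[sid], {})[t] = sid
    pairs = [(d[class_a], d[class_b]) for d in by_patient.values() if len(d) == 2]
    if len(pairs) < 2:
        raise ValueError("paired design needs at least 2 complete patient pairs")
    cols_a = [a for a, _ in pairs]
    cols_b = [b for _, b in pairs]
    Z = matrix.data[cols_a].to_numpy() - matrix.data[cols_b].to_numpy()
    n = Z.shape[1]

    def one_sample_d(Zm, s0):
        mean = Zm.mean(axis=-1)
        sd = Zm.std(axis=-1, ddof=1)
        s = sd / np.sqrt(n)
        return mean / (s + s0), s

    _, s = one_sample_d(Z, 0.0)
    best_cv, s0 = np.inf, None
    for pct in S0_PERCENTILE_GRID:
        cand = float(np.percentile(s, pct))
        d_cand = Z.mean(axis=1) / (s + cand)
        cv = _window_spread_cv(d_cand, s, config.n_s_windows)
        if cv < best_cv - 1e-12:
            best_cv, s0 = cv, cand
    if s0 is None:
        s0 = float(np.percentile(s, 50))

    d_obs, _ = one_sample_d(Z, s0)
    total = 2**n
    n_perm = min(config.n_permutations, total)
    if total <= config.n_permutations:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
    d_perm = np.empty((Z.shape[0], signs.shape[0]))
    Zsq_mean = (Z**2).mean(axis=1)
    for i, sg in enumerate(signs):
        Zp_mean = (Z * sg).mean(axis=1)
        var = (Zsq_mean - Zp_mean**2) * n / (n - 1)
        s_p = np.sqrt(np.clip(var, 0.0, None) / n)
        d_perm[:, i] = Zp_mean / (s_p + s0)
    mean_a = matrix.data[cols_a].to_numpy().mean(axis=1)
    mean_b = matrix.data[cols_b].to_numpy().mean(axis=1)
    return Z, mean_a, mean_b, d_obs, d_perm, s0


def select_dems(
    result: SamResult | pd.DataFrame,
    fc_threshold: float = 3.0,
    background: float = 5.0,
    fc_scale: str = "log2",
) -> pd.DataFrame:
    """Differentially expressed features passing the fold-change and background rules.

    Keeps called features with ``|log2fc| > fc_threshold`` (``fc_scale='linear'``
    reads the threshold as a linear ratio instead, i.e. ``|log2fc| >
    log2(fc_threshold)``) and a class mean above ``background`` in at least one
    of the two contrasted groups.
    """
    table = result.table if isinstance(result, SamResult) else result
    if table.empty:
        return table.copy()
    if fc_scale == "log2":
        fc_cut = fc_threshold
    elif fc_scale == "linear":
        fc_cut = np.log2(fc_threshold)
    else:
        raise ValueError(f"unknown fc_scale {fc_scale!r}")
    keep = (
        table["called"]
        & (table["log2fc"].abs() > fc_cut)
        & ((table["mean_a"] > background) | (table["mean_b"] > background))
    )
    return table.loc[keep].reset_index(drop=True)
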