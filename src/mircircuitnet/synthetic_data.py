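"""Synthetic matched N/T/M cohort generator with planted ground truth.

Emulates the statistical structure of a matched tumor-progression expression
study: normal mucosa (N), primary tumor (T) and metastasis (M) samples drawn
from a partially overlapping patient set, miRNA and gene assays profiling
slightly different sample subsets, class-level differential effects
concentrated in the T-vs-N transition, repressive miRNA->target relations
(linear in log2 space with additive Gaussian noise), TF-driven and
miRNA-driven feed-forward circuits, and exponential proportional-hazards
survival times.

The generator's parameters are the study conditions for every downstream
recovery test: identical config + seed reproduce byte-identical outputs.

Model
-----
A sample value for feature *f* in sample *s* of patient *p* is

    x[f, s] = baseline[f] + class_effect[f, tissue(s)] + u[f, p]*1{tissue in T,M}
              + eps[f, s]

with ``eps ~ N(0, within_sd^2)`` and a per-(feature, patient) random effect
``u ~ N(0, patient_effect_sd^2)`` shared by the T and M samples of the same
patient (this is what makes a patient's tumor and metastasis cluster
together).  A planted repression (m, g, b) replaces the gene row by

    g[s] = g_baseline - b * (m[s] - mean(m)) + eta[s],   eta ~ N(0, sd^2)

so the population anti-correlation is analytically
``r = -b*sd_m / sqrt(b^2*sd_m^2 + sd^2)``.  Values are clipped to the
[0, 15] log2 signal range; clipping events are counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    SampleSheet,
    SurvivalRecord,
    validate_interactions,
    validate_target_predictions,
)

SIGNAL_MIN, SIGNAL_MAX = 0.0, 15.0


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; ``seed`` fixes every random draw.

    Sample counts default to the matched-study structure: 23/31/24 N/T/M
    miRNA-assay samples and 23/30/27 gene-assay samples with 77 shared,
    drawn from 42 patients (8 of whom contribute full N-T-M triplets).
    """

    seed: int = 0
    n_patients: int = 46
    # per-class master sample counts; the two assays profile subsets of these
    n_class_n: int = 23
    n_class_t: int = 31
    n_class_m: int = 27
    n_mirna_only_t: int = 1   # T samples profiled only on the miRNA array
    n_gene_only_m: int = 3    # M samples profiled only on the gene array
    t_patient_offset: int = 8
    m_patient_offset: int = 15

    n_mirnas: int = 300
    n_genes: int = 2000

    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    within_sd: float = 1.0
    patient_effect_sd: float = 0.8
    frac_low_mirnas: float = 0.10   # near-background miRNAs, removed by detection filter

    # planted differential expression (log2 effects); T-vs-N effects persist in M
    n_dem_tn: int = 24
    n_dem_mt: int = 6
    dem_effect: float = 3.5
    dem_baseline_mean: float = 8.5
    dem_baseline_sd: float = 0.5
    tn_effect_persists_in_m: bool = True
    n_deg_tn: int = 60
    deg_effect: float = 2.5

    # planted repressive miRNA -> gene relations
    n_planted_repressions: int = 100
    repression_slope: float = 1.0
    repression_noise_sd: float = 1.0

    # prediction table
    n_decoy_predictions: int = 5000
    conserved_frac_planted: float = 0.87
    conserved_frac_decoy: float = 0.25

    # TF layer / circuits
    n_circuits_tf_driven: int = 3
    n_circuits_mirna_driven: int = 3
    n_decoy_tfs: int = 10
    n_decoy_tf_edges: int = 50
    tf_coupling: float = 0.8
    tf_noise_sd: float = 0.7

    # survival
    n_survival_patients: int = 46
    survival_betas: dict = field(default_factory=dict)  # mirna_id -> beta
    baseline_hazard: float = 0.05   # events per month
    censoring_rate: float = 0.3

    def validate(self) -> None:
        counts = [
            self.n_patients, self.n_class_n, self.n_class_t, self.n_class_m,
            self.n_mirnas, self.n_genes, self.n_dem_tn, self.n_dem_mt,
            self.n_deg_tn, self.n_planted_repressions, self.n_decoy_predictions,
            self.n_circuits_tf_driven, self.n_circuits_mirna_driven,
            self.n_decoy_tfs, self.n_decoy_tf_edges, self.n_survival_patients,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if self.n_dem_tn + self.n_dem_mt > self.n_mirnas:
            raise ValueError("planted DEMs exceed total miRNAs")
        if self.n_deg_tn + self.n_planted_repressions > self.n_genes:
            raise ValueError("planted DEGs plus repression targets exceed total genes")
        n_circ = self.n_circuits_tf_driven + self.n_circuits_mirna_driven
        if n_circ > self.n_planted_repressions:
            raise ValueError("each planted circuit needs its own planted repression")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must lie in [0, 1]")
        if not 0 <= self.frac_low_mirnas < 1:
            raise ValueError("frac_low_mirnas must lie in [0, 1)")
        needed = max(
            self.n_class_n,
            self.t_patient_offset + self.n_class_t,
            self.m_patient_offset + self.n_class_m,
        )
        if needed > self.n_patients:
            raise ValueError(
                f"patient offsets require {needed} patients but n_patients={self.n_patients}"
            )


@dataclass
class GroundTruth:
    """Planted-effect bookkeeping for downstream recovery tests."""

    dems: dict[str, pd.DataFrame]        # contrast -> (feature_id, effect)
    degs: dict[str, pd.DataFrame]
    repressions: pd.DataFrame            # mirna_id, gene_id, slope, noise_sd, analytic_r
    circuits: pd.DataFrame               # circuit_type, tf_id, mirna_id, gene_id
    survival_betas: dict[str, float]
    clip_events: int = 0

    def analytic_r(self, slope: float, sd_m: float, noise_sd: float) -> float:
        return -slope * sd_m / np.sqrt(slope**2 * sd_m**2 + noise_sd**2)


def _mirna_ids(n: int) -> list[str]:
    return [f"miR-{i+1:03d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i+1:04d}" for i in range(n)]


def _build_samples(config: CohortConfig) -> pd.DataFrame:
    """Master sample table with patient assignment and per-assay membership."""
    rows = []
    for i in range(config.n_class_n):
        rows.append(("N", i))
    for i in range(config.n_class_t):
        rows.append(("T", config.t_patient_offset + i))
    for i in range(config.n_class_m):
        rows.append(("M", config.m_patient_offset + i))
    df = pd.DataFrame(rows, columns=["tissue", "patient_index"])
    df["patient_id"] = df["patient_index"].map(lambda i: f"P{i+1:03d}")
    df["sample_id"] = [f"S{i+1:03d}_{t}" for i, t in enumerate(df["tissue"])]
    df["in_mirna"] = True
    df["in_gene"] = True
    # last M samples are gene-only; first T sample(s) beyond the gene count are miRNA-only
    m_idx = df.index[df["tissue"] == "M"]
    if config.n_gene_only_m:
        df.loc[m_idx[-config.n_gene_only_m:], "in_mirna"] = False
    t_idx = df.index[df["tissue"] == "T"]
    if config.n_mirna_only_t:
        df.loc[t_idx[-config.n_mirna_only_t:], "in_gene"] = False
    return df


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SampleSheet, GroundTruth]:
    """Generate the matched miRNA and gene matrices, sample sheet and truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = _build_samples(config)
    n_s = len(samples)
    tissues = samples["tissue"].to_numpy()
    patient_idx = samples["patient_index"].to_numpy()

    mirna_ids = _mirna_ids(config.n_mirnas)
    gene_ids = _gene_ids(config.n_genes)

    # --- planted feature assignment (disjoint index blocks) ---
    dem_tn = mirna_ids[: config.n_dem_tn]
    dem_mt = mirna_ids[config.n_dem_tn: config.n_dem_tn + config.n_dem_mt]
    deg_tn = gene_ids[: config.n_deg_tn]
    repression_genes = gene_ids[config.n_deg_tn: config.n_deg_tn + config.n_planted_repressions]

    def signed(n: int, magnitude: float) -> np.ndarray:
        signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        return signs * magnitude

    dem_tn_effects = signed(config.n_dem_tn, config.dem_effect)
    dem_mt_effects = signed(config.n_dem_mt, config.dem_effect)
    deg_tn_effects = signed(config.n_deg_tn, config.deg_effect)

    # --- miRNA matrix ---
    baseline_m = rng.normal(config.baseline_mean, config.baseline_sd, config.n_mirnas)
    baseline_m[: config.n_dem_tn + config.n_dem_mt] = rng.normal(
        config.dem_baseline_mean, config.dem_baseline_sd, config.n_dem_tn + config.n_dem_mt
    )
    n_low = int(round(config.frac_low_mirnas * config.n_mirnas))
    if n_low:
        # near-background rows live at the tail of the index, away from planted blocks
        baseline_m[config.n_mirnas - n_low:] = rng.normal(0.5, 0.2, n_low)

    mirna_values = np.empty((config.n_mirnas, n_s))
    mirna_values[:] = baseline_m[:, None]

    effect_m = np.zeros((config.n_mirnas, n_s))
    in_t = tissues == "T"
    in_m = tissues == "M"
    for row, eff in zip(range(config.n_dem_tn), dem_tn_effects):
        effect_m[row, in_t] += eff
        if config.tn_effect_persists_in_m:
            effect_m[row, in_m] += eff
    for off, eff in zip(range(config.n_dem_mt), dem_mt_effects):
        effect_m[config.n_dem_tn + off, in_m] += eff
    mirna_values += effect_m

    u_m = rng.normal(0.0, config.patient_effect_sd, (config.n_mirnas, config.n_patients))
    tumor_like = in_t | in_m
    mirna_values[:, tumor_like] += u_m[:, patient_idx[tumor_like]]
    mirna_values += rng.normal(0.0, config.within_sd, (config.n_mirnas, n_s))

    # --- gene matrix ---
    baseline_g = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    gene_values = np.empty((config.n_genes, n_s))
    gene_values[:] = baseline_g[:, None]
    for row, eff in zip(range(config.n_deg_tn), deg_tn_effects):
        gene_values[row, in_t] += eff
        if config.tn_effect_persists_in_m:
            gene_values[row, in_m] += eff
    u_g = rng.normal(0.0, config.patient_effect_sd, (config.n_genes, config.n_patients))
    gene_values[:, tumor_like] += u_g[:, patient_idx[tumor_like]]
    gene_values += rng.normal(0.0, config.within_sd, (config.n_genes, n_s))

    # --- planted repressions overwrite their target gene rows ---
    repression_rows = []
    mirna_index = {mid: i for i, mid in enumerate(mirna_ids)}
    # cycle regulators through the planted T-vs-N DEMs first so that induced
    # DEM networks are non-trivial, then through stable, well-expressed miRNAs
    n_stable = config.n_mirnas - n_low
    regulator_pool = dem_tn + mirna_ids[config.n_dem_tn + config.n_dem_mt: n_stable]
    if not regulator_pool and config.n_planted_repressions:
        raise ValueError("no miRNAs available to act as repression regulators")
    b = config.repression_slope
    sd_eta = config.repression_noise_sd
    for k, gene in enumerate(repression_genes):
        mid = regulator_pool[k % len(regulator_pool)]
        m_row = mirna_values[mirna_index[mid]]
        g_base = baseline_g[config.n_deg_tn + k]
        gi = gene_ids.index(gene)
        gene_values[gi] = g_base - b * (m_row - m_row.mean()) + rng.normal(0.0, sd_eta, n_s)
        sd_m = m_row.std(ddof=1)
        repression_rows.append(
            {
                "mirna_id": mid,
                "gene_id": gene,
                "slope": b,
                "noise_sd": sd_eta,
                "analytic_r": -b * sd_m / np.sqrt(b**2 * sd_m**2 + sd_eta**2),
            }
        )
    repressions = pd.DataFrame(
        repression_rows,
        columns=["mirna_id", "gene_id", "slope", "noise_sd", "analytic_r"],
    )

    # --- clip to the log2 signal range ---
    clip_events = int(np.sum(mirna_values < SIGNAL_MIN) + np.sum(mirna_values > SIGNAL_MAX)
                      + np.sum(gene_values < SIGNAL_MIN) + np.sum(gene_values > SIGNAL_MAX))
    mirna_values = np.clip(mirna_values, SIGNAL_MIN, SIGNAL_MAX)
    gene_values = np.clip(gene_values, SIGNAL_MIN, SIGNAL_MAX)

    mirna_cols = samples.loc[samples["in_mirna"], "sample_id"].tolist()
    gene_cols = samples.loc[samples["in_gene"], "sample_id"].tolist()
    mirna_matrix = ExpressionMatrix(
        pd.DataFrame(mirna_values[:, samples["in_mirna"].to_numpy()],
                     index=mirna_ids, columns=mirna_cols),
        "miRNA",
    )
    gene_matrix = ExpressionMatrix(
        pd.DataFrame(gene_values[:, samples["in_gene"].to_numpy()],
                     index=gene_ids, columns=gene_cols),
        "gene",
    )
    sheet = SampleSheet(samples[["sample_id", "patient_id", "tissue"]].copy())

    truth = GroundTruth(
        dems={
            "TvN": pd.DataFrame({"feature_id": dem_tn, "effect": dem_tn_effects}),
            "MvT": pd.DataFrame({"feature_id": dem_mt, "effect": dem_mt_effects}),
        },
        degs={"TvN": pd.DataFrame({"feature_id": deg_tn, "effect": deg_tn_effects})},
        repressions=repressions,
        circuits=pd.DataFrame(columns=["circuit_type", "tf_id", "mirna_id", "gene_id"]),
        survival_betas=dict(config.survival_betas),
        clip_events=clip_events,
    )
    return mirna_matrix, gene_matrix, sheet, truth


def generate_target_predictions(
    truth: GroundTruth, config: CohortConfig
) -> pd.DataFrame:
    """Planted repressions (and circuit miRNA->TF pairs) plus decoy predictions.

    Decoys are uniform draws over non-interacting (miRNA, gene) pairs; planted
    pairs get more negative miRSVR-style scores and a higher conserved-site
    fraction than decoys.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    planted = truth.repressions[["mirna_id", "gene_id"]].copy()
    circuit_tf_pairs = truth.circuits.loc[
        truth.circuits["circuit_type"] == "miRNA_driven", ["mirna_id", "tf_id"]
    ].rename(columns={"tf_id": "gene_id"})
    planted = pd.concat([planted, circuit_tf_pairs], ignore_index=True).drop_duplicates()
    planted_set = set(map(tuple, planted.to_numpy()))

    mirna_ids = _mirna_ids(config.n_mirnas)
    gene_ids = _gene_ids(config.n_genes)
    n_possible = len(mirna_ids) * len(gene_ids)
    if config.n_decoy_predictions > n_possible - len(planted_set):
        raise ValueError(
            f"requested {config.n_decoy_predictions} decoys but only "
            f"{n_possible - len(planted_set)} non-planted pairs exist"
        )
    decoys: set[tuple[str, str]] = set()
    while len(decoys) < config.n_decoy_predictions:
        need = config.n_decoy_predictions - len(decoys)
        mi = rng.integers(0, len(mirna_ids), size=2 * need + 10)
        gi = rng.integers(0, len(gene_ids), size=2 * need + 10)
        for a, b in zip(mi, gi):
            pair = (mirna_ids[a], gene_ids[b])
            if pair not in planted_set and pair not in decoys:
                decoys.add(pair)
                if len(decoys) == config.n_decoy_predictions:
                    break

    rows = []
    for mirna_id, gene_id in planted.itertuples(index=False):
        rows.append(
            {
                "mirna_id": mirna_id,
                "gene_id": gene_id,
                "score": rng.uniform(-1.5, -0.8),
                "conserved": bool(rng.random() < config.conserved_frac_planted),
            }
        )
    for mirna_id, gene_id in sorted(decoys):
        rows.append(
            {
                "mirna_id": mirna_id,
                "gene_id": gene_id,
                "score": rng.uniform(-0.8, -0.1),
                "conserved": bool(rng.random() < config.conserved_frac_decoy),
            }
        )
    return validate_target_predictions(pd.DataFrame(rows))


def generate_tf_layer(
    truth: GroundTruth,
    config: CohortConfig,
    mirna_matrix: ExpressionMatrix,
    gene_matrix: ExpressionMatrix,
) -> tuple[pd.DataFrame, ExpressionMatrix]:
    """Plant TF expression rows and TF->gene / TF->miRNA interactions.

    TF-driven circuits couple the TF positively to the miRNA of a planted
    repression (hence negatively to its target gene); miRNA-driven circuits
    make the TF itself a repressed target of the miRNA (hence positively
    correlated with the repressed gene).  Decoy TFs get independent
    expression and random interaction edges.  Updates ``truth.circuits``
    in place and returns the interaction table plus the gene matrix with TF
    rows appended.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n_circ = config.n_circuits_tf_driven + config.n_circuits_mirna_driven
    if n_circ > len(truth.repressions):
        raise ValueError("not enough planted repressions to host the requested circuits")

    gene_df = gene_matrix.data.copy()
    gene_samples = list(gene_df.columns)
    mirna_common = [s for s in mirna_matrix.sample_ids if s in set(gene_samples)]

    interactions = []
    circuit_rows = []
    tf_counter = 0

    def tf_profile_from(anchor: pd.Series, sign: float) -> pd.Series:
        """TF row coupled to an anchor miRNA profile over the shared samples."""
        base = rng.normal(config.baseline_mean, 0.5)
        prof = pd.Series(rng.normal(base, config.tf_noise_sd, len(gene_samples)),
                         index=gene_samples)
        centered = anchor - anchor.mean()
        prof.loc[mirna_common] += sign * config.tf_coupling * centered.loc[mirna_common]
        return prof.clip(SIGNAL_MIN, SIGNAL_MAX)

    for k in range(config.n_circuits_tf_driven):
        rep = truth.repressions.iloc[k]
        tf_counter += 1
        tf_id = f"TF{tf_counter:03d}"
        anchor = mirna_matrix.data.loc[rep["mirna_id"]]
        gene_df.loc[tf_id] = tf_profile_from(anchor, sign=+1.0)
        interactions.append((tf_id, rep["mirna_id"], "miRNA", "planted"))
        interactions.append((tf_id, rep["gene_id"], "gene", "planted"))
        circuit_rows.append(("TF_driven", tf_id, rep["mirna_id"], rep["gene_id"]))

    for k in range(config.n_circuits_mirna_driven):
        rep = truth.repressions.iloc[config.n_circuits_tf_driven + k]
        tf_counter += 1
        tf_id = f"TF{tf_counter:03d}"
        anchor = mirna_matrix.data.loc[rep["mirna_id"]]
        gene_df.loc[tf_id] = tf_profile_from(anchor, sign=-1.0)  # repressed by the miRNA
        interactions.append((tf_id, rep["gene_id"], "gene", "planted"))
        circuit_rows.append(("miRNA_driven", tf_id, rep["mirna_id"], rep["gene_id"]))

    # decoy TFs: independent expression, random edges
    decoy_tfs = []
    for _ in range(config.n_decoy_tfs):
        tf_counter += 1
        tf_id = f"TF{tf_counter:03d}"
        base = rng.normal(config.baseline_mean, 0.5)
        gene_df.loc[tf_id] = np.clip(
            rng.normal(base, config.within_sd, len(gene_samples)), SIGNAL_MIN, SIGNAL_MAX
        )
        decoy_tfs.append(tf_id)
    existing = {(r, t) for r, t, _, _ in interactions}
    gene_ids = _gene_ids(config.n_genes)
    mirna_ids = _mirna_ids(config.n_mirnas)
    n_added = 0
    while decoy_tfs and n_added < config.n_decoy_tf_edges:
        tf_id = decoy_tfs[int(rng.integers(0, len(decoy_tfs)))]
        if rng.random() < 0.5:
            target, kind = mirna_ids[int(rng.integers(0, len(mirna_ids)))], "miRNA"
        else:
            target, kind = gene_ids[int(rng.integers(0, len(gene_ids)))], "gene"
        if (tf_id, target) in existing:
            continue
        existing.add((tf_id, target))
        interactions.append((tf_id, target, kind, "decoy"))
        n_added += 1

    truth.circuits = pd.DataFrame(
        circuit_rows, columns=["circuit_type", "tf_id", "mirna_id", "gene_id"]
    )
    table = validate_interactions(
        pd.DataFrame(interactions,
                     columns=["regulator_id", "target_id", "target_kind", "source_label"])
    )
    return table, ExpressionMatrix(gene_df, "gene")


def generate_survival(
    truth: GroundTruth,
    config: CohortConfig,
    screen_mirnas: list[str] | None = None,
) -> list[SurvivalRecord]:
    """Exponential proportional-hazards survival records with miRNA covariates.

    Each patient gets one standardized (centered log2) level per screened
    miRNA; the hazard is ``baseline_hazard * exp(sum(beta_m * x_m))`` with the
    nonzero betas taken from ``truth.survival_betas``.  Censoring is an
    independent exponential clock calibrated to the requested censoring rate
    (``censoring_rate=1`` makes every record censored at a follow-up draw).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    if screen_mirnas is None:
        screen_mirnas = sorted(truth.survival_betas) or _mirna_ids(config.n_mirnas)[:26]
    betas = np.array([truth.survival_betas.get(m, 0.0) for m in screen_mirnas])
    n = config.n_survival_patients
    x = rng.normal(0.0, 1.0, (n, len(screen_mirnas)))
    lp = x @ betas if len(screen_mirnas) else np.zeros(n)
    rate = config.baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / rate)
    records = []
    if config.censoring_rate >= 1.0:
        follow_up = rng.exponential(1.0 / config.baseline_hazard, n)
        for i in range(n):
            covs = {m: float(x[i, j]) for j, m in enumerate(screen_mirnas)}
            records.append(SurvivalRecord(f"SP{i+1:03d}", float(follow_up[i]), False, covs))
        return records
    c = config.censoring_rate
    cens_rate = config.baseline_hazard * c / max(1.0 - c, 1e-12) if c > 0 else None
    cens_time = (rng.exponential(1.0 / cens_rate, n) if cens_rate
                 else np.full(n, np.inf))
    for i in range(n):
        t = min(event_time[i], cens_time[i])
        covs = {m: float(x[i, j]) for j, m in enumerate(screen_mirnas)}
        records.append(
            SurvivalRecord(f"SP{i+1:03d}", float(max(t, 1e-9)), bool(event_time[i] <= cens_time[i]), covs)
        )
    return records


def generate_gene_sets(
    truth: GroundTruth,
    config: CohortConfig,
    n_random_sets: int = 10,
    set_size: int = 20,
) -> dict[str, list[str]]:
    """Gene sets for the pathway stage: one coordinated planted set plus decoys.

    The planted set collects repression targets of *up*-modulated planted
    DEMs — a coordinated down-shift against the mixed-direction target
    universe.  Decoy sets mix repression targets and unrelated genes at
    random, so their members shift in no preferred direction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    up_dems = set(
        truth.dems["TvN"].loc[truth.dems["TvN"]["effect"] > 0, "feature_id"]
    )
    planted = truth.repressions.loc[
        truth.repressions["mirna_id"].isin(up_dems), "gene_id"
    ].tolist()
    sets: dict[str, list[str]] = {}
    if len(planted) >= 2:
        sets["planted_coordinated"] = planted[: max(set_size, 2)]
    target_pool = truth.repressions["gene_id"].tolist()
    gene_pool = _gene_ids(config.n_genes)
    for i in range(n_random_sets):
        members: list[str] = []
        while len(members) < set_size:
            pool = target_pool if (rng.random() < 0.5 and target_pool) else gene_pool
            g = pool[int(rng.integers(0, len(pool)))]
            if g not in members:
                members.append(g)
        sets[f"decoy_set_{i+1:02d}"] = members
    return sets


def config_to_dict(config: CohortConfig) -> dict:
    return asdict(config)


def config_from_dict(data: Mapping) -> CohortConfig:
    return CohortConfig(**dict(data))
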