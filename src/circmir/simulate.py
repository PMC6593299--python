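"""Synthetic serum-miRNA datasets with the structure the pipeline assumes.

Counts are drawn from a negative binomial,

    K_ij ~ NB(mean = s_j * q_i * 2^(beta_i x_j + gamma_i (age_j - mean age)),
              dispersion alpha_i)

with x_j the case indicator, q_i a log-normal baseline abundance, s_j a
log-normal library size factor, alpha_i a log-normal gene-wise dispersion
and beta_i the planted group effect in log2 units (gamma_i an optional age
effect, also log2 per year).  The default design mirrors an extreme
case-control serum study: 10 cases vs 11 controls, ~756 abundant miRNAs,
and case/control ages drawn from Normal(47.10, 6.45^2) / Normal(63.45,
4.25^2) truncated to [18, 90] — so group and age are strongly confounded
and the age-adjustment path is genuinely exercised.

All randomness flows through ``numpy.random.default_rng`` (PCG64) seeded
explicitly, so identical seeds give identical TSVs across platforms.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneSetCollection, ValidationError, validate_target_table

logger = logging.getLogger("circmir")


@dataclass
class SimulationParams:
    """Generative settings; defaults follow the study design being emulated."""

    n_case: int = 10
    n_control: int = 11
    n_features: int = 756
    frac_de: float = 0.02              # fraction of features with a planted group effect
    lfc_range: tuple[float, float] = (2.0, 4.26)  # |beta| drawn uniformly, sign +/- 1:1
    dispersion_median: float = 0.3     # log-normal gene-wise dispersion
    dispersion_log_sd: float = 0.5
    baseline_median: float = 50.0      # log-normal baseline mean counts (right-skewed)
    baseline_log_sd: float = 1.5
    size_factor_log_sd: float = 0.3
    age_case: tuple[float, float] = (47.10, 6.45)     # mean, sd (years)
    age_control: tuple[float, float] = (63.45, 4.25)
    age_bounds: tuple[float, float] = (18.0, 90.0)
    age_effect_sd: float = 0.0         # log2-per-year gene age effects (0 = no age effect)
    bmi_case: tuple[float, float] = (27.17, 3.79)
    bmi_control: tuple[float, float] = (25.23, 3.03)

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValidationError("both groups need at least one sample")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValidationError("frac_de must lie in [0, 1]")
        if self.lfc_range[0] > self.lfc_range[1] or self.lfc_range[0] < 0:
            raise ValidationError("lfc_range must be 0 <= low <= high")
        for name in ("dispersion_median", "baseline_median"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("dispersion_log_sd", "baseline_log_sd", "size_factor_log_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


def confounded_params(**overrides) -> SimulationParams:
    """Preset with per-gene age effects, so the group contrast is confounded
    with the age gap unless the model adjusts for age."""
    overrides.setdefault("age_effect_sd", 0.02)
    return SimulationParams(**overrides)


def _truncated_normal(rng, mean, sd, low, high, size):
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = (out < low) | (out > high)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=bad.sum())
    return np.clip(out, low, high)


def nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB with Var = mean + alpha*mean^2 via gamma-Poisson mixing (alpha -> 0
    degenerates to Poisson)."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    poisson_like = alpha < 1e-12
    if poisson_like.any():
        out[poisson_like] = rng.poisson(mean[poisson_like])
    rest = ~poisson_like
    if rest.any():
        shape = 1.0 / alpha[rest]
        lam = rng.gamma(shape, alpha[rest] * mean[rest])
        out[rest] = rng.poisson(lam)
    return out


def simulate_dataset(
    params: SimulationParams | None = None, seed: int = 0
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw (CountMatrix, sample metadata, truth table) under ``params``.

    The truth table records every planted per-feature parameter
    (beta = planted log2 group effect, gamma = log2-per-year age effect,
    alpha = dispersion, q = baseline mean) and per-sample size factors are
    returned inside the metadata (column ``true_size_factor``).
    """
    params = params or SimulationParams()
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.n_case + params.n_control
    features = [f"miR-sim-{i + 1}" for i in range(params.n_features)]
    samples = [f"DR{i + 1}" for i in range(params.n_case)] + [
        f"NDR{i + 1}" for i in range(params.n_control)
    ]
    group = np.array([1] * params.n_case + [0] * params.n_control)

    age = np.concatenate(
        [
            _truncated_normal(rng, *params.age_case, *params.age_bounds, params.n_case),
            _truncated_normal(rng, *params.age_control, *params.age_bounds, params.n_control),
        ]
    ).round(1)
    bmi = np.concatenate(
        [
            rng.normal(*params.bmi_case, size=params.n_case),
            rng.normal(*params.bmi_control, size=params.n_control),
        ]
    ).round(2)
    sex = rng.choice(["M", "F"], size=n)

    q = params.baseline_median * rng.lognormal(0.0, params.baseline_log_sd, params.n_features)
    alpha = params.dispersion_median * rng.lognormal(
        0.0, params.dispersion_log_sd, params.n_features
    )
    s = rng.lognormal(0.0, params.size_factor_log_sd, n)
    s /= np.exp(np.mean(np.log(s)))  # geometric mean 1

    n_de = int(round(params.frac_de * params.n_features))
    de_idx = rng.choice(params.n_features, size=n_de, replace=False)
    beta = np.zeros(params.n_features)
    if n_de:
        magnitudes = rng.uniform(*params.lfc_range, size=n_de)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        beta[de_idx] = magnitudes * signs
    gamma = (
        rng.normal(0.0, params.age_effect_sd, params.n_features)
        if params.age_effect_sd > 0
        else np.zeros(params.n_features)
    )

    age_centered = age - age.mean()
    log2_mu = (
        np.log2(q)[:, None]
        + beta[:, None] * group[None, :]
        + gamma[:, None] * age_centered[None, :]
    )
    mean = s[None, :] * np.power(2.0, log2_mu)
    counts = nb_draw(rng, mean, alpha[:, None])

    cm = CountMatrix(pd.DataFrame(counts, index=features, columns=samples))
    metadata = pd.DataFrame(
        {
            "group": np.where(group == 1, "DR", "NDR"),
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "true_size_factor": s,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth = pd.DataFrame(
        {
            "feature": features,
            "beta": beta,
            "gamma": gamma,
            "alpha": alpha,
            "q": q,
            "is_de": beta != 0.0,
        }
    ).set_index("feature")
    logger.info(
        "simulated %d features x %d samples (%d planted DE) with seed %d",
        params.n_features, n, n_de, seed,
    )
    return cm, metadata, truth


def simulate_low_abundance_mix(
    params: SimulationParams | None = None,
    seed: int = 0,
    low_fraction: float = 0.7,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Dataset in which ~``low_fraction`` of the features fall below the
    total-count-200 abundance filter (emulating the drop from the full
    detected miRNA complement to the abundant subset).

    Low-abundance features get baselines drawn so their expected grand total
    is uniform on [2, 150]; the truth table gains a ``planted_low`` flag."""
    if not 0.0 <= low_fraction <= 1.0:
        raise ValidationError("low_fraction must lie in [0, 1]")
    params = params or SimulationParams()
    params.validate()
    cm, metadata, truth = simulate_dataset(params, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 176]))
    n = params.n_case + params.n_control
    n_low = int(round(low_fraction * params.n_features))
    low_idx = rng.choice(params.n_features, size=n_low, replace=False)
    planted_low = np.zeros(params.n_features, dtype=bool)
    planted_low[low_idx] = True
    if n_low:
        target_totals = rng.uniform(2.0, 150.0, size=n_low)
        alpha = truth["alpha"].to_numpy()[low_idx]
        s = metadata["true_size_factor"].to_numpy()
        per_sample_mean = target_totals[:, None] / n * s[None, :]
        low_counts = nb_draw(rng, per_sample_mean, alpha[:, None])
        counts = cm.counts.to_numpy().copy()
        counts[low_idx] = low_counts
        cm = CountMatrix(pd.DataFrame(counts, index=cm.features, columns=cm.samples))
    truth = truth.copy()
    truth["planted_low"] = planted_low
    truth["is_de"] = truth["is_de"] & ~planted_low
    truth["beta"] = np.where(planted_low, 0.0, truth["beta"])
    truth["total_count"] = cm.row_totals().to_numpy()
    return cm, metadata, truth


def make_target_fixture(
    panel: list[str] | None = None,
    n_union: int = 55,
    n_unique_top: int = 41,
    pathway_overlap: int = 4,
    pathway_size: int = 11,
    n_decoy_sets: int = 9,
    decoy_size: int = 25,
    seed: int = 0,
) -> tuple[pd.DataFrame, GeneSetCollection]:
    """Synthetic target table + gene-set collection with a prescribed overlap
    structure: the panel's validated-target union has ``n_union`` genes, of
    which ``n_unique_top`` are targeted by the first panel miRNA alone, and
    exactly ``pathway_overlap`` fall inside a ``pathway_size``-gene pathway.

    Gene symbols are synthetic (GENE0001...).  Decoy sets are drawn from
    outside the union so their overlap is 0.
    """
    if panel is None:
        panel = ["miR-sim-A", "miR-sim-B", "miR-sim-C", "miR-sim-D", "miR-sim-E"]
    if len(panel) < 2:
        raise ValidationError("panel needs >= 2 miRNAs to split unique/shared targets")
    if n_unique_top > n_union:
        raise ValidationError("n_unique_top cannot exceed n_union")
    if pathway_overlap > pathway_size:
        raise ValidationError("pathway_overlap cannot exceed pathway_size")
    if pathway_overlap > n_union - n_unique_top and pathway_overlap > 0:
        # pathway genes must be shared (targeted by top + one other miRNA)
        # to keep the unique-to-top count exact
        if n_unique_top + pathway_overlap > n_union:
            raise ValidationError("n_unique_top + pathway_overlap exceeds n_union")

    rng = np.random.default_rng(seed)
    gene_id = iter(f"GENE{i:04d}" for i in range(1, 10_000))
    top = panel[0]
    others = panel[1:]

    unique_genes = [next(gene_id) for _ in range(n_unique_top)]
    pathway_genes = [next(gene_id) for _ in range(pathway_overlap)]
    n_shared_rest = n_union - n_unique_top - pathway_overlap
    shared_genes = [next(gene_id) for _ in range(n_shared_rest)]

    rows: list[tuple[str, str, str]] = []
    rows += [(top, g, "luciferase") for g in unique_genes]
    # pathway genes: validated for the top miRNA and one other (jointly regulated)
    for i, g in enumerate(pathway_genes):
        rows.append((top, g, "luciferase"))
        rows.append((others[i % len(others)], g, "luciferase"))
    for i, g in enumerate(shared_genes):
        rows.append((others[i % len(others)], g, "luciferase"))

    targets = validate_target_table(pd.DataFrame(rows, columns=["mirna", "gene", "evidence"]))

    pathway_fill = [next(gene_id) for _ in range(pathway_size - pathway_overlap)]
    sets = {"NAD_METABOLISM_SIRTUINS_AGING": set(g.upper() for g in pathway_genes + pathway_fill)}
    descriptions = {"NAD_METABOLISM_SIRTUINS_AGING": "synthetic pathway fixture"}
    for d in range(n_decoy_sets):
        members = {next(gene_id).upper() for _ in range(decoy_size)}
        sets[f"DECOY_SET_{d + 1:03d}"] = members
        descriptions[f"DECOY_SET_{d + 1:03d}"] = "synthetic decoy set"
    collection = GeneSetCollection(sets, descriptions)
    return targets, collection


def write_dataset(outdir, cm: CountMatrix, metadata: pd.DataFrame, truth: pd.DataFrame) -> None:
    """Write counts.tsv, metadata.tsv and truth.tsv into ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="mirna")
    metadata.drop(columns=["true_size_factor"], errors="ignore").to_csv(
        outdir / "metadata.tsv", sep="\t", index_label="sample_id"
    )
    truth.to_csv(outdir / "truth.tsv", sep="\t")
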