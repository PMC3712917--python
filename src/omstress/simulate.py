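"""Synthetic omics data with planted ground truth.

Generators for the three kinds of input the analysis stages consume, each
emulating the statistical structure of the bacterial ethanol-stress study
design this package models:

* spectral counts — ~1,000 proteins over 2 conditions x 2 replicate runs,
  log-normal baseline abundances, negative-binomial counts (Poisson at
  dispersion 0) and planted log2 effects for a labeled subset;
* expression matrices with operon structure — genes partitioned into
  transcription units, members sharing a latent per-array profile with a
  configurable correlation, plus ab initio-style prediction scores whose
  ambiguous band the expression data must arbitrate;
* metabolite peak tables — log-normal peak areas with per-sample
  internal-standard recovery jitter that the normalization must cancel,
  and planted fold changes.

Every generator is a pure function of its config (seed included) and
returns the data together with truth labels for recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "gen_spectral_counts",
    "gen_expression_with_operons",
    "gen_metabolite_table",
]


@dataclass
class SimulationConfig:
    """Study-scale defaults for all three generators.

    Counts mirror the study scale (about one thousand identified proteins,
    1,808 genes, 45 metabolites, two conditions with two replicates each);
    ``depth`` is the expected total spectra per run, ``dispersion`` the
    negative-binomial overdispersion (variance = m + dispersion * m^2).
    The operon size distribution gives P(unit size = k) for k = 1.. and is
    calibrated to roughly 1.7 genes per transcription unit; the two
    baseline arrays are unstressed references used for discretization base
    values.
    """

    seed: int = 0
    # proteomics
    n_proteins: int = 1000
    depth: float = 25_000.0
    frac_up: float = 0.05
    frac_down: float = 0.05
    effect_log2: float = 2.0
    dispersion: float = 0.03
    # operons / expression
    n_genes: int = 1808
    n_arrays: int = 16
    n_baseline_arrays: int = 2
    operon_size_probs: tuple[float, ...] = (0.63, 0.15, 0.10, 0.06, 0.04, 0.02)
    within_operon_correlation: float = 0.8
    noise_sd: float = 0.3
    profile_sd: float = 1.5
    ambiguous_fraction: float = 0.3
    # metabolites
    n_metabolites: int = 45
    frac_changed: float = 0.2
    metabolite_fold: float = 2.0
    time_points: tuple[float, ...] = (10.0, 13.5, 26.0)
    replicate_cv: float = 0.15
    is_jitter_sd: float = 0.2

    def validate(self) -> None:
        if self.frac_up < 0 or self.frac_down < 0 or self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up and frac_down must be >=0 and sum to <=1")
        for name in ("n_proteins", "n_genes", "n_metabolites", "n_arrays"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0.0 <= self.within_operon_correlation <= 1.0:
            raise ValueError("within_operon_correlation must lie in [0, 1]")
        probs = np.asarray(self.operon_size_probs, dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("operon_size_probs must be a probability vector")
        if not 0.0 <= self.ambiguous_fraction <= 1.0:
            raise ValueError("ambiguous_fraction must lie in [0, 1]")
        if not 0.0 <= self.frac_changed <= 1.0:
            raise ValueError("frac_changed must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls(**{k: v for k, v in d.items()})
        cfg.validate()
        return cfg


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = m + dispersion * m^2 (Poisson at 0)."""
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def gen_spectral_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Protein x run spectrum counts with planted effects.

    Returns ``(counts, design, truth)``. Baseline relative abundances are
    log-normal and scaled to the target run depth; planted UP/DOWN
    proteins multiply their treatment-run mean by 2**(+-effect_log2).
    Truth carries the per-protein status, effect and the expected baseline
    count per run.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    ids = [f"P{i + 1:04d}" for i in range(n)]
    abundance = rng.lognormal(mean=0.0, sigma=1.2, size=n)
    base_mean = config.depth * abundance / abundance.sum()

    n_up = round(config.frac_up * n)
    n_down = round(config.frac_down * n)
    planted = rng.choice(n, size=n_up + n_down, replace=False)
    effect = np.zeros(n)
    effect[planted[:n_up]] = config.effect_log2
    effect[planted[n_up:]] = -config.effect_log2

    treat_mean = base_mean * 2.0**effect
    runs = {"T1": treat_mean, "T2": treat_mean, "C1": base_mean, "C2": base_mean}
    counts = pd.DataFrame(
        {r: _nb_counts(rng, m, config.dispersion) for r, m in runs.items()},
        index=pd.Index(ids, name="protein_id"),
    )
    design = pd.DataFrame(
        {
            "condition": ["treatment", "treatment", "control", "control"],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(list(runs), name="run_id"),
    )
    status = np.where(effect > 0, "UP", np.where(effect < 0, "DOWN", "null"))
    truth = pd.DataFrame(
        {
            "true_status": status,
            "effect_log2": effect,
            "baseline_expected": base_mean,
        },
        index=counts.index,
    )
    return counts, design, truth


def gen_expression_with_operons(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], pd.DataFrame]:
    """Expression matrix + scored adjacent gene pairs + truth.

    Genes are partitioned into transcription units by the size
    distribution; each unit draws a latent per-array profile (zero on the
    baseline arrays) and members observe a mix of the unit profile and an
    independent private profile, weighted by the within-operon
    correlation, plus measurement noise. Prediction scores are drawn
    class-conditionally: confident scores fall below 1.5 (operon pairs) or
    above 5 (boundary pairs); an ``ambiguous_fraction`` of each class falls
    in [1.5, 5] with only a mild raw-score signal, which is what the
    expression adjustment can improve on.

    Returns ``(expr, pairs, baseline_arrays, truth)`` where ``truth`` has
    one row per adjacent pair with its true class.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"g{i + 1:04d}" for i in range(n)]
    arrays = [f"a{j + 1:02d}" for j in range(config.n_arrays)]
    baseline = arrays[: config.n_baseline_arrays]

    # partition into units
    sizes = []
    remaining = n
    support = np.arange(1, len(config.operon_size_probs) + 1)
    while remaining > 0:
        s = int(rng.choice(support, p=config.operon_size_probs))
        sizes.append(min(s, remaining))
        remaining -= sizes[-1]
    unit_of_gene = np.repeat(np.arange(len(sizes)), sizes)

    rho = config.within_operon_correlation
    n_free = config.n_arrays - config.n_baseline_arrays
    unit_profiles = np.zeros((len(sizes), config.n_arrays))
    unit_profiles[:, config.n_baseline_arrays :] = rng.normal(
        0.0, config.profile_sd, size=(len(sizes), n_free)
    )
    private = np.zeros((n, config.n_arrays))
    private[:, config.n_baseline_arrays :] = rng.normal(
        0.0, config.profile_sd, size=(n, n_free)
    )
    mu = rng.normal(10.0, 1.0, size=n)
    signal = rho * unit_profiles[unit_of_gene] + (1.0 - rho) * private
    noise = rng.normal(0.0, config.noise_sd, size=(n, config.n_arrays)) if config.noise_sd > 0 else 0.0
    expr = pd.DataFrame(
        mu[:, None] + signal + noise,
        index=pd.Index(genes, name="gene_id"),
        columns=arrays,
    )

    rows = []
    for i in range(n - 1):
        same = unit_of_gene[i] == unit_of_gene[i + 1]
        ambiguous = rng.random() < config.ambiguous_fraction
        if same:
            score = (
                rng.triangular(1.5, 1.5, 5.0) if ambiguous else rng.uniform(0.0, 1.5)
            )
        else:
            score = (
                rng.triangular(1.5, 5.0, 5.0) if ambiguous else rng.uniform(5.0, 10.0)
            )
        rows.append(
            {
                "upstream_gene": genes[i],
                "downstream_gene": genes[i + 1],
                "prediction_score": score,
                "true_class": "operon_pair" if same else "boundary_pair",
            }
        )
    truth = pd.DataFrame(rows)
    pairs = truth[["upstream_gene", "downstream_gene", "prediction_score"]].copy()
    return expr, pairs, baseline, truth


def gen_metabolite_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format metabolite peak table with internal standard.

    Latent per-gram concentrations are log-normal per metabolite with
    log-normal replicate variation; a planted subset multiplies its
    treatment concentration by ``metabolite_fold`` at every time point.
    Peak areas fold in the sample mass and a per-sample recovery factor
    that also scales the internal-standard area, so only normalization by
    the internal standard and mass recovers the planted ratios.

    Returns ``(table, truth)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_metabolites
    mets = [f"m{i + 1:02d}" for i in range(n)]
    base_conc = rng.lognormal(mean=2.0, sigma=1.0, size=n)
    n_changed = round(config.frac_changed * n)
    changed_idx = rng.choice(n, size=n_changed, replace=False)
    fold = np.ones(n)
    # planted changes alternate direction
    fold[changed_idx[::2]] = config.metabolite_fold
    fold[changed_idx[1::2]] = 1.0 / config.metabolite_fold

    sigma_rep = np.sqrt(np.log1p(config.replicate_cv**2))
    rows = []
    for tp in config.time_points:
        for cond in ("treatment", "control"):
            for rep in (1, 2):
                sample = f"{cond[0].upper()}{rep}_t{tp:g}"
                mass = 0.1 * rng.lognormal(0.0, 0.05)
                recovery = rng.lognormal(0.0, config.is_jitter_sd)
                is_area = 1.0e6 * recovery
                conc = base_conc * (fold if cond == "treatment" else 1.0)
                conc = conc * rng.lognormal(0.0, sigma_rep, size=n)
                areas = conc * mass * recovery * 1.0e4
                for m, area in zip(mets, areas):
                    rows.append(
                        {
                            "metabolite_id": m,
                            "sample_id": sample,
                            "condition": cond,
                            "time_point": tp,
                            "replicate": rep,
                            "peak_area": area,
                            "internal_standard_area": is_area,
                            "sample_mass": mass,
                        }
                    )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "changed": fold != 1.0,
            "true_fold": fold,
        },
        index=pd.Index(mets, name="metabolite_id"),
    )
    return table, truth
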