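"""Synthetic data generators for every pipeline stage.

Three generators mirror the three kinds of input the pipeline consumes:

* :func:`simulate_organoid_counts` draws organoid-style RNA-seq counts from
  the same generative model the DE stage fits (NB counts with treatment /
  subject / cluster varying intercepts), returning the ground truth so that
  parameter recovery and error control are machine-checkable.
* :func:`simulate_cohort` emulates a clinical-trial cohort on a continuous
  log-intensity scale (microarray-like): a latent per-patient "program
  activation" shifts a gene set's expression and modulates a binary response
  outcome through a logistic link; a negative slope encodes
  "high activation implies non-response".
* :func:`simulate_crossspecies_fc` draws paired human/mouse log fold changes
  from a bivariate latent with a chosen correlation, with an identity
  ortholog pairing.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "SimDesign",
    "SimTruth",
    "CohortSimParams",
    "simulate_organoid_counts",
    "simulate_cohort",
    "simulate_crossspecies_fc",
]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB draws in the mean/dispersion parameterization, Var = mu + mu^2/phi."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    return rng.negative_binomial(phi, phi / (phi + mean))


@dataclass(frozen=True)
class SimDesign:
    """Design of an organoid-style count simulation.

    Defaults emulate a cytokine-stimulation organoid experiment: two
    treatment arms (stimulated vs control) with four donors measured in both
    arms, a modest fraction of genes truly responding with a two-natural-log
    effect, moderate donor and cluster variability, and gene-wise dispersion
    and baseline ranges typical of filtered bulk RNA-seq.
    """

    n_genes: int = 2000
    n_treatment_groups: int = 2
    n_subjects: int = 4
    n_clusters: int = 2
    replicates_per_cell: int = 1
    frac_de: float = 0.1
    effect_size: float = 2.0
    sigma1: float = 0.0
    sigma2: float = 0.3
    sigma3: float = 0.2
    beta0_range: tuple[float, float] = (3.0, 8.0)
    phi_range: tuple[float, float] = (2.0, 20.0)
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0
    noise_seed: int | None = None  # redraw counts under identical gene truth

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_treatment_groups", "n_subjects", "n_clusters",
                     "replicates_per_cell"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        for name in ("sigma1", "sigma2", "sigma3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.phi_range[0] > 0 and self.phi_range[1] >= self.phi_range[0]):
            raise ValueError("phi_range must be a positive interval")
        if not (self.size_factor_range[0] > 0
                and self.size_factor_range[1] >= self.size_factor_range[0]):
            raise ValueError("size_factor_range must be a positive interval")
        if self.beta0_range[1] < self.beta0_range[0]:
            raise ValueError("beta0_range must be a non-empty interval")


@dataclass
class SimTruth:
    """Ground truth behind a simulated count matrix."""

    genes: pd.DataFrame  # gene, beta0, delta, phi, is_de
    samples: pd.DataFrame  # sample, treatment, subject, cluster, size_factor


def simulate_organoid_counts(
    design: SimDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw a count matrix from the hierarchical NB generative model.

    Samples form a full factorial of treatment x subject x replicate, with a
    cluster label cycling over samples.  For genes flagged truly DE the
    treatment effect of the last treatment level (vs the first) is set to
    +/- ``effect_size`` (half up, half down); all other group effects are
    drawn from their zero-centred normals.  Returns (counts, sample metadata,
    truth).
    """
    d = design
    rng = substream(d.seed, "organoid_counts")
    rng_noise = substream(
        d.seed if d.noise_seed is None else d.noise_seed, "organoid_noise"
    )
    nt, ns, nr = d.n_treatment_groups, d.n_subjects, d.replicates_per_cell
    n = nt * ns * nr
    rows = []
    for t in range(nt):
        for p in range(ns):
            for r in range(nr):
                rows.append((f"s_t{t}_d{p}_r{r}", f"t{t}", f"d{p}"))
    sample_ids = [r[0] for r in rows]
    treatment = [r[1] for r in rows]
    subject = [r[2] for r in rows]
    cluster = [f"c{i % d.n_clusters}" for i in range(n)]
    sf = rng.uniform(*d.size_factor_range, size=n)

    G = d.n_genes
    gene_ids = [f"g{i:05d}" for i in range(G)]
    beta0 = rng.uniform(*d.beta0_range, size=G)
    phi = rng.uniform(*d.phi_range, size=G)
    n_de = int(round(d.frac_de * G))
    de_idx = rng.choice(G, size=n_de, replace=False)
    is_de = np.zeros(G, dtype=bool)
    is_de[de_idx] = True
    signs = np.ones(n_de)
    signs[1::2] = -1.0
    delta = np.zeros(G)
    delta[de_idx] = signs * d.effect_size

    beta_t = rng.normal(0.0, d.sigma1, size=(G, nt)) if d.sigma1 > 0 else np.zeros((G, nt))
    # DE genes: deterministic contrast between last and first level
    beta_t[is_de, 0] = 0.0
    beta_t[is_de, -1] = delta[is_de]
    beta_p = rng.normal(0.0, d.sigma2, size=(G, ns)) if d.sigma2 > 0 else np.zeros((G, ns))
    beta_c = (
        rng.normal(0.0, d.sigma3, size=(G, d.n_clusters))
        if d.sigma3 > 0
        else np.zeros((G, d.n_clusters))
    )

    t_idx = np.array([int(v[1:]) for v in treatment])
    p_idx = np.array([int(v[1:]) for v in subject])
    c_idx = np.array([int(v[1:]) for v in cluster])
    eta = beta0[:, None] + beta_t[:, t_idx] + beta_p[:, p_idx] + beta_c[:, c_idx]
    mean = sf[None, :] * np.exp(eta)
    counts = _nb_draw(rng_noise, mean, phi[:, None])

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    counts_df.index.name = "gene"
    meta = pd.DataFrame(
        {"treatment": treatment, "subject": subject, "cluster": cluster},
        index=pd.Index(sample_ids, name="sample"),
    )
    truth = SimTruth(
        genes=pd.DataFrame(
            {"beta0": beta0, "delta": delta, "phi": phi, "is_de": is_de},
            index=pd.Index(gene_ids, name="gene"),
        ),
        samples=meta.assign(size_factor=sf),
    )
    return counts_df, meta, truth


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of the cohort (trial-like) expression simulation.

    Defaults emulate the scale of a phase-3 biopsy cohort: several hundred
    patients, a small healthy-control arm, array-like log intensities, and a
    latent activation that both shifts the program genes (by
    ``delta * activation``) and lowers the response probability through
    ``logistic(gamma0 + gamma1 * activation)`` when ``gamma1 < 0``.
    """

    n_patients: int = 550
    n_controls: int = 18
    program_genes: tuple[str, ...] = tuple(f"PG{i:03d}" for i in range(50))
    delta: float = 2.0
    activation_mean: float = 1.0
    activation_sd: float = 1.0
    gamma0: float = -0.5
    gamma1: float = -1.5
    noise_sd: float = 1.0
    n_background_genes: int = 450
    gene_ids: tuple[str, ...] | None = None
    placebo_frac: float = 0.0
    placebo_response_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("n_patients and n_controls must be >= 1")
        if len(self.program_genes) == 0:
            raise ValueError("program_genes must be non-empty")
        if self.activation_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("activation_sd and noise_sd must be > 0")
        if not 0.0 <= self.placebo_frac <= 1.0:
            raise ValueError("placebo_frac must lie in [0, 1]")
        if self.gene_ids is not None:
            missing = sorted(set(self.program_genes) - set(self.gene_ids))
            if missing:
                raise ValueError(f"program genes not in gene panel: {missing}")


def simulate_cohort(
    params: CohortSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate cohort expression, clinical annotations and activation truth.

    Returns (expression genes x samples, cohort table, truth table).  Patient
    sample s carries activation a_s ~ Normal(activation_mean, activation_sd),
    shifting every program gene by a_s * delta; controls sit at baseline.
    Binary outcomes are Bernoulli(logistic(gamma0 + gamma1 * a_s)) for
    actively treated patients; placebo patients respond at a flat
    ``placebo_response_rate``.  An ordinal neutrophil-infiltration-like
    subscore (0..3) is derived from the activation for patients.  Controls
    carry no outcomes or subscores (missing).
    """
    p = params
    rng = substream(p.seed, "cohort")
    if p.gene_ids is not None:
        genes = list(p.gene_ids)
    else:
        genes = list(p.program_genes) + [f"BG{i:04d}" for i in range(p.n_background_genes)]
    program = set(p.program_genes)
    n = p.n_patients + p.n_controls
    sample_ids = [f"pt{i:04d}" for i in range(p.n_patients)] + [
        f"hc{i:03d}" for i in range(p.n_controls)
    ]
    is_patient = np.array([True] * p.n_patients + [False] * p.n_controls)

    a = np.zeros(n)
    a[is_patient] = rng.normal(p.activation_mean, p.activation_sd, size=p.n_patients)

    base = rng.uniform(5.0, 10.0, size=len(genes))
    expr = base[:, None] + rng.normal(0.0, p.noise_sd, size=(len(genes), n))
    prog_mask = np.array([g in program for g in genes])
    expr[np.ix_(prog_mask, is_patient)] += p.delta * a[is_patient][None, :]
    expr_df = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=sample_ids)

    arm = np.where(is_patient, "active", "none").astype(object)
    n_placebo = int(round(p.placebo_frac * p.n_patients))
    if n_placebo:
        placebo_idx = rng.choice(p.n_patients, size=n_placebo, replace=False)
        arm[placebo_idx] = "placebo"

    logit = p.gamma0 + p.gamma1 * a
    prob = 1.0 / (1.0 + np.exp(-logit))
    prob = np.where(arm == "placebo", p.placebo_response_rate, prob)
    clinical = np.where(is_patient, rng.random(n) < prob, np.nan)
    # mucosal healing tracks the same latent with a slightly easier threshold
    prob_mh = 1.0 / (1.0 + np.exp(-(p.gamma0 + 0.4 + p.gamma1 * a)))
    prob_mh = np.where(arm == "placebo", p.placebo_response_rate, prob_mh)
    mucosal = np.where(is_patient, rng.random(n) < prob_mh, np.nan)
    deep = np.where(is_patient, ((clinical == 1) & (mucosal == 1)).astype(float), np.nan)
    geboes = np.where(
        is_patient,
        np.clip(np.round(a + rng.normal(0, 0.5, n)), 0, 3),
        np.nan,
    )

    cohort = pd.DataFrame(
        {
            "group": np.where(is_patient, "patient", "control"),
            "arm": arm,
            "clinical_remission": clinical,
            "mucosal_healing": mucosal,
            "deep_remission": deep,
            "geboes_epithelium": geboes,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    truth = pd.DataFrame(
        {"activation": a, "response_prob": np.where(is_patient, prob, np.nan)},
        index=pd.Index(sample_ids, name="sample"),
    )
    return expr_df, cohort, truth


def simulate_crossspecies_fc(
    n_genes: int,
    rho: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    fc_scale: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired human/mouse log fold changes from a bivariate latent.

    The latent pair is bivariate normal with correlation ``rho`` (unit
    variance, scaled by ``fc_scale``); independent Gaussian noise of sd
    ``noise_sd`` is added to each species, attenuating the observable
    correlation.  Returns (human table, mouse table, ortholog map); the map
    is the identity pairing with species-prefixed ids.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = substream(seed, "xspecies")
    z = rng.standard_normal((n_genes, 2))
    lat_h = z[:, 0]
    lat_m = rho * z[:, 0] + np.sqrt(max(1.0 - rho**2, 0.0)) * z[:, 1]
    fc_h = fc_scale * lat_h + (rng.normal(0, noise_sd, n_genes) if noise_sd else 0.0)
    fc_m = fc_scale * lat_m + (rng.normal(0, noise_sd, n_genes) if noise_sd else 0.0)
    h_ids = [f"hsa_G{i:05d}" for i in range(n_genes)]
    m_ids = [f"mmu_G{i:05d}" for i in range(n_genes)]
    human = pd.DataFrame({"logFC_e": fc_h}, index=pd.Index(h_ids, name="gene"))
    mouse = pd.DataFrame({"logFC_e": fc_m}, index=pd.Index(m_ids, name="gene"))
    orth = pd.DataFrame({"gene_a": h_ids, "gene_b": m_ids})
    return human, mouse, orth
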