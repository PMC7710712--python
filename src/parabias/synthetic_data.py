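"""Synthetic trees, study tables and trait tables with the assumed structure.

The generator mirrors the data model the analysis assumes: a rooted
ultrametric phylogeny; a species-level sex-bias in log-odds of infection
equal to a grand mean ``delta`` plus a Brownian (phylogenetically
correlated) deviation; an extra independent study-level deviation on the
logit scale; binomial sampling of infected counts per sex within each study;
Brownian log body mass; and logit mortality optionally linked to each sex's
logit prevalence through a configurable slope, with residual phylogenetic
signal ``lambda_true``.

Defaults follow the study conditions of the comparative dataset the pipeline
is built for: 96 host species (the blood-parasite analysis), one to four
studies per species (~2.4 effect sizes per species), per-sex sample sizes
spanning 4 to 500 individuals, a baseline prevalence around 20%, annual
mortalities around 0.4, and polygamy scores concentrated at 0.  The sex
effect is applied to the male side only, so ``delta`` is exactly the
expected log odds ratio — the estimand of the meta-analysis.

Everything is driven by one integer seed; the same seed reproduces every
byte of the emitted CSV/Newick files.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .data_io import SpeciesTraits, StudyRecord
from .effect_sizes import inv_logit
from .tree_tools import lambda_scale, vcv_from_tree

__all__ = [
    "SimConfig",
    "SimulatedData",
    "simulate_tree",
    "simulate_sexbias_effects",
    "simulate_study_table",
    "simulate_traits",
    "simulate_dataset",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic-data generator (see module docstring)."""

    seed: int = 0
    n_species: int = 96
    tree_model: str = "yule"  # or "birth_death"
    birth_rate: float = 1.0
    death_rate: float = 0.0

    delta: float = 0.0  # true mean sex-bias log OR
    sigma2_phylo: float = 0.1
    sigma2_study: float = 0.1

    studies_min: int = 1
    studies_max: int = 4
    n_per_sex_min: int = 4
    n_per_sex_max: int = 500

    base_prev_logit_mean: float = -1.386  # baseline prevalence ~ 20%
    base_prev_brownian_var: float = 0.5

    mort_intercept_m: float = -0.405  # annual mortality ~ 0.4
    mort_intercept_f: float = -0.405
    mort_slope_on_prev: float = 0.0
    mort_brownian_sigma2: float = 0.3
    mort_lambda_true: float = 0.9

    mass_log_mean: float = 3.5  # ~33 g
    mass_brownian_var: float = 0.5
    ssd_mean: float = 0.05  # males slightly heavier
    ssd_sd: float = 0.1

    polygamy_probs_m: tuple[float, ...] = (0.70, 0.15, 0.08, 0.04, 0.03)
    polygamy_probs_f: tuple[float, ...] = (0.85, 0.08, 0.04, 0.02, 0.01)

    period_probs: tuple[float, ...] = (0.5, 0.2, 0.3)  # breeding/nonbreeding/year_round
    detection_probs: tuple[float, ...] = (0.4, 0.5, 0.1)  # molecular/microscopy/both

    funnel_bias: float = 0.0  # links E[yi] to sei for publication-bias tests

    parasite_class: str = "blood"
    parasite_category: str = "Haemoproteus"

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.tree_model not in ("yule", "birth_death"):
            raise ValueError(f"unknown tree model {self.tree_model!r}")
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("need birth_rate > 0 and death_rate >= 0")
        if self.tree_model == "birth_death" and self.death_rate >= self.birth_rate:
            raise ValueError("birth_death model needs death_rate < birth_rate")
        for name in ("sigma2_phylo", "sigma2_study", "base_prev_brownian_var",
                     "mort_brownian_sigma2", "mass_brownian_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")
        if not 0.0 <= self.mort_lambda_true <= 1.0:
            raise ValueError("mort_lambda_true must lie in [0, 1]")
        if not (1 <= self.studies_min <= self.studies_max):
            raise ValueError("need 1 <= studies_min <= studies_max")
        if not (1 <= self.n_per_sex_min <= self.n_per_sex_max):
            raise ValueError("need 1 <= n_per_sex_min <= n_per_sex_max")


@dataclass
class SimulatedData:
    tree: dendropy.Tree
    species: list[str]
    effects: dict[str, float]  # true per-species sex-bias log OR
    baselines: dict[str, float]  # female (baseline) logit prevalence
    studies: list[StudyRecord]
    traits: list[SpeciesTraits]


def _subseed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([int(seed), stream]).generate_state(1)[0] % 2**31)


def simulate_tree(config: SimConfig, seed: int | None = None) -> dendropy.Tree:
    """A rooted ultrametric tree with n_species tips, depth normalized to 1."""
    config.validate()
    seed = config.seed if seed is None else seed
    rng = random.Random(_subseed(seed, 1))
    death = 0.0 if config.tree_model == "yule" else config.death_rate
    tree = treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=death,
        num_extant_tips=config.n_species,
        rng=rng,
    )
    tree.is_rooted = True
    # the process stops exactly at the n-th speciation, leaving zero-length
    # terminal branches (coincident tips); grow every extant lineage by one
    # exponential waiting time so all terminal branches are positive
    dt = rng.expovariate(config.n_species * (config.birth_rate + death))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + dt
    # force exact ultrametricity, then rescale depth to 1
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    max_depth = max(depths)
    for leaf in tree.leaf_node_iter():
        short = max_depth - leaf.root_distance
        leaf.edge.length = (leaf.edge.length or 0.0) + short
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= max_depth
    width = len(str(config.n_species))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"Species {i:0{width}d}"
    return tree


def _brownian_chol(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    vcv = vcv_from_tree(tree, scale="correlation")
    jitter = 1e-10 * np.eye(len(vcv.labels))
    return vcv.labels, np.linalg.cholesky(vcv.C + jitter)


def simulate_sexbias_effects(
    tree: dendropy.Tree, config: SimConfig, seed: int | None = None
) -> dict[str, float]:
    """True per-species sex-bias: delta plus Brownian deviation.

    Across species the deviations have covariance sigma2_phylo * C with C the
    depth-1 (correlation-scaled) phylogenetic matrix.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(_subseed(seed, 2))
    labels, L = _brownian_chol(tree)
    dev = math.sqrt(config.sigma2_phylo) * (L @ rng.standard_normal(len(labels)))
    return {lab: config.delta + d for lab, d in zip(labels, dev)}


def _simulate_baselines(
    tree: dendropy.Tree, config: SimConfig, seed: int
) -> dict[str, float]:
    rng = np.random.default_rng(_subseed(seed, 3))
    labels, L = _brownian_chol(tree)
    dev = math.sqrt(config.base_prev_brownian_var) * (
        L @ rng.standard_normal(len(labels))
    )
    return {lab: config.base_prev_logit_mean + d for lab, d in zip(labels, dev)}


_PERIODS = ("breeding", "nonbreeding", "year_round")
_DETECTIONS = ("molecular", "microscopy", "both")


def simulate_study_table(
    tree: dendropy.Tree,
    effects: dict[str, float],
    config: SimConfig,
    seed: int | None = None,
    baselines: dict[str, float] | None = None,
) -> list[StudyRecord]:
    """Per-species studies with binomial infected counts per sex.

    Female logit prevalence is the species baseline; male logit prevalence is
    baseline + species effect + study-level N(0, sigma2_study) deviation,
    plus ``funnel_bias`` times the study's expected standard error when a
    funnel asymmetry is requested.
    """
    seed = config.seed if seed is None else seed
    if baselines is None:
        baselines = _simulate_baselines(tree, config, seed)
    rng = np.random.default_rng(_subseed(seed, 4))
    records: list[StudyRecord] = []
    study_no = 0
    for species in sorted(effects):
        n_studies = int(rng.integers(config.studies_min, config.studies_max + 1))
        for _ in range(n_studies):
            study_no += 1
            n_m = int(rng.integers(config.n_per_sex_min, config.n_per_sex_max + 1))
            n_f = int(rng.integers(config.n_per_sex_min, config.n_per_sex_max + 1))
            dev = rng.normal(0.0, math.sqrt(config.sigma2_study))
            f_logit = baselines[species]
            m_logit = f_logit + effects[species] + dev
            if config.funnel_bias != 0.0:
                p_m0, p_f0 = inv_logit(m_logit), inv_logit(f_logit)
                sei_exp = math.sqrt(
                    1.0 / max(n_m * p_m0 * (1 - p_m0), 0.5)
                    + 1.0 / max(n_f * p_f0 * (1 - p_f0), 0.5)
                )
                m_logit += config.funnel_bias * sei_exp
            inf_m = int(rng.binomial(n_m, inv_logit(m_logit)))
            inf_f = int(rng.binomial(n_f, inv_logit(f_logit)))
            period = _PERIODS[rng.choice(3, p=np.asarray(config.period_probs))]
            if config.parasite_class == "blood":
                detection = _DETECTIONS[
                    rng.choice(3, p=np.asarray(config.detection_probs))
                ]
            else:
                detection = "not_applicable"
            records.append(
                StudyRecord(
                    study_id=f"S{study_no:04d}",
                    species=species,
                    parasite_class=config.parasite_class,
                    parasite_category=config.parasite_category,
                    males_examined=n_m,
                    males_infected=inf_m,
                    females_examined=n_f,
                    females_infected=inf_f,
                    period=period,
                    detection=detection,
                )
            )
    return records


def simulate_traits(
    tree: dendropy.Tree,
    effects: dict[str, float],
    config: SimConfig,
    seed: int | None = None,
    baselines: dict[str, float] | None = None,
) -> list[SpeciesTraits]:
    """Species traits: Brownian log mass, mortality linked to prevalence.

    Logit mortality per sex = sex intercept + slope * (that sex's latent
    logit prevalence) + residual noise with covariance
    mort_brownian_sigma2 * C(lambda_true); mortalities come back through the
    inverse logit so they always lie in (0, 1).
    """
    seed = config.seed if seed is None else seed
    if baselines is None:
        baselines = _simulate_baselines(tree, config, seed)
    rng = np.random.default_rng(_subseed(seed, 5))
    labels, L = _brownian_chol(tree)
    n = len(labels)
    log_mass_m = config.mass_log_mean + math.sqrt(config.mass_brownian_var) * (
        L @ rng.standard_normal(n)
    )
    ssd = rng.normal(config.ssd_mean, config.ssd_sd, size=n)

    corr = vcv_from_tree(tree, scale="correlation").C
    C_lam = lambda_scale(corr, config.mort_lambda_true)
    L_lam = np.linalg.cholesky(C_lam + 1e-10 * np.eye(n))
    noise_m = math.sqrt(config.mort_brownian_sigma2) * (L_lam @ rng.standard_normal(n))
    noise_f = math.sqrt(config.mort_brownian_sigma2) * (L_lam @ rng.standard_normal(n))

    traits: list[SpeciesTraits] = []
    for i, lab in enumerate(labels):
        prev_f = baselines[lab]
        prev_m = prev_f + effects[lab]
        lat_m = config.mort_intercept_m + config.mort_slope_on_prev * prev_m + noise_m[i]
        lat_f = config.mort_intercept_f + config.mort_slope_on_prev * prev_f + noise_f[i]
        traits.append(
            SpeciesTraits(
                species=lab,
                male_mass=float(np.exp(log_mass_m[i])),
                female_mass=float(np.exp(log_mass_m[i] - ssd[i])),
                male_mortality=inv_logit(lat_m),
                female_mortality=inv_logit(lat_f),
                male_polygamy=int(rng.choice(5, p=np.asarray(config.polygamy_probs_m))),
                female_polygamy=int(rng.choice(5, p=np.asarray(config.polygamy_probs_f))),
            )
        )
    return traits


def simulate_dataset(config: SimConfig) -> SimulatedData:
    """Generate a full consistent dataset (tree, studies, traits) from one seed."""
    config.validate()
    tree = simulate_tree(config)
    effects = simulate_sexbias_effects(tree, config)
    baselines = _simulate_baselines(tree, config, config.seed)
    studies = simulate_study_table(tree, effects, config, baselines=baselines)
    traits = simulate_traits(tree, effects, config, baselines=baselines)
    return SimulatedData(
        tree=tree,
        species=sorted(effects),
        effects=effects,
        baselines=baselines,
        studies=studies,
        traits=traits,
    )
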