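"""End-to-end orchestration: meta-analysis suite and PGLS suite.

`run_meta_suite` mirrors the per-class / per-category layout of the
meta-analytic results table: for each parasite class an overall model over
all its effect sizes (optionally including multi-category "Combined" rows)
plus one model per parasite category, each with residual heterogeneity Q,
the Egger asymmetry test, and — when asymmetry is flagged — influence
diagnostics and an outlier-excluded refit.  Ectoparasite rows are excluded
by default (too few species to analyze) with a logged notice.

`run_pgls_suite` builds one consensus phylogeny per parasite class from a
seeded subsample of the candidate trees, resolves polytomies, aggregates
study-level effects per species, derives the transformed variables, and runs
the six-model PGLS suite.

Per-category/per-model failures never abort the whole run; they are recorded
in the run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import (
    BLOOD_CATEGORIES,
    GI_CATEGORIES,
    StudyRecord,
    TreeSet,
    canonical_name,
    read_study_table,
    read_trait_table,
    read_trees,
    write_results_table,
    write_trees,
)
from .effect_sizes import (
    aggregate_by_species,
    build_derived_vars,
    compute_effects,
    pool_prevalence,
)
from .phylo_meta import (
    MetaModelSpec,
    egger_test,
    fit_meta,
    influence_diagnostics,
    refit_without_outliers,
)
from .pgls import run_model_suite
from .tree_tools import majority_consensus, prune_and_align, resolve_polytomies, vcv_from_tree

logger = logging.getLogger("parabias")

__all__ = ["RunConfig", "run_meta_suite", "run_pgls_suite", "run_all"]

_CLASS_CATEGORIES = {
    "blood": BLOOD_CATEGORIES,
    "gastrointestinal": GI_CATEGORIES,
}


@dataclass
class RunConfig:
    """Configuration of a pipeline run (serialized verbatim into the output)."""

    study_table: str = ""
    trait_table: str = ""
    trees: str = ""
    tree_format: str = "newick"
    seed: int = 1
    n_trees_subsample: int = 1000
    consensus_threshold: float = 0.5
    consensus_length_rule: str = "mean"
    correction: str = "only_zero_cells"
    correction_increment: float = 0.5
    egger_mode: str = "se_moderator"
    influence_resid_threshold: float = 2.0
    influence_hat_factor: float = 2.0
    aggregation: str = "weighted_average"  # or "sister_tips"
    prevalence_pooling: str = "pooled_counts"
    include_combined_in_overall: bool = True
    classes: tuple[str, ...] = ("blood", "gastrointestinal")
    polytomy_epsilon: float = 1e-8
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.classes, list):
            cfg.classes = tuple(cfg.classes)
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["classes"] = list(self.classes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _checksum(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _prepare_outdir(config: RunConfig) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest = {"version": __version__, "seed": config.seed, "inputs": {}}
    for key in ("study_table", "trait_table", "trees"):
        path = getattr(config, key)
        if path and Path(path).exists():
            manifest["inputs"][key] = {"path": str(path), "sha256": _checksum(path)}
    with open(outdir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return outdir


def _subsample_trees(treeset: TreeSet, n: int, seed: int) -> list:
    trees = list(treeset)
    if n >= len(trees):
        return trees
    rng = random.Random(seed)
    idx = sorted(rng.sample(range(len(trees)), n))
    return [trees[i] for i in idx]


def _class_consensus(treeset: TreeSet, species: list[str], config: RunConfig):
    """Subsample -> prune to the class species -> consensus -> binary tree."""
    sample = _subsample_trees(treeset, config.n_trees_subsample, config.seed)
    pruned = [prune_and_align(t, species)[0] for t in sample]
    cons = majority_consensus(
        pruned, threshold=config.consensus_threshold,
        length_rule=config.consensus_length_rule,
    )
    return resolve_polytomies(cons, epsilon=config.polytomy_epsilon, seed=config.seed)


def _fit_block(effects, spec, phylo, config, analysis, group, rows, extras):
    """Fit one meta model + Q + Egger (+ outlier refit); append result rows."""
    fit = fit_meta(effects, spec, phylo)
    egger = None
    excluded_ids: list[tuple[str, str]] = []
    refit = None
    try:
        egger = egger_test(effects, spec, phylo, mode=config.egger_mode)
    except ValueError as exc:
        logger.info("%s/%s: Egger test not run (%s)", analysis, group, exc)
    if egger is not None and egger.biased:
        report = influence_diagnostics(
            fit,
            resid_threshold=config.influence_resid_threshold,
            hat_factor=config.influence_hat_factor,
        )
        if report.flagged:
            refit = refit_without_outliers(
                effects, spec, phylo, report, original_fit=fit
            )
            excluded_ids = report.flagged_ids
            egger_after = None
            try:
                keep = [i for i in range(len(effects)) if i not in set(report.flagged)]
                egger_after = egger_test(
                    [effects[i] for i in keep], spec, phylo, mode=config.egger_mode
                )
            except ValueError:
                pass
            logger.info(
                "%s/%s: excluded %d influential effect(s) %s; Egger P %.4f -> %s",
                analysis, group, len(excluded_ids), excluded_ids, egger.p,
                f"{egger_after.p:.4f}" if egger_after else "n/a",
            )
    rows.append(
        {
            "analysis": analysis,
            "group": group,
            "k": fit.k,
            "n_species": fit.n_species,
            "n_studies": fit.n_studies,
            "estimate": fit.estimate,
            "ci_low": float(fit.ci_low[0]),
            "ci_high": float(fit.ci_high[0]),
            "Z_or_t": float(fit.z[0]),
            "P": float(fit.p[0]),
            "Q": fit.QE,
            "Q_df": fit.QE_df,
            "Q_P": fit.QE_p,
        }
    )
    extras.append(
        {
            "analysis": analysis,
            "group": group,
            "sigma2_phylo": fit.sigma2_phylo,
            "sigma2_study": fit.sigma2_study,
            "low_power_flag": fit.low_power_flag,
            "egger_mode": config.egger_mode,
            "egger_p": egger.p if egger else float("nan"),
            "egger_biased": bool(egger.biased) if egger else False,
            "n_excluded": len(excluded_ids),
            "excluded_ids": ";".join(f"{s}|{sp}" for s, sp in excluded_ids),
            "estimate_after_exclusion": refit.estimate if refit else float("nan"),
        }
    )
    return fit


def run_meta_suite(config: RunConfig, outdir: Path | None = None):
    """Per-class and per-category phylogenetic meta-analyses (Table-1 layout)."""
    outdir = _prepare_outdir(config) if outdir is None else outdir
    records, report = read_study_table(config.study_table)
    logger.info("study table: %s", report.summary())
    treeset = read_trees(config.trees, format=config.tree_format)

    n_ecto = sum(1 for r in records if r.parasite_class == "ectoparasite")
    if n_ecto:
        logger.info("excluding %d ectoparasite row(s) from the analysis", n_ecto)

    rows: list[dict] = []
    extras: list[dict] = []
    effect_rows: list[dict] = []
    failures = 0
    attempts = 0
    for pclass in config.classes:
        class_records = [r for r in records if r.parasite_class == pclass]
        if not class_records:
            logger.info("class %s: no usable rows, skipped", pclass)
            continue
        effects_all = compute_effects(
            class_records, config.correction, config.correction_increment
        )
        for e in effects_all:
            effect_rows.append(
                {
                    "study_id": e.study_id,
                    "species": e.species,
                    "parasite_class": e.parasite_class,
                    "parasite_category": e.parasite_category,
                    "yi": e.yi,
                    "vi": e.vi,
                    "sei": e.sei,
                    "corrected": e.corrected,
                }
            )
        species = sorted({e.species for e in effects_all}, key=str.casefold)
        try:
            cons = _class_consensus(treeset, species, config)
        except (KeyError, ValueError) as exc:
            logger.error("class %s: consensus failed (%s); class skipped", pclass, exc)
            failures += 1
            attempts += 1
            continue
        write_trees([cons], outdir / f"consensus_{pclass}.nwk")
        phylo = vcv_from_tree(cons, scale="correlation")

        groups: list[tuple[str, list]] = []
        overall = (
            effects_all
            if config.include_combined_in_overall
            else [e for e in effects_all if e.parasite_category != "Combined"]
        )
        groups.append(("overall", overall))
        for category in _CLASS_CATEGORIES.get(pclass, ()):
            cat = [e for e in effects_all if e.parasite_category == category]
            if cat:
                groups.append((category, cat))

        for group, effects in groups:
            attempts += 1
            moderators = []
            if len({e.period for e in effects}) > 1:
                moderators.append("period")
            if pclass == "blood" and len({e.detection for e in effects}) > 1:
                moderators.append("detection")
            spec = MetaModelSpec(moderators=tuple(moderators))
            try:
                _fit_block(effects, spec, phylo, config, pclass, group, rows, extras)
            except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
                logger.error("%s/%s: fit failed (%s)", pclass, group, exc)
                failures += 1

    results = write_results_table(rows, outdir / "meta_results.csv")
    pd.DataFrame(extras).to_csv(outdir / "meta_details.csv", index=False)
    pd.DataFrame(effect_rows).to_csv(outdir / "effect_sizes.csv", index=False)
    # forest-plot data: per-group estimate and CI
    forest = [
        {k: row[k] for k in ("analysis", "group", "estimate", "ci_low", "ci_high", "k")}
        for row in rows
    ]
    pd.DataFrame(forest).to_csv(outdir / "forest_data.csv", index=False)
    if attempts and failures == attempts:
        raise RuntimeError("all meta-analysis groups failed")
    return results


def _species_table_for_class(records, traits_by_key, pooling):
    """One row per species: aggregated sex-bias effect + derived variables."""
    effects = compute_effects(records)
    agg = aggregate_by_species(effects)
    by_species: dict[str, list[StudyRecord]] = {}
    for r in records:
        by_species.setdefault(r.species_key, []).append(r)
    rows = {}
    for key, sp_effect in agg.items():
        prevalence = pool_prevalence(by_species[key], mode=pooling)
        traits = traits_by_key.get(key)
        dv = build_derived_vars(traits, prevalence, species=sp_effect.species)
        row = {f.name: getattr(dv, f.name) for f in dataclasses.fields(dv)}
        row.pop("species")
        row["prev_bias"] = sp_effect.ybar
        row["prev_bias_var"] = sp_effect.vbar
        row["k_local"] = sp_effect.k_local
        rows[sp_effect.species] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df, agg


def _sister_tip_expansion(cons, table, records, config):
    """One row (and one tip) per study: multi-study species become sister tips.

    Each added tip keeps the species' terminal branch length; the row carries
    that study's own log odds ratio as the sex-bias value while the
    species-level traits are duplicated across its studies.
    """
    from .tree_tools import add_sister_tips

    effects = compute_effects(records, config.correction, config.correction_increment)
    by_species: dict[str, list] = {}
    for e in effects:
        by_species.setdefault(e.species, []).append(e)
    tree = cons
    rows = {}
    for species, es in by_species.items():
        base = table.loc[species].to_dict()
        if len(es) == 1:
            base["prev_bias"] = es[0].yi
            rows[species] = base
            continue
        labels = [f"{species}#{i + 1}" for i in range(len(es))]
        tree = add_sister_tips(
            tree, species, k=len(es), seed=config.seed,
            epsilon=config.polytomy_epsilon, labels=labels,
        )
        for lab, e in zip(labels, es):
            row = dict(base)
            row["prev_bias"] = e.yi
            rows[lab] = row
    return tree, pd.DataFrame.from_dict(rows, orient="index")


def run_pgls_suite(config: RunConfig, outdir: Path | None = None):
    """Per-class PGLS model suite on species-level data (Table-2 layout)."""
    outdir = _prepare_outdir(config) if outdir is None else outdir
    records, report = read_study_table(config.study_table)
    logger.info("study table: %s", report.summary())
    traits, trait_report = read_trait_table(config.trait_table)
    logger.info("trait table: %s", trait_report.summary())
    treeset = read_trees(config.trees, format=config.tree_format)
    traits_by_key = {t.species_key: t for t in traits}
    tree_tips = {
        canonical_name(t.label).casefold() for t in treeset.trees.taxon_namespace
    }

    rows: list[dict] = []
    agg_rows: list[dict] = []
    scatter_rows: list[dict] = []
    for pclass in config.classes:
        class_records = [r for r in records if r.parasite_class == pclass]
        if not class_records:
            logger.info("class %s: no usable rows, skipped", pclass)
            continue
        in_tree = [r for r in class_records if r.species_key in tree_tips]
        dropped = sorted({r.species for r in class_records} - {r.species for r in in_tree})
        if dropped:
            logger.info("class %s: species not in tree, dropped: %s", pclass, dropped)
        if not in_tree:
            logger.error("class %s: no species overlap with the tree", pclass)
            continue
        table, agg = _species_table_for_class(
            in_tree, traits_by_key, config.prevalence_pooling
        )
        for sp_effect in agg.values():
            agg_rows.append(
                {
                    "parasite_class": pclass,
                    "species": sp_effect.species,
                    "ybar": sp_effect.ybar,
                    "vbar": sp_effect.vbar,
                    "k_local": sp_effect.k_local,
                }
            )
        species = list(table.index)
        try:
            cons = _class_consensus(treeset, species, config)
        except (KeyError, ValueError) as exc:
            logger.error("class %s: consensus failed (%s)", pclass, exc)
            continue
        if config.aggregation == "sister_tips":
            cons, table = _sister_tip_expansion(cons, table, in_tree, config)
        elif config.aggregation != "weighted_average":
            raise ValueError(f"unknown aggregation mode {config.aggregation!r}")
        write_trees([cons], outdir / f"consensus_pgls_{pclass}.nwk")
        suite = run_model_suite(table, cons)
        for name, reason in suite.skipped.items():
            logger.info("class %s model %s skipped: %s", pclass, name, reason)
        for name, fit in suite.fits.items():
            if fit.dropped_species:
                logger.info(
                    "class %s model %s: listwise deletion dropped %s",
                    pclass, name, fit.dropped_species,
                )
            for j, coef in enumerate(fit.coef_names):
                if coef == "intercept":
                    continue
                rows.append(
                    {
                        "analysis": f"{pclass}:{name}",
                        "group": coef,
                        "k": fit.n,
                        "n_species": fit.n,
                        "estimate": float(fit.beta[j]),
                        "ci_low": float(fit.beta[j] - 1.959963984540054 * fit.se[j]),
                        "ci_high": float(fit.beta[j] + 1.959963984540054 * fit.se[j]),
                        "Z_or_t": float(fit.t[j]),
                        "P": float(fit.p[j]),
                        "lambda": fit.lambda_ml,
                        "adj_R2": fit.adj_r2,
                    }
                )
        for sp in table.index:
            scatter_rows.append(
                {
                    "parasite_class": pclass,
                    "species": sp,
                    "prev_bias": table.loc[sp, "prev_bias"],
                    "mort_bias": table.loc[sp, "mort_bias"],
                }
            )

    results = write_results_table(rows, outdir / "pgls_results.csv")
    pd.DataFrame(agg_rows).to_csv(outdir / "species_effects.csv", index=False)
    pd.DataFrame(scatter_rows).to_csv(outdir / "sexbias_scatter.csv", index=False)
    return results


def run_all(config: RunConfig):
    outdir = _prepare_outdir(config)
    meta = run_meta_suite(config, outdir=outdir)
    pgls = run_pgls_suite(config, outdir=outdir)
    return meta, pgls
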