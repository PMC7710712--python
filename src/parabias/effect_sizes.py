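"""Sex-bias effect sizes from 2x2 prevalence tables, and variable transforms.

The effect size throughout is the log odds ratio of infection, male odds over
female odds, so positive values mean male-biased prevalence.  Its large-sample
sampling variance is the usual sum of reciprocal cell counts.  Zero cells are
handled with the Haldane–Anscombe continuity correction (add 0.5 to all four
cells of affected tables only, by default), which also lets double-zero
studies (0% prevalence in both sexes) stay in the data as yi = 0 with a large
variance rather than being dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .data_io import SpeciesTraits, StudyRecord, canonical_name

__all__ = [
    "EffectSize",
    "SpeciesEffect",
    "DerivedVars",
    "compute_log_or",
    "compute_effects",
    "aggregate_species_effect",
    "aggregate_by_species",
    "logit",
    "inv_logit",
    "pool_prevalence",
    "build_derived_vars",
]


@dataclass(frozen=True)
class EffectSize:
    """A sex-bias log odds ratio with its sampling variance and provenance."""

    study_id: str
    species: str
    parasite_class: str
    parasite_category: str
    yi: float
    vi: float
    corrected: bool
    period: str = "breeding"
    detection: str = "not_applicable"

    @property
    def sei(self) -> float:
        return math.sqrt(self.vi)

    @property
    def species_key(self) -> str:
        return canonical_name(self.species).casefold()


@dataclass(frozen=True)
class SpeciesEffect:
    """Inverse-variance weighted average of a species' study-level effects."""

    species: str
    ybar: float
    vbar: float
    k_local: int


@dataclass(frozen=True)
class DerivedVars:
    """Per-species transformed variables feeding the PGLS stage.

    All logarithms are natural.  ``mort_bias`` and ``ssd`` are zero exactly
    when the sexes are equal; ``mating_bias`` is the male-minus-female
    polygamy score in [-4, 4].  Any field that cannot be computed from the
    available traits is None.
    """

    species: str
    logit_prev_m: float | None = None
    logit_prev_f: float | None = None
    logit_mort_m: float | None = None
    logit_mort_f: float | None = None
    mort_bias: float | None = None
    log_mass_m: float | None = None
    log_mass_f: float | None = None
    ssd: float | None = None
    mating_bias: float | None = None
    male_polygamy: int | None = None
    female_polygamy: int | None = None


def compute_log_or(
    record: StudyRecord,
    correction: str = "only_zero_cells",
    increment: float = 0.5,
) -> EffectSize:
    """Log odds ratio (male over female) and its sampling variance.

    The 2x2 table is a = males infected, b = males clean, c = females
    infected, d = females clean; yi = ln[(a/b)/(c/d)] and
    vi = 1/a + 1/b + 1/c + 1/d.  Under ``only_zero_cells`` (default) the
    increment is added to all four cells iff any cell is zero; ``always``
    adds it unconditionally; ``never`` requires all cells positive.
    """
    if correction not in ("only_zero_cells", "always", "never"):
        raise ValueError(f"unknown correction policy {correction!r}")
    if record.males_examined < 1 or record.females_examined < 1:
        raise ValueError("both sexes must have examined >= 1")
    a = float(record.males_infected)
    b = float(record.males_examined - record.males_infected)
    c = float(record.females_infected)
    d = float(record.females_examined - record.females_infected)
    has_zero = 0.0 in (a, b, c, d)
    corrected = False
    if correction == "always" or (correction == "only_zero_cells" and has_zero):
        a, b, c, d = (x + increment for x in (a, b, c, d))
        corrected = True
    elif has_zero:  # correction == "never"
        raise ValueError(
            "log odds ratio undefined: zero cell with correction='never'"
        )
    yi = math.log((a / b) / (c / d))
    vi = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return EffectSize(
        study_id=record.study_id,
        species=record.species,
        parasite_class=record.parasite_class,
        parasite_category=record.parasite_category,
        yi=yi,
        vi=vi,
        corrected=corrected,
        period=record.period,
        detection=record.detection,
    )


def compute_effects(
    records: Iterable[StudyRecord],
    correction: str = "only_zero_cells",
    increment: float = 0.5,
) -> list[EffectSize]:
    """Vectorized convenience wrapper over :func:`compute_log_or`."""
    return [compute_log_or(r, correction, increment) for r in records]


def aggregate_species_effect(effects: Sequence[EffectSize]) -> SpeciesEffect:
    """Inverse-variance weighted average effect for one species.

    weights w_i = 1/v_i; ybar = sum(w y)/sum(w); vbar = 1/sum(w).
    """
    if not effects:
        raise ValueError("need at least one effect size")
    keys = {e.species_key for e in effects}
    if len(keys) > 1:
        raise ValueError(f"effects span multiple species: {sorted(keys)}")
    weights = [1.0 / e.vi for e in effects]
    wsum = sum(weights)
    ybar = sum(w * e.yi for w, e in zip(weights, effects)) / wsum
    return SpeciesEffect(
        species=effects[0].species,
        ybar=ybar,
        vbar=1.0 / wsum,
        k_local=len(effects),
    )


def aggregate_by_species(effects: Iterable[EffectSize]) -> dict[str, SpeciesEffect]:
    """Group effects by canonical species key and aggregate each group."""
    groups: dict[str, list[EffectSize]] = {}
    for e in effects:
        groups.setdefault(e.species_key, []).append(e)
    return {key: aggregate_species_effect(group) for key, group in groups.items()}


def logit(p: float, n: int | None = None) -> float:
    """Logit transform with an empirical-logit fallback at the boundary.

    For 0 < p < 1 this is ln(p/(1-p)).  For p in {0, 1} the sample size ``n``
    must be supplied and the 0.5-adjusted empirical logit
    ln((p*n + 0.5) / ((1-p)*n + 0.5)) is used instead.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    if p in (0.0, 1.0):
        if n is None:
            raise ValueError(
                f"logit({p}) undefined; supply n for the empirical logit"
            )
        return math.log((p * n + 0.5) / ((1.0 - p) * n + 0.5))
    return math.log(p / (1.0 - p))


def inv_logit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def pool_prevalence(
    records: Sequence[StudyRecord], mode: str = "pooled_counts"
) -> tuple[tuple[float, int], tuple[float, int]]:
    """Pool per-sex prevalence across a species' studies.

    ``pooled_counts`` (default) sums infected and examined before dividing;
    ``mean_of_studies`` averages the per-study prevalences (the total examined
    is still reported so boundary proportions can use the empirical logit).
    Returns ((male_prev, male_n), (female_prev, female_n)).
    """
    if not records:
        raise ValueError("no records to pool")
    if mode == "pooled_counts":
        m_n = sum(r.males_examined for r in records)
        f_n = sum(r.females_examined for r in records)
        m_p = sum(r.males_infected for r in records) / m_n
        f_p = sum(r.females_infected for r in records) / f_n
    elif mode == "mean_of_studies":
        m_n = sum(r.males_examined for r in records)
        f_n = sum(r.females_examined for r in records)
        m_p = sum(r.males_infected / r.males_examined for r in records) / len(records)
        f_p = sum(r.females_infected / r.females_examined for r in records) / len(records)
    else:
        raise ValueError(f"unknown pooling mode {mode!r}")
    return (m_p, m_n), (f_p, f_n)


def build_derived_vars(
    traits: SpeciesTraits | None,
    prevalence: tuple[tuple[float, int], tuple[float, int]] | None = None,
    species: str | None = None,
) -> DerivedVars:
    """Assemble the transformed per-species variables for PGLS.

    Missing trait fields yield None in the corresponding derived variable
    rather than a hard error (listwise deletion happens per model later).
    """
    if traits is None and species is None:
        raise ValueError("need traits or an explicit species name")
    name = species if species is not None else traits.species

    logit_prev_m = logit_prev_f = None
    if prevalence is not None:
        (m_p, m_n), (f_p, f_n) = prevalence
        logit_prev_m = logit(m_p, m_n)
        logit_prev_f = logit(f_p, f_n)

    logit_mort_m = logit_mort_f = mort_bias = None
    log_mass_m = log_mass_f = ssd = None
    mating_bias = None
    male_pg = female_pg = None
    if traits is not None:
        if traits.male_mortality is not None:
            logit_mort_m = logit(traits.male_mortality)
        if traits.female_mortality is not None:
            logit_mort_f = logit(traits.female_mortality)
        if traits.male_mortality is not None and traits.female_mortality is not None:
            mort_bias = math.log(traits.male_mortality / traits.female_mortality)
        if traits.male_mass is not None:
            log_mass_m = math.log(traits.male_mass)
        if traits.female_mass is not None:
            log_mass_f = math.log(traits.female_mass)
        if traits.male_mass is not None and traits.female_mass is not None:
            ssd = math.log(traits.male_mass / traits.female_mass)
        if traits.male_polygamy is not None and traits.female_polygamy is not None:
            mating_bias = float(traits.male_polygamy - traits.female_polygamy)
        male_pg = traits.male_polygamy
        female_pg = traits.female_polygamy

    return DerivedVars(
        species=name,
        logit_prev_m=logit_prev_m,
        logit_prev_f=logit_prev_f,
        logit_mort_m=logit_mort_m,
        logit_mort_f=logit_mort_f,
        mort_bias=mort_bias,
        log_mass_m=log_mass_m,
        log_mass_f=log_mass_f,
        ssd=ssd,
        mating_bias=mating_bias,
        male_polygamy=male_pg,
        female_polygamy=female_pg,
    )
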