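"""Additive-null phene-interaction statistics and deep-carbon accounting.

Given replicated shoot-biomass measurements for a reference phenotype and
for phenotypes differing in one or more phene states, the additive null
model predicts the biomass of a phene combination as the reference plus the
sum of the single-phene deltas.  An observed response above / equal to /
below the expectation indicates a synergistic / additive / antagonistic
interaction, gated on a two-sided z comparison of the two means.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Iterable

import pandas as pd
from scipy import stats

from .errors import InvalidInputError, ParseError

REFERENCE_LABEL = "reference"


def _as_phene_set(label) -> frozenset:
    if isinstance(label, frozenset):
        return label
    if isinstance(label, (set, list, tuple)):
        return frozenset(label)
    label = str(label).strip()
    if label.lower() in ("", REFERENCE_LABEL):
        return frozenset()
    return frozenset(p.strip() for p in label.split("+") if p.strip())


@dataclass
class PhenotypeBiomassTable:
    """Phenotype × replicate shoot biomass (g).

    Built from a tidy frame with columns ``phenotype`` (label; single-phene
    labels are plain names, combinations joined with '+', the reference is
    ``'reference'``), ``replicate`` and ``biomass``.  Requires the reference
    phenotype and at least two replicates per phenotype.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in ("phenotype", "replicate", "biomass")
                   if c not in self.frame.columns]
        if missing:
            raise ParseError(f"biomass table missing column(s): {', '.join(missing)}")
        self.frame = self.frame.assign(
            _phenes=self.frame["phenotype"].map(_as_phene_set))
        counts = self.frame.groupby("_phenes", sort=False).size()
        if frozenset() not in counts.index:
            raise InvalidInputError("no reference phenotype in table")
        too_few = [k for k, n in counts.items() if n < 2]
        if too_few:
            raise InvalidInputError(
                "phenotypes need >= 2 replicates for variance estimation: "
                + ", ".join("+".join(sorted(k)) or REFERENCE_LABEL
                            for k in too_few))

    def stats_for(self, phenes) -> tuple:
        """(mean, variance, n) of biomass for a phenotype (by phene set)."""
        key = _as_phene_set(phenes)
        sel = self.frame.loc[self.frame["_phenes"] == key, "biomass"]
        if sel.empty:
            name = "+".join(sorted(key)) or REFERENCE_LABEL
            raise InvalidInputError(f"phenotype {name!r} not present in table")
        return float(sel.mean()), float(sel.var(ddof=1)), int(sel.size)

    def phenotypes(self):
        return sorted(self.frame["_phenes"].unique(), key=lambda s: (len(s), sorted(s)))


def expected_additive(table: PhenotypeBiomassTable, combo: Iterable[str],
                      n_population: int = 5) -> tuple:
    """Additive-null expectation (mean, SE) for a phene combination.

    expected = reference mean + Σ (single-phene mean − reference mean).
    The variance of the expectation sums the variances of all summands (the
    reference and each single-phene delta, each delta carrying the variance
    of both the single-phene phenotype and the reference); the standard
    error divides by the population size ``n_population``.
    """
    combo = _as_phene_set(combo)
    ref_mean, ref_var, _ = table.stats_for(frozenset())
    expected = ref_mean
    variance = ref_var
    for phene in sorted(combo):
        mean_i, var_i, _ = table.stats_for(frozenset({phene}))
        expected += mean_i - ref_mean
        variance += var_i + ref_var
    return expected, sqrt(variance / n_population)


def classify_interaction(actual_mean: float, expected_mean: float,
                         se_actual: float, se_expected: float,
                         alpha: float = 0.05) -> dict:
    """Interaction percent and label for an observed vs expected response.

    percent = 100·(actual − expected)/expected.  The label is synergistic
    (above) or antagonistic (below) only when the two-sided z comparison on
    the propagated standard errors is significant at ``alpha``; otherwise
    additive.
    """
    if expected_mean <= 0.0:
        raise InvalidInputError("expected response must be positive")
    if actual_mean <= 0.0:
        raise InvalidInputError("actual response must be positive")
    percent = 100.0 * (actual_mean - expected_mean) / expected_mean
    se = sqrt(se_actual ** 2 + se_expected ** 2)
    z = (actual_mean - expected_mean) / se if se > 0.0 else float("inf")
    p_value = 2.0 * stats.norm.sf(abs(z)) if se > 0.0 else 0.0
    if p_value >= alpha:
        label = "additive"
    elif percent > 0.0:
        label = "synergistic"
    else:
        label = "antagonistic"
    return {"percent": percent, "label": label, "z": z, "p_value": p_value}


def interaction_table(table: PhenotypeBiomassTable,
                      n_population: int = 5, alpha: float = 0.05
                      ) -> pd.DataFrame:
    """Expected/actual/percent/label for every multi-phene phenotype present."""
    rows = []
    for phenes in table.phenotypes():
        if len(phenes) < 2:
            continue
        actual_mean, actual_var, n = table.stats_for(phenes)
        expected, se_expected = expected_additive(table, phenes, n_population)
        res = classify_interaction(actual_mean, expected,
                                   sqrt(actual_var / n), se_expected, alpha)
        rows.append({
            "phenotype": "+".join(sorted(phenes)),
            "actual_mean": actual_mean,
            "expected_mean": expected,
            "se_expected": se_expected,
            "percent": res["percent"],
            "label": res["label"],
            "p_value": res["p_value"],
        })
    return pd.DataFrame(rows)


def carbon_per_hectare(delta_g_per_plant: float, density: float) -> tuple:
    """Per-hectare carbon (and CO2 equivalent) from a per-plant carbon gain.

    kg C ha⁻¹ = Δg·density·10⁴ m² ha⁻¹ / 10³ g kg⁻¹;
    kg CO2 ha⁻¹ applies the 44/12 molar-mass ratio.
    """
    if delta_g_per_plant < 0.0 or density <= 0.0:
        raise InvalidInputError("carbon gain must be >= 0 and density > 0")
    kg_c = delta_g_per_plant * density * 1.0e4 / 1.0e3
    return kg_c, kg_c * 44.0 / 12.0
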