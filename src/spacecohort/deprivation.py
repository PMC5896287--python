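"""Composite material-deprivation covariate.

The index is the per-area sum of cross-area z-scores of four census
proportions (unemployment, low education, tenancy, no bathroom), computed
separately at each census year.  Inter-census years are filled in by the
conditional expectation of a first-order random walk given the flanking
censuses (linear interpolation in time; martingale carry-forward/backward
outside the observed range), and the covariate meets cohort-level mortality
with a configurable lag, 10 years by default.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .car import ValidationError
from .lexis import CohortData

INDICATORS = ("p_unemployed", "p_low_edu", "p_tenant", "p_no_bath")


@dataclasses.dataclass(frozen=True)
class DeprivationPanel:
    """Per-area, per-census-year proportions of the four indicators (I, Y, 4)."""

    area_ids: tuple[str, ...]
    census_years: tuple[int, ...]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.area_ids), len(self.census_years), len(INDICATORS))
        if self.proportions.shape != shape:
            raise ValidationError(f"proportions must have shape {shape}")
        if np.any(self.proportions < 0) or np.any(self.proportions > 1):
            raise ValidationError("proportions must lie in [0, 1]")
        if list(self.census_years) != sorted(set(self.census_years)):
            raise ValidationError("census years must be strictly increasing")


@dataclasses.dataclass(frozen=True)
class DeprivationIndex:
    """Per-area, per-year index with an observed/imputed provenance flag."""

    area_ids: tuple[str, ...]
    years: tuple[int, ...]
    values: np.ndarray  # (I, len(years))
    observed: tuple[bool, ...]  # per year

    def at_year(self, year: int) -> np.ndarray:
        try:
            j = self.years.index(year)
        except ValueError:
            raise ValidationError(f"no index values for year {year}") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for j, yr in enumerate(self.years):
            prov = "observed-census" if self.observed[j] else "imputed"
            for i, aid in enumerate(self.area_ids):
                recs.append({"area_id": aid, "year": yr, "index": self.values[i, j], "provenance": prov})
        return pd.DataFrame(recs)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_deprivation_csv(path) -> DeprivationPanel:
    """Read a long CSV: area_id, census_year, p_unemployed, p_low_edu, p_tenant, p_no_bath."""
    df = pd.read_csv(path, dtype={"area_id": str})
    missing = [c for c in ("area_id", "census_year", *INDICATORS) if c not in df.columns]
    if missing:
        raise ValidationError(f"deprivation CSV missing columns: {missing}")
    areas = tuple(dict.fromkeys(df["area_id"]))
    years = tuple(sorted(df["census_year"].unique()))
    props = np.full((len(areas), len(years), len(INDICATORS)), np.nan)
    ai = {a: i for i, a in enumerate(areas)}
    yi = {y: j for j, y in enumerate(years)}
    for rec in df.itertuples(index=False):
        props[ai[rec.area_id], yi[rec.census_year]] = [getattr(rec, k) for k in INDICATORS]
    if np.isnan(props).any():
        raise ValidationError("every area must be present at every census year")
    return DeprivationPanel(areas, tuple(int(y) for y in years), props)


def compute_deprivation_index(panel: DeprivationPanel) -> DeprivationIndex:
    """Sum of cross-area z-scores of the four indicators, per census year.

    Standardisation is unweighted across areas (population standard
    deviation); by construction the cross-area mean of the index is zero at
    every census year.
    """
    if len(panel.area_ids) < 2:
        raise ValidationError("z-scores need at least 2 areas")
    vals = np.zeros((len(panel.area_ids), len(panel.census_years)))
    for j, year in enumerate(panel.census_years):
        block = panel.proportions[:, j, :]
        mean = block.mean(axis=0)
        sd = block.std(axis=0)
        zero = np.flatnonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(mean)))
        if zero.size:
            raise ValidationError(
                f"indicator {INDICATORS[zero[0]]!r} has zero cross-area variance in {year}"
            )
        vals[:, j] = ((block - mean) / sd).sum(axis=1)
    return DeprivationIndex(
        area_ids=panel.area_ids,
        years=panel.census_years,
        values=vals,
        observed=tuple(True for _ in panel.census_years),
    )


def impute_rw1(index: DeprivationIndex, target_years: Sequence[int]) -> DeprivationIndex:
    """Fill target years with the RW1 (Gaussian-bridge) conditional expectation.

    Interior targets get the linear-in-time interpolation of the flanking
    observed values — the conditional mean of a random-walk bridge, which at a
    midpoint year is just the average of the two adjacent censuses.  Targets
    outside the observed range get the nearest observed value (the martingale
    prediction).  Already-observed years pass through unchanged.
    """
    obs_years = [y for y, o in zip(index.years, index.observed) if o]
    if not obs_years:
        raise ValidationError("no observed years to impute from")
    obs = np.array(obs_years, dtype=float)
    obs_vals = np.column_stack([index.at_year(int(y)) for y in obs_years])

    years: list[int] = list(index.years)
    values = [index.values[:, j] for j in range(len(index.years))]
    flags = list(index.observed)
    for ty in target_years:
        ty = int(ty)
        if ty in index.years:
            continue
        # np.interp is exactly the RW1 bridge mean inside, nearest value outside
        v = np.array([np.interp(ty, obs, obs_vals[i]) for i in range(obs_vals.shape[0])])
        years.append(ty)
        values.append(v)
        flags.append(False)

    order = np.argsort(years)
    return DeprivationIndex(
        area_ids=index.area_ids,
        years=tuple(int(years[k]) for k in order),
        values=np.column_stack([values[k] for k in order]),
        observed=tuple(flags[k] for k in order),
    )


def lag_covariate(
    index: DeprivationIndex, cohort_data: CohortData, lag_years: int = 10
) -> CohortData:
    """Attach the lagged deprivation index as the model covariate x_it.

    Each cohort's reference calendar year (person-year-weighted centre of its
    cells, carried on ``cohort_data``) is shifted back by ``lag_years`` and
    snapped to the nearest available index year; the resulting x is centred
    across all (area, cohort) cells.
    """
    if cohort_data.cohort_ref_years is None:
        raise ValidationError("cohort_data lacks cohort reference years")
    if set(cohort_data.area_ids) - set(index.area_ids):
        missing = sorted(set(cohort_data.area_ids) - set(index.area_ids))
        raise ValidationError(f"areas missing from the deprivation index: {missing}")

    avail = np.array(index.years, dtype=float)
    area_pos = [index.area_ids.index(a) for a in cohort_data.area_ids]
    I, T = cohort_data.shape
    x = np.zeros((I, T))
    missing_years: list[int] = []
    for t, ref in enumerate(cohort_data.cohort_ref_years):
        if not np.isfinite(ref):
            raise ValidationError(f"cohort {cohort_data.cohort_labels[t]!r} has no reference year")
        want = ref - lag_years
        j = int(np.argmin(np.abs(avail - want)))
        # snapping tolerance: half the index grid spacing
        spacing = float(np.diff(avail).min()) if avail.size > 1 else 0.0
        if abs(avail[j] - want) > max(spacing / 2.0, 0.5):
            missing_years.append(int(round(want)))
            continue
        x[:, t] = index.values[area_pos, j]
    if missing_years:
        raise ValidationError(f"index years needed but unavailable: {sorted(set(missing_years))}")
    x = x - x.mean()
    return dataclasses.replace(cohort_data, x=x)
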