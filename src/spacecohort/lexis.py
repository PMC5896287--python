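"""Lexis grids, birth-cohort aggregation, and age-cohort expected counts.

Area-level deaths and person-years come cross-classified by age-class and
calendar period (a Lexis grid).  Birth-cohorts run along the diagonals of
that grid; each (age, period) cell is assigned to one 10-year cohort on a
5-year step.  Expected counts are the denominators of the relative risks:
person-years times age-specific reference rates predicted by a two-factor
age-cohort Poisson model fitted on the region-wide totals, with the cohort
effects deliberately excluded so that the expectation is adjusted by age but
carries no cohort signal.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .car import ValidationError


# ---------------------------------------------------------------------------
# Lexis grid data model
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class LexisGrid:
    """Rectangular area × age-class × period grid of deaths and person-years.

    ``age_classes`` are [lower, upper) bands in years (``upper=None`` marks an
    open-ended top band); ``periods`` are [start, end] calendar intervals.
    ``deaths`` and ``person_years`` have shape (I, A, P).
    """

    area_ids: tuple[str, ...]
    age_classes: tuple[tuple[int, int | None], ...]
    periods: tuple[tuple[int, int], ...]
    deaths: np.ndarray
    person_years: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.area_ids), len(self.age_classes), len(self.periods))
        if self.deaths.shape != shape or self.person_years.shape != shape:
            raise ValidationError(f"deaths/person_years must have shape {shape}")
        if np.any(self.deaths < 0) or np.any(self.person_years < 0):
            raise ValidationError("negative deaths or person-years")
        if np.any((self.person_years == 0) & (self.deaths > 0)):
            raise ValidationError("deaths recorded in cells with zero person-years")
        lowers = [a[0] for a in self.age_classes]
        if lowers != sorted(lowers) or len(set(lowers)) != len(lowers):
            raise ValidationError("age classes must be strictly increasing")
        for (lo, hi), (lo2, _) in zip(self.age_classes, self.age_classes[1:]):
            if hi is None or hi > lo2:
                raise ValidationError("age classes overlap (open band must be last)")

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def regional(self) -> "LexisGrid":
        """Collapse all areas into a single region-wide grid."""
        return LexisGrid(
            area_ids=("region",),
            age_classes=self.age_classes,
            periods=self.periods,
            deaths=self.deaths.sum(axis=0, keepdims=True),
            person_years=self.person_years.sum(axis=0, keepdims=True),
        )


def _floor5(x: int) -> int:
    return (x // 5) * 5


def cohort_label(lower: int) -> str:
    """Label for the 10-year cohort starting at ``lower``: 1905 -> '1905-15'."""
    return f"{lower}-{str(lower + 10)[2:]}"


def assign_cohorts(grid: LexisGrid) -> dict[tuple[int, int], str]:
    """Map every (age index, period index) cell to its birth-cohort label.

    Cohorts are 10-year intervals on a 5-year step.  A cell with age band
    [lo, hi) and period starting at ``p`` covers births in roughly
    [p - hi, p - lo); snapping both bounds down to the 5-year grid yields the
    10-year label.  Cells on the same diagonal share a label.
    """
    mapping: dict[tuple[int, int], str] = {}
    for ai, (lo, hi) in enumerate(grid.age_classes):
        eff_hi = lo + 5 if hi is None else hi
        for pi, (pstart, _) in enumerate(grid.periods):
            c_lo = _floor5(pstart - eff_hi)
            mapping[(ai, pi)] = cohort_label(c_lo)
    return mapping


# ---------------------------------------------------------------------------
# Age-cohort reference model
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class AgeCohortFit:
    """Two-factor Poisson age-cohort fit on regional totals.

    Log rates decompose as ``intercept + age_effect[a] + cohort_effect[c]``
    with the first age-class and the reference cohort pinned at zero.  The
    age-specific reference rates ``exp(intercept + age_effect[a])`` are the
    rates of the reference cohort and the basis of the expected counts.
    """

    age_classes: tuple[tuple[int, int | None], ...]
    cohorts: tuple[str, ...]
    reference_cohort: str
    intercept: float
    age_effects: np.ndarray
    cohort_effects: np.ndarray
    fitted_deaths_total: float
    observed_deaths_total: float

    @property
    def reference_rates(self) -> np.ndarray:
        """Fitted age-specific rates at the reference cohort (per person-year)."""
        return np.exp(self.intercept + self.age_effects)

    def rate(self, age_index: int, cohort: str) -> float:
        ci = self.cohorts.index(cohort)
        return float(np.exp(self.intercept + self.age_effects[age_index] + self.cohort_effects[ci]))


def _cohort_sort_key(label: str) -> int:
    return int(label.split("-")[0])


def fit_age_cohort_reference(
    grid: LexisGrid, reference_cohort: str | None = None
) -> AgeCohortFit:
    """Fit the age-cohort Poisson reference model on region-wide totals.

    Maximum likelihood for ``log rate(a, c) = mu + age_a + cohort_c`` with a
    log person-years offset, via iteratively reweighted least squares.  The
    reference cohort (default: the cohort with the highest crude rate, the
    epidemic peak) has its effect fixed at zero.  Age classes with no
    person-years anywhere are dropped with a warning.
    """
    import statsmodels.api as sm

    reg = grid.regional()
    mapping = assign_cohorts(reg)
    rows = []
    for (ai, pi), coh in mapping.items():
        py = reg.person_years[0, ai, pi]
        if py > 0:
            rows.append((ai, coh, reg.deaths[0, ai, pi], py))
    if not rows:
        raise ValidationError("no cells with person-years to fit on")
    df = pd.DataFrame(rows, columns=["age", "cohort", "deaths", "py"])

    present_ages = sorted(df["age"].unique())
    if len(present_ages) < len(grid.age_classes):
        warnings.warn("age classes without person-years dropped from the reference fit")
    cohorts = tuple(sorted(df["cohort"].unique(), key=_cohort_sort_key))
    if reference_cohort is not None and reference_cohort not in cohorts:
        raise ValidationError(f"reference cohort {reference_cohort!r} not present in the grid")

    # fit against an arbitrary baseline cohort; the reference is fixed
    # afterwards by an exact shift reparameterisation
    baseline = cohorts[0]
    n = len(df)
    age_levels = present_ages
    x_cols = [np.ones(n)]
    for a in age_levels[1:]:
        x_cols.append((df["age"] == a).to_numpy(float))
    for c in cohorts:
        if c != baseline:
            x_cols.append((df["cohort"] == c).to_numpy(float))
    design = np.column_stack(x_cols)

    model = sm.GLM(
        df["deaths"].to_numpy(float),
        design,
        family=sm.families.Poisson(),
        offset=np.log(df["py"].to_numpy(float)),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer endog is fine for a rate model
        res = model.fit(tol=1e-10, maxiter=300)
    if not res.converged:
        raise RuntimeError(f"age-cohort IRLS did not converge: {res.mle_retvals}")

    params = res.params
    intercept = float(params[0])
    age_eff = np.zeros(len(grid.age_classes))
    for k, a in enumerate(age_levels[1:], start=1):
        age_eff[a] = params[k]
    coh_eff = np.zeros(len(cohorts))
    pos = len(age_levels)
    for c in cohorts:
        if c != baseline:
            coh_eff[cohorts.index(c)] = params[pos]
            pos += 1

    # identify against the reference cohort: the epidemic peak (maximum
    # fitted cohort effect) unless one was requested explicitly
    if reference_cohort is None:
        reference_cohort = cohorts[int(np.argmax(coh_eff))]
    shift = coh_eff[cohorts.index(reference_cohort)]
    coh_eff = coh_eff - shift
    intercept += float(shift)

    return AgeCohortFit(
        age_classes=grid.age_classes,
        cohorts=cohorts,
        reference_cohort=reference_cohort,
        intercept=intercept,
        age_effects=age_eff,
        cohort_effects=coh_eff,
        fitted_deaths_total=float(res.fittedvalues.sum()),
        observed_deaths_total=float(df["deaths"].sum()),
    )


# ---------------------------------------------------------------------------
# Cohort-level model table
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CohortData:
    """Area × cohort table the mortality models are fitted on.

    ``y`` observed deaths, ``E`` expected deaths (positive), ``x`` covariate
    (may be None before the deprivation merge); ``cohort_ref_years`` is the
    person-year-weighted central calendar year of each cohort's cells, used to
    align a time-varying covariate.
    """

    area_ids: tuple[str, ...]
    cohort_labels: tuple[str, ...]
    y: np.ndarray
    E: np.ndarray
    x: np.ndarray | None = None
    cohort_ref_years: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = (len(self.area_ids), len(self.cohort_labels))
        for name in ("y", "E", "x"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != shape:
                raise ValidationError(f"{name} must have shape {shape}")
        if np.any(self.E <= 0):
            raise ValidationError("expected counts must be positive for every modeled cell")

    @property
    def shape(self) -> tuple[int, int]:
        return self.y.shape

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, aid in enumerate(self.area_ids):
            for t, coh in enumerate(self.cohort_labels):
                recs.append(
                    {
                        "area_id": aid,
                        "cohort_label": coh,
                        "y": self.y[i, t],
                        "E": self.E[i, t],
                        "x": np.nan if self.x is None else self.x[i, t],
                    }
                )
        return pd.DataFrame(recs)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_cohort_csv(path) -> CohortData:
    df = pd.read_csv(path, dtype={"area_id": str, "cohort_label": str})
    areas = tuple(dict.fromkeys(df["area_id"]))
    cohorts = tuple(sorted(df["cohort_label"].unique(), key=_cohort_sort_key))
    shape = (len(areas), len(cohorts))
    y = np.zeros(shape)
    E = np.zeros(shape)
    x = np.zeros(shape)
    has_x = "x" in df.columns and df["x"].notna().all()
    ai = {a: i for i, a in enumerate(areas)}
    ci = {c: t for t, c in enumerate(cohorts)}
    for rec in df.itertuples(index=False):
        i, t = ai[rec.area_id], ci[rec.cohort_label]
        y[i, t], E[i, t] = rec.y, rec.E
        if has_x:
            x[i, t] = rec.x
    return CohortData(areas, cohorts, y, E, x if has_x else None)


def compute_expected(
    grid: LexisGrid,
    fit: AgeCohortFit,
    retain: int | Sequence[str] | None = 6,
) -> CohortData:
    """Aggregate observed and expected cases along the cohort diagonals.

    Per cell, expected = person-years × age-specific reference rate (cohort
    effects excluded); cells are then summed into (area, cohort) totals.
    ``retain`` keeps either the given cohort labels or, for an integer n, the
    n cohorts with the largest regional person-years (the best-observed
    diagonals).  Areas with no person-years in any retained cell are excluded.
    """
    mapping = assign_cohorts(grid)
    ref_rates = fit.reference_rates
    cohorts_all = sorted({c for c in mapping.values()}, key=_cohort_sort_key)

    py_by_cohort = {c: 0.0 for c in cohorts_all}
    for (ai, pi), coh in mapping.items():
        py_by_cohort[coh] += float(grid.person_years[:, ai, pi].sum())

    if retain is None:
        kept = cohorts_all
    elif isinstance(retain, int):
        kept = sorted(
            sorted(cohorts_all, key=lambda c: -py_by_cohort[c])[:retain],
            key=_cohort_sort_key,
        )
    else:
        missing = [c for c in retain if c not in cohorts_all]
        if missing:
            raise ValidationError(f"requested cohorts not present in the grid: {missing}")
        kept = sorted(retain, key=_cohort_sort_key)

    ci = {c: t for t, c in enumerate(kept)}
    I, T = grid.n_areas, len(kept)
    y = np.zeros((I, T))
    E = np.zeros((I, T))
    wsum_year = np.zeros(T)
    wsum = np.zeros(T)
    for (ai, pi), coh in mapping.items():
        t = ci.get(coh)
        if t is None:
            continue
        py = grid.person_years[:, ai, pi]
        y[:, t] += grid.deaths[:, ai, pi]
        E[:, t] += py * ref_rates[ai]
        pstart, pend = grid.periods[pi]
        mid = 0.5 * (pstart + pend)
        w = float(py.sum())
        wsum_year[t] += w * mid
        wsum[t] += w

    keep_areas = E.sum(axis=1) > 0
    if not keep_areas.all():
        dropped = [grid.area_ids[i] for i in np.flatnonzero(~keep_areas)]
        warnings.warn(f"areas with no person-years in retained cohorts excluded: {dropped}")
    ref_years = np.where(wsum > 0, wsum_year / np.maximum(wsum, 1e-300), np.nan)

    return CohortData(
        area_ids=tuple(np.array(grid.area_ids)[keep_areas]),
        cohort_labels=tuple(kept),
        y=y[keep_areas],
        E=E[keep_areas],
        cohort_ref_years=ref_years,
    )


# ---------------------------------------------------------------------------
# Long-format CSV interface
# ---------------------------------------------------------------------------

_LEXIS_COLS = ["area_id", "age_lower", "age_upper", "period_start", "period_end", "deaths", "person_years"]


def read_lexis_csv(path) -> LexisGrid:
    """Read a long-format Lexis CSV (columns: area_id, age_lower, age_upper,
    period_start, period_end, deaths, person_years); blank age_upper marks the
    open-ended top band."""
    df = pd.read_csv(path, dtype={"area_id": str})
    missing = [c for c in _LEXIS_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"lexis CSV missing columns: {missing}")
    areas = tuple(dict.fromkeys(df["area_id"]))
    ages = sorted(
        {(int(lo), None if pd.isna(hi) else int(hi)) for lo, hi in zip(df["age_lower"], df["age_upper"])}
    )
    periods = sorted({(int(s), int(e)) for s, e in zip(df["period_start"], df["period_end"])})
    shape = (len(areas), len(ages), len(periods))
    deaths = np.zeros(shape)
    py = np.zeros(shape)
    a_ix = {a: i for i, a in enumerate(areas)}
    g_ix = {g: i for i, g in enumerate(ages)}
    p_ix = {p: i for i, p in enumerate(periods)}
    for rec in df.itertuples(index=False):
        hi = None if pd.isna(rec.age_upper) else int(rec.age_upper)
        key = (a_ix[rec.area_id], g_ix[(int(rec.age_lower), hi)], p_ix[(int(rec.period_start), int(rec.period_end))])
        deaths[key] = rec.deaths
        py[key] = rec.person_years
    return LexisGrid(areas, tuple(ages), tuple(periods), deaths, py)


def write_lexis_csv(grid: LexisGrid, path) -> None:
    recs = []
    for i, aid in enumerate(grid.area_ids):
        for ai, (lo, hi) in enumerate(grid.age_classes):
            for pi, (ps, pe) in enumerate(grid.periods):
                recs.append((aid, lo, "" if hi is None else hi, ps, pe,
                             grid.deaths[i, ai, pi], grid.person_years[i, ai, pi]))
    pd.DataFrame(recs, columns=_LEXIS_COLS).to_csv(path, index=False)
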