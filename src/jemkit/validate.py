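"""Assign JEM exposures to cohort members and compute validity statistics.

Three families of statistics are supported, mirroring standard JEM
validation practice:

* **Agreement** — Cohen's kappa between paired binary exposure assignments,
  interpreted as poor (<0.20), fair (0.21-0.40), moderate (0.41-0.60),
  good (0.61-0.80) and excellent (0.81-1).
* **Discrimination** — the area under the ROC curve (pairwise concordance
  probability, ties counted 1/2), interpreted as failed (0.50-0.59),
  poor (0.60-0.69), fair (0.70-0.79), good (0.80-0.89), excellent (0.90-1).
* **Predictive validity** — age-adjusted odds ratios from a logistic
  regression of a binary pain outcome on binary JEM exposure, with Wald 95%
  confidence intervals, stratified by gender (all analyses run separately
  for men and women).

The printed interpretation scales leave the gaps (0.20, 0.21) etc.
unaddressed; values are rounded half-up to 2 decimals before banding, with
half-open bands at 0.205 / 0.405 / 0.605 / 0.805 (kappa) and 0.595 / 0.695 /
0.795 / 0.895 (AUC) — this reproduces every printed labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .errors import DataError, DegenerateStatisticError, LoadError
from .model import (
    DEFAULT_SCHEME,
    GENDERS,
    CategoryScheme,
    JEM,
    dichotomize,
)

COHORT_BASE_COLUMNS = ["person_id", "occupation_code", "gender", "age"]

DEFAULT_AGE_WINDOW = (25.0, 60.0)

KAPPA_BANDS = ((0.205, "poor"), (0.405, "fair"), (0.605, "moderate"),
               (0.805, "good"), (np.inf, "excellent"))
AUC_BANDS = ((0.595, "failed"), (0.695, "poor"), (0.795, "fair"),
             (0.895, "good"), (np.inf, "excellent"))


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------


def read_cohort(path: str | Path,
                age_window: tuple[float, float] = DEFAULT_AGE_WINDOW) -> pd.DataFrame:
    """Read cohort microdata; enforce the working-age window (default 25-60)."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        sep = "\t" if "\t" in fh.readline() else ","
    df = pd.read_csv(path, sep=sep, dtype={"occupation_code": str,
                                           "person_id": str})
    missing = [c for c in COHORT_BASE_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required columns {missing}")
    bad = ~df["gender"].isin(GENDERS)
    if bad.any():
        raise LoadError(
            f"{path}: {int(bad.sum())} record(s) with missing/invalid gender"
        )
    lo, hi = age_window
    out_of_window = (df["age"] < lo) | (df["age"] > hi)
    if out_of_window.any():
        raise LoadError(
            f"{path}: {int(out_of_window.sum())} record(s) outside the "
            f"{lo:g}-{hi:g} working-age window"
        )
    return df


def write_cohort(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write cohort microdata; internal `true_*` columns are not exported."""
    cols = [c for c in df.columns if not c.startswith("true_")]
    df[cols].to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# exposure assignment
# ---------------------------------------------------------------------------


@dataclass
class AssignmentResult:
    """Per-person exposure assignment plus the unmatched-code report."""

    frame: pd.DataFrame  # person_id, occupation_code, gender, category, exposed
    exposure_id: str
    n_assigned: int
    n_unmatched: int
    unmatched_codes: dict[str, int] = field(default_factory=dict)


def assign_exposure(
    cohort: pd.DataFrame,
    jem: JEM,
    exposure_id: str,
    exposed_cut: int = 2,
    scheme: CategoryScheme = DEFAULT_SCHEME,
) -> AssignmentResult:
    """Look up each individual's (occupation, gender) in the matrix.

    Unmatched individuals are marked missing and counted, never silently
    dropped; if *everyone* is unmatched the warning escalates to an error.
    """
    if exposed_cut != scheme.exposed_cut:
        scheme = CategoryScheme(scheme.band_upper_edges, exposed_cut)
    if len(cohort) == 0:
        raise DataError("empty cohort")
    lookup: dict[tuple[str, str], tuple[int, bool]] = {}
    for cell in jem:
        if cell.exposure_id != exposure_id:
            continue
        lookup[(cell.occupation.code, cell.gender)] = (
            cell.effective_category(), dichotomize(cell, scheme))
    categories, exposed = [], []
    unmatched: dict[str, int] = {}
    for code, gender in zip(cohort["occupation_code"].astype(str),
                            cohort["gender"]):
        hit = lookup.get((code, gender))
        if hit is None:
            unmatched[code] = unmatched.get(code, 0) + 1
            categories.append(np.nan)
            exposed.append(np.nan)
        else:
            categories.append(hit[0])
            exposed.append(float(hit[1]))
    frame = cohort.copy()
    frame["category"] = categories
    frame["exposed"] = exposed
    n_unmatched = sum(unmatched.values())
    if n_unmatched == len(cohort):
        raise DataError(
            f"no cohort member matched the matrix for {exposure_id!r} "
            f"(all {n_unmatched} unmatched)"
        )
    return AssignmentResult(frame, exposure_id, len(cohort) - n_unmatched,
                            n_unmatched, unmatched)


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------


def cohen_kappa(x: Sequence[int], y: Sequence[int]) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) on paired binaries.

    p_e is the sum of marginal products. Symmetric in its arguments.

    Raises
    ------
    DegenerateStatisticError
        When p_e = 1 (both vectors constant and equal), where kappa is
        undefined.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise DataError("kappa needs two paired 1-d vectors of length >= 2")
    if np.isnan(x.astype(float)).any() or np.isnan(y.astype(float)).any():
        raise DataError("kappa input contains missing values")
    n = x.size
    levels = np.union1d(np.unique(x), np.unique(y))
    p_o = float(np.mean(x == y))
    p_e = 0.0
    for lev in levels:
        p_e += float(np.mean(x == lev)) * float(np.mean(y == lev))
    if p_e >= 1.0 - 1e-15:
        raise DegenerateStatisticError(
            "kappa undefined: expected agreement p_e = 1 "
            "(both vectors constant and equal)"
        )
    return (p_o - p_e) / (1.0 - p_e)


def _round2_half_up(v: float) -> float:
    return np.floor(v * 100 + 0.5) / 100.0


def interpret_kappa(kappa: float) -> str:
    """Band a kappa value on the poor/fair/moderate/good/excellent scale."""
    if kappa > 1.0 + 1e-12:
        raise DataError(f"kappa {kappa} exceeds 1")
    k = _round2_half_up(float(kappa))
    for edge, label in KAPPA_BANDS:
        if k < edge:
            return label
    raise AssertionError("unreachable")


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Pairwise concordance probability (ties counted 1/2).

    ``scores`` may be ordinal matrix categories or binary assignments;
    ``labels`` is the binary reference classification and must contain both
    classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DataError("auc needs paired 1-d score and label vectors")
    if np.unique(labels).size < 2:
        raise DataError("auc undefined: labels contain a single class")
    return float(roc_auc_score(labels, scores))


def interpret_auc(value: float) -> str:
    """Band an AUC on the failed/poor/fair/good/excellent scale."""
    if not 0.0 <= value <= 1.0 + 1e-12:
        raise DataError(f"AUC {value} outside [0, 1]")
    v = _round2_half_up(float(value))
    for edge, label in AUC_BANDS:
        if v < edge:
            return label
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# predictive validity: age-adjusted logistic odds ratios
# ---------------------------------------------------------------------------


@dataclass
class ORResult:
    """Odds ratio with a Wald 95% CI from a logistic fit.

    ``converged`` is False on separation or non-convergence, in which case
    the estimates are NaN — a flagged result, never a silent one.
    """

    oddsratio: float
    ci_low: float
    ci_high: float
    n: int
    converged: bool = True
    note: str = ""

    @property
    def estimates_valid(self) -> bool:
        return self.converged and np.isfinite(self.oddsratio)


def logistic_or(
    outcome: Sequence[int],
    exposure: Sequence[int],
    age: Sequence[float] | None = None,
    age_bands: Sequence[float] | None = None,
) -> ORResult:
    """Odds ratio for a binary exposure, optionally adjusted for age.

    Fits outcome ~ intercept + exposure (+ age) by maximum likelihood
    (Newton-Raphson, relative log-likelihood tolerance 1e-8, max 50
    iterations); the OR is the exponentiated exposure coefficient and the CI
    a Wald interval exponentiated from the log scale. Age enters as a
    continuous linear term by default; pass ``age_bands`` (cut points) to
    use categorical age bands instead.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise DataError("outcome and exposure must be paired 1-d vectors")
    cols = [np.ones_like(x), x]
    names = ["const", "exposure"]
    if age is not None:
        a = np.asarray(age, dtype=float)
        if a.shape != y.shape:
            raise DataError("age vector length mismatch")
        if age_bands is not None:
            codes = np.digitize(a, np.asarray(age_bands, dtype=float))
            for lev in np.unique(codes)[1:]:
                cols.append((codes == lev).astype(float))
                names.append(f"age_band_{lev}")
        else:
            cols.append(a)
            names.append("age")
    X = np.column_stack(cols)
    n = y.size
    if n < 10 * X.shape[1]:
        raise DataError(f"n={n} too small for {X.shape[1]} design columns")
    if np.unique(x).size < 2:
        raise DataError("exposure has a single class")
    if np.unique(y).size < 2:
        raise DataError("outcome has a single class")
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(method="newton", maxiter=50, tol=1e-8,
                                     disp=0, warn_convergence=False)
        converged = bool(fit.mle_retvals.get("converged", False))
        beta = fit.params[1]
        se = fit.bse[1]
    except Exception as exc:  # separation / singular design
        return ORResult(np.nan, np.nan, np.nan, n, converged=False,
                        note=f"fit failed: {exc}")
    if not converged or not np.isfinite(beta) or not np.isfinite(se) or se > 1e3:
        return ORResult(np.nan, np.nan, np.nan, n, converged=False,
                        note="non-convergence or quasi-separation")
    from scipy.stats import norm

    z = norm.ppf(0.975)
    return ORResult(float(np.exp(beta)), float(np.exp(beta - z * se)),
                    float(np.exp(beta + z * se)), n)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


@dataclass
class ValidationResult:
    """One agreement or predictive-validity estimate with stratum labels."""

    statistic: str  # kappa | auc | or
    value: float
    ci_low: float | None
    ci_high: float | None
    band_label: str | None
    cohort_id: str
    gender: str
    exposure_id: str
    outcome_id: str | None
    n: int
    flag: str = ""


def validity_report(
    cohort: pd.DataFrame,
    jem: JEM,
    pairs: Iterable[tuple[str, str]],
    cohort_id: str = "cohort",
    exposed_cut: int = 2,
    age_adjusted: bool = True,
) -> pd.DataFrame:
    """Age-adjusted OR per (gender, exposure, outcome) pair.

    One row per stratum, computed on gender-stratified subsets. Strata where
    the fit is degenerate (single class, separation, too few observations)
    are flagged in the output, never dropped silently.
    """
    pairs = list(pairs)
    known_exposures = set(jem.exposure_ids())
    outcome_cols = set(cohort.columns) - set(COHORT_BASE_COLUMNS)
    results: list[ValidationResult] = []
    for exposure_id, outcome_id in pairs:
        if exposure_id not in known_exposures:
            raise DataError(f"unknown exposure {exposure_id!r}")
        if outcome_id not in outcome_cols:
            raise DataError(f"unknown outcome {outcome_id!r}")
        assignment = assign_exposure(cohort, jem, exposure_id, exposed_cut)
        for gender in GENDERS:
            sub = assignment.frame
            sub = sub[(sub["gender"] == gender) & sub["exposed"].notna()
                      & sub[outcome_id].notna()]
            base = dict(statistic="or", cohort_id=cohort_id, gender=gender,
                        exposure_id=exposure_id, outcome_id=outcome_id)
            if len(sub) == 0:
                results.append(ValidationResult(
                    value=np.nan, ci_low=None, ci_high=None, band_label=None,
                    n=0, flag="empty stratum", **base))
                continue
            try:
                fit = logistic_or(sub[outcome_id].astype(int),
                                  sub["exposed"].astype(int),
                                  sub["age"] if age_adjusted else None)
            except DataError as exc:
                results.append(ValidationResult(
                    value=np.nan, ci_low=None, ci_high=None, band_label=None,
                    n=len(sub), flag=str(exc), **base))
                continue
            results.append(ValidationResult(
                value=fit.oddsratio, ci_low=fit.ci_low, ci_high=fit.ci_high,
                band_label=None, n=fit.n,
                flag="" if fit.estimates_valid else (fit.note or "flagged"),
                **base))
    return pd.DataFrame([r.__dict__ for r in results])


def agreement_report(
    population: pd.DataFrame,
    jem_a: JEM,
    jem_b: JEM,
    exposure_ids: Iterable[str],
    exposed_cut: int = 2,
    score_scale: str = "ordinal",
) -> pd.DataFrame:
    """Kappa + AUC + exposed proportions per exposure and gender.

    AUC is directional (scores from one matrix against binary labels from
    the other); both orientations are reported since neither matrix is a
    gold standard. ``score_scale`` selects ordinal categories or binary
    assignments as scores — both are defensible and labelled in the output.
    """
    if score_scale not in ("ordinal", "binary"):
        raise DataError(f"score_scale must be ordinal|binary, got {score_scale!r}")
    rows = []
    for exposure_id in exposure_ids:
        for gender in GENDERS:
            pop = population[population["gender"] == gender]
            if pop.empty:
                continue
            a = assign_exposure(pop, jem_a, exposure_id, exposed_cut)
            b = assign_exposure(pop, jem_b, exposure_id, exposed_cut)
            both = a.frame["exposed"].notna() & b.frame["exposed"].notna()
            if not both.any():
                rows.append({"exposure_id": exposure_id, "gender": gender,
                             "flag": "no joint assignments"})
                continue
            xa = a.frame.loc[both, "exposed"].astype(int).to_numpy()
            xb = b.frame.loc[both, "exposed"].astype(int).to_numpy()
            score_col = "category" if score_scale == "ordinal" else "exposed"
            sa = a.frame.loc[both, score_col].astype(float).to_numpy()
            sb = b.frame.loc[both, score_col].astype(float).to_numpy()
            row = {"exposure_id": exposure_id, "gender": gender,
                   "n": int(both.sum()),
                   "pct_exposed_a": 100.0 * float(xa.mean()),
                   "pct_exposed_b": 100.0 * float(xb.mean()),
                   "score_scale": score_scale, "flag": ""}
            try:
                k = cohen_kappa(xa, xb)
                row["kappa"] = k
                row["kappa_band"] = interpret_kappa(k)
            except DegenerateStatisticError:
                row["kappa"] = np.nan
                row["flag"] = "degenerate kappa"
            for label, scores, labels in (("auc_a_vs_b", sa, xb),
                                          ("auc_b_vs_a", sb, xa)):
                try:
                    v = auc(scores, labels)
                    row[label] = v
                    row[label + "_band"] = interpret_auc(v)
                except DataError:
                    row[label] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
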