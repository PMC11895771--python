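"""Construct a gender-specific JEM from survey microdata.

This is the step each national matrix performs upstream of harmonization:
within every (occupation, gender) cell, the prevalence of an exposure is the
share of respondents reporting it. Optionally, only asymptomatic respondents
contribute — symptomatic workers tend to over-report physical exposures, so
some matrices exclude them from both numerator and denominator.

Survey file format (delimited text, header):
    respondent_id, occupation_code, gender, symptomatic, <exposure_id>...
with one 0/1 column per exposure. Rows missing an answer for one exposure
are dropped for that exposure's cell only.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError, LoadError
from .model import (
    DEFAULT_SCHEME,
    GENDERS,
    CategoryScheme,
    ExposureDefinition,
    JEM,
    JEMCell,
    OccupationCode,
    categorize,
    dichotomize,
)

SURVEY_BASE_COLUMNS = ["respondent_id", "occupation_code", "gender"]


def read_survey(path: str | Path) -> pd.DataFrame:
    """Read survey microdata, rejecting rows with missing gender (counted)."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        sep = "\t" if "\t" in fh.readline() else ","
    df = pd.read_csv(path, sep=sep, dtype={"occupation_code": str,
                                           "respondent_id": str})
    missing = [c for c in SURVEY_BASE_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required columns {missing}")
    bad = ~df["gender"].isin(GENDERS)
    if bad.any():
        raise LoadError(
            f"{path}: {int(bad.sum())} record(s) with missing/invalid gender rejected",
            [f"row {i + 2}: gender {g!r}" for i, g in
             df.loc[bad, "gender"].items()],
        )
    if df["respondent_id"].duplicated().any():
        dups = df.loc[df["respondent_id"].duplicated(), "respondent_id"].tolist()
        raise LoadError(f"{path}: duplicate respondent_id(s) {dups[:5]}")
    return df


def build_jem(
    records: pd.DataFrame,
    registry: Iterable[ExposureDefinition],
    coding_system: str,
    jem_id: str = "survey_jem",
    asymptomatic_only: bool = False,
    min_n: int = 10,
    scheme: CategoryScheme = DEFAULT_SCHEME,
) -> JEM:
    """Aggregate survey records into a gender-specific JEM.

    For each (occupation, gender, exposure): prevalence_pct = 100 x
    (# exposed) / (# respondents with an answer), over the (optionally
    asymptomatic-filtered) records. Cells with fewer than ``min_n``
    respondents are kept but flagged unreliable — small occupations can bias
    estimates, but dropping them would lose coverage.

    Raises
    ------
    DataError
        On empty input, or ``asymptomatic_only`` without a symptomatic column.
    """
    registry = list(registry)
    if not registry:
        raise DataError("exposure registry is empty")
    if records is None or len(records) == 0:
        raise DataError("no survey records to build from")
    df = records.copy()
    exposure_ids = [d.exposure_id for d in registry if d.exposure_id in df.columns]
    if not exposure_ids:
        raise DataError(
            f"no registry exposure columns found in survey "
            f"(registry: {[d.exposure_id for d in registry]})"
        )
    if asymptomatic_only:
        if "symptomatic" not in df.columns or df["symptomatic"].isna().all():
            raise DataError(
                "asymptomatic_only=True but the survey has no symptomatic field"
            )
        df = df[df["symptomatic"].astype(float) == 0]
        if df.empty:
            raise DataError("asymptomatic filter removed every respondent")

    df["occupation_code"] = df["occupation_code"].astype(str)
    cells = []
    for exposure_id in exposure_ids:
        col = pd.to_numeric(df[exposure_id], errors="coerce")
        if not col.dropna().isin((0, 1)).all():
            bad = sorted(col.dropna()[~col.dropna().isin((0, 1))].unique())
            raise DataError(f"exposure {exposure_id!r}: non-binary values {bad}")
        sub = df.loc[col.notna(), ["occupation_code", "gender"]].copy()
        sub["exposed"] = col.dropna().to_numpy()
        grouped = sub.groupby(["occupation_code", "gender"], sort=True)["exposed"]
        for (code, gender), values in grouped:
            n = int(values.size)
            prevalence = 100.0 * float(values.sum()) / n
            cells.append(JEMCell(
                occupation=OccupationCode(code, coding_system),
                gender=gender,
                exposure_id=exposure_id,
                prevalence_pct=prevalence,
                category=categorize(prevalence, scheme),
                n_respondents=n,
                reliable=n >= min_n,
                source_id=jem_id,
            ))
    # deterministic cell order regardless of input record order
    cells.sort(key=lambda c: c.key)
    return JEM(jem_id, coding_system, cells)


def prevalence_table(
    jem: JEM,
    population: pd.DataFrame,
    exposed_cut: int | None = None,
    scheme: CategoryScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Population share assigned to exposed occupations, per exposure and gender.

    ``population`` needs ``occupation_code`` and ``gender`` columns (one row
    per individual). Returns a tidy frame with columns exposure_id, gender,
    pct_exposed, n_matched, n_unmatched; individuals whose code is absent
    from the matrix are counted as unmatched, never silently dropped.
    """
    if exposed_cut is not None:
        scheme = CategoryScheme(scheme.band_upper_edges, exposed_cut)
    pop = population[["occupation_code", "gender"]].astype(str)
    rows = []
    for exposure_id in jem.exposure_ids():
        for gender in GENDERS:
            codes = pop.loc[pop["gender"] == gender, "occupation_code"]
            if codes.empty:
                continue
            statuses = []
            n_unmatched = 0
            for code in codes:
                cell = jem.get(code, gender, exposure_id)
                if cell is None:
                    n_unmatched += 1
                else:
                    statuses.append(dichotomize(cell, scheme))
            n_matched = len(statuses)
            pct = 100.0 * float(np.mean(statuses)) if n_matched else float("nan")
            rows.append({
                "exposure_id": exposure_id,
                "gender": gender,
                "pct_exposed": pct,
                "n_matched": n_matched,
                "n_unmatched": n_unmatched,
            })
    return pd.DataFrame(rows)


def write_survey(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)
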