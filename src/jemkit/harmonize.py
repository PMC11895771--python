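"""Merge several JEMs on a common coding system into one harmonized matrix.

The reference workflow resolves disagreements between national matrices by an
expert panel. A panel is not simulatable, so the default rule here is
``flag``: every non-unanimous cell is marked FLAGGED and exported to a review
worksheet, preserving the human-in-the-loop step as an explicit interface.
Automated stand-in rules are provided for fully unattended runs:

``majority``
    the modal category among present sources; ties are FLAGGED.
``weighted_median``
    the respondent-count-weighted lower median (deterministic, conservative
    toward lower exposure on ties).
``available_consensus``
    unanimity required only among the sources that cover the cell;
    disagreement among present sources is FLAGGED.

Every automated resolution is a stand-in for panel judgement and is labelled
as such in the ledger. Cells where all sources agree and all sources are
present are rule-invariant and produce no ledger entry; every other cell —
disagreement or missing information — is logged, one entry per cell.
Occupations absent from a source matrix are treated as absent, not as
category 0.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CodingSystemMismatch, ConfigError, DataError
from .model import (
    DEFAULT_SCHEME,
    CategoryScheme,
    JEM,
    JEMCell,
    OccupationCode,
    categorize,
)
from .validate import assign_exposure, cohen_kappa


class Flagged(enum.Enum):
    FLAGGED = "FLAGGED"

    def __repr__(self):  # pragma: no cover - cosmetic
        return "FLAGGED"


FLAGGED = Flagged.FLAGGED

RULES = ("flag", "majority", "weighted_median", "available_consensus")

STANDIN_NOTE = "automated stand-in for panel consensus"


@dataclass
class ConflictLedgerEntry:
    """Audit record of one harmonization decision."""

    occupation_code: str
    gender: str
    exposure_id: str
    source_categories: dict[str, int | None]
    source_n: dict[str, int | None]
    rule_applied: str
    resolved_category: int | Flagged
    note: str = ""
    stage: str = ""

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["resolved_category"] = ("FLAGGED"
                                  if self.resolved_category is FLAGGED
                                  else self.resolved_category)
        return json.dumps(d, sort_keys=True)


def _weighted_lower_median(categories: Sequence[int],
                           weights: Sequence[float]) -> int:
    order = np.argsort(categories, kind="stable")
    cats = np.asarray(categories)[order]
    w = np.asarray(weights, dtype=float)[order]
    if w.sum() <= 0:
        w = np.ones_like(w)
    cum = np.cumsum(w)
    half = w.sum() / 2.0
    idx = int(np.searchsorted(cum, half))  # lower median: first cum >= half
    return int(cats[min(idx, len(cats) - 1)])


def harmonize_cell(
    categories: Mapping[str, int | None],
    weights: Mapping[str, int | None] | None = None,
    rule: str = "flag",
) -> tuple[int | Flagged, ConflictLedgerEntry | None]:
    """Resolve one cell across sources.

    ``categories`` maps source id -> band (None if the source does not cover
    the cell). Returns the resolved category (or FLAGGED) and a ledger entry,
    which is None exactly when all sources are present and unanimous.
    """
    if rule not in RULES:
        raise ConfigError(f"unknown resolution rule {rule!r}; choose from {RULES}")
    present = {s: c for s, c in categories.items() if c is not None}
    if not present:
        raise DataError("harmonize_cell: all sources absent")
    weights = weights or {}
    values = sorted(set(present.values()))

    if len(values) == 1 and len(present) == len(categories):
        return values[0], None  # full unanimity: rule-invariant, no entry

    note_bits = []
    missing = [s for s, c in categories.items() if c is None]
    if missing:
        note_bits.append(f"missing in: {','.join(sorted(missing))}")
    if len(present) == 1:
        note_bits.append("single-source")

    if rule == "flag":
        resolved: int | Flagged = FLAGGED
        note_bits.append("sent to review worksheet")
    elif rule == "available_consensus":
        resolved = values[0] if len(values) == 1 else FLAGGED
        if len(values) > 1:
            note_bits.append("present sources disagree")
    elif rule == "majority":
        counts = pd.Series(list(present.values())).value_counts()
        top = counts[counts == counts.max()].index.tolist()
        resolved = int(top[0]) if len(top) == 1 else FLAGGED
        if len(top) > 1:
            note_bits.append(f"modal tie between {sorted(top)}")
    else:  # weighted_median
        cats = list(present.values())
        w = [float(weights.get(s) or 1.0) for s in present]
        resolved = _weighted_lower_median(cats, w)
    if resolved is not FLAGGED and len(values) > 1:
        note_bits.append(STANDIN_NOTE)

    entry = ConflictLedgerEntry(
        occupation_code="", gender="", exposure_id="",
        source_categories=dict(categories),
        source_n={s: weights.get(s) for s in categories},
        rule_applied=rule,
        resolved_category=resolved,
        note="; ".join(note_bits),
    )
    return resolved, entry


@dataclass
class HarmonizationResult:
    jem: JEM
    ledger: list[ConflictLedgerEntry] = field(default_factory=list)
    #: per (exposure_id, gender): share of cells that were fully unanimous
    agreement: pd.DataFrame | None = None


def harmonize_jems(
    jems: Sequence[JEM],
    rule: str = "flag",
    jem_id: str = "harmonized",
    stage: str = "",
    scheme: CategoryScheme = DEFAULT_SCHEME,
) -> HarmonizationResult:
    """Harmonize two or more matrices cell by cell.

    The cell universe is the union of keys across sources. FLAGGED cells are
    excluded from the harmonized matrix (they await review via the ledger /
    worksheet). A harmonized cell carries the respondent-weighted mean source
    prevalence only when that mean re-bands to the resolved category;
    otherwise it is category-only.
    """
    if len(jems) < 2:
        raise DataError("harmonization needs at least two matrices")
    systems = {j.coding_system for j in jems}
    if len(systems) != 1:
        raise CodingSystemMismatch(f"matrices on different systems: {sorted(systems)}")
    coding_system = jems[0].coding_system
    ids = [j.jem_id for j in jems]
    if len(set(ids)) != len(ids):
        ids = [f"{j.jem_id}#{i}" for i, j in enumerate(jems)]

    universe = sorted(set().union(*(set(j.keys()) for j in jems)))
    out = JEM(jem_id, coding_system)
    ledger: list[ConflictLedgerEntry] = []
    tallies: dict[tuple[str, str], list[int]] = {}

    for code, gender, exposure_id in universe:
        source_cells = {sid: j.get(code, gender, exposure_id)
                        for sid, j in zip(ids, jems)}
        categories = {s: (c.effective_category() if c else None)
                      for s, c in source_cells.items()}
        weights = {s: (c.n_respondents if c else None)
                   for s, c in source_cells.items()}
        resolved, entry = harmonize_cell(categories, weights, rule)
        unanimous = entry is None
        agg = tallies.setdefault((exposure_id, gender), [0, 0])
        agg[0] += int(unanimous)
        agg[1] += 1
        if entry is not None:
            entry.occupation_code = code
            entry.gender = gender
            entry.exposure_id = exposure_id
            entry.stage = stage
            ledger.append(entry)
        if resolved is FLAGGED:
            continue
        present = [c for c in source_cells.values() if c is not None]
        prevs = [c.prevalence_pct for c in present]
        prevalence = None
        if all(p is not None for p in prevs):
            w = [float(c.n_respondents or 1) for c in present]
            mean = float(np.average(prevs, weights=w))
            if categorize(mean, scheme) == resolved:
                prevalence = mean
        n_total = sum(c.n_respondents for c in present
                      if c.n_respondents is not None) or None
        out.add_cell(JEMCell(
            occupation=OccupationCode(code, coding_system),
            gender=gender, exposure_id=exposure_id,
            prevalence_pct=prevalence,
            category=int(resolved),
            n_respondents=n_total,
            reliable=all(c.reliable for c in present),
            source_id=jem_id,
            provenance=tuple(s for s, c in source_cells.items() if c is not None),
        ))

    agreement = pd.DataFrame(
        [{"exposure_id": e, "gender": g,
          "agreement_rate": a / t, "n_cells": t}
         for (e, g), (a, t) in sorted(tallies.items())]
    )
    return HarmonizationResult(out, ledger, agreement)


def staged_harmonize(
    stages: Sequence[tuple[str, Sequence[JEM]]],
    rule: str = "flag",
    jem_id: str = "harmonized",
    scheme: CategoryScheme = DEFAULT_SCHEME,
) -> HarmonizationResult:
    """Run harmonization in labelled stages, feeding each result forward.

    ``stages`` is a list of (stage_label, matrices); from the second stage on
    the previous result is prepended to that stage's matrices. The ledger
    keeps every stage's entries, tagged with the stage label, so staged and
    one-shot runs remain auditable even where they differ.
    """
    if not stages:
        raise DataError("no stages given")
    result: HarmonizationResult | None = None
    full_ledger: list[ConflictLedgerEntry] = []
    for i, (label, jems) in enumerate(stages):
        batch = list(jems)
        if result is not None:
            batch = [result.jem] + batch
        stage_id = jem_id if i == len(stages) - 1 else f"{jem_id}:{label}"
        result = harmonize_jems(batch, rule=rule, jem_id=stage_id,
                                stage=label, scheme=scheme)
        full_ledger.extend(result.ledger)
    result.ledger = full_ledger
    return result


# ---------------------------------------------------------------------------
# agreement between two matrices on a reference population
# ---------------------------------------------------------------------------


@dataclass
class JemAgreement:
    """Individual-level agreement between two matrices (kappa + proportions)."""

    exposure_id: str
    gender: str | None
    kappa: float
    pct_exposed_a: float
    pct_exposed_b: float
    n: int


def agreement_kappa_between_jems(
    jem_a: JEM,
    jem_b: JEM,
    population: pd.DataFrame,
    exposure_id: str,
    gender: str | None = None,
    exposed_cut: int = 2,
) -> JemAgreement:
    """Assign binary exposure from both matrices to every individual and
    compute Cohen's kappa on the paired vectors, with each matrix's exposed
    proportion reported alongside.

    Individuals not assignable under *both* matrices are excluded (and must
    not be everyone).
    """
    pop = population
    if gender is not None:
        pop = pop[pop["gender"] == gender]
    a = assign_exposure(pop, jem_a, exposure_id, exposed_cut)
    b = assign_exposure(pop, jem_b, exposure_id, exposed_cut)
    both = a.frame["exposed"].notna() & b.frame["exposed"].notna()
    if not both.any():
        raise DataError(
            f"no individuals assignable under both matrices for {exposure_id!r}"
        )
    x = a.frame.loc[both, "exposed"].astype(int).to_numpy()
    y = b.frame.loc[both, "exposed"].astype(int).to_numpy()
    return JemAgreement(
        exposure_id=exposure_id,
        gender=gender,
        kappa=cohen_kappa(x, y),
        pct_exposed_a=100.0 * float(x.mean()),
        pct_exposed_b=100.0 * float(y.mean()),
        n=int(both.sum()),
    )


# ---------------------------------------------------------------------------
# ledger / worksheet output
# ---------------------------------------------------------------------------


def write_ledger(ledger: Iterable[ConflictLedgerEntry], path: str | Path) -> None:
    """Write the conflict ledger as JSON lines, one decision per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for entry in ledger:
            fh.write(entry.to_json() + "\n")


def write_review_worksheet(ledger: Iterable[ConflictLedgerEntry],
                           path: str | Path, sep: str = ",") -> None:
    """Export FLAGGED cells as a delimited worksheet for expert review."""
    rows = []
    for e in ledger:
        if e.resolved_category is not FLAGGED:
            continue
        row = {"occupation_code": e.occupation_code, "gender": e.gender,
               "exposure_id": e.exposure_id, "stage": e.stage, "note": e.note}
        for s, c in sorted(e.source_categories.items()):
            row[f"category_{s}"] = c
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
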