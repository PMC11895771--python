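"""Transcode a JEM between occupational coding systems.

National matrices arrive on national classifications (e.g. PCS 2003,
SSYK 96, STYRK 98) and must be moved onto a common system (ISCO-88 COM)
before harmonization, sometimes via an intermediate system (PCS 2003 ->
ISCO-88 -> ISCO-88 COM). A crosswalk is a weighted mapping between two
systems; transcoding applies it cell-wise:

* one-to-one: the prevalence is copied;
* one-to-many (split): the source prevalence is replicated to every target,
  weights only apportion the bookkeeping of contributing respondent counts;
* many-to-one (merge): the target prevalence is the weighted mean of source
  prevalences — workforce-size weights if supplied, else explicit crosswalk
  weights, else source respondent counts, else equal weights.

Categories are always recomputed from the transcoded prevalence, never
averaged directly: averaging ordinal codes is lossy, and the bands are
defined on proportions. Source codes absent from the crosswalk are dropped
and reported, never silently lost — crosswalks between national systems are
known to be incomplete.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import CodingSystemMismatch, DataError, LoadError
from .model import (
    DEFAULT_SCHEME,
    CategoryScheme,
    JEM,
    JEMCell,
    OccupationCode,
    categorize,
)

XWALK_COLUMNS = ["source_system", "target_system", "source_code", "target_code",
                 "weight"]


@dataclass(frozen=True)
class CrosswalkEntry:
    source_code: str
    target_code: str
    weight: float | None = None  # None = unspecified in the table

    def __post_init__(self):
        if self.weight is not None and self.weight < 0:
            raise DataError(
                f"crosswalk {self.source_code}->{self.target_code}: negative weight"
            )


class Crosswalk:
    """A weighted mapping from one occupational coding system to another."""

    def __init__(self, source_system: str, target_system: str,
                 entries: list[CrosswalkEntry] | None = None,
                 dropped_paths: list[tuple[str, str]] | None = None):
        self.source_system = source_system
        self.target_system = target_system
        self.entries: list[CrosswalkEntry] = []
        #: (source_code, intermediate_code) pairs lost while chaining
        self.dropped_paths = list(dropped_paths or [])
        self._by_source: dict[str, list[CrosswalkEntry]] = defaultdict(list)
        for e in entries or []:
            self.add_entry(e)

    def add_entry(self, entry: CrosswalkEntry) -> None:
        for existing in self._by_source[entry.source_code]:
            if existing.target_code == entry.target_code:
                raise DataError(
                    f"duplicate crosswalk pair "
                    f"({entry.source_code}, {entry.target_code})"
                )
        self.entries.append(entry)
        self._by_source[entry.source_code].append(entry)

    def targets_of(self, source_code: str) -> list[CrosswalkEntry]:
        return list(self._by_source.get(source_code, []))

    def normalized_weights(self, source_code: str) -> dict[str, float]:
        """Per-source weights summing to 1 (unspecified weights -> equal)."""
        entries = self._by_source.get(source_code, [])
        raw = [1.0 if e.weight is None else e.weight for e in entries]
        total = sum(raw)
        if total <= 0:
            raise DataError(f"source code {source_code!r}: weights sum to 0")
        return {e.target_code: w / total for e, w in zip(entries, raw)}

    @property
    def has_explicit_weights(self) -> bool:
        return any(e.weight is not None for e in self.entries)

    def target_codes(self) -> set[str]:
        return {e.target_code for e in self.entries}

    @classmethod
    def identity(cls, codes, system: str) -> "Crosswalk":
        return cls(system, system,
                   [CrosswalkEntry(c, c, 1.0) for c in codes])


@dataclass
class TranscodeResult:
    """A transcoded matrix plus the unmapped-codes summary."""

    jem: JEM
    #: source codes absent from the crosswalk -> number of cells dropped
    unmapped_codes: dict[str, int] = field(default_factory=dict)


def transcode_jem(
    jem: JEM,
    xwalk: Crosswalk,
    size_weights: Mapping[str, float] | None = None,
    jem_id: str | None = None,
    scheme: CategoryScheme = DEFAULT_SCHEME,
) -> TranscodeResult:
    """Apply a crosswalk to every cell of a matrix.

    ``size_weights`` maps source occupation codes to workforce counts and,
    when given, overrides the merge-weight cascade (crosswalk weights, then
    source respondent counts, then equal).
    """
    if jem.coding_system != xwalk.source_system:
        raise CodingSystemMismatch(
            f"JEM is on {jem.coding_system!r} but crosswalk expects "
            f"{xwalk.source_system!r}"
        )
    out_id = jem_id or f"{jem.jem_id}@{xwalk.target_system}"
    unmapped: dict[str, int] = defaultdict(int)
    # accumulate contributions per output key
    contrib: dict[tuple[str, str, str], list] = defaultdict(list)

    for cell in jem:
        entries = xwalk.targets_of(cell.occupation.code)
        if not entries:
            unmapped[cell.occupation.code] += 1
            continue
        norm = xwalk.normalized_weights(cell.occupation.code)
        # merge mass = source size x the share of the source flowing to the
        # target; sequential transcoding then equals transcoding via a
        # chained crosswalk (up to respondent-count rounding)
        if size_weights is not None and cell.occupation.code in size_weights:
            base = float(size_weights[cell.occupation.code])
        elif cell.n_respondents is not None:
            base = float(cell.n_respondents)
        else:
            base = 1.0
        for entry in entries:
            split = norm[entry.target_code]
            key = (entry.target_code, cell.gender, cell.exposure_id)
            contrib[key].append((cell, base * split, split))

    out = JEM(out_id, xwalk.target_system)
    for (code, gender, exposure_id), parts in sorted(contrib.items()):
        sources = [c for c, _, _ in parts]
        weights = [w for _, w, _ in parts]
        if any(c.prevalence_pct is None for c in sources):
            # category-only sources: single-source passthrough, merges flagged
            if len(sources) == 1:
                cell = sources[0]
                out.add_cell(JEMCell(
                    occupation=OccupationCode(code, xwalk.target_system),
                    gender=gender, exposure_id=exposure_id,
                    prevalence_pct=cell.prevalence_pct,
                    category=cell.effective_category(),
                    n_respondents=cell.n_respondents,
                    reliable=cell.reliable, source_id=out_id,
                    provenance=(cell.occupation.code,),
                ))
                continue
            raise DataError(
                f"cannot merge category-only cells into {code}/{gender}/"
                f"{exposure_id}: prevalences required for the weighted mean"
            )
        total_w = sum(weights)
        if total_w <= 0:
            weights = [1.0] * len(parts)
            total_w = float(len(parts))
        prevalence = sum(c.prevalence_pct * w
                         for c, w in zip(sources, weights)) / total_w
        n_parts = [c.n_respondents * split for c, _, split in parts
                   if c.n_respondents is not None]
        n = int(round(sum(n_parts))) if n_parts else None
        out.add_cell(JEMCell(
            occupation=OccupationCode(code, xwalk.target_system),
            gender=gender, exposure_id=exposure_id,
            prevalence_pct=prevalence,
            category=categorize(prevalence, scheme),
            n_respondents=n,
            reliable=all(c.reliable for c in sources),
            source_id=out_id,
            provenance=tuple(sorted({c.occupation.code for c in sources})),
        ))
    return TranscodeResult(out, dict(unmapped))


def chain(xwalk_1: Crosswalk, xwalk_2: Crosswalk) -> Crosswalk:
    """Compose two crosswalks into a single source->target mapping.

    Weights multiply along each path and are renormalized per source code.
    Paths whose intermediate code is absent from the second crosswalk are
    dropped and recorded in ``dropped_paths`` — never lost silently.
    Transcoding via the chained walk equals transcoding twice in sequence
    when no codes are dropped.
    """
    if xwalk_1.target_system != xwalk_2.source_system:
        raise CodingSystemMismatch(
            f"cannot chain: {xwalk_1.target_system!r} != {xwalk_2.source_system!r}"
        )
    acc: dict[tuple[str, str], float] = defaultdict(float)
    dropped: list[tuple[str, str]] = []
    sources = sorted(xwalk_1._by_source)
    for source in sources:
        norm1 = xwalk_1.normalized_weights(source)
        for mid, w1 in norm1.items():
            if not xwalk_2.targets_of(mid):
                dropped.append((source, mid))
                continue
            for target, w2 in xwalk_2.normalized_weights(mid).items():
                acc[(source, target)] += w1 * w2
    entries = [CrosswalkEntry(s, t, w) for (s, t), w in sorted(acc.items())]
    return Crosswalk(xwalk_1.source_system, xwalk_2.target_system, entries,
                     dropped_paths=dropped)


def recode_population(population: pd.DataFrame, xwalk: Crosswalk) -> tuple[pd.DataFrame, dict[str, int]]:
    """Recode a population's occupation codes to the crosswalk's target system.

    Individual-level recoding must be single-valued, so for split codes the
    highest-weight target is taken (ties broken lexicographically). Rows with
    unmapped codes are dropped and counted in the returned summary.
    """
    mapping: dict[str, str] = {}
    for source in xwalk._by_source:
        norm = xwalk.normalized_weights(source)
        best = min(norm.items(), key=lambda kv: (-kv[1], kv[0]))
        mapping[source] = best[0]
    codes = population["occupation_code"].astype(str)
    mapped = codes.map(mapping)
    dropped: dict[str, int] = (
        codes[mapped.isna()].value_counts().astype(int).to_dict())
    out = population[mapped.notna()].copy()
    out["occupation_code"] = mapped[mapped.notna()]
    return out, dropped


def read_crosswalk(path: str | Path) -> Crosswalk:
    """Read a crosswalk table (delimited text; blank weight = unspecified)."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        sep = "\t" if "\t" in fh.readline() else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     na_values=[""])
    missing = [c for c in XWALK_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise LoadError(f"{path}: no data rows")
    systems = df[["source_system", "target_system"]].drop_duplicates()
    if len(systems) != 1:
        raise LoadError(f"{path}: multiple system pairs in one file")
    entries = []
    for idx, row in df.iterrows():
        w = None if pd.isna(row["weight"]) else float(row["weight"])
        entries.append(CrosswalkEntry(str(row["source_code"]),
                                      str(row["target_code"]), w))
    try:
        return Crosswalk(str(systems.iloc[0, 0]), str(systems.iloc[0, 1]), entries)
    except DataError as exc:
        raise LoadError(f"{path}: {exc}") from exc


def write_crosswalk(xwalk: Crosswalk, path: str | Path, sep: str = ",") -> None:
    rows = [{
        "source_system": xwalk.source_system,
        "target_system": xwalk.target_system,
        "source_code": e.source_code,
        "target_code": e.target_code,
        "weight": "" if e.weight is None else repr(float(e.weight)),
    } for e in xwalk.entries]
    pd.DataFrame(rows, columns=XWALK_COLUMNS).to_csv(path, sep=sep, index=False)
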