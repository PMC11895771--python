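"""Core data types for gender-specific job exposure matrices (JEMs).

A JEM maps (occupation code, gender, exposure) to the prevalence of workers
reporting that exposure, banded into five ordinal categories by the share of
workers exposed:

    0 = 0-5%,  1 = 6-24%,  2 = 25-49%,  3 = 50-74%,  4 = 75-100%

For agreement and predictive-validity analyses the bands are collapsed to a
binary classification: an occupation is *exposed* when at least 25% of its
workers report the exposure (category >= 2), *non-exposed* below that.

Matrices are gender-specific throughout: a cell exists per gender
independently and is never pooled across genders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml

from .errors import DataError, DomainError, LoadError

GENDERS = ("M", "F")

#: Upper (inclusive) integer-percent edge of each band, in band order 0..4.
BAND_UPPER_EDGES = (5, 24, 49, 74, 100)

JEM_COLUMNS = [
    "jem_id",
    "coding_system",
    "occupation_code",
    "gender",
    "exposure_id",
    "prevalence_pct",
    "category",
    "n_respondents",
    "reliable",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExposureDefinition:
    """One harmonized physical-workload dimension.

    Parameters
    ----------
    exposure_id : short token used in file headers and matrix keys.
    label : human-readable name.
    threshold_text : the wording of the exposure threshold, e.g.
        ">20 kg several times per day" or "at least 1/4 of the time".
    """

    exposure_id: str
    label: str
    threshold_text: str = ""

    def __post_init__(self):
        if not self.exposure_id:
            raise DataError("exposure_id must be non-empty")
        if not self.label:
            raise DataError(f"exposure {self.exposure_id!r}: label must be non-empty")


@dataclass(frozen=True)
class OccupationCode:
    """An occupation code within a named coding system.

    Codes are strings, never integers — leading zeros of 4-digit codes are
    significant. Equality requires both the code and the coding system.
    """

    code: str
    coding_system: str

    def __post_init__(self):
        if not self.code:
            raise DataError("occupation code must be non-empty")
        if not self.coding_system:
            raise DataError(f"code {self.code!r}: coding_system must be non-empty")


@dataclass(frozen=True)
class CategoryScheme:
    """The five-band prevalence scheme and the dichotomization cut.

    ``exposed_cut`` is the minimum band counted as exposed when collapsing to
    a binary classification; the default (2) corresponds to the 25% edge.
    """

    band_upper_edges: tuple[int, ...] = BAND_UPPER_EDGES
    exposed_cut: int = 2

    def __post_init__(self):
        edges = self.band_upper_edges
        if list(edges) != sorted(edges) or edges[-1] != 100:
            raise DataError(f"band edges must increase and end at 100, got {edges}")
        if not 0 <= self.exposed_cut <= len(edges) - 1:
            raise DataError(f"exposed_cut {self.exposed_cut} outside band range")

    @property
    def n_bands(self) -> int:
        return len(self.band_upper_edges)


DEFAULT_SCHEME = CategoryScheme()


@dataclass(frozen=True)
class JEMCell:
    """One matrix cell: (occupation, gender, exposure) -> prevalence/category.

    At least one of ``prevalence_pct`` and ``category`` must be present; when
    both are, the category must equal ``categorize(prevalence_pct)``.
    ``provenance`` lists contributing source codes or matrices after
    transcoding/harmonization.
    """

    occupation: OccupationCode
    gender: str
    exposure_id: str
    prevalence_pct: float | None = None
    category: int | None = None
    n_respondents: int | None = None
    reliable: bool = True
    source_id: str = ""
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        if self.gender not in GENDERS:
            raise DataError(
                f"gender must be one of {GENDERS}, got {self.gender!r} "
                f"(cell {self.occupation.code}/{self.exposure_id})"
            )
        if self.prevalence_pct is None and self.category is None:
            raise DataError(
                f"cell {self.key}: needs a prevalence or a category, has neither"
            )
        if self.prevalence_pct is not None:
            if not 0.0 <= self.prevalence_pct <= 100.0:
                raise DomainError(
                    f"cell {self.key}: prevalence {self.prevalence_pct} outside [0, 100]"
                )
            expected = categorize(self.prevalence_pct)
            if self.category is not None and self.category != expected:
                raise DataError(
                    f"cell {self.key}: category {self.category} contradicts "
                    f"prevalence {self.prevalence_pct}% (bands to {expected})"
                )
        if self.category is not None and not 0 <= self.category <= 4:
            raise DomainError(f"cell {self.key}: category {self.category} not in 0..4")
        if self.n_respondents is not None and self.n_respondents < 0:
            raise DomainError(f"cell {self.key}: negative n_respondents")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.occupation.code, self.gender, self.exposure_id)

    def effective_category(self) -> int:
        """The stored category, or the one derived from the prevalence."""
        if self.category is not None:
            return self.category
        return categorize(self.prevalence_pct)


class JEM:
    """A gender-specific job exposure matrix.

    Cells are keyed by (occupation code, gender, exposure_id); all cells share
    the matrix's coding system.
    """

    def __init__(self, jem_id: str, coding_system: str,
                 cells: Iterable[JEMCell] = ()):
        if not jem_id or not coding_system:
            raise DataError("jem_id and coding_system must be non-empty")
        self.jem_id = jem_id
        self.coding_system = coding_system
        self._cells: dict[tuple[str, str, str], JEMCell] = {}
        for cell in cells:
            self.add_cell(cell)

    def add_cell(self, cell: JEMCell) -> None:
        if cell.occupation.coding_system != self.coding_system:
            raise DataError(
                f"cell {cell.key}: coding system {cell.occupation.coding_system!r} "
                f"differs from matrix system {self.coding_system!r}"
            )
        if cell.key in self._cells:
            raise DataError(f"duplicate cell key {cell.key} in JEM {self.jem_id!r}")
        self._cells[cell.key] = cell

    def get(self, code: str, gender: str, exposure_id: str) -> JEMCell | None:
        return self._cells.get((code, gender, exposure_id))

    def __len__(self) -> int:
        return len(self._cells)

    def __iter__(self) -> Iterator[JEMCell]:
        return iter(self._cells.values())

    def __contains__(self, key: tuple[str, str, str]) -> bool:
        return key in self._cells

    @property
    def cells(self) -> Mapping[tuple[str, str, str], JEMCell]:
        return dict(self._cells)

    def keys(self):
        return self._cells.keys()

    def occupation_codes(self) -> list[str]:
        return sorted({k[0] for k in self._cells})

    def exposure_ids(self) -> list[str]:
        return sorted({k[2] for k in self._cells})

    def replace_id(self, jem_id: str) -> "JEM":
        out = JEM(jem_id, self.coding_system)
        for cell in self:
            out.add_cell(cell)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, JEM):
            return NotImplemented
        return (self.coding_system == other.coding_system
                and self._cells == other._cells)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cell in self:
            rows.append({
                "jem_id": self.jem_id,
                "coding_system": self.coding_system,
                "occupation_code": cell.occupation.code,
                "gender": cell.gender,
                "exposure_id": cell.exposure_id,
                "prevalence_pct": cell.prevalence_pct,
                "category": cell.category,
                "n_respondents": cell.n_respondents,
                "reliable": cell.reliable,
                "provenance": "+".join(cell.provenance),
            })
        frame = pd.DataFrame(rows, columns=JEM_COLUMNS + ["provenance"])
        return frame.sort_values(
            ["occupation_code", "gender", "exposure_id"]
        ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# banding operations
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def categorize(prevalence_pct: float, scheme: CategoryScheme = DEFAULT_SCHEME) -> int:
    """Map a prevalence (percent of workers exposed) to its ordinal band.

    The prevalence is rounded half-up to an integer percent first, so the
    printed integer bands form a total partition of [0, 100]: 5.4% -> band 0,
    5.5% -> band 1.

    Raises
    ------
    DomainError
        If ``prevalence_pct`` lies outside [0, 100].
    """
    p = float(prevalence_pct)
    if math.isnan(p) or not 0.0 <= p <= 100.0:
        raise DomainError(f"prevalence {prevalence_pct!r} outside [0, 100]")
    r = _round_half_up(p)
    for band, upper in enumerate(scheme.band_upper_edges):
        if r <= upper:
            return band
    raise AssertionError("unreachable: bands end at 100")


def dichotomize(cell: JEMCell, scheme: CategoryScheme = DEFAULT_SCHEME) -> bool:
    """Collapse a cell to binary exposed / non-exposed.

    True (exposed) iff the cell's category is at least ``scheme.exposed_cut``
    (default 2, i.e. >= 25% of workers exposed).
    """
    return cell.effective_category() >= scheme.exposed_cut


# ---------------------------------------------------------------------------
# exposure registry
# ---------------------------------------------------------------------------


def load_registry(path: str | Path | None = None) -> list[ExposureDefinition]:
    """Load an exposure registry from YAML; packaged default if no path.

    The packaged registry contains the five harmonized physical-workload
    exposures (heavy lifting, faster breathing, kneeling or squatting,
    forward bent posture, hands above shoulder level).
    """
    if path is None:
        from importlib.resources import files

        text = files("jemkit.data").joinpath("exposures.yaml").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    raw = yaml.safe_load(text)
    if not isinstance(raw, list) or not raw:
        raise LoadError("exposure registry must be a non-empty YAML list")
    defs = [ExposureDefinition(**entry) for entry in raw]
    ids = [d.exposure_id for d in defs]
    if len(set(ids)) != len(ids):
        raise LoadError(f"duplicate exposure ids in registry: {ids}")
    return defs


# ---------------------------------------------------------------------------
# JEM file I/O
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_jem(path: str | Path, jem_id: str | None = None) -> JEM:
    """Read a JEM from delimited text (comma default, tab accepted).

    Invalid rows are rejected together, with row-numbered diagnostics in the
    raised :class:`LoadError`. Rows with a missing gender are rejected (the
    matrix is gender-specific throughout) and counted in the error message.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str,
                     keep_default_na=False, na_values=[""])
    missing = [c for c in JEM_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required columns {missing}")

    problems: list[str] = []
    cells: list[JEMCell] = []
    seen: dict[tuple[str, str, str], int] = {}
    n_missing_gender = 0

    if df.empty:
        raise LoadError(f"{path}: no data rows")
    file_jem_id = jem_id or str(df["jem_id"].iloc[0])
    coding_system = str(df["coding_system"].iloc[0])

    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based, after the header
        gender = row["gender"]
        if pd.isna(gender) or gender not in GENDERS:
            n_missing_gender += 1
            problems.append(f"row {rowno}: missing or invalid gender {gender!r}")
            continue
        try:
            prev = None if pd.isna(row["prevalence_pct"]) else float(row["prevalence_pct"])
            cat = None if pd.isna(row["category"]) else int(float(row["category"]))
            n = None if pd.isna(row["n_respondents"]) else int(float(row["n_respondents"]))
            reliable = str(row["reliable"]).strip().lower() in ("true", "1", "yes", "")
            prov = ()
            if "provenance" in df.columns and not pd.isna(row.get("provenance")):
                prov = tuple(p for p in str(row["provenance"]).split("+") if p)
            cell = JEMCell(
                occupation=OccupationCode(str(row["occupation_code"]), coding_system),
                gender=gender,
                exposure_id=str(row["exposure_id"]),
                prevalence_pct=prev,
                category=cat,
                n_respondents=n,
                reliable=reliable,
                source_id=file_jem_id,
                provenance=prov,
            )
        except (DataError, DomainError, ValueError) as exc:
            problems.append(f"row {rowno}: {exc}")
            continue
        if cell.key in seen:
            problems.append(
                f"row {rowno}: duplicate key {cell.key} (first at row {seen[cell.key]})"
            )
            continue
        seen[cell.key] = rowno
        cells.append(cell)

    if problems:
        msg = f"{path}: {len(problems)} invalid row(s)"
        if n_missing_gender:
            msg += f" ({n_missing_gender} with missing/invalid gender)"
        raise LoadError(msg, problems)
    return JEM(file_jem_id, coding_system, cells)


def write_jem(jem: JEM, path: str | Path, sep: str = ",") -> None:
    """Write a JEM as delimited text; round-trips through :func:`read_jem`.

    Prevalences are written with 6 decimals (lossless to that precision);
    occupation codes are written verbatim, preserving leading zeros.
    """
    frame = jem.to_frame()
    frame["prevalence_pct"] = frame["prevalence_pct"].map(
        lambda v: "" if pd.isna(v) else f"{v:.6f}"
    )
    frame["category"] = frame["category"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    frame["n_respondents"] = frame["n_respondents"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    frame.to_csv(path, sep=sep, index=False)


def cells_equal(a: JEM, b: JEM, prevalence_tol: float = 1e-6) -> bool:
    """Key-by-key equality of two matrices, prevalence compared to a tolerance."""
    if a.coding_system != b.coding_system or set(a.keys()) != set(b.keys()):
        return False
    for key, ca in a.cells.items():
        cb = b.cells[key]
        if ca.effective_category() != cb.effective_category():
            return False
        pa, pb = ca.prevalence_pct, cb.prevalence_pct
        if (pa is None) != (pb is None):
            return False
        if pa is not None and abs(pa - pb) > prevalence_tol:
            return False
    return True
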