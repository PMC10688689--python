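"""Reading tag-resight records and deriving the count summaries the estimators use.

The atomic observation is one animal seen once in one breeding season
(:class:`SightingRecord`).  From a pile of such records this module builds

* per-cohort natal-dispersal counts (tagged / breeding / resident / emigrant),
* year-to-year reappearance counts, the raw material for the reappearance
  rate ``pi`` and for the adult-dispersal tally,
* pooled age distributions of breeding females, the raw material for the
  return-rate regression.

Females are assumed to start breeding at age 3-4, so any sighting of a female
aged ``min_breeding_age`` (default 3) or older counts as a breeding record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sealdisp")

#: Default age (years) from which an observed female is assumed to be breeding.
MIN_BREEDING_AGE = 3

REQUIRED_SIGHTING_COLUMNS = (
    "animal_id",
    "birth_colony",
    "birth_year",
    "obs_year",
    "obs_colony",
)


class SightingParseError(ValueError):
    """A sightings file row could not be parsed or fails a sanity check."""


class ConfigurationError(ValueError):
    """Inputs are inconsistent with the declared two-colony study design."""


class InsufficientDataError(ValueError):
    """Not enough observations to compute the requested summary."""


@dataclass(frozen=True, slots=True)
class SightingRecord:
    """One animal-year observation of a tagged female."""

    animal_id: str
    birth_colony: str
    birth_year: int
    obs_year: int
    obs_colony: str

    @property
    def age(self) -> int:
        return self.obs_year - self.birth_year


@dataclass(frozen=True)
class CohortDispersalTable:
    """Per-cohort natal dispersal counts.

    ``counts`` is indexed by ``(birth_year, birth_colony)`` with integer columns
    ``tagged`` (T, females tagged as pups), ``breeding`` (B, ever observed
    breeding), ``resident`` (first seen breeding at the birth colony) and
    ``emigrant`` (first seen breeding at the opposite colony).
    """

    counts: pd.DataFrame
    colonies: tuple[str, str]

    def __post_init__(self) -> None:
        c = self.counts
        if (c["breeding"] != c["resident"] + c["emigrant"]).any():
            raise ValueError("breeding != resident + emigrant in some cohort")
        if (c["breeding"] > c["tagged"]).any():
            raise ValueError("more breeders than tagged animals in some cohort")
        if (c[["tagged", "breeding", "resident", "emigrant"]] < 0).any().any():
            raise ValueError("negative count in cohort table")

    def direction(self, origin: str) -> pd.DataFrame:
        """Rows for cohorts born at ``origin``, indexed by birth year."""
        if origin not in self.colonies:
            raise ConfigurationError(f"unknown colony {origin!r}")
        sub = self.counts.xs(origin, level="birth_colony").sort_index()
        return sub

    def totals(self) -> pd.DataFrame:
        """Column sums per birth colony (the 'Total' row of the cohort table)."""
        return self.counts.groupby(level="birth_colony").sum()


@dataclass(frozen=True)
class ReappearanceTable:
    """Consecutive-season reappearance counts per colony of first observation.

    ``counts`` is indexed by colony with columns ``n_year1`` (breeding records in
    years up to ``final_year - 1``), ``same`` (reseen at the same colony the next
    year) and ``other`` (seen at the opposite colony the next year).
    """

    counts: pd.DataFrame
    colonies: tuple[str, str]
    final_year: int

    def __post_init__(self) -> None:
        c = self.counts
        if (c["same"] + c["other"] > c["n_year1"]).any():
            raise ValueError("more reappearances than year-1 trials")
        if (c < 0).any().any():
            raise ValueError("negative reappearance count")

    def pi_counts(self, colony: str) -> tuple[int, int]:
        """(successes, trials) for the reappearance rate at ``colony``."""
        row = self.counts.loc[colony]
        return int(row["same"]), int(row["n_year1"])


@dataclass(frozen=True)
class AgeCountTable:
    """Distinct breeding females observed at each age, pooled over years.

    ``counts`` is a DataFrame indexed by age with one integer column per colony
    of observation.
    """

    counts: pd.DataFrame
    colonies: tuple[str, str]


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _coerce_colonies(
    seen: Iterable[str], colonies: Sequence[str] | None
) -> tuple[str, str]:
    seen = sorted(set(seen))
    if colonies is not None:
        colonies = tuple(colonies)
        if len(colonies) != 2 or len(set(colonies)) != 2:
            raise ConfigurationError("exactly two distinct colony labels required")
        unknown = [c for c in seen if c not in colonies]
        if unknown:
            raise ConfigurationError(f"unknown colony label(s) {unknown}")
        return colonies  # declared order defines same-season priority
    if len(seen) > 2:
        raise ConfigurationError(f"more than two colonies in data: {seen}")
    if len(seen) == 1:
        # degenerate but legal: all sightings at one colony
        return (seen[0], seen[0] + "_other")
    if not seen:
        raise ConfigurationError("no colony labels present and none declared")
    return (seen[0], seen[1])


def read_sightings(
    path: str | Path, colonies: Sequence[str] | None = None
) -> list[SightingRecord]:
    """Read a CSV sightings file into validated, deduplicated records.

    The file must have a header with columns
    ``animal_id,birth_colony,birth_year,obs_year,obs_colony``.  Duplicate
    ``(animal_id, obs_year, obs_colony)`` rows collapse to one record; rows with
    an observation before birth are rejected.  Records come back sorted by
    ``(animal_id, obs_year)``.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError as exc:
        raise SightingParseError(f"{path}: empty file, header required") from exc
    missing = [c for c in REQUIRED_SIGHTING_COLUMNS if c not in frame.columns]
    if missing:
        raise SightingParseError(f"{path}: missing column(s) {missing}")
    frame = frame[list(REQUIRED_SIGHTING_COLUMNS)]
    if frame.empty:
        return []
    if frame.isna().any().any():
        line = int(frame.isna().any(axis=1).idxmax()) + 2  # header is line 1
        raise SightingParseError(f"{path}: line {line}: missing field")
    for col in ("birth_year", "obs_year"):
        converted = pd.to_numeric(frame[col], errors="coerce")
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + 2
            raise SightingParseError(
                f"{path}: line {line}: non-integer {col} "
                f"{frame.loc[converted.isna().idxmax(), col]!r}"
            )
        frame[col] = converted.astype(int)
    bad_age = frame["obs_year"] < frame["birth_year"]
    if bad_age.any():
        line = int(bad_age.idxmax()) + 2
        raise SightingParseError(f"{path}: line {line}: obs_year before birth_year")
    _coerce_colonies(
        pd.concat([frame["birth_colony"], frame["obs_colony"]]), colonies
    )
    frame = frame.drop_duplicates(subset=["animal_id", "obs_year", "obs_colony"])
    frame = frame.sort_values(["animal_id", "obs_year"], kind="stable")
    return [SightingRecord(*row) for row in frame.itertuples(index=False)]


def _records_frame(records: Iterable[SightingRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.reset_index(drop=True)
    return pd.DataFrame(
        [
            (r.animal_id, r.birth_colony, r.birth_year, r.obs_year, r.obs_colony)
            for r in records
        ],
        columns=list(REQUIRED_SIGHTING_COLUMNS),
    )


def _check_birth_constant(frame: pd.DataFrame) -> None:
    per_animal = frame.groupby("animal_id")[["birth_colony", "birth_year"]].nunique()
    bad = per_animal[(per_animal > 1).any(axis=1)]
    if not bad.empty:
        raise SightingParseError(
            f"inconsistent birth colony/year for animal(s) {list(bad.index[:5])}"
        )


def _resolve_seasons(frame: pd.DataFrame, colonies: tuple[str, str]) -> pd.DataFrame:
    """One row per (animal, obs_year): same-season double sightings resolved.

    An animal recorded at both colonies in the same season is assigned to the
    colony listed first in ``colonies`` (a declared, deterministic priority; no
    within-season dates exist in the record schema).
    """
    dup = frame.duplicated(subset=["animal_id", "obs_year"], keep=False)
    n_double = frame[dup].groupby(["animal_id", "obs_year"]).ngroups
    if n_double:
        logger.warning(
            "%d animal-season(s) observed at both colonies; assigning to %r "
            "by declared priority",
            n_double,
            colonies[0],
        )
    priority = {colonies[0]: 0, colonies[1]: 1}
    out = (
        frame.assign(_prio=frame["obs_colony"].map(priority))
        .sort_values(["animal_id", "obs_year", "_prio"], kind="stable")
        .drop_duplicates(subset=["animal_id", "obs_year"])
        .drop(columns="_prio")
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Tallies
# ---------------------------------------------------------------------------


def tally_cohorts(
    records: Iterable[SightingRecord] | pd.DataFrame,
    tagged_totals: pd.DataFrame | Mapping[tuple[int, str], int],
    min_breeding_age: int = MIN_BREEDING_AGE,
    colonies: Sequence[str] | None = None,
) -> CohortDispersalTable:
    """Build the per-cohort tagged/breeding/resident/emigrant table.

    Each animal is counted once: its first observation at age
    ``>= min_breeding_age`` fixes its breeding colony, and it is a resident if
    that colony equals its birth colony, an emigrant otherwise.  Later moves are
    ignored here (they belong to the adult-dispersal tally).  Animals never seen
    at breeding age contribute only to the tagged total, which is supplied
    separately since never-resighted animals do not appear in the sightings.

    ``tagged_totals`` is a DataFrame with columns
    ``birth_year, colony, n_tagged`` (or an equivalent mapping).
    """
    frame = _records_frame(records)
    if isinstance(tagged_totals, Mapping):
        totals = pd.DataFrame(
            [(y, c, n) for (y, c), n in tagged_totals.items()],
            columns=["birth_year", "colony", "n_tagged"],
        )
    else:
        totals = tagged_totals.copy()
    for col in ("birth_year", "colony", "n_tagged"):
        if col not in totals.columns:
            raise ConfigurationError(f"tagged_totals missing column {col!r}")
    label_pool = pd.concat(
        [totals["colony"].astype(str), frame["birth_colony"], frame["obs_colony"]]
    )
    colony_pair = _coerce_colonies(label_pool.astype(str), colonies)
    _check_birth_constant(frame)

    index = pd.MultiIndex.from_frame(
        totals[["birth_year", "colony"]].rename(columns={"colony": "birth_colony"})
    )
    if index.has_duplicates:
        raise ConfigurationError("duplicate (birth_year, colony) in tagged_totals")
    out = pd.DataFrame(
        0,
        index=index,
        columns=["tagged", "breeding", "resident", "emigrant"],
        dtype=int,
    )
    out["tagged"] = totals["n_tagged"].to_numpy(dtype=int)

    breeders = frame[frame["obs_year"] - frame["birth_year"] >= min_breeding_age]
    if not breeders.empty:
        resolved = _resolve_seasons(breeders, colony_pair)
        first = resolved.sort_values("obs_year", kind="stable").drop_duplicates(
            subset="animal_id"
        )
        for row in first.itertuples(index=False):
            key = (row.birth_year, row.birth_colony)
            if key not in out.index:
                raise ConfigurationError(
                    f"cohort {key} present in sightings but absent from tagged_totals"
                )
            out.loc[key, "breeding"] += 1
            kind = "resident" if row.obs_colony == row.birth_colony else "emigrant"
            out.loc[key, kind] += 1
    out = out.sort_index()
    return CohortDispersalTable(counts=out, colonies=colony_pair)


def tally_reappearance(
    records: Iterable[SightingRecord] | pd.DataFrame,
    final_year: int,
    min_breeding_age: int = MIN_BREEDING_AGE,
    colonies: Sequence[str] | None = None,
) -> ReappearanceTable:
    """Count year-to-year reappearances of breeding females per colony.

    Every breeding record (one resolved animal-season at age
    ``>= min_breeding_age``) in a year up to ``final_year - 1`` is one trial; a
    female seen in k qualifying years contributes k trials.  The year after the
    trial classifies the outcome: reseen at the same colony, seen at the
    opposite colony, or not seen.  ``final_year`` itself supplies only year-2
    outcomes, since search effort after it is unknown.
    """
    frame = _records_frame(records)
    frame = frame[frame["obs_year"] - frame["birth_year"] >= min_breeding_age]
    if frame.empty or frame["obs_year"].min() > final_year:
        raise InsufficientDataError(
            f"no breeding records in or before final_year={final_year}"
        )
    colony_pair = _coerce_colonies(
        pd.concat([frame["birth_colony"], frame["obs_colony"]]), colonies
    )
    resolved = _resolve_seasons(frame, colony_pair)
    where = {
        (row.animal_id, row.obs_year): row.obs_colony
        for row in resolved.itertuples(index=False)
    }
    counts = pd.DataFrame(
        0, index=list(colony_pair), columns=["n_year1", "same", "other"], dtype=int
    )
    counts.index.name = "colony"
    for (animal, year), colony in where.items():
        if year > final_year - 1:
            continue
        counts.loc[colony, "n_year1"] += 1
        nxt = where.get((animal, year + 1))
        if nxt is None:
            continue
        counts.loc[colony, "same" if nxt == colony else "other"] += 1
    return ReappearanceTable(counts=counts, colonies=colony_pair, final_year=final_year)


def tally_adult_dispersal(reapp: ReappearanceTable) -> tuple[int, int, float]:
    """Adult dispersal from consecutive-season pairs.

    Returns ``(pairs, movers, rate)`` where ``pairs`` is the number of females
    observed in two consecutive seasons, ``movers`` those at the opposite colony
    in the second season, and ``rate = movers / pairs`` the annual adult
    dispersal probability.
    """
    pairs = int((reapp.counts["same"] + reapp.counts["other"]).sum())
    movers = int(reapp.counts["other"].sum())
    if pairs == 0:
        raise InsufficientDataError("no consecutive-season pairs; rate undefined")
    return pairs, movers, movers / pairs


def tally_ages(
    records: Iterable[SightingRecord] | pd.DataFrame,
    min_breeding_age: int = MIN_BREEDING_AGE,
    colonies: Sequence[str] | None = None,
    max_birth_year: int | None = None,
) -> AgeCountTable:
    """Count distinct breeding females observed at each age, pooled over years.

    Under constant detection the ratio of counts at successive ages estimates
    the return rate (each year a tagged female survives and keeps her tags with
    probability tau, and the pooled age distribution decays accordingly).

    ``max_birth_year`` restricts the tally to cohorts born in or before that
    year.  Use it to keep the decay unbiased: cohorts born too close to the
    end of observation cannot be seen at old ages, which otherwise steepens
    the pooled age distribution beyond the true return rate.
    """
    frame = _records_frame(records)
    frame = frame.assign(age=frame["obs_year"] - frame["birth_year"])
    frame = frame[frame["age"] >= min_breeding_age]
    if max_birth_year is not None:
        frame = frame[frame["birth_year"] <= max_birth_year]
    if frame.empty:
        pair = _coerce_colonies([], colonies) if colonies else ("colony_1", "colony_2")
        empty = pd.DataFrame(columns=list(pair), dtype=int)
        empty.index.name = "age"
        return AgeCountTable(counts=empty, colonies=pair)
    colony_pair = _coerce_colonies(
        pd.concat([frame["birth_colony"], frame["obs_colony"]]), colonies
    )
    resolved = _resolve_seasons(frame, colony_pair)
    resolved = resolved.assign(age=resolved["obs_year"] - resolved["birth_year"])
    table = (
        resolved.groupby(["age", "obs_colony"])["animal_id"]
        .nunique()
        .unstack("obs_colony", fill_value=0)
        .reindex(columns=list(colony_pair), fill_value=0)
        .astype(int)
    )
    table.index.name = "age"
    table.columns.name = None
    return AgeCountTable(counts=table, colonies=colony_pair)
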