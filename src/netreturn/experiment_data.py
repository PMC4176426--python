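"""Branch-level exclusion-experiment records and economic parameters.

The exclusion experiment nets single lateral branches on treatment trees
(birds excluded) and leaves matched control branches open. At the end of
each phase every nut on a branch is assigned to one of: intact, lost to
birds, lost to non-bird factors (storms, tree health, natural abortion),
or completely disappeared with the cause unattributed. Unattributed
disappearances occur only on open branches and are later partitioned by
:mod:`netreturn.damage_attribution`.

Records are stored one row per branch in plain CSV; economic parameter
sets load from YAML or JSON keyed exactly by field name. Counts are
integers throughout — percentages are derived on output, never stored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

ROW_LOCATIONS = ("edge", "interior")
TREATMENTS = ("netted", "open")
PHASES = ("pre_harvest", "post_harvest")

#: CSV column order for branch records.
RECORD_COLUMNS = (
    "block_id",
    "row_location",
    "treatment",
    "phase",
    "initial_count",
    "intact",
    "bird_loss",
    "nonbird_loss",
    "unattributed_loss",
)

_COUNT_FIELDS = RECORD_COLUMNS[4:]


class SchemaError(ValueError):
    """A records file is missing a required column."""


class RecordValidationError(ValueError):
    """A record violates a count invariant (conservation, sign, netting)."""


@dataclass(frozen=True)
class BranchRecord:
    """Outcome counts for one lateral branch in one experimental phase.

    Invariants (enforced on construction):

    * ``intact + bird_loss + nonbird_loss + unattributed_loss ==
      initial_count`` — every nut is accounted for;
    * all counts are non-negative integers;
    * netted branches carry no bird loss (birds are excluded).
    """

    block_id: str
    row_location: str
    treatment: str
    phase: str
    initial_count: int
    intact: int
    bird_loss: int
    nonbird_loss: int
    unattributed_loss: int = 0

    def __post_init__(self) -> None:
        if self.row_location not in ROW_LOCATIONS:
            raise RecordValidationError(
                f"row_location must be one of {ROW_LOCATIONS}, got {self.row_location!r}"
            )
        if self.treatment not in TREATMENTS:
            raise RecordValidationError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if self.phase not in PHASES:
            raise RecordValidationError(
                f"phase must be one of {PHASES}, got {self.phase!r}"
            )
        for name in _COUNT_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise RecordValidationError(f"{name} must be an integer, got {value!r}")
            if value < 0:
                raise RecordValidationError(f"{name} must be non-negative, got {value}")
        total = self.intact + self.bird_loss + self.nonbird_loss + self.unattributed_loss
        if total != self.initial_count:
            raise RecordValidationError(
                f"outcome categories sum to {total} but initial_count is "
                f"{self.initial_count}"
            )
        if self.treatment == "netted" and self.bird_loss != 0:
            raise RecordValidationError(
                "netted branch cannot have bird_loss > 0 (birds are excluded)"
            )

    @property
    def total_loss(self) -> int:
        return self.initial_count - self.intact

    def rate(self, outcome: str) -> float:
        """Per-branch loss rate for ``outcome`` in {'bird', 'nonbird', 'total'}.

        A branch that started empty contributes a rate of 0.
        """
        if self.initial_count == 0:
            return 0.0
        lost = {
            "bird": self.bird_loss,
            "nonbird": self.nonbird_loss,
            "total": self.total_loss,
        }[outcome]
        return lost / self.initial_count

    def replace(self, **changes) -> "BranchRecord":
        """Return a copy with ``changes`` applied (re-validated)."""
        return dataclasses.replace(self, **changes)


def read_records(path: str | Path, *, delimiter: str = ",") -> list[BranchRecord]:
    """Read branch records from a delimited text file.

    Parameters
    ----------
    path
        CSV file with a header row naming at least :data:`RECORD_COLUMNS`.
        Extra columns (e.g. derived percentages) are ignored.
    delimiter
        Field delimiter, comma by default.

    Raises
    ------
    SchemaError
        If a required column is missing.
    RecordValidationError
        If a row violates a count invariant; the message names the
        offending data row (1-based, excluding the header).
    """
    frame = pd.read_csv(path, sep=delimiter, dtype={"block_id": str})
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records: list[BranchRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            records.append(
                BranchRecord(
                    block_id=str(getattr(row, "block_id")),
                    row_location=str(getattr(row, "row_location")),
                    treatment=str(getattr(row, "treatment")),
                    phase=str(getattr(row, "phase")),
                    initial_count=int(getattr(row, "initial_count")),
                    intact=int(getattr(row, "intact")),
                    bird_loss=int(getattr(row, "bird_loss")),
                    nonbird_loss=int(getattr(row, "nonbird_loss")),
                    unattributed_loss=int(getattr(row, "unattributed_loss")),
                )
            )
        except RecordValidationError as err:
            raise RecordValidationError(f"row {i}: {err}") from err
    return records


def records_frame(records: Iterable[BranchRecord], *, percentages: bool = False) -> pd.DataFrame:
    """Tabulate records; optionally append derived percent-loss columns."""
    frame = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=RECORD_COLUMNS)
    if percentages and len(frame):
        with_nuts = frame["initial_count"].where(frame["initial_count"] > 0)
        frame["percent_bird_loss"] = (100 * frame["bird_loss"] / with_nuts).fillna(0.0)
        frame["percent_nonbird_loss"] = (100 * frame["nonbird_loss"] / with_nuts).fillna(0.0)
    return frame


def write_records(
    records: Sequence[BranchRecord],
    path: str | Path,
    *,
    delimiter: str = ",",
    percentages: bool = False,
) -> None:
    """Write records as delimited text re-readable by :func:`read_records`.

    An empty collection produces a header-only file. With
    ``percentages=True`` derived percent-loss columns are appended for
    human consumption; :func:`read_records` ignores them.
    """
    frame = records_frame(records, percentages=percentages)
    frame.to_csv(path, sep=delimiter, index=False)


@dataclass(frozen=True)
class EconomicParams:
    """Economic parameters of the almond crop.

    Defaults are the 2012 wholesale price (AUD$5.05 kg⁻¹), the mean raw
    shelled-almond mass (1.3 g), the mean crop per tree (1268 nuts), the
    recommended planting density (250 trees ha⁻¹) and a good yield of
    1.5 t ha⁻¹.
    """

    price_per_kg: float = 5.05
    nut_mass_g: float = 1.3
    nuts_per_tree: float = 1268
    trees_per_ha: float = 250
    yield_t_per_ha: float = 1.5

    def __post_init__(self) -> None:
        for name in ("price_per_kg", "nut_mass_g", "nuts_per_tree", "trees_per_ha", "yield_t_per_ha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


#: Time (s), wage (AUD/hr) and machine-hire (AUD/hr) defaults per method.
_METHOD_DEFAULTS = {
    "mechanical": dict(time_per_tree_s=20.0, wage_per_hr=20.0, machine_hire_per_hr=38.0),
    "handpole": dict(time_per_tree_s=60.0, wage_per_hr=15.96, machine_hire_per_hr=0.0),
}


@dataclass(frozen=True)
class ReplacementModel:
    """Parameters of one human-derived mummy-nut removal method.

    ``mechanical``: tree shaker at ~20 s per tree, driver wage plus a
    retail machinery hire rate. ``handpole``: a labourer knocking nuts
    down with a pole, minutes per tree at minimum wage, no machinery.
    Unspecified fields take the method defaults.
    """

    method: str = "mechanical"
    time_per_tree_s: float | None = None
    wage_per_hr: float | None = None
    machine_hire_per_hr: float | None = None

    def __post_init__(self) -> None:
        if self.method not in _METHOD_DEFAULTS:
            raise ValueError(f"method must be one of {tuple(_METHOD_DEFAULTS)}, got {self.method!r}")
        defaults = _METHOD_DEFAULTS[self.method]
        for name in ("time_per_tree_s", "wage_per_hr", "machine_hire_per_hr"):
            if getattr(self, name) is None:
                object.__setattr__(self, name, defaults[name])
        if self.time_per_tree_s <= 0:
            raise ValueError("time_per_tree_s must be strictly positive")
        if self.wage_per_hr < 0 or self.machine_hire_per_hr < 0:
            raise ValueError("hourly rates must be non-negative")

    @classmethod
    def handpole(cls, minutes_per_tree: float = 1.0, wage_per_hr: float = 15.96) -> "ReplacementModel":
        """Hand-poling model from minutes per tree at the given wage."""
        return cls(method="handpole", time_per_tree_s=minutes_per_tree * 60.0, wage_per_hr=wage_per_hr)

    @classmethod
    def mechanical(
        cls,
        time_per_tree_s: float = 20.0,
        wage_per_hr: float = 20.0,
        machine_hire_per_hr: float = 38.0,
    ) -> "ReplacementModel":
        """Mechanical shaking model (driver wage + machinery hire)."""
        return cls(
            method="mechanical",
            time_per_tree_s=time_per_tree_s,
            wage_per_hr=wage_per_hr,
            machine_hire_per_hr=machine_hire_per_hr,
        )


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path} must contain a mapping of parameter names to values")
    return data


def load_params(path: str | Path) -> EconomicParams:
    """Load :class:`EconomicParams` from a YAML or JSON file."""
    return EconomicParams(**_load_mapping(path))


def load_replacement_model(path: str | Path) -> ReplacementModel:
    """Load a :class:`ReplacementModel` from a YAML or JSON file."""
    return ReplacementModel(**_load_mapping(path))


def save_params(params: EconomicParams | ReplacementModel, path: str | Path) -> None:
    """Write a parameter set to YAML or JSON (chosen by file suffix)."""
    path = Path(path)
    data = dataclasses.asdict(params)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
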