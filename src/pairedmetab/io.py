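"""Core data model and validated I/O for paired concentration tables.

The central container is :class:`ConcentrationTable`: a wide matrix of
metabolite concentrations (mmol/L) over samples, where each sample is one
animal measured under one of two conditions (``BEFORE`` / ``AFTER`` an
exposure).  Every analysis stage consumes this container, so validation is
strict at construction time: a complete paired design, unique metabolite
names, finite non-negative values, and no missing entries (incomplete
quantification must be resolved upstream — values are never imputed here).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "SampleKey",
    "ConcentrationTable",
    "PathwaySet",
    "ValidationError",
    "read_concentration_table",
    "write_concentration_table",
    "paired_differences",
    "read_pathway_sets",
]


class ValidationError(ValueError):
    """Raised when an input violates the paired-design data contract."""


class Condition(enum.Enum):
    BEFORE = "before"
    AFTER = "after"

    @classmethod
    def parse(cls, token: str) -> "Condition":
        t = str(token).strip().lower()
        for c in cls:
            if c.value == t:
                return c
        raise ValidationError(
            f"unknown condition {token!r}; expected 'before' or 'after'"
        )


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one measurement: which animal, which condition."""

    animal_id: str
    condition: Condition = field(compare=False)

    def __post_init__(self) -> None:
        # order=True sorts by animal_id; condition ordering handled explicitly
        if not self.animal_id:
            raise ValidationError("animal_id must be a non-empty string")


def _condition_rank(c: Condition) -> int:
    return 0 if c is Condition.BEFORE else 1


@dataclass
class ConcentrationTable:
    """Paired wide matrix of metabolite concentrations.

    Parameters
    ----------
    data:
        DataFrame of shape (2 * n_animals, n_metabolites); values in mmol/L.
    samples:
        One :class:`SampleKey` per row of ``data``, in row order.

    Rows are normalised on construction to (animal sorted, BEFORE then
    AFTER).  Construction validates the full paired-design contract and
    raises :class:`ValidationError` on any violation.
    """

    data: pd.DataFrame
    samples: list[SampleKey]

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.data):
            raise ValidationError(
                f"{len(self.samples)} sample keys for {len(self.data)} rows"
            )
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            dup = sorted({c for c in cols if cols.count(c) > 1})
            raise ValidationError(f"duplicate metabolite names: {dup}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = self._first_non_numeric()
            raise ValidationError(f"non-numeric value at {bad}")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing value for metabolite {cols[c]!r} in sample "
                f"{self._label(self.samples[r])} (missing values are rejected, "
                "not imputed)"
            )
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value for {cols[c]!r} in {self._label(self.samples[r])}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative concentration {values[r, c]} for {cols[c]!r} in "
                f"{self._label(self.samples[r])}"
            )
        seen: set[tuple[str, Condition]] = set()
        for key in self.samples:
            pair = (key.animal_id, key.condition)
            if pair in seen:
                raise ValidationError(
                    f"duplicate sample for animal {key.animal_id!r} "
                    f"condition {key.condition.value!r}"
                )
            seen.add(pair)
        by_animal: dict[str, set[Condition]] = {}
        for key in self.samples:
            by_animal.setdefault(key.animal_id, set()).add(key.condition)
        for animal, conds in sorted(by_animal.items()):
            if conds != {Condition.BEFORE, Condition.AFTER}:
                missing = ({Condition.BEFORE, Condition.AFTER} - conds).pop()
                raise ValidationError(
                    f"unpaired sample {animal} (missing {missing.value!r} row)"
                )
        # normalise row order: animal sorted, BEFORE then AFTER
        order = sorted(
            range(len(self.samples)),
            key=lambda i: (self.samples[i].animal_id, _condition_rank(self.samples[i].condition)),
        )
        self.data = self.data.iloc[order].reset_index(drop=True).astype(float)
        self.samples = [self.samples[i] for i in order]

    @staticmethod
    def _label(key: SampleKey) -> str:
        return f"{key.animal_id}/{key.condition.value}"

    def _first_non_numeric(self) -> str:
        for j, col in enumerate(self.data.columns):
            series = pd.to_numeric(self.data[col], errors="coerce")
            raw_na = self.data[col].isna()
            bad = series.isna() & ~raw_na
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                return f"row {i}, column {col!r} (value {self.data[col].iloc[i]!r})"
        return "unknown position"

    # -- accessors ---------------------------------------------------------

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.columns)

    @property
    def animals(self) -> list[str]:
        return sorted({k.animal_id for k in self.samples})

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    def condition_slice(self, condition: Condition) -> pd.DataFrame:
        """Rows of one condition, indexed by animal (sorted)."""
        mask = [k.condition is condition for k in self.samples]
        sub = self.data.loc[mask]
        sub.index = pd.Index(
            [k.animal_id for k, m in zip(self.samples, mask) if m], name="animal_id"
        )
        return sub.sort_index()

    def class_labels(self) -> np.ndarray:
        """Condition of every row as a string array ('before'/'after')."""
        return np.array([k.condition.value for k in self.samples])

    def subset(self, metabolites: Sequence[str]) -> "ConcentrationTable":
        missing = [m for m in metabolites if m not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown metabolites: {missing}")
        return ConcentrationTable(self.data[list(metabolites)].copy(), list(self.samples))

    def swap_conditions(self) -> "ConcentrationTable":
        """Relabel every BEFORE row AFTER and vice versa (values untouched)."""
        flipped = [
            SampleKey(
                k.animal_id,
                Condition.AFTER if k.condition is Condition.BEFORE else Condition.BEFORE,
            )
            for k in self.samples
        ]
        return ConcentrationTable(self.data.copy(), flipped)


@dataclass(frozen=True)
class PathwaySet:
    """A named metabolite set (one line of a GMT file)."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"empty pathway {self.name!r}")


# -- file I/O --------------------------------------------------------------


def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_concentration_table(path: str | Path, design_path: str | Path) -> ConcentrationTable:
    """Read a wide concentration CSV/TSV plus its design file.

    The main file has the sample ID in its first column and one numeric
    column per metabolite.  The design file has columns ``sample_id``,
    ``animal_id``, ``condition`` (``before``/``after``, case-insensitive).
    """
    path, design_path = Path(path), Path(design_path)
    raw = _read_delimited(path)
    if raw.shape[1] < 2:
        raise ValidationError(f"{path}: expected sample-ID column plus metabolites")
    design = _read_delimited(design_path)
    needed = {"sample_id", "animal_id", "condition"}
    if not needed.issubset(design.columns):
        raise ValidationError(
            f"{design_path}: design file needs columns {sorted(needed)}"
        )
    key_by_sample = {
        str(row.sample_id): SampleKey(str(row.animal_id), Condition.parse(row.condition))
        for row in design.itertuples()
    }
    sample_ids = raw.iloc[:, 0].astype(str).tolist()
    unknown = [s for s in sample_ids if s not in key_by_sample]
    if unknown:
        raise ValidationError(f"samples missing from design file: {unknown}")
    values = raw.iloc[:, 1:]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value {values.iat[i, j]!r} at row "
            f"{i + 2} column {values.columns[j]!r}"
        )
    return ConcentrationTable(numeric, [key_by_sample[s] for s in sample_ids])


def write_concentration_table(
    table: ConcentrationTable, path: str | Path, design_path: str | Path
) -> None:
    """Write the table and its design mapping; inverse of the reader."""
    path, design_path = Path(path), Path(design_path)
    ids = [f"{k.animal_id}_{k.condition.value}" for k in table.samples]
    out = table.data.copy()
    out.insert(0, "sample_id", ids)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    out.to_csv(path, sep=sep, index=False)
    design = pd.DataFrame(
        {
            "sample_id": ids,
            "animal_id": [k.animal_id for k in table.samples],
            "condition": [k.condition.value for k in table.samples],
        }
    )
    dsep = "\t" if design_path.suffix.lower() in {".tsv", ".tab"} else ","
    design.to_csv(design_path, sep=dsep, index=False)


def paired_differences(table: ConcentrationTable) -> pd.DataFrame:
    """Within-animal (AFTER − BEFORE) concentration changes.

    Returns a DataFrame of shape (n_animals, n_metabolites) indexed by
    animal.  This matrix is the sole input to the sign-consistency
    prefilter and the paired t-tests.
    """
    before = table.condition_slice(Condition.BEFORE)
    after = table.condition_slice(Condition.AFTER)
    return after - before


def read_pathway_sets(path: str | Path) -> list[PathwaySet]:
    """Parse a GMT file (name, description, tab-separated members)."""
    sets: list[PathwaySet] = []
    names: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        name = fields[0].strip()
        description = fields[1].strip() if len(fields) > 1 else ""
        members = frozenset(tok.strip() for tok in fields[2:] if tok.strip())
        if not name:
            raise ValidationError(f"{path}:{lineno}: pathway with no name")
        if name in names:
            raise ValidationError(f"{path}:{lineno}: duplicate pathway name {name!r}")
        if not members:
            raise ValidationError(f"{path}:{lineno}: empty pathway {name!r}")
        names.add(name)
        sets.append(PathwaySet(name=name, members=members, description=description))
    return sets
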