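"""Reading, validating and writing individual-level lifetime-fecundity tables.

The canonical table is a delimited text file (comma by default, tab accepted)
with one row per individual worm and the columns

    line_id, block, food, replicate, lifetime_fecundity

``line_id`` is a categorical label (an isogenic line), ``block`` a 1-based
experimental block index, ``food`` the food-environment label, ``replicate``
a 1-based within-cell replicate index and ``lifetime_fecundity`` the total
number of viable progeny produced by that individual over its reproductive
life.  Fecundity is stored as a float — the analysis models it with Gaussian
likelihoods — and integer inputs are widened on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("line_id", "block", "food", "replicate", "lifetime_fecundity")

#: Line numbering used in the study's figures (1 = N2 ... 21 = PX179).
LINE_LABELS = {
    1: "N2", 2: "CB4853", 3: "JU1400", 4: "JU1401", 5: "JU1409",
    6: "JU1410", 7: "JU1411", 8: "JU1416", 9: "JU1442", 10: "JU1494",
    11: "JU262", 12: "JU319", 13: "JU345", 14: "JU362", 15: "JU393",
    16: "JU400", 17: "MY1", 18: "MY16", 19: "MY2", 20: "PX174", 21: "PX179",
}


class FormatError(ValueError):
    """Structural problem with an input table (missing column, bad cell)."""


class ValidationError(ValueError):
    """A dataset invariant is violated (negative fecundity, duplicate key)."""


@dataclass(frozen=True)
class Dataset:
    """An immutable collection of lifetime-fecundity observations.

    Wraps a normalized :class:`pandas.DataFrame` with the five required
    columns.  Construction validates the core invariants: non-negative
    fecundity and joint uniqueness of ``(line_id, block, food, replicate)``.

    ``allow_negative`` lifts the non-negativity check; it is set by the
    synthetic generator when zero-truncation is disabled so that simulated
    data follow the Gaussian working model exactly.  Real count data should
    never need it.
    """

    df: pd.DataFrame
    allow_negative: bool = False

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["line_id"] = df["line_id"].astype(str)
        df["food"] = df["food"].astype(str)
        for col in ("block", "replicate"):
            vals = pd.to_numeric(df[col], errors="raise")
            if not np.allclose(vals, np.round(vals)):
                raise FormatError(f"column {col!r} must be integer-valued")
            df[col] = vals.astype(int)
        lf = pd.to_numeric(df["lifetime_fecundity"], errors="coerce")
        bad = lf.isna() & df["lifetime_fecundity"].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"non-numeric lifetime_fecundity at data row {row + 1}: "
                f"{df['lifetime_fecundity'].iloc[row]!r}"
            )
        df["lifetime_fecundity"] = lf.astype(float)
        neg = df["lifetime_fecundity"] < 0
        if neg.any() and not self.allow_negative:
            row = int(np.flatnonzero(neg.to_numpy())[0])
            raise ValidationError(
                f"negative lifetime_fecundity at data row {row + 1}: "
                f"{df['lifetime_fecundity'].iloc[row]}"
            )
        dup = df.duplicated(subset=["line_id", "block", "food", "replicate"])
        if dup.any():
            key = df.loc[dup, ["line_id", "block", "food", "replicate"]].iloc[0]
            raise ValidationError(
                "duplicate observation key (line_id={line_id!r}, block={block}, "
                "food={food!r}, replicate={replicate})".format(**key.to_dict())
            )
        object.__setattr__(self, "df", df.reset_index(drop=True))

    # -- derived design quantities -------------------------------------
    @property
    def n_obs(self) -> int:
        return len(self.df)

    @property
    def lines(self) -> list[str]:
        return sorted(self.df["line_id"].unique(), key=_natural_key)

    @property
    def blocks(self) -> list[int]:
        return sorted(self.df["block"].unique())

    @property
    def foods(self) -> list[str]:
        return sorted(self.df["food"].unique())

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def counts_per_food(self) -> dict[str, int]:
        return self.df.groupby("food").size().to_dict()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.df.equals(other.df)


def _natural_key(label: str):
    """Sort '2' before '10' while keeping arbitrary labels sortable."""
    try:
        return (0, float(label), label)
    except ValueError:
        return (1, 0.0, label)


@dataclass
class ValidationReport:
    """Report-only summary of design balance and invariant violations."""

    per_food: dict[str, dict] = field(default_factory=dict)
    violations: list[str] = field(default_factory=list)

    @property
    def balanced(self) -> bool:
        return all(info["balanced"] for info in self.per_food.values())

    @property
    def ok(self) -> bool:
        return not self.violations


def read_fecundity_table(
    path,
    *,
    sep: str | None = None,
    column_map: dict[str, str] | None = None,
    allow_negative: bool = False,
) -> Dataset:
    """Read a delimited lifetime-fecundity table into a :class:`Dataset`.

    Parameters
    ----------
    path : str or path-like or file-like
        Table location. Comma- and tab-delimited files are auto-detected
        when ``sep`` is None.
    sep : str, optional
        Explicit field delimiter.
    column_map : dict, optional
        Mapping from the file's column names to the required names, so
        tables with other headers (e.g. supplementary material renamed
        columns) can be ingested: ``{"strain": "line_id", ...}``.
    allow_negative : bool
        Accept negative fecundities (untruncated model-exact synthetic
        tables only; real count data must be non-negative).
    """
    if sep is None:
        # sniff comma vs tab from the header line; the C engine with
        # round-trip float parsing keeps write/read cycles lossless
        if hasattr(path, "read"):
            text = path.read()
            header = text.splitlines()[0] if text else ""
            path = io.StringIO(text)
        else:
            with open(path) as fh:
                header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"missing required column(s): {', '.join(missing)} "
            f"(found: {', '.join(map(str, df.columns))})"
        )
    return Dataset(df, allow_negative=allow_negative)


def write_fecundity_table(data: Dataset, path, *, sep: str = ",") -> None:
    """Write a dataset as a delimited table; round-trips through ``read``."""
    df = data.df.copy()
    # integral fecundities are written without a decimal point so that a
    # write/read cycle is byte-stable on count-valued data
    lf = df["lifetime_fecundity"]
    if np.allclose(lf, np.round(lf)):
        df["lifetime_fecundity"] = lf.astype(int)
    try:
        df.to_csv(path, index=False, sep=sep)
    except OSError as exc:
        raise OSError(f"cannot write fecundity table to {path!r}: {exc}") from exc


def validate_dataset(data: Dataset) -> ValidationReport:
    """Check balance of the line × block × replicate design for each food.

    A food is *balanced* when every line appears in every block present for
    that food and all line × block cells hold the same number of replicates.
    The report never raises; violations are listed as strings.
    """
    report = ValidationReport()
    df = data.df
    for food, sub in df.groupby("food"):
        lines = sorted(sub["line_id"].unique(), key=_natural_key)
        blocks = sorted(sub["block"].unique())
        cells = sub.groupby(["line_id", "block"]).size()
        counts = set(cells.values)
        incomplete: list[str] = []
        for line in lines:
            for block in blocks:
                if (line, block) not in cells.index:
                    incomplete.append(f"line {line!r} missing from block {block}")
        if counts and len(counts) > 1:
            ref = int(cells.max())
            for (line, block), n in cells.items():
                if n != ref:
                    incomplete.append(
                        f"incomplete cell: line {line!r} block {block} has "
                        f"{n} replicates (expected {ref})"
                    )
        balanced = not incomplete
        n_rep = int(next(iter(counts))) if len(counts) == 1 else None
        report.per_food[food] = {
            "balanced": balanced,
            "n_obs": int(len(sub)),
            "n_lines": len(lines),
            "n_blocks": len(blocks),
            "n_replicates": n_rep,
            "incomplete_cells": incomplete,
        }
        report.violations.extend(incomplete)
    return report


def split_by_food(data: Dataset) -> dict[str, Dataset]:
    """Partition a dataset by food environment.

    The models are fitted to each food separately, so this is the first
    step of every analysis.  The outputs partition the input exactly: sizes
    sum to the input size and no empty mapping values are emitted.
    """
    if data.n_obs == 0:
        raise ValidationError("cannot split an empty dataset")
    return {
        food: Dataset(sub, allow_negative=data.allow_negative)
        for food, sub in data.df.groupby("food", sort=True)
    }
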