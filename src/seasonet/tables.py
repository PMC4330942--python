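"""Data containers for seasonal metabolite abundance tables and trait series.

The experimental design behind these containers is a year-long monthly
sampling of seeds in three states (dry, germinated, dehydrated), with
replicate metabolite profiles per month and two physiological traits scored
monthly as replicate counts of germinating / surviving seeds out of a fixed
batch size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Experiment timeline: the sampling year runs June through May.
MONTHS = ("Jun", "Jul", "Aug", "Sep", "Oct", "Nov",
          "Dec", "Jan", "Feb", "Mar", "Apr", "May")

#: Months treated as summer / winter for the seasonal contrast; the four
#: remaining months are shoulder months with no planted seasonal shift.
SUMMER_MONTHS = ("Jun", "Jul", "Aug", "Sep")
WINTER_MONTHS = ("Nov", "Dec", "Jan", "Feb")

SEED_STATES = ("dry", "germinated", "dehydrated")

COMPOUND_CLASSES = (
    "amino acid", "sugar", "organic acid", "fatty acid/lipid",
    "phenylpropanoid", "flavonoid", "anthocyanin", "other",
)

TRAITS = ("germination", "survival")

#: Seeds per replicate batch when scoring germination / survival.
TRAIT_BATCH_SIZE = 50


class SchemaError(ValueError):
    """Raised when an input table violates the expected schema."""


def month_order(months: pd.Series | pd.Index) -> pd.Categorical:
    """Return *months* as an ordered categorical on the Jun..May timeline."""
    return pd.Categorical(months, categories=list(MONTHS), ordered=True)


@dataclass
class AbundanceTable:
    """Samples x metabolites matrix of relative abundances with metadata.

    Parameters
    ----------
    values
        DataFrame indexed by a (month, state, replicate) MultiIndex with one
        column per metabolite.  Entries are nonnegative relative peak
        responses; missing measurements are NaN, never silent zeros.
    metabolite_meta
        DataFrame indexed by metabolite name with a ``compound_class``
        column.
    """

    values: pd.DataFrame
    metabolite_meta: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        if not isinstance(idx, pd.MultiIndex) or idx.names != ["month", "state", "replicate"]:
            raise SchemaError(
                "abundance index must be a (month, state, replicate) MultiIndex"
            )
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].tolist()
            raise SchemaError(f"duplicated sample triples: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise SchemaError(f"duplicated metabolite names: {dupes[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise SchemaError("abundance values must be finite (use NaN for missing)")
        missing_meta = self.values.columns.difference(self.metabolite_meta.index)
        if len(missing_meta):
            raise SchemaError(f"metabolites without metadata: {list(missing_meta)[:5]}")

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def months(self) -> list[str]:
        return [m for m in MONTHS if m in set(self.values.index.get_level_values("month"))]

    def for_state(self, state: str) -> "AbundanceTable":
        """Restrict to one seed state (dry / germinated / dehydrated)."""
        if state not in SEED_STATES:
            raise ValueError(f"unknown seed state {state!r}; expected one of {SEED_STATES}")
        sub = self.values.xs(state, level="state", drop_level=False)
        return AbundanceTable(sub, self.metabolite_meta)

    def monthly_means(self) -> pd.DataFrame:
        """Average replicates within each month -> months x metabolites.

        Rows follow the Jun..May timeline.  A single seed state is expected;
        mixing states would average across treatments.
        """
        states = set(self.values.index.get_level_values("state"))
        if len(states) > 1:
            raise ValueError(
                f"monthly_means on multiple states {sorted(states)}; select one with for_state()"
            )
        by_month = self.values.groupby(level="month", observed=True, sort=False).mean()
        order = [m for m in MONTHS if m in by_month.index]
        return by_month.loc[order]

    def compound_class(self, metabolite: str) -> str:
        return str(self.metabolite_meta.loc[metabolite, "compound_class"])


@dataclass
class TraitSeries:
    """Monthly germination / survival outcomes as replicate counts.

    ``counts`` is a long table with columns month, trait, replicate,
    successes; each count is out of ``batch_size`` seeds.
    """

    counts: pd.DataFrame
    batch_size: int = TRAIT_BATCH_SIZE

    def __post_init__(self) -> None:
        required = {"month", "trait", "replicate", "successes"}
        missing = required - set(self.counts.columns)
        if missing:
            raise SchemaError(f"trait table missing columns: {sorted(missing)}")
        bad_trait = set(self.counts["trait"]) - set(TRAITS)
        if bad_trait:
            raise SchemaError(f"unknown traits: {sorted(bad_trait)}")
        s = self.counts["successes"]
        if ((s < 0) | (s > self.batch_size)).any():
            raise SchemaError(f"successes must lie in [0, {self.batch_size}]")
        key = self.counts[["month", "trait", "replicate"]]
        if key.duplicated().any():
            raise SchemaError("duplicated (month, trait, replicate) rows in trait table")

    @property
    def percentages(self) -> pd.DataFrame:
        """Replicate-level percentages (long format, adds a 'percentage' column)."""
        out = self.counts.copy()
        out["percentage"] = 100.0 * out["successes"] / self.batch_size
        return out

    def monthly_percentages(self) -> pd.DataFrame:
        """Months x traits table of mean percentages on the Jun..May timeline."""
        pct = self.percentages
        wide = pct.pivot_table(index="month", columns="trait",
                               values="percentage", aggfunc="mean", observed=True)
        order = [m for m in MONTHS if m in wide.index]
        return wide.loc[order, [t for t in TRAITS if t in wide.columns]]


# ---------------------------------------------------------------------------
# CSV round-trip


def write_abundance_csv(table: AbundanceTable, path: str | Path) -> None:
    if table.values.empty:
        raise ValueError("refusing to write an empty abundance table")
    table.values.to_csv(path)


def write_traits_csv(traits: TraitSeries, path: str | Path) -> None:
    if traits.counts.empty:
        raise ValueError("refusing to write an empty trait table")
    traits.counts.to_csv(path, index=False)


def write_metabolite_meta_csv(table: AbundanceTable, path: str | Path) -> None:
    table.metabolite_meta.to_csv(path, index_label="metabolite")


def read_abundance_csv(path: str | Path,
                       meta_path: str | Path | None = None) -> AbundanceTable:
    """Read a wide abundance CSV (index columns month/state/replicate).

    If *meta_path* is omitted, every metabolite is assigned the compound
    class ``other``.
    """
    df = pd.read_csv(path, index_col=[0, 1, 2])
    df.index.names = ["month", "state", "replicate"]
    df = df.astype(float)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, index_col="metabolite")
    else:
        meta = pd.DataFrame({"compound_class": "other"}, index=df.columns)
    return AbundanceTable(df, meta)


def read_traits_csv(path: str | Path, batch_size: int = TRAIT_BATCH_SIZE) -> TraitSeries:
    df = pd.read_csv(path)
    return TraitSeries(df, batch_size=batch_size)


def validate_inputs(abundance_path: str | Path,
                    traits_path: str | Path,
                    meta_path: str | Path | None = None) -> list[str]:
    """Schema-check input CSVs; return a list of human-readable problems.

    An empty list means the files parse into valid containers.
    """
    errors: list[str] = []
    table = None
    try:
        # pandas mangles duplicated headers on read, so inspect them raw
        import csv
        with open(abundance_path, newline="") as fh:
            header = next(csv.reader(fh), [])
        dupes = {h for h in header[3:] if header[3:].count(h) > 1}
        if dupes:
            errors.append(f"abundance: duplicated metabolite columns {sorted(dupes)}")
        table = read_abundance_csv(abundance_path, meta_path)
    except (SchemaError, ValueError, KeyError, FileNotFoundError) as exc:
        errors.append(f"abundance: {exc}")
    else:
        arr = table.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            errors.append("abundance: negative abundance values present")
        bad_states = set(table.values.index.get_level_values("state")) - set(SEED_STATES)
        if bad_states:
            errors.append(f"abundance: unknown seed states {sorted(bad_states)}")
        bad_months = (set(table.values.index.get_level_values("month")) - set(MONTHS))
        if bad_months:
            errors.append(f"abundance: unknown months {sorted(bad_months)}")
    try:
        traits = read_traits_csv(traits_path)
    except (SchemaError, ValueError, KeyError, FileNotFoundError) as exc:
        errors.append(f"traits: {exc}")
    else:
        pct = traits.percentages["percentage"]
        if ((pct < 0) | (pct > 100)).any():
            errors.append("traits: percentages outside [0, 100]")
        bad_months = set(traits.counts["month"]) - set(MONTHS)
        if bad_months:
            errors.append(f"traits: unknown months {sorted(bad_months)}")
    return errors


def write_ground_truth_json(truth, path: str | Path) -> None:
    """Serialize a GroundTruth dataclass as JSON next to the fixture CSVs."""
    payload = {
        "block_assignment": dict(truth.block_assignment),
        "trait_correlation_signs": {
            f"{trait}|{block}": sign
            for (trait, block), sign in truth.trait_correlation_signs.items()
        },
        "seasonal_means": {m: list(map(float, row))
                           for m, row in truth.seasonal_means.iterrows()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
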