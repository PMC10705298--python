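"""Species trait table: loading, validation, transforms, filtering.

The table holds one row per species with a categorical intersexual-power
label and four continuous predictors:

* ``power`` — MD (male dominant), CD (co-dominant), FD (female dominant)
* ``bmr``   — male/female body mass ratio (> 0)
* ``cr``    — male/female upper-canine crown-height ratio (> 0)
* ``eo``    — expected estrous overlap, percent of time two females in the
  same group are simultaneously in estrus (0-100); stored on the percent
  scale throughout
* ``sr``    — adult males per adult female in a foraging group (> 0)

Missing cells stay missing (NaN); species lacking a predictor are dropped
per-analysis, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesTable",
    "DatasetError",
    "load_species_table",
    "species_table_from_frame",
    "log10_standardize",
    "exclude_extreme_dimorphism",
    "align_to_tree",
    "power_summary",
]

POWER_LABELS = ("MD", "CD", "FD")
LABEL_ALIASES = {
    "M": "MD", "MD": "MD", "MALE": "MD", "MALE-DOMINANT": "MD", "MALE DOMINANT": "MD",
    "C": "CD", "CD": "CD", "CO-DOMINANT": "CD", "CODOMINANT": "CD", "CO DOMINANT": "CD",
    "F": "FD", "FD": "FD", "FEMALE": "FD", "FEMALE-DOMINANT": "FD", "FEMALE DOMINANT": "FD",
}
PREDICTORS = ("bmr", "cr", "eo", "sr")
#: predictors that must be strictly positive ratios
RATIO_PREDICTORS = ("bmr", "cr", "sr")
#: default exclusion threshold: males more than 36% larger than females
DEFAULT_BMR_THRESHOLD = 1.36


class DatasetError(ValueError):
    """Invalid species table contents."""


@dataclass
class Standardization:
    """Parameters of a log10 + z-score transform, kept for reversibility."""

    mean: float
    sd: float

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (np.log10(values) - self.mean) / self.sd

    def invert(self, z: np.ndarray) -> np.ndarray:
        return np.power(10.0, z * self.sd + self.mean)


@dataclass
class SpeciesTable:
    """Validated species trait table backed by a pandas DataFrame."""

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        self.frame = self.frame.reset_index(drop=True)
        _validate_frame(self.frame)

    @property
    def species(self) -> list:
        return list(self.frame["species"])

    def __len__(self) -> int:
        return len(self.frame)

    def predictor(self, name: str, require_power: bool = True) -> pd.DataFrame:
        """Complete cases for one predictor: species, power, value.

        Rows missing the predictor (or the power label, when required) are
        dropped; row order is preserved.
        """
        if name not in PREDICTORS:
            raise DatasetError(f"unknown predictor {name!r}")
        cols = ["species", "power", name]
        sub = self.frame[cols]
        mask = sub[name].notna()
        if require_power:
            mask &= sub["power"].notna()
        return sub[mask].reset_index(drop=True)

    def binary_power(self) -> pd.Series:
        """0/1 coding of the power label: male-biased power (MD) = 1."""
        lab = self.frame["power"]
        out = pd.Series(np.where(lab == "MD", 1.0, 0.0), index=self.frame.index)
        out[lab.isna()] = np.nan
        return out


def _validate_frame(df: pd.DataFrame) -> None:
    required = {"species", "power"} | set(PREDICTORS)
    missing = required - set(df.columns)
    if missing:
        raise DatasetError(f"missing columns: {sorted(missing)}")
    dupes = df["species"][df["species"].duplicated()].tolist()
    if dupes:
        raise DatasetError(f"duplicate species: {sorted(set(dupes))}")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        p = row["power"]
        if pd.notna(p) and p not in POWER_LABELS:
            raise DatasetError(f"line {line}: unknown power label {p!r}")
        for col in RATIO_PREDICTORS:
            v = row[col]
            if pd.notna(v) and v <= 0:
                raise DatasetError(f"line {line}: {col} must be > 0, got {v}")
        eo = row["eo"]
        if pd.notna(eo) and not (0.0 <= eo <= 100.0):
            raise DatasetError(f"line {line}: eo must be in [0, 100], got {eo}")


def _normalize_labels(raw: pd.Series) -> pd.Series:
    def norm(v):
        if pd.isna(v) or str(v).strip() == "":
            return np.nan
        key = str(v).strip().upper()
        if key not in LABEL_ALIASES:
            raise DatasetError(f"unknown power label {v!r}")
        return LABEL_ALIASES[key]

    return raw.map(norm)


def load_species_table(path) -> SpeciesTable:
    """Load and validate a species CSV (columns species, power, bmr, cr, eo, sr)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = ({"species", "power"} | set(PREDICTORS)) - set(df.columns)
    if missing:
        raise DatasetError(f"{path}: missing columns {sorted(missing)}")
    df["power"] = _normalize_labels(df["power"])
    for col in PREDICTORS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return SpeciesTable(df[["species", "power", *PREDICTORS]], provenance=str(path))


def species_table_from_frame(df: pd.DataFrame, provenance: str = "") -> SpeciesTable:
    df = df.copy()
    df["power"] = _normalize_labels(df["power"])
    return SpeciesTable(df, provenance=provenance)


def log10_standardize(values) -> tuple:
    """log10-transform then z-score a positive vector.

    Returns ``(z, Standardization)``; the output has mean 0 and sample
    (ddof=1) SD 1.  Raises on non-positive or constant input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise DatasetError("need a 1-d vector with n >= 2")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise DatasetError("all values must be finite and > 0 for log10")
    lx = np.log10(x)
    mean = float(lx.mean())
    sd = float(lx.std(ddof=1))
    if sd == 0.0:
        raise DatasetError("constant input: zero variance after log10")
    return (lx - mean) / sd, Standardization(mean, sd)


def exclude_extreme_dimorphism(
    table: SpeciesTable, threshold: float = DEFAULT_BMR_THRESHOLD
) -> SpeciesTable:
    """Drop species whose BMR strictly exceeds ``threshold`` (males > 36%
    larger than females at the default); order of survivors preserved."""
    mask = ~(table.frame["bmr"] > threshold)  # keeps NaN-BMR rows
    return SpeciesTable(table.frame[mask], provenance=table.provenance)


def align_to_tree(table: SpeciesTable, tip_labels) -> tuple:
    """Intersect table species with tree tips.

    Returns ``(table restricted to shared species, report dict)``; species
    present in only one source are listed in the report, never silently
    dropped.
    """
    tips = list(tip_labels)
    shared = [s for s in table.species if s in set(tips)]
    report = {
        "shared": shared,
        "table_only": sorted(set(table.species) - set(tips)),
        "tree_only": sorted(set(tips) - set(table.species)),
    }
    sub = table.frame[table.frame["species"].isin(shared)]
    return SpeciesTable(sub, provenance=table.provenance), report


def power_summary(table: SpeciesTable) -> dict:
    """Counts and fractions of each power label (male-biased power = MD)."""
    lab = table.frame["power"].dropna()
    n = len(lab)
    counts = {k: int((lab == k).sum()) for k in POWER_LABELS}
    return {
        "n": n,
        "counts": counts,
        "fraction_md": counts["MD"] / n if n else float("nan"),
    }
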