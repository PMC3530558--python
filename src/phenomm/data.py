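"""Data model and delimited-text I/O for per-animal phenotyping tables.

The atomic unit is one animal's row: identifier, genotype (wildtype or
knockout — zygosity is collapsed, since one mutant genotype is analysed per
line), sex, batch label (the assay day; all animals measured on the same day
share a batch), body weight in grams, and one or more quantitative trait
values.  A :class:`TraitDataset` bundles the mutant and control records for a
single trait of a single mutant line, the unit on which the statistical
pipeline operates.

Batch labels are opaque strings compared for equality only.  When every label
parses as an ISO date the diagnostics layer may order batches temporally;
otherwise first-appearance order is used.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError, ValidationError

WILDTYPE = "wildtype"
KNOCKOUT = "knockout"
FEMALE = "female"
MALE = "male"

#: built-in label synonyms, all matched case-insensitively
GENOTYPE_SYNONYMS = {
    "wildtype": WILDTYPE, "wild-type": WILDTYPE, "wt": WILDTYPE, "+/+": WILDTYPE,
    "control": WILDTYPE,
    "knockout": KNOCKOUT, "ko": KNOCKOUT, "mutant": KNOCKOUT, "-/-": KNOCKOUT,
}
SEX_SYNONYMS = {
    "female": FEMALE, "f": FEMALE,
    "male": MALE, "m": MALE,
}

#: column roles understood by :func:`read_phenotype_table`
_REQUIRED_ROLES = ("animal_id", "genotype", "sex", "batch")


@dataclass
class PhenotypeRecord:
    """One animal's covariates and trait values.

    ``weight`` is body mass in grams; ``None`` means not recorded — such a
    record remains usable for analyses that do not adjust for weight.
    ``traits`` maps trait name to value; a trait missing for this animal is
    simply absent from the mapping (no imputation anywhere in the package).
    """

    animal_id: str
    genotype: str
    sex: str
    batch: str
    weight: float | None = None
    traits: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.genotype not in (WILDTYPE, KNOCKOUT):
            raise ValidationError(
                f"genotype must be '{WILDTYPE}' or '{KNOCKOUT}', got {self.genotype!r}"
            )
        if self.sex not in (FEMALE, MALE):
            raise ValidationError(
                f"sex must be '{FEMALE}' or '{MALE}', got {self.sex!r}"
            )
        if self.weight is not None:
            self.weight = float(self.weight)
            if not np.isfinite(self.weight) or self.weight <= 0:
                raise ValidationError(
                    f"weight must be a positive number of grams, got {self.weight!r} "
                    f"for animal {self.animal_id!r}"
                )

    @property
    def is_knockout(self) -> bool:
        return self.genotype == KNOCKOUT


@dataclass
class TraitDataset:
    """Matched mutant and control records for one trait of one line.

    Every record carries a non-missing value for ``trait_name``.  Construction
    via :func:`build_trait_dataset` guarantees at least one wildtype and one
    knockout record and non-empty batch labels.
    """

    trait_name: str
    line_id: str
    records: list[PhenotypeRecord]

    def __post_init__(self):
        if not self.records:
            raise InsufficientDataError(
                f"trait {self.trait_name!r} of line {self.line_id!r}: no records"
            )
        for r in self.records:
            if not str(r.batch):
                raise ValidationError(
                    f"record {r.animal_id!r} has an empty batch label"
                )

    def ensure_both_genotypes(self) -> "TraitDataset":
        """Raise unless both a wildtype and a knockout record are present.

        Genotype-comparison operations call this; control-only datasets are
        legitimate inputs for reference ranges and control diagnostics.
        """
        if self.n_knockout == 0 or self.n_wildtype == 0:
            raise InsufficientDataError(
                f"trait {self.trait_name!r} of line {self.line_id!r} needs at least "
                f"one wildtype and one knockout record "
                f"(got {self.n_wildtype} wildtype, {self.n_knockout} knockout)"
            )
        return self

    def trait_value(self, record: PhenotypeRecord) -> float:
        if self.trait_name == "weight":
            return float(record.weight)
        return float(record.traits[self.trait_name])

    # -- counts -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_knockout(self) -> int:
        return sum(r.is_knockout for r in self.records)

    @property
    def n_wildtype(self) -> int:
        return len(self.records) - self.n_knockout

    @property
    def batches(self) -> list[str]:
        """Distinct batch labels in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(str(r.batch))
        return list(seen)

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    def counts_by_group(self) -> dict[str, int]:
        """Animal counts per genotype x sex cell, plus batch counts per genotype."""
        out: dict[str, int] = {}
        for geno in (WILDTYPE, KNOCKOUT):
            for sex in (FEMALE, MALE):
                out[f"{geno}_{sex}"] = sum(
                    r.genotype == geno and r.sex == sex for r in self.records
                )
            out[f"{geno}_batches"] = len(
                {r.batch for r in self.records if r.genotype == geno}
            )
        return out

    # -- views ------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Numeric design frame: genotype 0=wildtype/1=knockout, sex 0=female/1=male."""
        return pd.DataFrame(
            {
                "animal_id": [r.animal_id for r in self.records],
                "genotype": [int(r.is_knockout) for r in self.records],
                "sex": [int(r.sex == MALE) for r in self.records],
                "batch": [str(r.batch) for r in self.records],
                "weight": [np.nan if r.weight is None else r.weight for r in self.records],
                "y": [self.trait_value(r) for r in self.records],
            }
        )

    def restrict(self, genotype: str | None = None, sex: str | None = None,
                 require_weight: bool = False) -> list[PhenotypeRecord]:
        out = self.records
        if genotype is not None:
            out = [r for r in out if r.genotype == genotype]
        if sex is not None:
            out = [r for r in out if r.sex == sex]
        if require_weight:
            out = [r for r in out if r.weight is not None]
        return out

    def values(self, genotype: str | None = None, sex: str | None = None) -> np.ndarray:
        return np.array(
            [self.trait_value(r) for r in self.restrict(genotype, sex)], dtype=float
        )


def batch_temporal_order(labels: Sequence[str]) -> list[str]:
    """Order batch labels temporally when they all parse as ISO dates.

    Falls back to first-appearance order otherwise — batch is fundamentally an
    opaque grouping label; calendar structure is a bonus used only by
    time-ordered diagnostics.
    """
    distinct: dict[str, None] = {}
    for lab in labels:
        distinct.setdefault(str(lab))
    labs = list(distinct)
    try:
        parsed = [_dt.date.fromisoformat(lab) for lab in labs]
    except ValueError:
        return labs
    return [lab for _, lab in sorted(zip(parsed, labs))]


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def _canon(label: str, synonyms: Mapping[str, str], extra: Mapping[str, str] | None,
           role: str, row: int):
    key = str(label).strip().lower()
    if extra:
        extra_lower = {str(k).strip().lower(): v for k, v in extra.items()}
        if key in extra_lower:
            return extra_lower[key]
    if key in synonyms:
        return synonyms[key]
    raise ValidationError(
        f"unrecognised {role} label {label!r} in data row {row}"
    )


def read_phenotype_table(
    path,
    column_map: Mapping[str, object] | None = None,
    sep: str | None = None,
) -> list[PhenotypeRecord]:
    """Read a delimited phenotyping table into records.

    Parameters
    ----------
    path : str or pathlib.Path
        UTF-8 text file with one header row; comma- or tab-delimited
        (sniffed when ``sep`` is None).
    column_map : mapping, optional
        Maps column roles to column names so arbitrary LIMS exports can be
        ingested.  Recognised roles: ``animal_id``, ``genotype``, ``sex``,
        ``batch``, ``weight`` (all defaulting to their own name), ``traits``
        (list of trait column names; default: every remaining column), and
        ``genotype_synonyms`` / ``sex_synonyms`` (extra label -> canonical
        value mappings, case-insensitive).

    Returns
    -------
    list of PhenotypeRecord
        One record per row.  Empty weight or trait cells yield missing values,
        not errors; malformed (non-numeric, non-empty) cells raise with the
        offending row number.
    """
    column_map = dict(column_map or {})
    geno_syn = column_map.pop("genotype_synonyms", None)
    sex_syn = column_map.pop("sex_synonyms", None)
    trait_cols = column_map.pop("traits", None)

    df = pd.read_csv(path, sep=sep, engine="python", dtype=str,
                     skipinitialspace=True)
    if df.empty and df.columns.size == 0:
        raise ValidationError(f"input file {path} is empty")

    colname = {role: str(column_map.get(role, role)) for role in
               (*_REQUIRED_ROLES, "weight")}
    for role in _REQUIRED_ROLES:
        if colname[role] not in df.columns:
            raise ConfigurationError(
                f"required column {colname[role]!r} (role {role!r}) "
                f"not found; available columns: {list(df.columns)}"
            )
    has_weight = colname["weight"] in df.columns

    if trait_cols is None:
        reserved = {colname[r] for r in colname}
        trait_cols = [c for c in df.columns if c not in reserved]
    else:
        trait_cols = [str(c) for c in trait_cols]
        for c in trait_cols:
            if c not in df.columns:
                raise ConfigurationError(f"trait column {c!r} not found")

    def _num(cell, col: str, row: int) -> float | None:
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return None
        s = str(cell).strip()
        if s == "" or s.lower() in ("na", "nan"):
            return None
        try:
            return float(s)
        except ValueError:
            raise ValidationError(
                f"malformed numeric value {cell!r} in column {col!r}, data row {row}"
            ) from None

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        traits = {}
        for c in trait_cols:
            v = _num(rowd[c], c, i)
            if v is not None:
                traits[c] = v
        records.append(PhenotypeRecord(
            animal_id=str(rowd[colname["animal_id"]]),
            genotype=_canon(rowd[colname["genotype"]], GENOTYPE_SYNONYMS, geno_syn,
                            "genotype", i),
            sex=_canon(rowd[colname["sex"]], SEX_SYNONYMS, sex_syn, "sex", i),
            batch=str(rowd[colname["batch"]]),
            weight=_num(rowd[colname["weight"]], colname["weight"], i)
            if has_weight else None,
            traits=traits,
        ))
    return records


def write_phenotype_table(records: Iterable[PhenotypeRecord], path, sep: str = ",") -> None:
    """Write records in the normalized column order.

    Columns: animal_id, genotype, sex, batch, weight, then traits
    alphabetically.  Missing values are written as empty cells so the file
    round-trips through :func:`read_phenotype_table`.
    """
    records = list(records)
    trait_names = sorted({t for r in records for t in r.traits})
    rows = []
    for r in records:
        row = {
            "animal_id": r.animal_id, "genotype": r.genotype, "sex": r.sex,
            "batch": r.batch,
            "weight": "" if r.weight is None else repr(r.weight),
        }
        for t in trait_names:
            row[t] = repr(r.traits[t]) if t in r.traits else ""
        rows.append(row)
    pd.DataFrame(rows, columns=["animal_id", "genotype", "sex", "batch", "weight",
                                *trait_names]).to_csv(path, sep=sep, index=False)


def build_trait_dataset(
    records: Iterable[PhenotypeRecord], trait_name: str, line_id: str = "",
    require_both_genotypes: bool = True,
) -> TraitDataset:
    """Assemble the analysis unit for one trait: records with that trait present.

    ``trait_name="weight"`` selects body weight itself as the dependent
    variable (records with recorded weight).  Raises
    :class:`InsufficientDataError` when either genotype group is empty after
    filtering (unless ``require_both_genotypes=False``, for control-only
    datasets), and :class:`ValidationError` when the trait appears nowhere.
    """
    records = list(records)
    if trait_name == "weight":
        kept = [r for r in records if r.weight is not None]
    else:
        kept = [r for r in records if trait_name in r.traits]
    if not kept:
        raise ValidationError(
            f"trait {trait_name!r} not present in any of {len(records)} records"
        )
    ds = TraitDataset(trait_name=trait_name, line_id=line_id, records=kept)
    if require_both_genotypes:
        ds.ensure_both_genotypes()
    return ds
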